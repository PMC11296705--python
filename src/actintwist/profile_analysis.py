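"""Longitudinal section-profile analytics for filament height maps.

The observables of helical twist in AFM topographs are read off a height
profile taken along the filament axis: *major* peaks are the crossover
points of the two long-pitch strands (their spacing is the half-helical
pitch, HHP), and *minor* peaks are individual protomer pairs in between.
The mean axial distance (MAD) of a half helix is its HHP divided by the
number of protomer pairs counted inside it.

Peak detection is deterministic: candidate maxima are scored by prominence
and a dynamic program selects the chain of peaks whose successive gaps lie
inside the admissible minor-pitch window (3–6.6 nm by default), maximising
total prominence with leftmost tie-breaking.  Crossover (major) points are
the maxima of a long-period low-pass envelope of the profile, refined to
sub-sample precision.

All distances in nm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from scipy.interpolate import interp1d

from .pseudo_afm import HeightMap

#: resampling step for uniform-grid spectral and peak operations, nm
RESAMPLE_STEP_NM = 0.5

#: fixed 3x3 Laplacian kernel applied after Gaussian smoothing
LAPLACIAN_KERNEL = np.array([[-1.0, -1.0, -1.0],
                             [-1.0, 8.0, -1.0],
                             [-1.0, -1.0, -1.0]])


@dataclass
class SectionProfile:
    """Arc-length-parameterized height profile along a section line."""

    distance: np.ndarray      # nm, strictly increasing
    height: np.ndarray        # nm
    band_half_width: float = 3.0
    frame_id: int | None = None

    def __post_init__(self) -> None:
        self.distance = np.asarray(self.distance, float)
        self.height = np.asarray(self.height, float)
        if self.distance.shape != self.height.shape:
            raise ValueError("distance and height must have equal length")
        if np.any(np.diff(self.distance) <= 0):
            raise ValueError("distance must be strictly increasing")

    def __len__(self) -> int:
        return len(self.distance)

    @property
    def step(self) -> float:
        return float(np.median(np.diff(self.distance)))

    def resampled(self, step: float = RESAMPLE_STEP_NM) -> "SectionProfile":
        """Linear-interpolation resample onto a uniform grid."""
        d = np.arange(self.distance[0], self.distance[-1] + step / 2, step)
        f = interp1d(self.distance, self.height, kind="linear",
                     bounds_error=False, fill_value=(self.height[0], self.height[-1]))
        return SectionProfile(d, f(d), self.band_half_width, self.frame_id)


@dataclass
class PeakSet:
    """Detected crossover (major) and protomer (minor) peak positions, nm."""

    major_peaks: np.ndarray
    minor_peaks: np.ndarray
    prominences: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.major_peaks = np.sort(np.asarray(self.major_peaks, float))
        self.minor_peaks = np.sort(np.asarray(self.minor_peaks, float))

    @property
    def all_peaks(self) -> np.ndarray:
        return np.sort(np.concatenate([self.major_peaks, self.minor_peaks]))


@dataclass
class HalfHelixMeasurement:
    """One half helix: pitch, counted protomer pairs, and derived MAD."""

    hhp: float               # nm
    protomer_pairs: float    # integer + 0.5
    side: str | None = None  # optional PE/BE label
    frame_id: int | None = None

    @property
    def mad(self) -> float:
        return self.hhp / self.protomer_pairs


# ---------------------------------------------------------------------------
# Profile extraction and filtering
# ---------------------------------------------------------------------------

def extract_profile(hmap: HeightMap, polyline: np.ndarray,
                    half_width: float = 3.0,
                    step: float | None = None,
                    frame_id: int | None = None,
                    zero_offset: bool = True) -> SectionProfile:
    """Band-averaged height profile along a polyline.

    At each arc-length sample the height is averaged over a segment of
    ``±half_width`` nm perpendicular to the local line direction (bilinear
    interpolation between pixel centres).  The profile offset is set to
    zero at the lowest height along the line, mirroring how AFM line
    profiles are referenced.
    """
    polyline = np.asarray(polyline, float).reshape(-1, 2)
    if len(polyline) < 2:
        raise ValueError("polyline needs at least two points")
    x_lo, y_lo = hmap.origin
    x_hi = x_lo + (hmap.shape[1] - 1) * hmap.pixel_size_xy
    y_hi = y_lo + (hmap.shape[0] - 1) * hmap.pixel_size_xy
    if (polyline[:, 0].min() < x_lo - 1e-9 or polyline[:, 0].max() > x_hi + 1e-9
            or polyline[:, 1].min() < y_lo - 1e-9 or polyline[:, 1].max() > y_hi + 1e-9):
        raise ValueError("out of bounds: polyline outside map extent")
    if step is None:
        step = hmap.pixel_size_xy / 2.0

    seg = np.diff(polyline, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = arc[-1]
    s = np.arange(0.0, total + step / 2, step)
    # position and unit tangent at each arc-length sample
    px = np.interp(s, arc, polyline[:, 0])
    py = np.interp(s, arc, polyline[:, 1])
    seg_idx = np.clip(np.searchsorted(arc, s, side="right") - 1, 0, len(seg) - 1)
    tang = seg[seg_idx] / seg_len[seg_idx, None]
    norm = np.stack([-tang[:, 1], tang[:, 0]], axis=1)

    offsets = np.arange(-half_width, half_width + 1e-9, step)
    # sample points: (n_samples, n_offsets, 2)
    pts_x = px[:, None] + norm[:, 0:1] * offsets[None, :]
    pts_y = py[:, None] + norm[:, 1:2] * offsets[None, :]
    rows = (pts_y - y_lo) / hmap.pixel_size_xy
    cols = (pts_x - x_lo) / hmap.pixel_size_xy
    vals = ndimage.map_coordinates(hmap.heights, [rows.ravel(), cols.ravel()],
                                   order=1, mode="nearest")
    vals = vals.reshape(pts_x.shape)
    # trapezoid-weighted band average (converges to the continuous mean),
    # restricted to offsets that stay inside the map
    inside = ((rows >= 0) & (rows <= hmap.shape[0] - 1)
              & (cols >= 0) & (cols <= hmap.shape[1] - 1))
    w = np.ones(len(offsets))
    w[0] = w[-1] = 0.5
    wgrid = np.where(inside, w[None, :], 0.0)
    with np.errstate(invalid="ignore"):
        height = np.sum(np.where(inside, vals, 0.0) * wgrid, axis=1) \
            / np.maximum(wgrid.sum(axis=1), 1e-12)
    if zero_offset:
        height = height - np.nanmin(height)
    return SectionProfile(distance=s, height=height,
                          band_half_width=half_width, frame_id=frame_id)


def log_filter(hmap: HeightMap, sigma_px: float = 1.27) -> HeightMap:
    """Laplacian-of-Gaussian high-pass filter for protomer visualisation.

    Gaussian blur (sigma in pixels) followed by the fixed 3x3 Laplacian
    kernel.  Output is for peak enhancement and display only — the filtered
    values are not heights.
    """
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    smoothed = ndimage.gaussian_filter(hmap.heights, sigma=sigma_px, mode="nearest")
    filtered = ndimage.convolve(smoothed, LAPLACIAN_KERNEL, mode="nearest")
    meta = dict(hmap.metadata)
    meta["filtered"] = {"type": "LoG", "sigma_px": sigma_px}
    return HeightMap(filtered, hmap.pixel_size_xy, hmap.origin, meta)


def gaussian_smooth(hmap: HeightMap, sigma_nm: float = 0.76) -> HeightMap:
    """Gaussian noise-reduction smoothing with sigma given in nm."""
    sigma_px = sigma_nm / hmap.pixel_size_xy
    out = ndimage.gaussian_filter(hmap.heights, sigma=sigma_px, mode="nearest")
    return HeightMap(out, hmap.pixel_size_xy, hmap.origin, dict(hmap.metadata))


def bandpass_profile(p: SectionProfile, pass_band_nm: tuple[float, float] = (5.0, 8.0),
                     keep_mean: bool = False) -> SectionProfile:
    """Brick-wall FFT bandpass on spatial period.

    Fourier components whose period (nm) lies outside ``pass_band_nm`` are
    zeroed; the mean is removed (unless ``keep_mean``).
    """
    low, high = pass_band_nm
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    p = p.resampled()
    step = p.step
    h = p.height - p.height.mean()
    spec = np.fft.rfft(h)
    freqs = np.fft.rfftfreq(len(h), d=step)  # cycles per nm
    with np.errstate(divide="ignore"):
        periods = np.where(freqs > 0, 1.0 / np.maximum(freqs, 1e-30), np.inf)
    keep = (periods >= low) & (periods <= high)
    if not np.any(keep):
        raise ValueError("empty band: no representable frequency in pass band")
    spec[~keep] = 0.0
    out = np.fft.irfft(spec, n=len(h))
    if keep_mean:
        out = out + p.height.mean()
    return SectionProfile(p.distance.copy(), out, p.band_half_width, p.frame_id)


def lowpass_profile(p: SectionProfile, min_period_nm: float = 15.0) -> SectionProfile:
    """Keep only components with period above ``min_period_nm`` (plus mean).

    The profile is reflection-padded by one cutoff period before the
    brick-wall filter, which suppresses the edge ringing a circular FFT
    would otherwise put within a period of the profile ends.
    """
    p = p.resampled()
    h = p.height - p.height.mean()
    pad = min(int(round(min_period_nm / p.step)), len(h) - 1)
    hp = np.concatenate([h[pad:0:-1], h, h[-2:-2 - pad:-1]]) if pad > 0 else h
    spec = np.fft.rfft(hp)
    freqs = np.fft.rfftfreq(len(hp), d=p.step)
    spec[freqs > 1.0 / min_period_nm] = 0.0
    out = np.fft.irfft(spec, n=len(hp))
    if pad > 0:
        out = out[pad:pad + len(h)]
    out = out + p.height.mean()
    return SectionProfile(p.distance.copy(), out, p.band_half_width, p.frame_id)


# ---------------------------------------------------------------------------
# Peak detection
# ---------------------------------------------------------------------------

def _best_chain(positions: np.ndarray, prominences: np.ndarray,
                gap_min: float, gap_max: float) -> list[int]:
    """Maximum-total-prominence chain with successive gaps in [gap_min, gap_max].

    O(n²) dynamic program over candidates sorted by position; ties broken
    toward the leftmost (earliest) predecessor, making the selection
    deterministic.
    """
    n = len(positions)
    if n == 0:
        return []
    best = prominences.copy()       # best chain score ending at i
    prev = np.full(n, -1, dtype=int)
    for i in range(n):
        for j in range(i):
            gap = positions[i] - positions[j]
            if gap > gap_max:
                continue
            if gap < gap_min:
                continue
            cand = best[j] + prominences[i]
            if cand > best[i] + 1e-12:
                best[i] = cand
                prev[i] = j
    end = int(np.argmax(best))
    chain = []
    while end >= 0:
        chain.append(end)
        end = prev[end]
    return chain[::-1]


def _select_peak_chains(positions: np.ndarray, prominences: np.ndarray,
                        gap_min: float, gap_max: float) -> np.ndarray:
    """Union of admissible peak chains, deterministic.

    The best chain is selected first; remaining candidates that are not
    within ``gap_min`` of an already-selected peak form further chains
    (two peaks or more), covering stretches the first chain could not
    reach across a single out-of-window gap.  Candidates closer than
    ``gap_min`` to any selected peak are rejected — the lower bound of the
    minor-pitch window is what discards spurious bumps riding on a true
    peak's flank.
    """
    selected: list[float] = []
    avail = np.ones(len(positions), dtype=bool)
    first_round = True
    while True:
        idx_avail = np.flatnonzero(avail)
        if len(idx_avail) == 0:
            break
        chain_local = _best_chain(positions[idx_avail], prominences[idx_avail],
                                  gap_min, gap_max)
        chain = idx_avail[np.asarray(chain_local, dtype=int)]
        if len(chain) < (1 if first_round else 2):
            break
        selected.extend(positions[chain].tolist())
        sel_arr = np.array(selected)
        for i in idx_avail:
            if np.min(np.abs(positions[i] - sel_arr)) < gap_min:
                avail[i] = False
        if first_round and len(chain) < 2:
            break
        first_round = False
    return np.sort(np.array(selected))


def detect_peaks(p: SectionProfile,
                 minor_pitch_nm: tuple[float, float] = (3.0, 6.6),
                 min_major_pitch_nm: float = 15.0,
                 max_major_pitch_warn_nm: float = 25.0,
                 band_nm: tuple[float, float] | None = None,
                 prominence: float | None = None) -> PeakSet:
    """Detect crossover (major) and protomer (minor) peaks on a profile.

    Candidate maxima are found by prominence (optionally on the profile
    band-filtered to ``band_nm``); a dynamic program keeps chains of peaks
    whose successive gaps lie inside the minor-pitch window, rejecting
    spurious bumps closer than the window's lower bound to a kept peak.
    Major peaks are the kept peaks nearest the maxima of the long-period
    (> ``min_major_pitch_nm``) low-pass envelope, subject to a minimum
    major gap; a gap far above ``max_major_pitch_warn_nm`` triggers a
    warning (the admissible range for a *minimum* major pitch tops out
    there).
    """
    p = p.resampled()
    step = p.step
    if band_nm is not None and len(p) * step > 2 * band_nm[1]:
        h = bandpass_profile(p, band_nm).height
    else:
        h = p.height - p.height.mean()
    if prominence is None:
        span = float(h.max() - h.min())
        prominence = 0.02 * span if span > 0 else 0.0
    if prominence <= 0 or len(p) < 4:
        return PeakSet(np.array([]), np.array([]))
    idx, props = signal.find_peaks(h, prominence=prominence)
    if len(idx) == 0:
        return PeakSet(np.array([]), np.array([]))
    positions = p.distance[idx]
    proms = props["prominences"]
    kept_pos = _select_peak_chains(positions, proms,
                                   minor_pitch_nm[0], minor_pitch_nm[1])
    if len(kept_pos) == 0:
        return PeakSet(np.array([]), np.array([]))
    prom_of = dict(zip(positions.tolist(), proms.tolist()))
    kept_prom = np.array([prom_of[pos] for pos in kept_pos])

    # crossover points: maxima of the long-period envelope, refined to
    # sub-sample precision by a local quadratic fit.  Envelope maxima are
    # used directly (not snapped to the tallest nearby bump) because the
    # crossover phase of a helical filament is carried by the envelope; the
    # tallest protomer bump near a crossover jitters by several nm.  The
    # envelope keeps only periods above the top of the admissible
    # minimum-major-pitch range, isolating the half-helix fundamental from
    # its harmonics.  Maxima within one minimum major pitch of the profile
    # ends are discarded (a crossover there cannot be confirmed).
    lp = lowpass_profile(p, min_period_nm=max_major_pitch_warn_nm)
    min_dist_samples = max(int(min_major_pitch_nm / step), 1)
    env_idx, _ = signal.find_peaks(lp.height, distance=min_dist_samples)
    edge_margin = min_major_pitch_nm
    majors: list[float] = []
    for ei in env_idx:
        pos = lp.distance[ei]
        if pos < lp.distance[0] + edge_margin or pos > lp.distance[-1] - edge_margin:
            continue
        if 0 < ei < len(lp.height) - 1:
            y0, y1, y2 = lp.height[ei - 1:ei + 2]
            denom = y0 - 2 * y1 + y2
            if abs(denom) > 1e-12:
                pos = pos + float(np.clip(0.5 * (y0 - y2) / denom, -1, 1)) * step
        # a crossover must be supported by a detected peak nearby
        if np.min(np.abs(kept_pos - pos)) <= minor_pitch_nm[1]:
            majors.append(pos)
    majors_arr = np.array(majors)
    # enforce the minimum major pitch deterministically (drop the later of
    # any too-close pair)
    if len(majors_arr) > 1:
        filtered = [majors_arr[0]]
        for m in majors_arr[1:]:
            if m - filtered[-1] >= min_major_pitch_nm:
                filtered.append(m)
        majors_arr = np.array(filtered)
    gaps = np.diff(majors_arr)
    if np.any(gaps > max_major_pitch_warn_nm * 2):
        warnings.warn("major-peak gap far above the admissible minimum-pitch "
                      "range; crossover detection may have missed peaks",
                      stacklevel=2)
    minor_mask = ~np.isin(kept_pos, majors_arr)
    return PeakSet(major_peaks=majors_arr, minor_peaks=kept_pos[minor_mask],
                   prominences={float(pos): float(pr)
                                for pos, pr in zip(kept_pos, kept_prom)})


def measure_half_helices(peaks: PeakSet, frame_id: int | None = None,
                         ) -> list[HalfHelixMeasurement]:
    """HHP, protomer-pair count and MAD for each consecutive crossover pair.

    For crossovers (m_i, m_{i+1}): hhp = m_{i+1} - m_i, and the pair count
    is the number of peaks (major + minor) in the half-open interval from
    m_i to m_{i+1} minus 0.5 — the counting convention that yields 6.5
    pairs for the canonical 13-protomer half helix.

    The protomer-peak lattice carries a phase relative to the crossover
    points, and a peak that localises within a fraction of a pixel of a
    counting boundary would flip between adjacent half helices.  To make
    membership jitter-proof, the counting boundaries are placed half a
    minor pitch below the typical peak phase: with g the median minor gap
    and phi the median offset of the peak nearest each crossover, the
    boundary for crossover m_i sits at m_i + phi - g/2 — maximally far
    from every peak whatever the lattice phase.  The reported hhp is still
    the crossover-to-crossover distance.
    """
    majors = peaks.major_peaks
    if len(majors) < 2:
        return []
    allp = peaks.all_peaks
    minors = peaks.minor_peaks
    # lattice gap and crossover phase
    gaps = np.diff(np.sort(minors)) if len(minors) > 1 else np.diff(np.sort(allp))
    g = float(np.median(gaps)) if len(gaps) else 0.0
    if g > 0 and len(minors):
        # circular mean of the peak phase at the crossovers (offsets are
        # only defined modulo the lattice gap g)
        offsets = []
        for m in majors:
            d = minors - m
            offsets.append(d[np.argmin(np.abs(d))] % g)
        ang = 2 * np.pi * np.asarray(offsets) / g
        phi = (np.arctan2(np.sin(ang).sum(), np.cos(ang).sum())
               / (2 * np.pi) * g) % g
        shift = phi - g / 2.0
    else:
        shift = 0.0
    out = []
    for m0, m1 in zip(majors[:-1], majors[1:]):
        count = int(np.sum((allp >= m0 + shift) & (allp < m1 + shift)))
        pairs = count - 0.5
        if pairs <= 0:
            continue
        out.append(HalfHelixMeasurement(hhp=float(m1 - m0), protomer_pairs=pairs,
                                        frame_id=frame_id))
    return out


def classify_decoration(peak_heights: np.ndarray,
                        delta_height_nm: float = 1.3,
                        reference_height_nm: float | None = None) -> np.ndarray:
    """Threshold utility to split decorated (cofilactin) from bare segments.

    Cofilactin crossovers run ~1–1.6 nm taller than bare actin; peaks more
    than ``delta_height_nm`` above the reference (default: the lowest peak)
    are labelled decorated.
    """
    peak_heights = np.asarray(peak_heights, float)
    if reference_height_nm is None:
        reference_height_nm = float(peak_heights.min()) if len(peak_heights) else 0.0
    return np.where(peak_heights - reference_height_nm >= delta_height_nm,
                    "decorated", "bare")


# ---------------------------------------------------------------------------
# Axial-distance time series
# ---------------------------------------------------------------------------

def track_ad_series(frames: list[HeightMap], polylines: list[np.ndarray],
                    minor_pitch_nm: tuple[float, float] = (3.0, 6.6),
                    min_major_pitch_nm: float = 15.0,
                    half_width: float = 3.0,
                    band_nm: tuple[float, float] | None = None,
                    max_pairs: int | None = None):
    """Per-pair axial distances across a movie of height maps.

    For each frame the minor-peak gaps along the profile are indexed by
    protomer-pair number via nearest-neighbour matching of gap midpoints to
    the previous frame; unmatched pairs are recorded as gaps (NaN), never
    zeros.  Frames where over half the established pairs go missing are
    flagged.  Returns an :class:`actintwist.correlation.ADTimeSeries`.
    """
    from .correlation import ADTimeSeries

    mids_prev: np.ndarray | None = None
    rows: list[np.ndarray] = []
    flagged: list[int] = []
    n_pairs = 0
    per_frame: list[tuple[np.ndarray, np.ndarray]] = []
    for hmap, line in zip(frames, polylines):
        prof = extract_profile(hmap, line, half_width=half_width)
        if band_nm is not None:
            prof = bandpass_profile(prof, band_nm)
        peaks = detect_peaks(prof, minor_pitch_nm, min_major_pitch_nm)
        pos = peaks.all_peaks
        gaps = np.diff(pos)
        ok = (gaps >= minor_pitch_nm[0]) & (gaps <= minor_pitch_nm[1])
        mids = (pos[:-1] + pos[1:])[ok] / 2.0
        per_frame.append((mids, gaps[ok]))
        n_pairs = max(n_pairs, len(mids))
    if max_pairs is not None:
        n_pairs = min(n_pairs, max_pairs)

    for t, (mids, gaps) in enumerate(per_frame):
        row = np.full(n_pairs, np.nan)
        if mids_prev is None:
            k = min(len(gaps), n_pairs)
            row[:k] = gaps[:k]
            if len(mids):
                mids_prev = mids[:n_pairs]
        else:
            for m, g in zip(mids, gaps):
                j = int(np.argmin(np.abs(mids_prev - m))) if len(mids_prev) else 0
                if len(mids_prev) and abs(mids_prev[j] - m) <= minor_pitch_nm[1] / 2:
                    if j < n_pairs and np.isnan(row[j]):
                        row[j] = g
            matched = np.sum(~np.isnan(row))
            if matched < 0.5 * n_pairs:
                flagged.append(t)
        rows.append(row)
    values = np.array(rows).T  # (pairs, frames)
    return ADTimeSeries(values=values, frame_interval=1.0, flagged_frames=flagged)
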