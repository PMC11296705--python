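"""Autocorrelation analytics for protomer spacing and height profiles.

Two complementary views of filament dynamics:

* **Temporal**: the axial distance (AD) between adjacent protomers on the
  same long-pitch strand, tracked per protomer pair over a movie, is
  autocorrelated in time and fitted with a second-order exponential decay
  ``a1 exp(-t/t1) + a2 exp(-t/t2) + y0`` — the two time constants separate
  a fast (sub-second) and a slow (seconds) relaxation of the local twist.

* **Spatial**: the protomer-height profile along the filament ridgeline is
  band-filtered to the protomer periodicity (5–8 nm), autocorrelated via
  the Wiener–Khinchin theorem (inverse FFT of the power spectrum), and the
  ACF is fitted with an exponentially decaying sinusoid

      rho(d) = exp(-d/D1) [ D2 cos(d/D3 + g1) + D4 sin(d/D5 + g2)
                            + D6 cos(d/D7 + g3) + D8 sin(d/D9 + g4) ]

  whose decay constant D1 measures how far protomer-height similarity
  persists along the filament.  The fit minimises mean squared error with
  a Nadam (Nesterov-accelerated adaptive moment) gradient descent, with
  seeded multi-start and box constraints; the Hilbert envelope of the ACF
  initialises D1.

The temporal ACF estimator is the standard biased form

    ACF(k) = sum_{i=1..n-k} (y_i - ym)(y_{i+k} - ym) / sum_i (y_i - ym)^2

so ACF(0) = 1 and |ACF(k)| <= 1.  Gaps (NaN) are handled with
pairwise-complete products rescaled to the full-length sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline
from scipy.optimize import curve_fit

from .profile_analysis import SectionProfile, RESAMPLE_STEP_NM
from .pseudo_afm import HeightMap


class ZeroVarianceError(ValueError):
    """Series is constant: the autocorrelation is undefined."""


class FitFailedError(RuntimeError):
    """No optimizer start converged to a finite solution."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ADTimeSeries:
    """Axial-distance series per protomer pair over frames; NaN marks gaps."""

    values: np.ndarray        # (n_pairs, n_frames) nm
    frame_interval: float     # seconds
    flagged_frames: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, float))
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_pairs(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def pair(self, index: int) -> np.ndarray:
        return self.values[index]


@dataclass
class ACFCurve:
    """Lag-indexed autocorrelation; lag in seconds (temporal) or nm (spatial)."""

    lag: np.ndarray
    coefficient: np.ndarray

    def __post_init__(self) -> None:
        self.lag = np.asarray(self.lag, float)
        self.coefficient = np.asarray(self.coefficient, float)
        if self.lag.shape != self.coefficient.shape:
            raise ValueError("lag and coefficient must have equal length")


@dataclass
class DecayFit:
    """Second-order exponential decay fit, time constants ordered t1 <= t2."""

    t1: float
    t2: float
    a1: float
    a2: float
    y0: float
    rss: float
    effectively_single: bool = False

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        return self.a1 * np.exp(-t / self.t1) + self.a2 * np.exp(-t / self.t2) + self.y0


@dataclass
class SinusoidFit:
    """Decaying-sinusoid fit parameters; D1 is the decay constant in nm."""

    params: np.ndarray  # [D1, D2..D9, g1..g4]
    mse: float
    converged: bool = True

    @property
    def D1(self) -> float:
        return float(self.params[0])

    def predict(self, d: np.ndarray) -> np.ndarray:
        return decaying_sinusoid(np.asarray(d, float), *self.params)


# ---------------------------------------------------------------------------
# Temporal ACF
# ---------------------------------------------------------------------------

def temporal_acf(series: np.ndarray, frame_interval: float = 1.0,
                 k_max: int | None = None,
                 max_gap_fraction: float = 0.3) -> ACFCurve:
    """Biased autocorrelation of one pair's AD sequence.

    NaN entries are treated as gaps: products and squares are summed over
    complete pairs only and rescaled by the nominal/valid count ratio, so
    the gap-free case reduces exactly to the standard biased estimator.
    """
    y = np.asarray(series, float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 observations")
    valid = ~np.isnan(y)
    n_valid = int(valid.sum())
    if n_valid < 3:
        raise ValueError("need at least 3 valid observations")
    gap_fraction = 1.0 - n_valid / n
    if gap_fraction > max_gap_fraction:
        import warnings

        warnings.warn(f"series has {gap_fraction:.0%} gaps; ACF estimate "
                      "may be unreliable", stacklevel=2)
    ym = np.nanmean(y)
    dev = y - ym
    denom_sum = np.nansum(dev ** 2)
    if denom_sum < 1e-14:
        raise ZeroVarianceError("zero variance: constant series")
    denom = denom_sum * (n / n_valid)
    if k_max is None:
        k_max = n // 2
    k_max = min(k_max, n - 1)
    coeffs = np.empty(k_max + 1)
    for k in range(k_max + 1):
        a, b = dev[: n - k], dev[k:]
        pair_ok = valid[: n - k] & valid[k:]
        m_k = int(pair_ok.sum())
        if m_k == 0:
            coeffs[k] = np.nan
            continue
        num = np.sum(a[pair_ok] * b[pair_ok]) * ((n - k) / m_k)
        coeffs[k] = num / denom
    lags = np.arange(k_max + 1) * frame_interval
    return ACFCurve(lag=lags, coefficient=coeffs)


def _expdec2(t, a1, t1, a2, t2, y0):
    return a1 * np.exp(-t / t1) + a2 * np.exp(-t / t2) + y0


def fit_expdec2(curve: ACFCurve, n_starts: int = 8, seed: int = 0,
                n_eff: int | None = None, y0_bound: float = 0.05) -> DecayFit:
    """Least-squares second-order exponential decay fit with multi-start.

    Two statistical guards make the close-time-constant problem
    identifiable on noisy ACF estimates:

    * the fit window is restricted to the head of the curve — lags past
      the point where |ACF| has stayed under its sampling-noise floor
      (~2/sqrt(n_eff)) for several consecutive lags carry no decay
      information; ``n_eff`` is the effective number of observations
      behind the curve (defaults to twice the lag count);
    * residuals are weighted by the Bartlett large-lag standard error of
      an autocorrelation estimate, and the constant offset y0 is tightly
      bounded (default ±0.05) because the ACF of a stationary series
      decays to zero — a loose offset absorbs the slow component.

    Starts spread the two time constants log-uniformly over the fit
    window; the best (lowest weighted RSS) converged start wins.  Time
    constants are reported in canonical order t1 <= t2; a fit where the
    second component is negligible or the constants coincide is flagged
    ``effectively_single``.
    """
    t = curve.lag
    y = curve.coefficient
    ok = np.isfinite(y)
    t, y = t[ok], y[ok]
    if len(t) < 6:
        raise ValueError("need at least 6 lag points")
    if n_eff is None:
        n_eff = 2 * len(t)
    # Bartlett standard error of r_k under an AR-ish null
    var = np.cumsum(np.concatenate([[0.0], 2 * y[:-1] ** 2])) / n_eff + 1.0 / n_eff
    sigma = np.sqrt(var)
    floor = 2.0 / np.sqrt(max(n_eff, 4))
    below = np.abs(y) < floor
    run = 0
    cut = len(t)
    for k in range(len(t)):
        run = run + 1 if below[k] else 0
        if run >= 5:
            cut = k + 1
            break
    cut = max(cut, 12)
    t, y, sigma = t[:cut], y[:cut], sigma[:cut]
    if len(t) < 6:
        raise ValueError("need at least 6 lag points")
    span = max(t[-1], 1e-6)
    rng = np.random.default_rng(seed)
    best = None
    t_lo = max(t[1] - t[0], 1e-6) / 2 if len(t) > 1 else 1e-3
    for _ in range(n_starts):
        lt1, lt2 = np.sort(rng.uniform(np.log(t_lo), np.log(span), size=2))
        p0 = [0.6, float(np.exp(lt1)), 0.4, float(np.exp(lt2)), 0.0]
        try:
            popt, _ = curve_fit(
                _expdec2, t, y, p0=p0, sigma=sigma, maxfev=20000,
                bounds=([-2, t_lo / 10, -2, t_lo / 10, -y0_bound],
                        [2, span * 100, 2, span * 100, y0_bound]))
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum(((_expdec2(t, *popt) - y) / sigma) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        raise FitFailedError("fit failed: no start converged")
    rss, (a1, t1, a2, t2, y0) = best
    if t2 < t1:
        a1, t1, a2, t2 = a2, t2, a1, t1
    single = (abs(a2) < 0.05 * max(abs(a1), 1e-12)) or (t2 / max(t1, 1e-12) < 1.5)
    return DecayFit(t1=float(t1), t2=float(t2), a1=float(a1), a2=float(a2),
                    y0=float(y0), rss=rss, effectively_single=bool(single))


def mean_acf(curves: list[ACFCurve]) -> ACFCurve:
    """Average several ACF curves sharing a lag grid (e.g. over pairs)."""
    if not curves:
        raise ValueError("no curves")
    lag = curves[0].lag
    n = min(len(c.coefficient) for c in curves)
    stack = np.vstack([c.coefficient[:n] for c in curves])
    return ACFCurve(lag=lag[:n], coefficient=np.nanmean(stack, axis=0))


# ---------------------------------------------------------------------------
# Ridgeline and spatial ACF
# ---------------------------------------------------------------------------

def ridgeline_profile(hmap: HeightMap, step: float = RESAMPLE_STEP_NM,
                      max_jump_px: float = 8.0) -> SectionProfile:
    """Height profile along the filament ridgeline (sub-pixel crest).

    Assumes the filament runs along x (columns).  Per column, the ridge row
    is the height maximum refined to sub-pixel by a local quadratic fit;
    ridge points are joined by a cubic spline and the surface height is
    sampled along it at ``step`` nm arc length.
    """
    h = hmap.heights
    ny, nx = h.shape
    if nx < 4:
        raise ValueError("map too narrow for ridge tracking")
    # a ridge exists only where the filament is: trim leading/trailing
    # columns that are essentially bare substrate
    col_max = h.max(axis=0)
    lit = col_max > 0.2 * col_max.max()
    j0, j1 = int(np.argmax(lit)), nx - int(np.argmax(lit[::-1]))
    if j1 - j0 < 4:
        raise ValueError("ridge tracking lost: no filament columns")
    ridge_rows = np.empty(j1 - j0)
    for jj, j in enumerate(range(j0, j1)):
        col = h[:, j]
        i = int(np.argmax(col))
        if 0 < i < ny - 1:
            denom = col[i - 1] - 2 * col[i] + col[i + 1]
            delta = 0.5 * (col[i - 1] - col[i + 1]) / denom if abs(denom) > 1e-12 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        ridge_rows[jj] = i + delta
    # suppress single-column crest flips before the continuity check
    from scipy.ndimage import median_filter

    ridge_rows = median_filter(ridge_rows, size=3, mode="nearest")
    jumps = np.abs(np.diff(ridge_rows))
    if np.any(jumps > max_jump_px):
        raise ValueError("ridge tracking lost: discontinuous ridgeline")
    xs = hmap.x_coords()[j0:j1]
    ys = hmap.origin[1] + ridge_rows * hmap.pixel_size_xy
    spline_y = CubicSpline(xs, ys)
    # arc length along the spline
    fine_x = np.linspace(xs[0], xs[-1], 8 * nx)
    fine_y = spline_y(fine_x)
    seg = np.hypot(np.diff(fine_x), np.diff(fine_y))
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    s = np.arange(0.0, arc[-1] + step / 2, step)
    sx = np.interp(s, arc, fine_x)
    sy = np.interp(s, arc, fine_y)
    from scipy import ndimage

    rows = (sy - hmap.origin[1]) / hmap.pixel_size_xy
    cols = (sx - hmap.origin[0]) / hmap.pixel_size_xy
    vals = ndimage.map_coordinates(h, [rows, cols], order=3, mode="nearest")
    return SectionProfile(distance=s, height=vals)


def spatial_acf(p: SectionProfile, band_nm: tuple[float, float] | None = (5.0, 8.0),
                ) -> ACFCurve:
    """Wiener–Khinchin autocorrelation of a (band-filtered) height profile.

    The mean-subtracted profile is brick-wall filtered to the protomer
    periodicity band, its power spectrum is inverted back to real space
    (circular autocorrelation), and the result is normalised to 1 at zero
    distance.
    """
    p = p.resampled()
    h = p.height - p.height.mean()
    if band_nm is not None:
        from .profile_analysis import bandpass_profile

        p_f = bandpass_profile(p, band_nm)
        h = p_f.height
    spec = np.fft.rfft(h)
    power = np.abs(spec) ** 2
    acf = np.fft.irfft(power, n=len(h))
    if acf[0] < 1e-14:
        raise ZeroVarianceError("zero variance after filtering")
    acf = acf / acf[0]
    half = len(h) // 2 + 1
    lags = np.arange(half) * p.step
    return ACFCurve(lag=lags, coefficient=acf[:half])


def hilbert_envelope(curve: ACFCurve) -> SectionProfile:
    """Magnitude of the analytic signal of the ACF (its oscillation envelope).

    Computed in the Fourier domain by doubling positive frequencies and
    zeroing negative ones; the envelope is non-negative and bounds the
    rectified curve away from the boundaries.
    """
    analytic = signal.hilbert(curve.coefficient)
    return SectionProfile(distance=curve.lag.copy(), height=np.abs(analytic))


# ---------------------------------------------------------------------------
# Decaying-sinusoid fit (Nadam)
# ---------------------------------------------------------------------------

def decaying_sinusoid(d, D1, D2, D3, D4, D5, D6, D7, D8, D9, g1, g2, g3, g4):
    """Exponentially decaying four-term sinusoid rho(d)."""
    e = np.exp(-d / D1)
    s = (D2 * np.cos(d / D3 + g1) + D4 * np.sin(d / D5 + g2)
         + D6 * np.cos(d / D7 + g3) + D8 * np.sin(d / D9 + g4))
    return e * s


# box constraints: decay length in (1, 500) nm; the reciprocal-period
# parameters D3, D5, D7, D9 are constrained so the corresponding period
# 2*pi*D lies in (2, 60) nm
_D1_BOUNDS = (1.0, 500.0)
_PERIOD_BOUNDS_NM = (2.0, 60.0)
_DPER_BOUNDS = (_PERIOD_BOUNDS_NM[0] / (2 * np.pi), _PERIOD_BOUNDS_NM[1] / (2 * np.pi))
_AMP_BOUNDS = (-5.0, 5.0)


def _grad_mse(d: np.ndarray, y: np.ndarray, p: np.ndarray) -> tuple[float, np.ndarray]:
    """MSE loss and its analytic gradient for the decaying sinusoid."""
    D1, D2, D3, D4, D5, D6, D7, D8, D9, g1, g2, g3, g4 = p
    e = np.exp(-d / D1)
    c1, s1 = np.cos(d / D3 + g1), np.sin(d / D3 + g1)
    s2, c2 = np.sin(d / D5 + g2), np.cos(d / D5 + g2)
    c3, s3 = np.cos(d / D7 + g3), np.sin(d / D7 + g3)
    s4, c4 = np.sin(d / D9 + g4), np.cos(d / D9 + g4)
    s_sum = D2 * c1 + D4 * s2 + D6 * c3 + D8 * s4
    rho = e * s_sum
    r = rho - y
    n = len(d)
    loss = float(np.mean(r ** 2))
    w = 2.0 * r / n
    g = np.empty(13)
    g[0] = np.sum(w * rho * d) / D1 ** 2
    g[1] = np.sum(w * e * c1)
    g[2] = np.sum(w * e * D2 * s1 * d) / D3 ** 2
    g[3] = np.sum(w * e * s2)
    g[4] = -np.sum(w * e * D4 * c2 * d) / D5 ** 2
    g[5] = np.sum(w * e * c3)
    g[6] = np.sum(w * e * D6 * s3 * d) / D7 ** 2
    g[7] = np.sum(w * e * s4)
    g[8] = -np.sum(w * e * D8 * c4 * d) / D9 ** 2
    g[9] = -np.sum(w * e * D2 * s1)
    g[10] = np.sum(w * e * D4 * c2)
    g[11] = -np.sum(w * e * D6 * s3)
    g[12] = np.sum(w * e * D8 * c4)
    return loss, g


_LO = np.array([_D1_BOUNDS[0], _AMP_BOUNDS[0], _DPER_BOUNDS[0], _AMP_BOUNDS[0],
                _DPER_BOUNDS[0], _AMP_BOUNDS[0], _DPER_BOUNDS[0], _AMP_BOUNDS[0],
                _DPER_BOUNDS[0], -2 * np.pi, -2 * np.pi, -2 * np.pi, -2 * np.pi])
_HI = np.array([_D1_BOUNDS[1], _AMP_BOUNDS[1], _DPER_BOUNDS[1], _AMP_BOUNDS[1],
                _DPER_BOUNDS[1], _AMP_BOUNDS[1], _DPER_BOUNDS[1], _AMP_BOUNDS[1],
                _DPER_BOUNDS[1], 2 * np.pi, 2 * np.pi, 2 * np.pi, 2 * np.pi])


def _nadam(d, y, p0, lr=1e-2, n_iter=5000,
           beta1=0.9, beta2=0.999, eps=1e-8) -> tuple[np.ndarray, float]:
    p = np.clip(np.asarray(p0, float), _LO, _HI)
    m = np.zeros_like(p)
    v = np.zeros_like(p)
    best_p, best_loss = p.copy(), np.inf
    # parameter-scale step sizes: decay/period parameters move on larger scales
    scale = np.ones(13)
    scale[0] = 10.0
    scale[[2, 4, 6, 8]] = 0.2
    stall = 0
    for it in range(1, n_iter + 1):
        loss, g = _grad_mse(d, y, p)
        if loss < best_loss - 1e-14:
            best_loss, best_p = loss, p.copy()
            stall = 0
        else:
            stall += 1
            if stall > 500 or best_loss < 1e-12:
                break
        if not np.all(np.isfinite(g)):
            break
        m = beta1 * m + (1 - beta1) * g
        v = beta2 * v + (1 - beta2) * g ** 2
        m_hat = m / (1 - beta1 ** it)
        v_hat = v / (1 - beta2 ** it)
        update = (beta1 * m_hat + (1 - beta1) * g / (1 - beta1 ** it))
        p = p - lr * scale * update / (np.sqrt(v_hat) + eps)
        p = np.clip(p, _LO, _HI)
    loss, _ = _grad_mse(d, y, p)
    if loss < best_loss:
        best_loss, best_p = loss, p
    return best_p, float(best_loss)


def _initial_guess(curve: ACFCurve) -> np.ndarray:
    """D1 from the log-envelope, dominant period from the spectrum."""
    d = curve.lag
    y = curve.coefficient
    env = hilbert_envelope(curve).height
    pos = env > max(1e-3, 0.01 * env.max())
    if pos.sum() >= 4:
        slope, intercept = np.polyfit(d[pos], np.log(env[pos]), 1)
        d1 = -1.0 / slope if slope < -1e-9 else 50.0
    else:
        d1 = 50.0
    d1 = float(np.clip(d1, *_D1_BOUNDS))
    step = d[1] - d[0] if len(d) > 1 else 1.0
    spec = np.abs(np.fft.rfft(y - y.mean()))
    freqs = np.fft.rfftfreq(len(y), d=step)
    k = int(np.argmax(spec[1:]) + 1) if len(spec) > 1 else 1
    period = 1.0 / freqs[k] if freqs[k] > 0 else 5.5
    dper = float(np.clip(period / (2 * np.pi), *_DPER_BOUNDS))
    amp = float(np.clip(np.max(np.abs(y)), 0.1, 2.0))
    return np.array([d1, amp, dper, 0.0, dper, 0.0, dper, 0.0, dper,
                     0.0, 0.0, 0.0, 0.0])


def fit_decaying_sinusoid(curve: ACFCurve, init: np.ndarray | None = None,
                          lr: float = 1e-2, n_iter: int = 5000,
                          n_starts: int = 8, seed: int = 0) -> SinusoidFit:
    """Fit the decaying sinusoid to an ACF curve by Nadam gradient descent.

    Multi-start: the data-driven initial guess plus seeded jitters of it;
    the start with the lowest MSE wins.  Parameters are box-constrained
    (decay 1–500 nm; periods 2–60 nm).
    """
    d = curve.lag
    y = curve.coefficient
    if len(d) < 30:
        raise ValueError("need at least 30 samples")
    if np.max(np.abs(y)) < 1e-12:
        raise ValueError("unidentifiable decay: all-zero curve")
    p0 = _initial_guess(curve) if init is None else np.asarray(init, float)
    rng = np.random.default_rng(seed)
    best_p, best_loss = None, np.inf
    for i in range(n_starts):
        start = p0.copy()
        if i > 0:
            start[0] *= np.exp(rng.normal(0, 0.4))
            start[[2, 4, 6, 8]] *= np.exp(rng.normal(0, 0.15, size=4))
            start[[1, 3, 5, 7]] += rng.normal(0, 0.1, size=4)
            start[9:] += rng.normal(0, 0.3, size=4)
        p, loss = _nadam(d, y, start, lr=lr, n_iter=n_iter)
        if np.isfinite(loss) and loss < best_loss:
            best_p, best_loss = p, loss
    if best_p is None:
        raise FitFailedError("fit failed: optimizer diverged on every start")
    return SinusoidFit(params=best_p, mse=best_loss, converged=True)
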