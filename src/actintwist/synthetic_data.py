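"""Seeded generators for every synthetic input the pipeline consumes.

Raw high-speed AFM movies and the deposited structure ensemble are large
external inputs; these generators emulate their essential features with
analytically known ground truth:

* helical filament point clouds (bare, cofilin-decorated, hybrid) on the
  genetic-helix convention — protomer *j* sits at axial position
  ``j * rise`` and azimuth ``j * twist``, so the two long-pitch strands are
  the even and odd protomers and crossovers recur every
  ``180/(180 - |twist|)`` protomers;
* axial-distance (AD) time series as a sum of two stationary AR(1)
  processes whose autocorrelation times are the planted (t1, t2);
* decaying-sinusoid ACF curves evaluated from the model itself;
* structural ensembles with planted domain-rotation modes for PCA
  recovery tests.

Every generator is deterministic given its seed and returns machine-
readable ground truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .pseudo_afm import ImagingParams, HeightMap, render
from .correlation import ADTimeSeries, ACFCurve, decaying_sinusoid
from .structure_ensemble import StructureChain
from .filament_builder import helical_parameters_from_twist


# ---------------------------------------------------------------------------
# Filaments
# ---------------------------------------------------------------------------

@dataclass
class SyntheticFilamentSpec:
    """Geometry and imaging conditions of a synthetic filament.

    Defaults are canonical bare F-actin: 166.589° twist and 2.75 nm rise
    (half-helical pitch ≈ 36.9 nm, 6.5 protomer pairs), 2.5 nm protomer
    blobs at 2.5 nm helix radius.  ``decorated_range`` marks a protomer
    index interval rendered with enlarged blobs, emulating the ~1.3 nm
    extra height of a cofilin-decorated (cofilactin) segment.
    """

    twist_per_protomer: float = 166.589   # degrees, magnitude
    rise_per_protomer: float = 2.75       # nm
    filament_radius: float = 2.5          # nm, helix radius of blob centres
    protomer_blob: float = 2.5            # nm, blob sphere radius
    n_protomers: int = 62
    decorated_range: tuple[int, int] | None = None  # half-open [a, b)
    decoration_height_offset: float = 1.3  # nm, within the observed 1-1.6
    imaging: ImagingParams = field(default_factory=ImagingParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 90.0 < self.twist_per_protomer < 180.0:
            raise ValueError("invalid geometry: twist must lie in (90, 180)")
        if self.rise_per_protomer <= 0:
            raise ValueError("invalid geometry: rise must be positive")
        if self.decorated_range is not None:
            a, b = self.decorated_range
            if not (0 <= a <= b <= self.n_protomers):
                raise ValueError("decorated_range outside [0, n_protomers)")


@dataclass
class FilamentGroundTruth:
    """Analytic observables of a synthetic filament."""

    protomer_axial_nm: np.ndarray     # per-protomer axial position
    crossover_axial_nm: np.ndarray    # crossover positions along the axis
    hhp: float                        # nm
    protomers_per_hhp: int
    protomer_pairs: float
    mad_geometric: float              # 2 x rise
    mad_counted: float                # hhp / pairs (the AFM counting value)
    minor_pitch: float                # axial gap along one strand = 2 x rise


def make_helix_points(spec: SyntheticFilamentSpec,
                      ) -> tuple[np.ndarray, np.ndarray, FilamentGroundTruth]:
    """Point-cloud filament (centers nm, radii nm) plus analytic ground truth.

    Decorated protomers get blobs enlarged by the decoration height offset.
    The filament runs along +x with blob centres at ``filament_radius`` from
    the axis; protomer 0 starts at azimuth 90° (facing the probe).
    """
    hp = helical_parameters_from_twist(spec.twist_per_protomer,
                                       spec.rise_per_protomer)
    j = np.arange(spec.n_protomers)
    axial = j * spec.rise_per_protomer
    # left-handed genetic helix: azimuth decreases by the twist magnitude
    phi = np.radians(90.0) - j * np.radians(spec.twist_per_protomer)
    centers = np.stack([
        axial,
        spec.filament_radius * np.cos(phi),
        spec.filament_radius * np.sin(phi),
    ], axis=1)
    radii = np.full(spec.n_protomers, float(spec.protomer_blob))
    if spec.decorated_range is not None:
        a, b = spec.decorated_range
        radii[a:b] += spec.decoration_height_offset

    # crossover positions: the continuous helical phase passes "protomer
    # facing the probe" once per half helix on either strand
    hhp = hp.hhp
    n_cross = int(np.floor(axial[-1] / hhp)) + 1
    crossovers = np.arange(n_cross) * hhp
    truth = FilamentGroundTruth(
        protomer_axial_nm=axial,
        crossover_axial_nm=crossovers,
        hhp=hhp,
        protomers_per_hhp=hp.protomers_per_hhp,
        protomer_pairs=hp.protomer_pairs_per_hhp,
        mad_geometric=hp.mad,
        mad_counted=hhp / hp.protomer_pairs_per_hhp,
        minor_pitch=2 * spec.rise_per_protomer,
    )
    return centers, radii, truth


def render_filament(spec: SyntheticFilamentSpec,
                    ) -> tuple[HeightMap, FilamentGroundTruth]:
    """Render a synthetic filament to a height map with its ground truth."""
    centers, radii, truth = make_helix_points(spec)
    params = ImagingParams(**{**asdict(spec.imaging), "seed": spec.seed})
    hmap = render((centers, radii), params)
    hmap.metadata["ground_truth"] = {
        "hhp": truth.hhp,
        "protomer_pairs": truth.protomer_pairs,
        "mad_counted": truth.mad_counted,
    }
    return hmap, truth


def axis_polyline(hmap: HeightMap) -> np.ndarray:
    """Horizontal center-line polyline through a rendered filament map."""
    y_mid = hmap.origin[1] + (hmap.shape[0] - 1) * hmap.pixel_size_xy / 2
    x0 = hmap.origin[0]
    x1 = hmap.origin[0] + (hmap.shape[1] - 1) * hmap.pixel_size_xy
    return np.array([[x0, y_mid], [x1, y_mid]])


# ---------------------------------------------------------------------------
# Axial-distance time series
# ---------------------------------------------------------------------------

@dataclass
class ADSimSpec:
    """Two-timescale AD fluctuation model.

    The series is ``mean_ad`` plus a stationary zero-mean fluctuation of
    standard deviation ``ad_sigma`` split between two AR(1) processes with
    autocorrelation times ``t1`` and ``t2`` (variance weights a1, a2),
    plus white measurement noise.  The theoretical ACF of the noise-free
    fluctuation is ``a1 exp(-t/t1) + a2 exp(-t/t2)``.
    """

    mean_ad: float = 5.5        # nm
    t1: float = 0.4             # s
    t2: float = 2.0             # s
    a1: float = 0.5
    a2: float = 0.5
    ad_sigma: float = 0.25      # nm, total fluctuation SD
    noise_sigma: float = 0.05   # nm, white measurement noise
    n_frames: int = 258
    frame_interval: float = 0.5  # s
    n_pairs: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("correlation times must be positive")
        if abs(self.a1 + self.a2 - 1.0) > 1e-9 and (self.a1 or self.a2):
            raise ValueError("mixing weights a1 + a2 must equal 1")


def _ar1(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1) sample path."""
    x = np.empty(n)
    x[0] = rng.normal(0.0, 1.0)
    innov_sd = np.sqrt(1.0 - phi ** 2)
    eps = rng.normal(0.0, innov_sd, n - 1)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t - 1]
    return x


def simulate_ad_series(spec: ADSimSpec) -> tuple[ADTimeSeries, dict]:
    """Seeded AD series with planted two-timescale autocorrelation."""
    rng = np.random.default_rng(spec.seed)
    dt = spec.frame_interval
    phi1 = np.exp(-dt / spec.t1)
    phi2 = np.exp(-dt / spec.t2)
    values = np.empty((spec.n_pairs, spec.n_frames))
    for p in range(spec.n_pairs):
        slow = np.zeros(spec.n_frames)
        if spec.a1 > 0:
            slow = slow + np.sqrt(spec.a1) * _ar1(rng, spec.n_frames, phi1)
        if spec.a2 > 0:
            slow = slow + np.sqrt(spec.a2) * _ar1(rng, spec.n_frames, phi2)
        noise = rng.normal(0.0, spec.noise_sigma, spec.n_frames)
        values[p] = spec.mean_ad + spec.ad_sigma * slow + noise
    truth = {"t1": spec.t1, "t2": spec.t2, "a1": spec.a1, "a2": spec.a2,
             "mean_ad": spec.mean_ad}
    return ADTimeSeries(values=values, frame_interval=dt), truth


# ---------------------------------------------------------------------------
# Decaying-sinusoid curves
# ---------------------------------------------------------------------------

def simulate_decaying_sinusoid(params: np.ndarray | list,
                               noise_sigma: float = 0.0, seed: int = 0,
                               d_max: float = 100.0, step: float = 0.5,
                               ) -> tuple[ACFCurve, np.ndarray]:
    """Evaluate the decaying-sinusoid model on a grid, plus Gaussian noise."""
    params = np.asarray(params, float)
    if params[0] <= 0:
        raise ValueError("decay constant D1 must be positive")
    d = np.arange(0.0, d_max + step / 2, step)
    y = decaying_sinusoid(d, *params)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sigma, len(d))
    return ACFCurve(lag=d, coefficient=y), params


# ---------------------------------------------------------------------------
# Planted-mode structural ensembles
# ---------------------------------------------------------------------------

def make_mode_ensemble(base: StructureChain, mode: np.ndarray,
                       amplitudes: np.ndarray, noise_sigma: float = 0.0,
                       seed: int = 0, extra_modes: list | None = None,
                       ) -> tuple[list[StructureChain], np.ndarray]:
    """Ensemble members = base + amplitude * mode (+ optional extra modes).

    ``mode`` is an (N, 3) displacement field on the base Cα atoms (unit
    scale of choice); isotropic Gaussian noise is added per member.
    ``extra_modes`` is a list of (mode, amplitudes) pairs planted on top.
    Returns the chains and the planted amplitudes as ground truth.
    """
    mode = np.asarray(mode, float)
    if mode.shape != base.ca_coords.shape:
        raise ValueError("mode must be defined on the base atoms")
    amplitudes = np.asarray(amplitudes, float)
    rng = np.random.default_rng(seed)
    chains = []
    for m, amp in enumerate(amplitudes):
        coords = base.ca_coords + amp * mode
        if extra_modes:
            for extra_mode, extra_amps in extra_modes:
                coords = coords + extra_amps[m] * np.asarray(extra_mode, float)
        if noise_sigma > 0:
            coords = coords + rng.normal(0.0, noise_sigma, coords.shape)
        chains.append(StructureChain(
            pdb_id=f"SYN{m:03d}", chain_id="A",
            residue_numbers=base.residue_numbers.copy(),
            ca_coords=coords, annotations={"planted_amplitude": float(amp)}))
    return chains, amplitudes


def make_synthetic_actin_chain(n_residues: int = 200, seed: int = 0,
                               ) -> StructureChain:
    """Compact random-walk Cα chain used as a PCA test scaffold.

    A smooth self-avoiding-ish 3D curve with ~3.8 Å steps; residue numbers
    1..n.  This synthetic chain stands in for a deposited actin monomer in
    tests that only need geometry, not chemistry.
    """
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, 1.0, (n_residues, 3))
    # smooth the walk so the chain is locally stiff like a protein backbone
    from scipy.ndimage import uniform_filter1d

    steps = uniform_filter1d(steps, size=5, axis=0)
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    coords = np.cumsum(steps * 3.8, axis=0)
    return StructureChain(pdb_id="SYNBASE", chain_id="A",
                          residue_numbers=np.arange(1, n_residues + 1),
                          ca_coords=coords)


def rotation_mode(base: StructureChain, subset_mask: np.ndarray,
                  axis: np.ndarray, pivot: np.ndarray,
                  degrees_per_unit: float = 1.0) -> np.ndarray:
    """Displacement field of a small rigid rotation of a residue subset.

    Linearised rotation of the masked atoms about ``axis`` through
    ``pivot``; one amplitude unit corresponds to ``degrees_per_unit``.
    Used to plant outer-domain hinge modes.
    """
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    disp = np.zeros_like(base.ca_coords)
    rel = base.ca_coords[subset_mask] - np.asarray(pivot, float)
    disp[subset_mask] = np.radians(degrees_per_unit) * np.cross(axis, rel)
    return disp
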