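"""Pseudo-AFM rendering of atomic models by tip-shape dilation.

An AFM topograph of a rigid sample is, geometrically, the gray-scale
dilation of the sample surface by the reflected tip shape: at each lateral
position the tip is lowered until it first touches the sample, and the apex
height at contact is the recorded height.  The tip is modelled as a sphere
of radius ``probe_radius`` smoothly capped on a cone of half-angle
``cone_half_angle`` (apex down), the standard sphere-cone probe.  The
sample is a union of spheres (atoms, or coarse-grained protomer blobs).

For an atom of radius ``r_a`` centred at height ``z_a`` and lateral
distance ``d`` from the tip axis, the contact height of the apex has a
closed form in two regimes (R = probe radius, θ = cone half-angle):

    sphere contact (d <= (R + r_a) cos θ):
        h = z_a + sqrt((R + r_a)^2 - d^2) - R
    cone contact (d > (R + r_a) cos θ):
        h = z_a + (R + r_a)/sin θ - R - d / tan θ

The pixel height is the maximum over atoms, floored at the mica plane
(z = 0).  Gaussian noise is added before quantization to the z-ADC step,
mimicking detector noise followed by digitisation.  All lengths in nm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np


@dataclass
class ImagingParams:
    """Tip geometry, scan grid and noise model for rendering.

    Defaults follow common high-resolution imaging of actin filaments:
    a 2 nm probe with a 5° half-angle cone, 1 nm pixels, 0.064 nm height
    quantization and 0.1 nm RMS noise.
    """

    probe_radius: float = 2.0       # nm
    cone_half_angle: float = 5.0    # degrees
    pixel_size_xy: float = 1.0      # nm
    z_step: float = 0.064           # nm; 0 disables quantization
    noise_sigma: float = 0.1        # nm; 0 disables noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.pixel_size_xy <= 0:
            raise ValueError("invalid grid: pixel size must be positive")
        if self.z_step < 0 or self.noise_sigma < 0:
            raise ValueError("z_step and noise_sigma must be non-negative")


@dataclass
class HeightMap:
    """2D topograph in nm with pixel geometry metadata.

    ``origin`` is the (x, y) position of the centre of pixel (row 0, col 0);
    x runs along columns, y along rows.
    """

    heights: np.ndarray
    pixel_size_xy: float
    origin: tuple[float, float] = (0.0, 0.0)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2D matrix")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    def x_coords(self) -> np.ndarray:
        return self.origin[0] + np.arange(self.shape[1]) * self.pixel_size_xy

    def y_coords(self) -> np.ndarray:
        return self.origin[1] + np.arange(self.shape[0]) * self.pixel_size_xy


#: van der Waals radii in nm for common elements; anything else falls back
#: to ``default_atom_radius``.
VDW_RADII_NM = {
    "H": 0.120, "C": 0.170, "N": 0.155, "O": 0.152,
    "S": 0.180, "P": 0.180,
}
DEFAULT_ATOM_RADIUS_NM = 0.15


def place_on_mica(centers: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Translate z so the lowest sphere surface touches the z = 0 plane."""
    centers = np.asarray(centers, float).copy()
    radii = np.asarray(radii, float)
    if len(centers):
        centers[:, 2] -= np.min(centers[:, 2] - radii)
    return centers


def atoms_from_coords(coords_angstrom: np.ndarray,
                      elements: np.ndarray | None = None,
                      default_radius: float = DEFAULT_ATOM_RADIUS_NM,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Convert structure coordinates (Å) to (centers nm, radii nm)."""
    centers = np.asarray(coords_angstrom, float) / 10.0
    if elements is None:
        radii = np.full(len(centers), default_radius)
    else:
        radii = np.array([VDW_RADII_NM.get(str(e).upper().strip(), default_radius)
                          for e in elements])
    return centers, radii


def _contact_heights(d: np.ndarray, za: float, ra: float,
                     probe_radius: float, theta_rad: float) -> np.ndarray:
    """Tip-apex contact height vs lateral distance for one atom sphere."""
    rr = probe_radius + ra
    h = np.full(d.shape, -np.inf)
    sph = d <= rr * np.cos(theta_rad)
    h[sph] = za + np.sqrt(np.maximum(rr ** 2 - d[sph] ** 2, 0.0)) - probe_radius
    cone = ~sph
    h[cone] = (za + rr / np.sin(theta_rad) - probe_radius
               - d[cone] / np.tan(theta_rad))
    return h


def render(atoms: tuple[np.ndarray, np.ndarray] | list,
           params: ImagingParams,
           extent: tuple[float, float, float, float] | None = None,
           margin: float = 3.0,
           place: bool = True) -> HeightMap:
    """Render a union of spheres into a height map by tip dilation.

    ``atoms`` is either a pair (centers (N,3) nm, radii (N,) nm) or a list
    of ((x, y, z), r) tuples.  With ``place`` the model is translated so its
    lowest sphere surface touches the mica plane (z = 0).  ``extent``
    overrides the automatic scan window (xmin, xmax, ymin, ymax); otherwise
    the bounding box of the atoms plus ``margin`` nm is used.
    """
    if isinstance(atoms, tuple) and len(atoms) == 2:
        centers = np.asarray(atoms[0], float).reshape(-1, 3)
        radii = np.asarray(atoms[1], float).reshape(-1)
    else:
        centers = np.array([a[0] for a in atoms], float).reshape(-1, 3)
        radii = np.array([a[1] for a in atoms], float).reshape(-1)
    px = params.pixel_size_xy

    if len(centers) == 0:
        if extent is None:
            extent = (0.0, 10.0, 0.0, 10.0)
    else:
        if place:
            centers = place_on_mica(centers, radii)
        if np.any(centers[:, 2] < radii - 1e-9):
            raise ValueError("atoms must lie above the mica plane (z >= 0)")
        if extent is None:
            extent = (centers[:, 0].min() - margin, centers[:, 0].max() + margin,
                      centers[:, 1].min() - margin, centers[:, 1].max() + margin)

    xmin, xmax, ymin, ymax = extent
    nx = max(int(np.floor((xmax - xmin) / px)) + 1, 1)
    ny = max(int(np.floor((ymax - ymin) / px)) + 1, 1)
    xs = xmin + np.arange(nx) * px
    ys = ymin + np.arange(ny) * px
    heights = np.zeros((ny, nx))

    theta = np.radians(params.cone_half_angle)
    for (cx, cy, cz), ra in zip(centers, radii):
        # lateral footprint: contact height reaches 0 on the cone flank at
        # d0; restrict the update to that window
        rr = params.probe_radius + ra
        d0 = (cz + rr / np.sin(theta) - params.probe_radius) * np.tan(theta)
        d0 = max(d0, rr)
        i0, i1 = np.searchsorted(xs, [cx - d0, cx + d0])
        j0, j1 = np.searchsorted(ys, [cy - d0, cy + d0])
        if i0 == i1 or j0 == j1:
            continue
        dx = xs[i0:i1] - cx
        dy = ys[j0:j1] - cy
        d = np.hypot(dx[None, :], dy[:, None])
        h = _contact_heights(d, cz, ra, params.probe_radius, theta)
        np.maximum(heights[j0:j1, i0:i1], h, out=heights[j0:j1, i0:i1])

    if params.noise_sigma > 0:
        rng = np.random.default_rng(params.seed)
        heights = heights + rng.normal(0.0, params.noise_sigma, heights.shape)
    if params.z_step > 0:
        heights = np.round(heights / params.z_step) * params.z_step
    np.maximum(heights, 0.0, out=heights)

    return HeightMap(heights=heights, pixel_size_xy=px, origin=(xmin, ymin),
                     metadata={"imaging": asdict(params), "provenance": "render"})


# ---------------------------------------------------------------------------
# I/O: TIFF or CSV matrix, each with a JSON sidecar for pixel metadata
# ---------------------------------------------------------------------------

def save_height_map(hmap: HeightMap, path: str | Path) -> None:
    """Write a height map as 32-bit float TIFF (or CSV) + JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(str(path), hmap.heights.astype(np.float32))
    else:
        np.savetxt(path, hmap.heights, delimiter=",")
    sidecar = {
        "pixel_size_xy": hmap.pixel_size_xy,
        "origin": list(hmap.origin),
        "metadata": hmap.metadata,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_height_map(path: str | Path) -> HeightMap:
    """Read a height map written by :func:`save_height_map`.

    A missing sidecar is tolerated (pixel size defaults to 1 nm).
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        heights = np.asarray(tifffile.imread(str(path)), dtype=float)
    else:
        heights = np.loadtxt(path, delimiter=",")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        return HeightMap(heights, sidecar.get("pixel_size_xy", 1.0),
                         tuple(sidecar.get("origin", (0.0, 0.0))),
                         sidecar.get("metadata", {}))
    return HeightMap(heights, 1.0)
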