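"""Helical filament construction from protomer pairs.

The rigid-body transform between two adjacent protomer chains of a deposited
filament structure is the helical generator: applying it repeatedly to one
protomer produces a filament of arbitrary length.  The axis-angle
decomposition of the generator yields the per-protomer twist and rise, from
which the half-helical pitch (HHP), protomer count per half helix, and the
mean axial distance (MAD) follow.

Angle conventions: the per-protomer twist magnitude of actin is ~166–167°
(canonical) and ~162° (cofilin-supertwisted).  Crossovers of the two
long-pitch strands recur every 180/(180-|twist|) protomers, so

    protomers_per_crossover = 180 / (180 - |twist|)
    hhp  = protomers_per_crossover * rise
    mad  = 2 * rise

Distances inside transforms are Å (structure-file units); helical parameters
are reported in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_ensemble import StructureChain, kabsch

A_PER_NM = 10.0
#: default per-protomer rise when a transform does not supply one:
#: MAD 5.5 nm / 2 protomers per pair.
DEFAULT_RISE_NM = 2.75


@dataclass
class RigidTransform:
    """Screw transform between adjacent protomers: x -> rotation @ x + translation."""

    rotation: np.ndarray     # (3, 3) proper orthogonal
    translation: np.ndarray  # (3,) Å
    rmsd: float = 0.0        # Å

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, float)
        self.translation = np.asarray(self.translation, float)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")

    @property
    def rotation_angle(self) -> float:
        """Axis-angle magnitude in degrees, in [0, 180]."""
        return float(np.degrees(Rotation.from_matrix(self.rotation).magnitude()))

    @property
    def screw_axis(self) -> np.ndarray:
        """Unit rotation axis (undefined direction sign for 180° rotations)."""
        rv = Rotation.from_matrix(self.rotation).as_rotvec()
        norm = np.linalg.norm(rv)
        if norm < 1e-12:
            # identity rotation: fall back to the translation direction
            t = np.linalg.norm(self.translation)
            return self.translation / t if t > 0 else np.array([1.0, 0.0, 0.0])
        return rv / norm

    @property
    def rise(self) -> float:
        """Translation component along the screw axis, Å (signed)."""
        return float(self.screw_axis @ self.translation)

    @property
    def handedness(self) -> str:
        """Left- or right-handed genetic helix.

        Left-handed means the rotation (as a positive axis-angle) points
        against the rise direction, i.e. the twist about the direction of
        advance is negative — the actin convention.
        """
        return "left" if self.rise < 0 else "right"

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation,
                              rmsd=self.rmsd)

    def power(self, n: int) -> "RigidTransform":
        out = RigidTransform(np.eye(3), np.zeros(3))
        for _ in range(n):
            out = self.compose(out)
        return out

    @property
    def axis_point(self) -> np.ndarray:
        """A point on the screw-axis line (the invariant line of the motion)."""
        axis = self.screw_axis
        t_perp = self.translation - (axis @ self.translation) * axis
        # solve (I - R) p = t_perp in the plane perpendicular to axis
        a = np.eye(3) - self.rotation
        p, *_ = np.linalg.lstsq(a, t_perp, rcond=None)
        return p - (axis @ p) * axis


@dataclass
class HelicalParams:
    """Per-protomer helical geometry and the derived AFM observables (nm)."""

    twist_per_protomer: float      # degrees, magnitude
    rise_per_protomer: float       # nm
    handedness: str = "left"

    @property
    def protomers_per_crossover(self) -> float:
        return 180.0 / (180.0 - abs(self.twist_per_protomer))

    @property
    def protomers_per_hhp(self) -> int:
        """Nearest odd integer to protomers_per_crossover (ties upward)."""
        x = self.protomers_per_crossover
        lower = 2 * np.floor((x - 1) / 2) + 1  # largest odd <= relevant band
        return int(lower if x - lower < (lower + 2) - x else lower + 2)

    @property
    def protomer_pairs_per_hhp(self) -> float:
        return self.protomers_per_hhp / 2.0

    @property
    def hhp(self) -> float:
        return self.protomers_per_crossover * self.rise_per_protomer

    @property
    def mad(self) -> float:
        return 2.0 * self.rise_per_protomer


@dataclass
class FilamentModel:
    """Ordered protomer units generated by repeated application of a transform."""

    protomer_units: list[np.ndarray]                # each (n_i, 3) Å
    generator: RigidTransform
    unit_labels: list[str] = field(default_factory=list)
    axis: np.ndarray | None = None                  # unit vector after alignment

    @property
    def n_units(self) -> int:
        return len(self.protomer_units)

    def all_coords(self) -> np.ndarray:
        return np.vstack(self.protomer_units)

    def unit_centroids(self) -> np.ndarray:
        return np.array([u.mean(axis=0) for u in self.protomer_units])


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def fit_rigid_transform(chain_a: StructureChain, chain_b: StructureChain) -> RigidTransform:
    """Kabsch transform mapping chain_b onto chain_a over their shared residues.

    For two adjacent protomers of a filament this is the helical generator:
    applying it to protomer *i* produces protomer *i+1* along the filament.
    """
    shared = np.intersect1d(chain_a.residue_numbers, chain_b.residue_numbers)
    if len(shared) < 3:
        raise ValueError("ill-conditioned fit: < 3 shared residues")
    a = chain_a.subset(shared).ca_coords
    b = chain_b.subset(shared).ca_coords
    # reject (near-)colinear point sets: the rotation about the colinear
    # axis would be unconstrained
    sv = np.linalg.svd(b - b.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise ValueError("ill-conditioned fit: colinear point set")
    t = kabsch(b, a)
    return RigidTransform(t.rotation, t.translation, rmsd=t.rmsd)


def helical_parameters(t: RigidTransform, rise_nm: float | None = None) -> HelicalParams:
    """Derive twist/rise and the crossover observables from a transform.

    ``rise_nm`` overrides the transform's translation-derived rise (used when
    the transform comes from a printed table without distances).
    """
    twist = t.rotation_angle
    if not 90.0 < twist < 180.0:
        if twist >= 180.0:
            raise ValueError("no crossover (untwisted two-start ladder)")
        raise ValueError(f"twist magnitude {twist:.2f} outside (90, 180) degrees")
    if rise_nm is None:
        rise_nm = abs(t.rise) / A_PER_NM
    return HelicalParams(twist_per_protomer=twist, rise_per_protomer=rise_nm,
                         handedness=t.handedness)


def helical_parameters_from_twist(twist_deg: float,
                                  rise_nm: float = DEFAULT_RISE_NM) -> HelicalParams:
    """Helical observables directly from a printed twist magnitude."""
    twist = abs(twist_deg)
    if not 90.0 < twist < 180.0:
        raise ValueError("twist magnitude must lie in (90, 180) degrees")
    return HelicalParams(twist_per_protomer=twist, rise_per_protomer=rise_nm)


def build_filament(asym_unit: np.ndarray | Sequence[np.ndarray],
                   t: RigidTransform, n: int,
                   labels: Sequence[str] | None = None,
                   decorated_until: int | None = None) -> FilamentModel:
    """Apply the generator ``n-1`` times to the asymmetric unit.

    ``asym_unit`` is one coordinate set or a list of them (e.g. actin +
    bound cofilin carried together).  ``decorated_until`` keeps any extra
    chains only for units below that index, supporting hybrid filaments
    where the first *k* protomers are cofilin-decorated and the rest bare.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    if isinstance(asym_unit, np.ndarray):
        parts = [np.asarray(asym_unit, float)]
    else:
        parts = [np.asarray(p, float) for p in asym_unit]
    units: list[np.ndarray] = []
    unit_labels: list[str] = []
    current = [p.copy() for p in parts]
    for i in range(n):
        keep = current if (decorated_until is None or i < decorated_until) else current[:1]
        units.append(np.vstack(keep))
        decorated = decorated_until is None or i < decorated_until
        if labels is not None:
            unit_labels.append(labels[i % len(labels)])
        else:
            unit_labels.append("decorated" if (decorated and len(parts) > 1) else "bare")
        current = [t.apply(p) for p in current]
    return FilamentModel(protomer_units=units, generator=t, unit_labels=unit_labels)


def align_to_axis(f: FilamentModel, origin: Sequence[float] = (0.0, 0.0, 0.0)) -> FilamentModel:
    """Rigidly move the filament so its screw axis is the +x direction.

    The screw-axis line is mapped onto the x-axis (y = z = 0) and unit 0's
    centroid is placed at x = origin[0] (its y/z follow from the axis); the
    motion is rigid, so all pairwise distances are preserved.
    """
    axis = f.generator.screw_axis
    if f.generator.rise < 0:
        axis = -axis  # make protomer index increase along +x
    p0 = f.generator.axis_point
    rot, _ = Rotation.align_vectors([[1.0, 0.0, 0.0]], [axis])
    r = rot.as_matrix()
    moved = [(u - p0) @ r.T for u in f.protomer_units]
    # the screw axis is now the line y = z = 0; slide along it so unit 0's
    # centroid sits at the configured x origin
    shift = np.asarray(origin, float) - np.array([moved[0].mean(axis=0)[0], 0.0, 0.0])
    shift[1:] = np.asarray(origin, float)[1:]
    moved = [u + shift for u in moved]
    out = FilamentModel(protomer_units=moved, generator=f.generator,
                        unit_labels=list(f.unit_labels))
    out.axis = np.array([1.0, 0.0, 0.0])
    return out


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

_CHAIN_IDS = [chr(ord("A") + i) for i in range(26)]


def write_filament_pdb(f: FilamentModel, path) -> None:
    """Write protomer units as consecutive chains of a Cα-only PDB file."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb_io

    total = sum(len(u) for u in f.protomer_units)
    atoms = struc.AtomArray(total)
    coords, chain_ids, res_ids = [], [], []
    for i, u in enumerate(f.protomer_units):
        coords.append(u)
        chain_ids.extend([_CHAIN_IDS[i % 26]] * len(u))
        res_ids.extend(range(1, len(u) + 1))
    atoms.coord = np.vstack(coords)
    atoms.chain_id = np.array(chain_ids)
    atoms.res_id = np.array(res_ids)
    atoms.res_name = np.full(total, "ALA")
    atoms.atom_name = np.full(total, "CA")
    atoms.element = np.full(total, "C")
    out = pdb_io.PDBFile()
    pdb_io.set_structure(out, atoms)
    out.write(str(path))


def load_filament_pair_table(path=None):
    """The curated chain-pair list used to build long filaments.

    Columns: pdb_id, chain_pair (mobile+reference ids, e.g. "BA" meaning
    fit chain B onto chain A), kind (F-actin / C-actin / cofilactin /
    boundary).
    """
    import pandas as pd
    from .structure_ensemble import _data_path

    path = _data_path("filament_pairs.csv") if path is None else path
    return pd.read_csv(path)


def transform_report(t: RigidTransform) -> dict:
    """JSON-serialisable summary of a fitted generator."""
    return {
        "rotation_matrix": t.rotation.tolist(),
        "translation_angstrom": t.translation.tolist(),
        "rmsd_angstrom": t.rmsd,
        "rotation_angle_deg": t.rotation_angle,
        "screw_axis": t.screw_axis.tolist(),
        "rise_angstrom": t.rise,
        "handedness": t.handedness,
    }
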