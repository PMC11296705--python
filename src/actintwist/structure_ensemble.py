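"""Conformational-ensemble analysis of actin chains.

Parses deposited structures (PDB/mmCIF), maps the residues common to an
ensemble of chains, superposes every chain on a reference using only the
inner domain (SD3+SD4), and performs PCA on the Cα coordinate deviations.
The leading components separate the monomeric (G), filamentous (F) and
cofilin-remodelled (C) conformations of the actin protomer; modes can be
back-projected onto coordinates for visualisation.

Coordinates are in Å throughout.  Residues are indexed in mature-sequence
("gene") numbering; a per-entry integer offset absorbs deposits whose
author numbering differs (the N-terminal residues of actin are cleaved
post-translationally, so some entries are shifted by a small constant).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence
from urllib.request import urlretrieve

import numpy as np
import yaml
import biotite.structure as struc
import biotite.structure.io.pdb as pdb_io
import biotite.structure.io.pdbx as pdbx_io


class ChainNotFoundError(KeyError):
    """Requested chain id absent from the structure file."""


class EmptyChainError(ValueError):
    """Chain contains no Cα atoms."""


class DegenerateEnsembleError(ValueError):
    """All ensemble members identical: covariance has zero total variance."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class StructureChain:
    """One protein chain reduced to its Cα trace.

    ``residue_numbers`` are in gene numbering (deposited id + ``offset``).
    """

    pdb_id: str
    chain_id: str
    residue_numbers: np.ndarray  # (N,) int, strictly increasing
    ca_coords: np.ndarray        # (N, 3) float, Å
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        if self.ca_coords.shape != (len(self.residue_numbers), 3):
            raise ValueError("ca_coords row count must equal residue count")
        if np.any(np.diff(self.residue_numbers) <= 0):
            raise ValueError("residue_numbers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residue_numbers)

    def subset(self, residues: Sequence[int]) -> "StructureChain":
        """Restrict the chain to ``residues`` (which must all be present)."""
        wanted = np.asarray(sorted(residues), dtype=int)
        pos = {r: i for i, r in enumerate(self.residue_numbers)}
        try:
            idx = np.array([pos[r] for r in wanted], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"residue {exc.args[0]} not present in chain") from exc
        return StructureChain(self.pdb_id, self.chain_id, wanted,
                              self.ca_coords[idx], dict(self.annotations))

    @property
    def label(self) -> tuple[str, str]:
        return (self.pdb_id, self.chain_id)


@dataclass
class ResidueSet:
    """Sorted residue set partitioned into the actin subdomains.

    ``subsets`` holds SD1–SD4 plus the derived OD (SD1∪SD2) and
    ID (SD3∪SD4), each intersected with ``residues``.
    """

    residues: np.ndarray
    subsets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.residues = np.unique(np.asarray(self.residues, dtype=int))

    def __len__(self) -> int:
        return len(self.residues)

    def __contains__(self, residue: int) -> bool:
        return bool(np.isin(residue, self.residues))


@dataclass
class RigidTransformResult:
    """Kabsch superposition result: x -> rotation @ x + translation."""

    rotation: np.ndarray     # (3, 3) proper orthogonal
    translation: np.ndarray  # (3,)
    rmsd: float              # over the fitting subset, Å

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class AlignedEnsemble:
    """Common-residue coordinates of every member after ID-only superposition."""

    chain_labels: list[tuple[str, str]]
    coords: np.ndarray  # (M, N, 3) Å
    residues: np.ndarray
    reference_label: tuple[str, str]


@dataclass
class PCAModel:
    mean_coords: np.ndarray         # (N, 3)
    eigenvectors: np.ndarray        # (K, 3N) rows orthonormal
    eigenvalues: np.ndarray         # (K,) descending, Å²
    variance_fractions: np.ndarray  # (K,)
    scores: np.ndarray              # (M, K)
    chain_labels: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def to_json(self, path: str | Path, matrix_path: str | Path | None = None) -> None:
        """Model summary as JSON; eigenvector matrix as a .npy sidecar."""
        path = Path(path)
        if matrix_path is None:
            matrix_path = path.with_suffix(".eigvec.npy")
        np.save(matrix_path, self.eigenvectors)
        payload = {
            "mean_coords": self.mean_coords.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "variance_fractions": self.variance_fractions.tolist(),
            "chain_labels": [list(l) for l in self.chain_labels],
            "eigenvector_matrix": str(matrix_path),
        }
        path.write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# Configuration: subdomain table and chain merges
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(resources.files("actintwist") / "data" / name))


def load_subdomain_table(path: str | Path | None = None) -> dict[str, list[tuple[int, int]]]:
    """Load SD1–SD4 residue ranges (inclusive) from YAML config."""
    path = _data_path("subdomains.yaml") if path is None else Path(path)
    raw = yaml.safe_load(Path(path).read_text())
    return {name: [tuple(r) for r in ranges]
            for name, ranges in raw["subdomains"].items()}


def load_chain_merges(path: str | Path | None = None) -> dict[str, dict[str, list[str]]]:
    path = _data_path("chain_merges.yaml") if path is None else Path(path)
    raw = yaml.safe_load(Path(path).read_text())
    return raw.get("merges", {})


def _ranges_to_set(ranges: Sequence[tuple[int, int]]) -> set[int]:
    out: set[int] = set()
    for lo, hi in ranges:
        out.update(range(lo, hi + 1))
    return out


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _read_atom_array(path: str | Path) -> struc.AtomArray:
    """First model of a PDB or mmCIF file as an AtomArray."""
    path = Path(path)
    if path.suffix.lower() in {".cif", ".mmcif", ".pdbx"}:
        cif = pdbx_io.CIFFile.read(str(path))
        return pdbx_io.get_structure(cif, model=1)
    pdbf = pdb_io.PDBFile.read(str(path))
    return pdb_io.get_structure(pdbf, model=1)


def load_chain(path: str | Path, chain_id: str, *, pdb_id: str | None = None,
               residue_offset: int = 0,
               merge_chains: Sequence[str] | None = None,
               annotations: Mapping | None = None) -> StructureChain:
    """Extract one chain's Cα trace from a structure file.

    ``merge_chains`` concatenates several deposited chain ids into the single
    returned chain (used for entries where one protomer is split across two
    chains).  ``residue_offset`` is added to the deposited residue ids to map
    them onto gene numbering.  Residues without a Cα record are dropped.
    """
    atoms = _read_atom_array(path)
    wanted = list(merge_chains) if merge_chains else [chain_id]
    present = set(np.unique(atoms.chain_id))
    missing = [c for c in wanted if c not in present]
    if missing:
        raise ChainNotFoundError(f"chain not found: {missing} in {path}")
    mask = np.isin(atoms.chain_id, wanted) & (atoms.atom_name == "CA")
    # exclude altloc duplicates and non-amino acid CA (e.g. calcium is "CA"
    # as element but its atom_name is also CA in some depositions)
    mask &= struc.filter_amino_acids(atoms)
    ca = atoms[mask]
    if ca.array_length() == 0:
        raise EmptyChainError(f"empty chain: no C-alpha atoms in {chain_id}")
    res = ca.res_id.astype(int) + residue_offset
    xyz = ca.coord.astype(float)
    # keep first occurrence per residue id, then sort by residue number
    _, first = np.unique(res, return_index=True)
    order = first[np.argsort(res[first])]
    return StructureChain(
        pdb_id=pdb_id or Path(path).stem.upper(),
        chain_id=chain_id,
        residue_numbers=res[order],
        ca_coords=xyz[order],
        annotations=dict(annotations or {}),
    )


def fetch_structure(pdb_id: str, cache_dir: str | Path,
                    fmt: str = "cif", timeout: float = 30.0) -> Path:
    """Download a structure from RCSB into ``cache_dir`` (skips if cached)."""
    import socket

    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    dest = cache_dir / f"{pdb_id.lower()}.{fmt}"
    if dest.exists():
        return dest
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.{fmt}"
    old = socket.getdefaulttimeout()
    socket.setdefaulttimeout(timeout)
    try:
        urlretrieve(url, dest)
    except Exception:
        dest.unlink(missing_ok=True)
        raise
    finally:
        socket.setdefaulttimeout(old)
    return dest


def load_ensemble_table(path: str | Path | None = None):
    """The curated actin-chain list (one row per entry) as a DataFrame."""
    import pandas as pd

    path = _data_path("ensemble_chains.csv") if path is None else Path(path)
    return pd.read_csv(path, keep_default_na=False)


#: mature actin chains lack the first two gene-encoded residues, so the
#: deposited numbering maps onto gene numbering with a +2 shift by default
#: (configurable per entry).
DEFAULT_GENE_OFFSET = 2


def load_structure_ensemble(cache_dir: str | Path,
                            table=None,
                            merges: dict | None = None,
                            residue_offset: int = DEFAULT_GENE_OFFSET,
                            fetch: bool = True) -> list[StructureChain]:
    """Load every chain of the curated ensemble from a structure cache.

    Structures are read from ``cache_dir`` (downloaded from RCSB when
    ``fetch`` and missing).  Split chains are merged per the shipped merge
    table; all residue ids are shifted onto gene numbering.
    """
    if table is None:
        table = load_ensemble_table()
    if merges is None:
        merges = load_chain_merges()
    chains: list[StructureChain] = []
    for _, row in table.iterrows():
        pdb_id = row["pdb_id"]
        path = Path(cache_dir) / f"{pdb_id.lower()}.cif"
        if not path.exists():
            if not fetch:
                raise FileNotFoundError(f"{path} missing and fetch disabled")
            path = fetch_structure(pdb_id, cache_dir)
        entry_merges = merges.get(pdb_id, {})
        skip = {c for group in entry_merges.values() for c in group[1:]}
        for chain_id in row["chains"].split("|"):
            if chain_id in skip:
                continue
            chains.append(load_chain(
                path, chain_id,
                pdb_id=pdb_id,
                residue_offset=residue_offset,
                merge_chains=entry_merges.get(chain_id),
                annotations={
                    "nucleotide": row.get("nucleotide", ""),
                    "protein_bound": row.get("protein_bound", ""),
                    "structural_class": row.get("structural_class", ""),
                }))
    return chains


# ---------------------------------------------------------------------------
# Common residues
# ---------------------------------------------------------------------------

def find_common_residues(chains: Sequence[StructureChain],
                         subdomain_table: Mapping[str, Sequence[tuple[int, int]]] | None = None,
                         ) -> ResidueSet:
    """Intersect residue numbers over the ensemble and partition by subdomain.

    All chains are the same protein in gene numbering, so the common-residue
    map is a plain set intersection after offset normalisation.
    """
    if len(chains) < 2:
        raise ValueError("need at least two chains")
    common = set(chains[0].residue_numbers.tolist())
    for ch in chains[1:]:
        common &= set(ch.residue_numbers.tolist())
    if not common:
        raise ValueError("no common residues")
    if subdomain_table is None:
        subdomain_table = load_subdomain_table()
    subsets: dict[str, np.ndarray] = {}
    for name, ranges in subdomain_table.items():
        subsets[name] = np.array(sorted(_ranges_to_set(ranges) & common), dtype=int)
    subsets["OD"] = np.union1d(subsets.get("SD1", []), subsets.get("SD2", [])).astype(int)
    subsets["ID"] = np.union1d(subsets.get("SD3", []), subsets.get("SD4", [])).astype(int)
    return ResidueSet(residues=np.array(sorted(common), dtype=int), subsets=subsets)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, reference: np.ndarray) -> RigidTransformResult:
    """Least-squares proper rotation + translation mapping mobile onto reference."""
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be matching (N, 3) arrays")
    if len(mobile) < 3:
        raise ValueError("underdetermined superposition: need >= 3 atoms")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return RigidTransformResult(rotation=rot, translation=trans, rmsd=rmsd)


def superpose_on_subset(mobile: StructureChain, reference: StructureChain,
                        subset: ResidueSet | Sequence[int],
                        subset_name: str = "ID",
                        ) -> tuple[np.ndarray, RigidTransformResult]:
    """Superpose ``mobile`` on ``reference`` fitting only the given residues.

    The transform is computed on the subset (e.g. the inner domain) and then
    applied to *all* residues shared by the two chains, so displacements of
    the unfitted domain are preserved in the returned coordinates.
    """
    if isinstance(subset, ResidueSet):
        sub_res = subset.subsets.get(subset_name, subset.residues)
    else:
        sub_res = np.asarray(sorted(subset), dtype=int)
    shared = np.intersect1d(mobile.residue_numbers, reference.residue_numbers)
    sub_res = np.intersect1d(sub_res, shared)
    if len(sub_res) < 3:
        raise ValueError("underdetermined superposition: < 3 subset atoms")
    t = kabsch(mobile.subset(sub_res).ca_coords, reference.subset(sub_res).ca_coords)
    return t.apply(mobile.subset(shared).ca_coords), t


def align_ensemble(chains: Sequence[StructureChain],
                   common: ResidueSet | None = None,
                   subset_name: str = "ID",
                   subset: Sequence[int] | None = None,
                   reference_index: int = 0) -> AlignedEnsemble:
    """Subset-only superposition of every chain onto the reference member.

    By default the inner domain (``subset_name="ID"``) anchors the
    alignment so outer-domain motions stay visible; pass an explicit
    ``subset`` of residue numbers to override (e.g. for structures whose
    numbering does not follow the actin convention).
    """
    if common is None:
        common = find_common_residues(chains)
    if subset is None:
        fit_subset: ResidueSet | Sequence[int] = common
    else:
        fit_subset = subset
    ref = chains[reference_index].subset(common.residues)
    coords = np.empty((len(chains), len(common.residues), 3))
    for i, ch in enumerate(chains):
        moved, _ = superpose_on_subset(ch.subset(common.residues), ref, fit_subset,
                                       subset_name=subset_name)
        coords[i] = moved
    return AlignedEnsemble(
        chain_labels=[ch.label for ch in chains],
        coords=coords,
        residues=common.residues.copy(),
        reference_label=chains[reference_index].label,
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def fit_pca(ensemble: AlignedEnsemble, n_components: int | None = None,
            orient_positive: int | None = None) -> PCAModel:
    """PCA of flattened Cα coordinate deviations from the ensemble mean.

    The covariance of the (M, 3N) deviation matrix is eigendecomposed (via
    SVD, unweighted atoms); eigenvalues are in descending order and scores
    are the projections of each member onto the eigenvectors.

    ``orient_positive`` optionally gives the index of a member (typically an
    F-actin reference) whose score is forced non-negative on every component,
    fixing the arbitrary eigenvector signs.
    """
    m, n, _ = ensemble.coords.shape
    if m < 3:
        raise ValueError("need at least 3 ensemble members")
    flat = ensemble.coords.reshape(m, 3 * n)
    mean = flat.mean(axis=0)
    dev = flat - mean
    total_var = float(np.sum(dev ** 2))
    if total_var < 1e-12:
        raise DegenerateEnsembleError("degenerate ensemble: zero total variance")
    # SVD of deviations == eigendecomposition of the covariance
    u, s, vt = np.linalg.svd(dev, full_matrices=False)
    eigvals = s ** 2 / m  # biased covariance normalisation
    k = min(m - 1, 3 * n) if n_components is None else min(n_components, len(eigvals))
    eigvals = eigvals[:k]
    eigvecs = vt[:k]
    scores = dev @ eigvecs.T
    if orient_positive is not None:
        flips = np.where(scores[orient_positive] < 0, -1.0, 1.0)
        eigvecs = eigvecs * flips[:, None]
        scores = scores * flips[None, :]
    denom = float(np.sum(s ** 2 / m))
    fractions = eigvals / denom
    return PCAModel(
        mean_coords=mean.reshape(n, 3),
        eigenvectors=eigvecs,
        eigenvalues=eigvals,
        variance_fractions=fractions,
        scores=scores,
        chain_labels=list(ensemble.chain_labels),
    )


def synthesize_mode(model: PCAModel, pc_index: int, amplitude: float) -> np.ndarray:
    """Back-project one principal component onto coordinates.

    Returns ``mean + amplitude * eigenvector`` reshaped to (N, 3); amplitude
    is in Å (score units).
    """
    if not 0 <= pc_index < model.n_components:
        raise IndexError(f"no such component: {pc_index}")
    disp = model.eigenvectors[pc_index].reshape(-1, 3)
    return model.mean_coords + amplitude * disp


def scores_table(model: PCAModel, n_components: int = 2):
    """Per-chain scores as a DataFrame (pdb_id, chain_id, PC1..PCk)."""
    import pandas as pd

    k = min(n_components, model.n_components)
    data = {
        "pdb_id": [l[0] for l in model.chain_labels],
        "chain_id": [l[1] for l in model.chain_labels],
    }
    for j in range(k):
        data[f"PC{j + 1}"] = model.scores[:, j]
    return pd.DataFrame(data)


def write_mode_pdb(coords: np.ndarray, residue_numbers: np.ndarray,
                   path: str | Path, chain_id: str = "A") -> None:
    """Write a synthesized Cα model as a PDB file."""
    n = len(residue_numbers)
    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(coords, float)
    atoms.chain_id = np.full(n, chain_id)
    atoms.res_id = np.asarray(residue_numbers, int)
    atoms.res_name = np.full(n, "ALA")
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    f = pdb_io.PDBFile()
    pdb_io.set_structure(f, atoms)
    f.write(str(path))
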