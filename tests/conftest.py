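"""Shared fixtures: synthetic chains, rendered filaments, tiny PDB files."""

import numpy as np
import pytest

from actintwist import (
    SyntheticFilamentSpec, render_filament, make_synthetic_actin_chain,
)


def _pdb_atom(serial, name, res_name, chain, res_id, x, y, z, element="C"):
    return (f"ATOM  {serial:>5}  {name:<3} {res_name:>3} {chain}{res_id:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2}\n")


@pytest.fixture
def tiny_pdb(tmp_path):
    """Three-residue chain A plus a two-residue chain B."""
    lines = []
    serial = 1
    for i, (x, y, z) in enumerate([(0, 0, 0), (3.8, 0, 0), (7.6, 0, 0.5)], start=1):
        lines.append(_pdb_atom(serial, "CA", "ALA", "A", i, x, y, z))
        serial += 1
    for i, (x, y, z) in enumerate([(0, 5, 0), (3.8, 5, 0)], start=1):
        lines.append(_pdb_atom(serial, "CA", "GLY", "B", i, x, y, z))
        serial += 1
    lines.append("END\n")
    path = tmp_path / "tiny.pdb"
    path.write_text("".join(lines))
    return path


@pytest.fixture
def merge_pdb(tmp_path):
    """Chain split across ids E and H, as in split-protomer depositions."""
    lines = []
    serial = 1
    for i in range(1, 4):
        lines.append(_pdb_atom(serial, "CA", "ALA", "E", i, 3.8 * i, 0, 0))
        serial += 1
    for i in range(4, 6):
        lines.append(_pdb_atom(serial, "CA", "ALA", "H", i, 3.8 * i, 0, 0))
        serial += 1
    lines.append("END\n")
    path = tmp_path / "merge.pdb"
    path.write_text("".join(lines))
    return path


@pytest.fixture
def missing_ca_pdb(tmp_path):
    """Residue 2 has only a CB record: it must be dropped on load."""
    lines = [
        _pdb_atom(1, "CA", "ALA", "A", 1, 0, 0, 0),
        _pdb_atom(2, "CB", "ALA", "A", 2, 3.8, 1, 0),
        _pdb_atom(3, "CA", "ALA", "A", 3, 7.6, 0, 0),
        "END\n",
    ]
    path = tmp_path / "gap.pdb"
    path.write_text("".join(lines))
    return path


@pytest.fixture(scope="session")
def base_chain():
    return make_synthetic_actin_chain(120, seed=0)


@pytest.fixture(scope="session")
def canonical_render():
    """Rendered 62-protomer bare filament at the canonical twist, seed 1."""
    spec = SyntheticFilamentSpec(seed=1)
    return render_filament(spec)


@pytest.fixture(scope="session")
def quiet_render():
    """Noise-free, unquantized canonical render for geometric oracles."""
    from actintwist import ImagingParams

    spec = SyntheticFilamentSpec(
        seed=0, imaging=ImagingParams(noise_sigma=0.0, z_step=0.0))
    return render_filament(spec)


@pytest.fixture
def rng():
    """Fresh deterministic generator per test (no cross-test coupling)."""
    return np.random.default_rng(12345)
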