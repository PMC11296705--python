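"""Chain loading, common-residue mapping, subset superposition and PCA."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from actintwist import (
    StructureChain, load_chain, find_common_residues, superpose_on_subset,
    align_ensemble, fit_pca, synthesize_mode, kabsch,
    make_mode_ensemble, make_synthetic_actin_chain, rotation_mode,
    load_subdomain_table, load_chain_merges,
    DegenerateEnsembleError, ChainNotFoundError,
)


class TestLoadChain:
    def test_reads_calpha_in_file_order(self, tiny_pdb):
        ch = load_chain(tiny_pdb, "A")
        assert len(ch) == 3
        assert ch.residue_numbers.tolist() == [1, 2, 3]
        np.testing.assert_allclose(ch.ca_coords[1], [3.8, 0, 0])

    def test_missing_chain_raises(self, tiny_pdb):
        with pytest.raises(ChainNotFoundError, match="chain not found"):
            load_chain(tiny_pdb, "Z")

    def test_chain_merge(self, merge_pdb):
        ch = load_chain(merge_pdb, "E", merge_chains=["E", "H"])
        assert len(ch) == 5
        assert ch.residue_numbers.tolist() == [1, 2, 3, 4, 5]

    def test_merge_table_ships_the_split_entries(self):
        merges = load_chain_merges()
        assert merges["6UC4"]["E"] == ["E", "H"]
        assert merges["6UC4"]["F"] == ["F", "G"]
        assert merges["6UBY"]["G"] == ["G", "H"]

    def test_residue_without_ca_is_dropped(self, missing_ca_pdb):
        ch = load_chain(missing_ca_pdb, "A")
        assert len(ch) == 2
        assert ch.residue_numbers.tolist() == [1, 3]

    def test_residue_offset_maps_to_gene_numbering(self, tiny_pdb):
        ch = load_chain(tiny_pdb, "A", residue_offset=2)
        assert ch.residue_numbers.tolist() == [3, 4, 5]


class TestCommonResidues:
    def test_identical_chains_give_full_set(self, base_chain):
        rs = find_common_residues([base_chain, base_chain])
        assert rs.residues.tolist() == base_chain.residue_numbers.tolist()

    def test_engineered_deletions_intersect(self, base_chain):
        def with_residues(res):
            return base_chain.subset(res)

        chains = [with_residues(range(1, 11)), with_residues(range(2, 11)),
                  with_residues(range(1, 10))]
        rs = find_common_residues(chains)
        assert rs.residues.tolist() == list(range(2, 10))

    def test_empty_intersection_raises(self, base_chain):
        a = base_chain.subset(range(1, 10))
        b = base_chain.subset(range(50, 60))
        with pytest.raises(ValueError, match="no common residues"):
            find_common_residues([a, b])

    def test_subdomain_partition_is_disjoint_and_contained(self):
        table = load_subdomain_table()
        chain = make_synthetic_actin_chain(375, seed=4)
        rs = find_common_residues([chain, chain], table)
        sds = [set(rs.subsets[k].tolist()) for k in ("SD1", "SD2", "SD3", "SD4")]
        for i in range(4):
            assert sds[i] <= set(rs.residues.tolist())
            for j in range(i + 1, 4):
                assert not sds[i] & sds[j]
        assert set(rs.subsets["ID"].tolist()) == sds[2] | sds[3]
        assert set(rs.subsets["OD"].tolist()) == sds[0] | sds[1]


class TestSuperposition:
    def test_self_superposition_is_identity(self, base_chain):
        rs = find_common_residues([base_chain, base_chain])
        moved, t = superpose_on_subset(base_chain, base_chain, rs.residues)
        assert t.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(moved, base_chain.ca_coords, atol=1e-9)

    def test_recovers_known_rotation(self, base_chain):
        rot = Rotation.from_rotvec(np.radians(170) * np.array([0, 0, 1.0]))
        mobile = StructureChain(
            "M", "A", base_chain.residue_numbers,
            base_chain.ca_coords @ rot.as_matrix().T + np.array([5.0, -3.0, 2.0]))
        moved, t = superpose_on_subset(mobile, base_chain,
                                       base_chain.residue_numbers)
        assert t.rmsd == pytest.approx(0.0, abs=1e-8)
        angle = np.degrees(Rotation.from_matrix(t.rotation).magnitude())
        assert angle == pytest.approx(170.0, abs=1e-6)

    def test_hinge_rotation_preserved_by_subset_alignment(self, base_chain):
        """Aligning on the static domain keeps the rotated domain displaced."""
        od = base_chain.residue_numbers < 60
        id_res = base_chain.residue_numbers[~od]
        pivot = base_chain.ca_coords[60]
        rot = Rotation.from_rotvec(np.radians(10) * np.array([0, 0, 1.0]))
        coords = base_chain.ca_coords.copy()
        coords[od] = (coords[od] - pivot) @ rot.as_matrix().T + pivot
        mobile = StructureChain("M", "A", base_chain.residue_numbers, coords)
        moved, t = superpose_on_subset(mobile, base_chain, id_res)
        assert t.rmsd == pytest.approx(0.0, abs=1e-8)
        od_disp = np.linalg.norm(moved[od] - base_chain.ca_coords[od], axis=1)
        assert od_disp.max() > 1.0

    def test_underdetermined_raises(self, base_chain):
        with pytest.raises(ValueError, match="underdetermined"):
            kabsch(base_chain.ca_coords[:2], base_chain.ca_coords[:2])


class TestPCA:
    def test_degenerate_ensemble_raises(self, base_chain):
        ens = align_ensemble([base_chain] * 3,
                             subset=base_chain.residue_numbers)
        with pytest.raises(DegenerateEnsembleError):
            fit_pca(ens)

    def test_planted_mode_dominates_and_correlates(self, base_chain):
        mask = base_chain.residue_numbers < 60
        mode = rotation_mode(base_chain, mask, axis=[0, 0, 1],
                             pivot=base_chain.ca_coords[60])
        amps = np.linspace(-10, 10, 21)
        chains, _ = make_mode_ensemble(base_chain, mode, amps,
                                       noise_sigma=0.05, seed=0)
        ens = align_ensemble(chains, subset=np.arange(61, 121))
        model = fit_pca(ens)
        assert model.variance_fractions[0] >= 0.95
        corr = np.corrcoef(amps, model.scores[:, 0])[0, 1]
        assert abs(corr) >= 0.99

    def test_two_orthogonal_modes_split_variance(self, base_chain):
        m1 = rotation_mode(base_chain, base_chain.residue_numbers <= 30,
                           axis=[0, 0, 1], pivot=base_chain.ca_coords[60])
        m2 = rotation_mode(base_chain,
                           (base_chain.residue_numbers > 30)
                           & (base_chain.residue_numbers <= 60),
                           axis=[1, 0, 0], pivot=base_chain.ca_coords[60])
        rng = np.random.default_rng(7)
        a1 = rng.normal(0, 1, 60)
        a2 = rng.normal(0, 1, 60)
        a1 *= np.sqrt(45) / (np.std(a1) * np.linalg.norm(m1))
        a2 *= np.sqrt(28) / (np.std(a2) * np.linalg.norm(m2))
        chains, _ = make_mode_ensemble(base_chain, m1, a1, noise_sigma=0.0,
                                       seed=1, extra_modes=[(m2, a2)])
        model = fit_pca(align_ensemble(chains, subset=np.arange(61, 121)))
        fracs = model.variance_fractions[:2]
        assert fracs[0] == pytest.approx(45 / 73, abs=0.05)
        assert fracs[1] == pytest.approx(28 / 73, abs=0.05)

    def test_orthonormality_and_reconstruction(self, base_chain):
        mask = base_chain.residue_numbers < 60
        mode = rotation_mode(base_chain, mask, axis=[0, 1, 0],
                             pivot=base_chain.ca_coords[70])
        chains, _ = make_mode_ensemble(base_chain, mode,
                                       np.linspace(-5, 5, 11),
                                       noise_sigma=0.1, seed=3)
        ens = align_ensemble(chains, subset=np.arange(61, 121))
        model = fit_pca(ens)
        gram = model.eigenvectors @ model.eigenvectors.T
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-9)
        assert model.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)
        rec = model.mean_coords.reshape(1, -1) + model.scores @ model.eigenvectors
        np.testing.assert_allclose(rec.reshape(ens.coords.shape), ens.coords,
                                   atol=1e-6)

    def test_variance_fractions_invariant_under_global_rotation(self, base_chain):
        mask = base_chain.residue_numbers < 60
        mode = rotation_mode(base_chain, mask, axis=[0, 0, 1],
                             pivot=base_chain.ca_coords[60])
        chains, _ = make_mode_ensemble(base_chain, mode,
                                       np.linspace(-8, 8, 15),
                                       noise_sigma=0.05, seed=5)
        rot = Rotation.from_euler("xyz", [20, 30, 40], degrees=True).as_matrix()
        rotated = [StructureChain(c.pdb_id, c.chain_id, c.residue_numbers,
                                  c.ca_coords @ rot.T) for c in chains]
        f1 = fit_pca(align_ensemble(chains, subset=np.arange(61, 121)))
        f2 = fit_pca(align_ensemble(rotated, subset=np.arange(61, 121)))
        np.testing.assert_allclose(f1.variance_fractions[:5],
                                   f2.variance_fractions[:5], atol=1e-9)


@pytest.fixture(scope="module")
def model(base_chain):
    mask = base_chain.residue_numbers < 60
    mode = rotation_mode(base_chain, mask, axis=[0, 0, 1],
                         pivot=base_chain.ca_coords[60])
    chains, _ = make_mode_ensemble(base_chain, mode,
                                   np.linspace(-10, 10, 21),
                                   noise_sigma=0.05, seed=0)
    ens = align_ensemble(chains, subset=np.arange(61, 121))
    return fit_pca(ens), ens


class TestSynthesizeMode:

    def test_zero_amplitude_is_the_mean(self, model):
        m, _ = model
        np.testing.assert_allclose(synthesize_mode(m, 0, 0.0), m.mean_coords)

    def test_linearity_midpoint(self, model):
        m, _ = model
        plus = synthesize_mode(m, 0, 4.2)
        minus = synthesize_mode(m, 0, -4.2)
        np.testing.assert_allclose((plus + minus) / 2, m.mean_coords, atol=1e-9)

    def test_reproduces_planted_member_within_noise(self, model):
        m, ens = model
        k = 3  # an arbitrary member
        synth = synthesize_mode(m, 0, float(m.scores[k, 0]))
        resid = np.linalg.norm(synth - ens.coords[k], axis=1)
        # everything but the planted mode is noise at sigma = 0.05 A
        assert np.percentile(resid, 95) < 0.3

    def test_out_of_range_component(self, model):
        m, _ = model
        with pytest.raises(IndexError, match="no such component"):
            synthesize_mode(m, m.n_components + 5, 1.0)
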