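"""PDB reading, residue pairing and Kabsch superposition with refinement."""

import numpy as np
import pytest
from Bio.SVDSuperimposer import SVDSuperimposer
from scipy.spatial.transform import Rotation

from qtykit import (
    ideal_helix_coords,
    kabsch_superpose,
    pair_residues,
    perturb_structure,
    read_structure,
    refine_superpose,
    write_structure,
)
from qtykit.structure import Residue, StructureModel

MINI_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  CA  GLY A   2       3.800   1.500   0.200  1.00  0.00           C
TER
ATOM      5  CA  LEU B  10       9.000   9.000   9.000  1.00  0.00           C
END
"""


def rotation_grid_rmsd(A, B, final_step_deg=0.2):
    """Brute-force oracle: coarse-to-fine Euler-angle grid search for the
    minimum RMSD proper rotation of centered B onto centered A."""
    A0 = A - A.mean(axis=0)
    B0 = B - B.mean(axis=0)

    def best_on(grid):
        R = Rotation.from_euler("zyz", grid, degrees=True).as_matrix()
        moved = np.einsum("mij,nj->mni", R, B0)
        rmsds = np.sqrt(((moved - A0[None]) ** 2).sum(axis=2).mean(axis=1))
        k = int(np.argmin(rmsds))
        return grid[k], float(rmsds[k])

    center, step = np.zeros(3), 12.0
    axes = [np.arange(0.0, 360.0, step),
            np.arange(0.0, 180.0 + step, step),
            np.arange(0.0, 360.0, step)]
    grid = np.array(np.meshgrid(*axes)).reshape(3, -1).T
    center, best = best_on(grid)
    while step > final_step_deg:
        step /= 4.0
        offsets = np.arange(-4 * step, 4 * step + step / 2, step)
        grid = center + np.array(np.meshgrid(*[offsets] * 3)).reshape(3, -1).T
        center, best = best_on(grid)
    return best


class TestReadStructure:
    def test_minimal_fixture(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINI_PDB)
        model = read_structure(p)
        assert model.chain_id == "A"
        assert model.sequence == "AG"
        assert np.allclose(model.residues[0].ca, [1.458, 0.0, 0.0])
        # residue 1 has a full atom list; residue 2 is CA-only
        assert len(model.residues[0].atoms) == 3
        assert model.residues[1].atoms == ()

    def test_chain_selection(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINI_PDB)
        model = read_structure(p, chain="B")
        assert model.sequence == "L"
        assert model.residues[0].resnum == 10

    def test_ca_only_round_trip(self, tmp_path, helix_model):
        p = tmp_path / "helix.pdb"
        write_structure(helix_model, p)
        back = read_structure(p)
        assert back.is_ca_only
        assert back.sequence == helix_model.sequence
        assert np.allclose(back.ca_coords(), helix_model.ca_coords(),
                           atol=1e-3)

    def test_no_residues_errors(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("END\n")
        with pytest.raises(ValueError):
            read_structure(p)

    def test_missing_ca_dropped_with_warning(self, tmp_path):
        p = tmp_path / "noca.pdb"
        p.write_text(
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000"
            "  1.00  0.00           N\n"
            "ATOM      2  CA  GLY A   2       1.000   0.000   0.000"
            "  1.00  0.00           C\nEND\n"
        )
        with pytest.warns(UserWarning, match="alpha-carbon"):
            model = read_structure(p)
        assert model.sequence == "G"


class TestPairResidues:
    def test_identical_models_fully_paired(self, helix_model):
        pairs = pair_residues(helix_model, helix_model, mode="by_resnum")
        assert pairs == [(i, i) for i in range(len(helix_model))]

    def test_by_resnum_skips_missing(self, helix_model):
        pruned = StructureModel(
            id="p", chain_id="A",
            residues=tuple(r for r in helix_model.residues
                           if not 5 <= r.resnum <= 10),
        )
        pairs = pair_residues(helix_model, pruned, mode="by_resnum")
        paired_nums = {helix_model.residues[i].resnum for i, _ in pairs}
        assert paired_nums.isdisjoint(range(5, 11))
        assert len(pairs) == len(helix_model) - 6

    def test_by_sequence_ignores_identity(self, helix_model):
        relabelled = helix_model.with_sequence("Q" * len(helix_model))
        pairs = pair_residues(helix_model, relabelled, mode="by_sequence")
        assert len(pairs) == len(helix_model)

    def test_by_sequence_unequal_lengths_error(self, helix_model):
        shorter = StructureModel(
            id="s", chain_id="A", residues=helix_model.residues[:-1]
        )
        with pytest.raises(ValueError):
            pair_residues(helix_model, shorter, mode="by_sequence")


class TestKabsch:
    def test_rigid_motion_rmsd_zero(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(50, 3))
        R = Rotation.from_euler("xyz", [31, -57, 112], degrees=True).as_matrix()
        B = A @ R.T + np.array([5.0, -3.0, 11.0])
        res = kabsch_superpose(A, B)
        assert res.rmsd_all < 1e-9
        assert np.isclose(np.linalg.det(res.rotation), 1.0, atol=1e-6)

    def test_collinear_closed_form(self):
        # scale mismatch along one axis cannot be rotated away:
        # per-point residuals 0.5, 0.5, 0 -> RMSD sqrt(1/6)
        A = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0.0, 0, 0]])
        B = np.array([[0.5, 0, 0], [-0.5, 0, 0], [0.0, 0, 0]])
        res = kabsch_superpose(A, B)
        assert res.rmsd_all == pytest.approx(np.sqrt(1.0 / 6.0), abs=1e-9)
        assert res.degenerate

    def test_matches_rotation_grid_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(3):
            A = rng.normal(size=(5, 3))
            B = rng.normal(size=(5, 3))
            ours = kabsch_superpose(A, B).rmsd_all
            assert ours == pytest.approx(rotation_grid_rmsd(A, B), abs=1e-3)
            assert ours <= rotation_grid_rmsd(A, B) + 1e-9  # true minimum

    def test_matches_biopython_svd_superimposer(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            A = rng.normal(size=(20, 3))
            B = rng.normal(size=(20, 3))
            sup = SVDSuperimposer()
            sup.set(A, B)
            sup.run()
            assert kabsch_superpose(A, B).rmsd_all == pytest.approx(
                float(sup.get_rms()), abs=1e-9
            )

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_symmetry_and_orthonormality(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(30, 3))
        B = A + rng.normal(scale=0.5, size=(30, 3))
        fwd, rev = kabsch_superpose(A, B), kabsch_superpose(B, A)
        assert fwd.rmsd_all == pytest.approx(rev.rmsd_all, abs=1e-9)
        assert np.allclose(fwd.rotation.T @ fwd.rotation, np.eye(3),
                           atol=1e-9)

    def test_rmsd_invariant_under_rigid_transform_of_input(self):
        rng = np.random.default_rng(6)
        A = rng.normal(size=(25, 3))
        B = A + rng.normal(scale=0.3, size=(25, 3))
        base = kabsch_superpose(A, B).rmsd_all
        R = Rotation.from_euler("zyx", [10, 20, 30], degrees=True).as_matrix()
        moved = kabsch_superpose(A, B @ R.T + 7.0)
        assert moved.rmsd_all == pytest.approx(base, abs=1e-9)


class TestRefineSuperpose:
    def test_identical_structures(self, helix_model):
        res = refine_superpose(helix_model, helix_model)
        assert res.rmsd_all == pytest.approx(0.0, abs=1e-9)
        assert res.rmsd_refined == pytest.approx(0.0, abs=1e-9)
        assert res.n_kept == res.n_paired == len(helix_model)

    def test_planted_outliers_excluded(self):
        model = ideal_helix_coords("A" * 100)
        noisy = perturb_structure(model, noise_sd=0.3, seed=11)
        outlier_idx = [7, 23, 50, 77, 93]
        residues = list(noisy.residues)
        for i in outlier_idx:
            r = residues[i]
            residues[i] = Residue(r.resnum, r.aa, r.ca + np.array([10.0, 0, 0]))
        planted = StructureModel(id="o", chain_id="A",
                                 residues=tuple(residues))
        res = refine_superpose(model, planted)
        assert set(outlier_idx).isdisjoint(res.kept)
        assert res.n_kept <= 95
        # reference: clean-subset Kabsch RMSD
        clean = [i for i in range(100) if i not in outlier_idx]
        clean_rmsd = kabsch_superpose(
            model.ca_coords()[clean], noisy.ca_coords()[clean]
        ).rmsd_all
        assert res.rmsd_refined <= res.rmsd_all
        assert res.rmsd_refined == pytest.approx(clean_rmsd, rel=0.10)

    def test_rmsd_refined_non_increasing_with_cycles(self):
        model = ideal_helix_coords("A" * 80)
        noisy = perturb_structure(model, noise_sd=1.0, seed=3)
        prev = np.inf
        for cycles in range(1, 6):
            r = refine_superpose(model, noisy, cycles=cycles)
            assert r.rmsd_refined <= prev + 1e-12
            prev = r.rmsd_refined

    def test_overly_aggressive_cutoff_errors(self):
        model = ideal_helix_coords("A" * 30)
        noisy = perturb_structure(model, noise_sd=1.0, seed=9)
        with pytest.raises(ValueError):
            refine_superpose(model, noisy, cycles=50, sigma_cutoff=0.01)
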