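"""Coordinate model, PDB I/O, geometry and conformational clustering."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sansemble.structures import (Ensemble, kabsch_superpose, kmeans_cluster,
                                  radius_of_gyration, read_pdb, rmsd, rotate_z,
                                  write_pdb)
from sansemble.synthetic_data import PentamerSpec, build_toy_pentamer

from conftest import single_bead_structure


class TestRadiusOfGyration:
    def test_single_point_is_zero(self):
        assert radius_of_gyration([[1.0, 2.0, 3.0]], [7.0]) == 0.0

    def test_two_unit_points_two_angstrom_apart(self):
        assert radius_of_gyration([[0, 0, 0], [2, 0, 0]]) == pytest.approx(1.0)

    def test_uniform_sphere_matches_closed_form(self):
        # Monte-Carlo points in a solid sphere vs √(3/5)·R
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(10_000, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts *= 50.0 * rng.random(10_000)[:, None] ** (1 / 3)
        assert radius_of_gyration(pts) == pytest.approx(np.sqrt(3 / 5) * 50.0,
                                                        rel=0.02)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            radius_of_gyration([[0, 0, 0], [1, 0, 0]], [0.0, 0.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            radius_of_gyration([[0, 0, 0]], [1.0, 1.0])

    @given(st.integers(0, 2 ** 31 - 1))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(20, 3)) * 10
        w = rng.random(20) + 0.1
        base = radius_of_gyration(pts, w)
        shifted = pts + rng.normal(size=3) * 100
        rotated = rotate_z(pts, rng.uniform(0, 360))
        assert radius_of_gyration(shifted, w) == pytest.approx(base, abs=1e-8)
        assert radius_of_gyration(rotated, w) == pytest.approx(base, abs=1e-8)


class TestRmsd:
    def test_identical_frames_zero(self):
        pts = np.random.default_rng(0).normal(size=(30, 3))
        assert rmsd(pts, pts) == 0.0

    def test_rotated_copy_superposes_to_zero(self):
        pts = np.random.default_rng(1).normal(size=(30, 3)) * 5
        rot = rotate_z(pts, 90.0) + np.array([3.0, -2.0, 7.0])
        assert rmsd(rot, pts, superpose=True) == pytest.approx(0.0, abs=1e-9)
        assert rmsd(rot, pts, superpose=False) > 1.0

    def test_matches_brute_force_arithmetic(self):
        a = np.array([[0, 0, 0], [1, 0, 0], [0, 2, 0], [0, 0, 3]], float)
        b = a + np.array([[0.1, 0, 0], [0, 0.2, 0], [0, 0, 0.3], [0.4, 0, 0]])
        expected = np.sqrt(sum((np.linalg.norm(x - y) ** 2
                                for x, y in zip(a, b))) / 4)
        assert rmsd(a, b) == pytest.approx(expected)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(2, 15, 3))
        assert rmsd(a, b) == pytest.approx(rmsd(b, a))

    def test_atom_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


class TestPdbIO:
    def test_pentamer_roundtrip(self, pentamer, tmp_path):
        path = tmp_path / "pent.pdb"
        write_pdb(pentamer, path)
        back = read_pdb(path)
        assert back.chains() == ["A", "B", "C", "D", "E"]
        assert back.n_atoms == pentamer.n_atoms
        # PDB format stores 3 decimals
        assert np.abs(back.positions - pentamer.positions).max() < 1e-3

    def test_two_model_file_selects_requested_model(self, tmp_path):
        lines = []
        for m, x in ((1, 1.0), (2, 9.0)):
            lines.append(f"MODEL     {m:4d}")
            lines.append(f"ATOM      1  CA  ALA A   1    {x:8.3f}{0.0:8.3f}"
                         f"{0.0:8.3f}  1.00  0.00           C")
            lines.append("ENDMDL")
        path = tmp_path / "two.pdb"
        path.write_text("\n".join(lines) + "\nEND\n")
        s2 = read_pdb(path, model_index=2)
        assert s2.positions[0, 0] == pytest.approx(9.0)

    def test_missing_model_reported(self, tmp_path):
        path = tmp_path / "one.pdb"
        path.write_text("ATOM      1  CA  ALA A   1       0.000   0.000"
                        "   0.000  1.00  0.00           C\nEND\n")
        with pytest.raises(ValueError, match="model 5"):
            read_pdb(path, model_index=5)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_pdb(tmp_path / "absent.pdb")


class TestKMeans:
    @staticmethod
    def _two_group_ensemble():
        """Frames jittered around a symmetric and a displaced conformer."""
        rng = np.random.default_rng(5)
        sym = build_toy_pentamer()
        asym = build_toy_pentamer(PentamerSpec(
            radial_disp=np.array([8.0, 0, 0, 0, 0]),
            tilt_deg=np.array([10.0, 0, 0, 0, 0])))
        frames, labels = [], []
        for base, lab in ((sym, 0), (asym, 1)):
            for _ in range(6):
                frames.append(base.positions + rng.normal(0, 0.3,
                                                          base.positions.shape))
                labels.append(lab)
        return Ensemble(sym, np.array(frames)), np.array(labels)

    def test_two_separated_groups_recovered(self):
        ens, labels = self._two_group_ensemble()
        res = kmeans_cluster(ens, 2, seed=0)
        # same partition up to label swap
        agree = (res.assignments == labels).mean()
        assert agree in (0.0, 1.0)
        assert len(res.centroid_frames) == 2

    def test_k_equals_frames_gives_zero_inertia(self):
        ens, _ = self._two_group_ensemble()
        res = kmeans_cluster(ens, ens.n_frames, seed=0)
        assert res.inertia == pytest.approx(0.0, abs=1e-6)

    def test_same_seed_is_deterministic(self):
        ens, _ = self._two_group_ensemble()
        a = kmeans_cluster(ens, 3, seed=42)
        b = kmeans_cluster(ens, 3, seed=42)
        assert np.array_equal(a.assignments, b.assignments)

    def test_inertia_nonincreasing_in_k(self):
        ens, _ = self._two_group_ensemble()
        inertias = [kmeans_cluster(ens, k, seed=7).inertia for k in (1, 2, 4, 6)]
        assert all(x >= y - 1e-9 for x, y in zip(inertias, inertias[1:]))

    def test_invalid_k_rejected(self):
        ens, _ = self._two_group_ensemble()
        with pytest.raises(ValueError):
            kmeans_cluster(ens, 0)
        with pytest.raises(ValueError):
            kmeans_cluster(ens, ens.n_frames + 1)


class TestContainers:
    def test_ensemble_weight_normalisation_enforced(self, pentamer):
        frames = pentamer.positions[None]
        with pytest.raises(ValueError):
            Ensemble(pentamer, frames, prior_weights=np.array([0.5]))
        ens = Ensemble(pentamer, frames)
        assert ens.prior_weights.sum() == pytest.approx(1.0, abs=1e-13)

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(ValueError):
            single_bead_structure([[0.0, 0.0, np.nan]])

    def test_kabsch_recovers_known_rotation(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(25, 3))
        moved = rotate_z(pts, 33.0) + [1, 2, 3]
        back, rot, _ = kabsch_superpose(moved, pts)
        assert np.abs(back - pts).max() < 1e-9
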