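"""Residue-level coarse graining, hydration layer and Debye sums."""

import numpy as np
import pytest

from sansemble.sans_forward import (ContrastModel, ScatteringCurve,
                                    add_water_layer, coarse_grain,
                                    debye_intensity, ensemble_intensity,
                                    pair_distribution_from_beads, read_dat,
                                    write_dat)
from sansemble.structures import radius_of_gyration, rotate_z

from conftest import single_bead_structure

# independent copies of the standard constants used by the hand-sum oracle
GLY_B_H2O_FM = 17.28
GLY_N_LABILE = 1
GLY_VOLUME = 60.1
B_D2O_FM, WATER_VOL = 19.145, 29.9


class TestCoarseGrain:
    def test_glycine_bead_matches_hand_sum(self):
        s = single_bead_structure([[0.0, 0.0, 0.0]], res_names=["GLY"])
        contrast = ContrastModel(d2o_fraction=1.0, exchange_fraction=1.0)
        beads = coarse_grain(s, contrast)
        expected = (GLY_B_H2O_FM + GLY_N_LABILE * (6.671 - (-3.742))
                    - B_D2O_FM / WATER_VOL * GLY_VOLUME)
        assert beads.b[0] == pytest.approx(expected, rel=1e-10)

    def test_one_bead_per_residue(self, pentamer):
        beads = coarse_grain(pentamer)
        assert beads.n_beads == len(pentamer.residue_keys()) == 350

    def test_unknown_residue_fails_or_skips(self):
        s = single_bead_structure([[0, 0, 0], [4, 0, 0]],
                                  res_names=["GLY", "XYZ"])
        with pytest.raises(KeyError):
            coarse_grain(s)
        beads = coarse_grain(s, on_unknown="skip")
        assert beads.n_beads == 1

    def test_empty_selection_rejected(self, pentamer):
        with pytest.raises(ValueError):
            coarse_grain(pentamer.select(np.zeros(pentamer.n_atoms, bool)))


class TestWaterLayer:
    def test_slab_covering_structure_adds_nothing(self, pentamer):
        beads = coarse_grain(pentamer)
        zmin, zmax = pentamer.positions[:, 2].min(), pentamer.positions[:, 2].max()
        out = add_water_layer(beads, pentamer, (zmin - 1, zmax + 1))
        assert out.n_beads == beads.n_beads

    def test_zero_fraction_is_identity(self, pentamer):
        contrast = ContrastModel(water_layer_fraction=0.0)
        beads = coarse_grain(pentamer, contrast)
        out = add_water_layer(beads, pentamer, contrast=contrast)
        assert out is beads

    def test_exposed_residue_shell_arithmetic(self):
        # two residues: one inside the slab, one far above it
        s = single_bead_structure([[0, 0, 0], [0, 0, 50.0]],
                                  res_names=["GLY", "GLY"])
        contrast = ContrastModel()
        beads = coarse_grain(s, contrast)
        out = add_water_layer(beads, s, (-5.0, 5.0), contrast)
        added = out.b[out.bead_class == "water-layer"]
        assert len(added) == 1
        expected = 0.06 * (B_D2O_FM / WATER_VOL) * contrast.shell_volume
        assert added.sum() == pytest.approx(expected)

    def test_inverted_slab_rejected(self, pentamer):
        beads = coarse_grain(pentamer)
        with pytest.raises(ValueError):
            add_water_layer(beads, pentamer, (10.0, -10.0))

    def test_pentamer_shell_only_outside_membrane(self, pentamer):
        beads = coarse_grain(pentamer)
        out = add_water_layer(beads, pentamer)  # slab from annotation
        shell = out.positions[out.bead_class == "water-layer"]
        zmin, zmax = pentamer.membrane_slab
        assert len(shell) > 0
        assert np.all((shell[:, 2] < zmin + 5) | (shell[:, 2] > zmax - 5))


class TestDebye:
    def test_forward_scattering_is_total_length_squared(self, quad_sphere):
        curve = debye_intensity(quad_sphere, np.array([0.0, 0.001]))
        assert curve.i[0] == pytest.approx(quad_sphere.b.sum() ** 2, rel=1e-12)

    def test_two_beads_at_qd_pi(self):
        from sansemble.sans_forward import BeadModel
        d = 10.0
        beads = BeadModel([[0, 0, 0], [0, 0, d]], [1.0, 1.0],
                          np.array(["protein"] * 2))
        curve = debye_intensity(beads, np.array([np.pi / d]))
        assert curve.i[0] == pytest.approx(2.0, abs=1e-12)

    def test_histogram_path_matches_brute_force(self):
        from sansemble.synthetic_data import uniform_sphere_beads
        beads = uniform_sphere_beads(500, 25.0, seed=3)
        q = np.linspace(0.01, 0.3, 25)
        # brute-force double-sum oracle, written independently
        d = np.linalg.norm(beads.positions[:, None] - beads.positions[None],
                           axis=-1)
        oracle = np.empty(len(q))
        for k, qk in enumerate(q):
            with np.errstate(invalid="ignore"):
                s = np.sin(qk * d) / (qk * d)
            s[np.isnan(s)] = 1.0
            oracle[k] = (np.outer(beads.b, beads.b) * s).sum()
        exact = debye_intensity(beads, q, exact_threshold=2000)
        hist = debye_intensity(beads, q, exact_threshold=0)
        assert np.max(np.abs(exact.i - oracle) / oracle) < 1e-12
        assert np.max(np.abs(hist.i - oracle) / oracle) < 1e-3

    def test_rigid_motion_invariance(self, quad_sphere):
        from sansemble.sans_forward import BeadModel
        q = np.linspace(0.01, 0.2, 15)
        base = debye_intensity(quad_sphere, q)
        moved = BeadModel(rotate_z(quad_sphere.positions, 77.0) + [5, -3, 11],
                          quad_sphere.b, quad_sphere.bead_class)
        assert np.allclose(debye_intensity(moved, q).i, base.i, rtol=1e-10)

    def test_intensity_bounded_by_forward_scattering(self, quad_sphere):
        q = np.linspace(0.0, 0.5, 60)
        curve = debye_intensity(quad_sphere, q)
        assert np.all(curve.i <= curve.i[0] * (1 + 1e-12))

    def test_negative_q_rejected(self, quad_sphere):
        with pytest.raises(ValueError):
            debye_intensity(quad_sphere, np.array([-0.1]))


class TestPairDistribution:
    def test_two_beads_single_bin(self):
        from sansemble.sans_forward import BeadModel
        beads = BeadModel([[0, 0, 0], [7.2, 0, 0]], [1.0, 1.0],
                          np.array(["protein"] * 2))
        pr = pair_distribution_from_beads(beads, bin_width=1.0)
        assert pr.dmax == pytest.approx(7.2)
        occupied = np.flatnonzero(pr.p > 0)
        assert len(occupied) == 1
        assert pr.r[occupied[0]] == pytest.approx(7.5)

    def test_rg_consistent_with_direct_weighting(self, quad_sphere):
        pr = pair_distribution_from_beads(quad_sphere, bin_width=0.5)
        direct = radius_of_gyration(quad_sphere.positions, quad_sphere.b)
        assert pr.rg() == pytest.approx(direct, rel=0.01)

    def test_sphere_shape_matches_closed_form(self):
        from sansemble.synthetic_data import uniform_sphere_beads
        beads = uniform_sphere_beads(3000, 30.0, seed=9)
        pr = pair_distribution_from_beads(beads, bin_width=1.0)
        r, R = pr.r, 30.0
        inside = r < 2 * R
        analytic = np.where(inside,
                            r ** 2 * (1 - 3 * r / (4 * R) + r ** 3 / (16 * R ** 3)),
                            0.0)
        corr = np.corrcoef(pr.p, analytic)[0, 1]
        assert corr > 0.995

    def test_integral_convention(self, quad_sphere):
        # 4π∫p dr = I(0) − Σb²
        pr = pair_distribution_from_beads(quad_sphere, bin_width=0.5)
        lhs = 4 * np.pi * pr.p.sum() * 0.5
        rhs = quad_sphere.b.sum() ** 2 - (quad_sphere.b ** 2).sum()
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_single_bead_rejected(self):
        from sansemble.sans_forward import BeadModel
        beads = BeadModel([[0, 0, 0]], [1.0], np.array(["protein"]))
        with pytest.raises(ValueError):
            pair_distribution_from_beads(beads)


class TestEnsembleIntensity:
    def test_single_frame_identity(self):
        q = np.linspace(0.01, 0.3, 10)
        c = ScatteringCurve(q, np.exp(-q ** 2))
        out = ensemble_intensity([c], np.array([1.0]))
        assert np.array_equal(out.i, c.i)

    def test_convex_combination_arithmetic(self):
        q = np.linspace(0.01, 0.3, 10)
        a = ScatteringCurve(q, np.ones(10))
        b = ScatteringCurve(q, 3 * np.ones(10))
        out = ensemble_intensity([a, b], np.array([0.4, 0.6]))
        assert np.allclose(out.i, 0.4 * 1 + 0.6 * 3)

    def test_grid_mismatch_rejected(self):
        a = ScatteringCurve(np.linspace(0.01, 0.3, 10), np.ones(10))
        b = ScatteringCurve(np.linspace(0.02, 0.4, 10), np.ones(10))
        with pytest.raises(ValueError):
            ensemble_intensity([a, b], np.array([0.5, 0.5]))


def test_dat_roundtrip(tmp_path):
    q = np.linspace(0.01, 0.3, 20)
    curve = ScatteringCurve(q, np.exp(-q ** 2 * 100), 0.01 * np.exp(-q ** 2 * 100))
    path = tmp_path / "curve.dat"
    write_dat(curve, path)
    back = read_dat(path)
    assert np.allclose(back.q, curve.q)
    assert np.allclose(back.i, curve.i)
    assert np.allclose(back.sigma, curve.sigma)
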