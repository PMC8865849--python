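"""BME reweighting, θ selection and the symmetric-fraction scan."""

import itertools

import numpy as np
import pytest

from sansemble.ensemble_reweight import (bme_reweight, differential_reweight,
                                         scan_symmetric_fraction, theta_lcurve)
from sansemble.sans_forward import ScatteringCurve, ensemble_intensity
from sansemble.synthetic_data import (DEFAULT_Q_GRID, NoiseModel,
                                      default_sym_asym_pair,
                                      make_asym_ensemble, make_mixture_dataset)


def _toy_problem(n_frames=3, n_q=20, seed=0):
    rng = np.random.default_rng(seed)
    q = np.linspace(0.01, 0.3, n_q)
    rgs = np.linspace(25, 45, n_frames)
    y = np.array([100 * np.exp(-q ** 2 * r ** 2 / 3) for r in rgs])
    data = ScatteringCurve(q, y[1], np.maximum(0.01 * y[1], 1e-3))
    return y, data


def brute_force_simplex(y, data, theta, resolution):
    """Exhaustive minimiser of Γ(w) = ½χ² − θS_rel on the weight simplex."""
    n = y.shape[0]
    best, best_w = np.inf, None
    steps = int(round(1 / resolution))
    w0 = np.full(n, 1.0 / n)
    for combo in itertools.product(range(steps + 1), repeat=n - 1):
        if sum(combo) > steps:
            continue
        w = np.array(list(combo) + [steps - sum(combo)], float) / steps
        yhat = w @ y
        c2 = (((yhat - data.i) / data.sigma) ** 2).sum()
        nz = w > 0
        s_rel = -(w[nz] * np.log(w[nz] / w0[nz])).sum()
        gamma = 0.5 * c2 - theta * s_rel
        if gamma < best:
            best, best_w = gamma, w
    return best_w


class TestBmeReweight:
    def test_huge_theta_returns_prior(self):
        # entropy domination: residuals of order one, θ = 1e9
        q = np.linspace(0.01, 0.3, 15)
        y = np.array([np.exp(-q ** 2 * r ** 2 / 3) for r in (30, 35, 40)])
        data = ScatteringCurve(q, y[1], np.full(15, 0.3))
        prior = np.array([0.5, 0.3, 0.2])
        res = bme_reweight(y, data, prior, theta=1e9)
        assert np.abs(res.weights - prior).max() < 1e-6

    def test_exact_frame_dominates_at_small_theta(self):
        y, data = _toy_problem()
        res = bme_reweight(y, data, theta=1e-3)
        assert res.weights[1] > 0.99
        assert res.converged

    def test_matches_brute_force_simplex_grid(self):
        y, data = _toy_problem()
        for theta in (0.5, 5.0):
            dual = bme_reweight(y, data, theta=theta)
            oracle = brute_force_simplex(y, data, theta, resolution=0.01)
            assert np.abs(dual.weights - oracle).max() < 0.02

    def test_matches_brute_force_on_four_frames(self):
        y, data = _toy_problem(n_frames=4)
        dual = bme_reweight(y, data, theta=2.0)
        oracle = brute_force_simplex(y, data, 2.0, resolution=0.02)
        assert np.abs(dual.weights - oracle).max() < 0.02

    def test_posterior_never_fits_worse_than_prior(self):
        y, data = _toy_problem(n_frames=5, seed=3)
        prior = np.full(5, 0.2)
        prior_chi2 = (((prior @ y - data.i) / data.sigma) ** 2).sum()
        for theta in (0.1, 1.0, 100.0):
            res = bme_reweight(y, data, prior, theta=theta)
            assert res.chi2 <= prior_chi2 + 1e-6

    def test_entropy_nonpositive_and_phi_eff_in_unit_interval(self):
        y, data = _toy_problem(n_frames=5, seed=4)
        res = bme_reweight(y, data, theta=1.0)
        assert res.s_rel <= 0.0
        assert 0.0 < res.phi_eff <= 1.0

    def test_monotone_in_theta(self):
        y, data = _toy_problem(n_frames=5, seed=5)
        thetas = np.logspace(-2, 3, 8)
        chis = [bme_reweight(y, data, theta=t).chi2 for t in thetas]
        srels = [bme_reweight(y, data, theta=t).s_rel for t in thetas]
        assert all(a <= b + 1e-6 for a, b in zip(chis, chis[1:]))
        assert all(a <= b + 1e-8 for a, b in zip(srels, srels[1:]))


class TestThetaLcurve:
    def test_selection_one_step_below_kink(self):
        y, data = _toy_problem(n_frames=4, seed=6)
        theta_grid = np.logspace(-3, 3, 10)
        theta_sel, trace, degenerate = theta_lcurve(y, data,
                                                    theta_grid=theta_grid)
        assert theta_sel in theta_grid
        if not degenerate:
            xy = np.array([[-t[2], t[1]] for t in trace])
            from sansemble.nma_refine import lcurve_corner
            kink, _ = lcurve_corner(np.log10(np.clip(xy, 1e-12, None) + 1e-12))
            assert theta_sel == theta_grid[max(kink - 1, 0)]

    def test_trace_consistent_with_direct_reweight(self):
        y, data = _toy_problem(n_frames=4, seed=7)
        _, trace, _ = theta_lcurve(y, data, theta_grid=np.logspace(-2, 2, 5))
        for theta, c2, s_rel in trace:
            res = bme_reweight(y, data, theta=theta)
            assert c2 == pytest.approx(res.chi2, rel=1e-6, abs=1e-9)
            assert s_rel == pytest.approx(res.s_rel, rel=1e-5, abs=1e-9)

    def test_needs_at_least_four_thetas(self):
        y, data = _toy_problem()
        with pytest.raises(ValueError):
            theta_lcurve(y, data, theta_grid=np.array([0.1, 1, 10]))


@pytest.fixture(scope="module")
def mixture():
    sym, _ = default_sym_asym_pair(seed=3)
    ens = make_asym_ensemble(8, seed=4)
    data, truth = make_mixture_dataset(0.4, sym, ens, DEFAULT_Q_GRID, seed=5)
    return data, truth


class TestDifferentialReweight:
    def test_f_zero_equals_plain_bme(self, mixture):
        # f = 0 subtracts nothing: identical to plain reweighting of the
        # identically scaled problem
        data, truth = mixture
        y = truth["frame_curves"]
        from sansemble.ensemble_reweight import _guinier_i0
        scale = _guinier_i0(data) / _guinier_i0(truth["sym_curve"])
        direct = bme_reweight(scale * y, data, theta=1.0)
        diff = differential_reweight(data, truth["sym_curve"], 0.0, y,
                                     theta=1.0)
        assert np.abs(diff.weights - direct.weights).max() < 1e-9

    def test_f_one_with_pure_symmetric_data_fits_residual_noise(self, mixture):
        data, truth = mixture
        sym_curve = truth["sym_curve"]
        noise = NoiseModel()
        rng = np.random.default_rng(8)
        pure = noise.apply(sym_curve, rng)
        res = differential_reweight(pure, sym_curve, 1.0,
                                    truth["frame_curves"], theta=1.0)
        # residual ≈ noise only: χ² per point of order 1
        assert res.chi2 / len(pure.q) < 3.0

    def test_invalid_fraction_rejected(self, mixture):
        data, truth = mixture
        with pytest.raises(ValueError):
            differential_reweight(data, truth["sym_curve"], 1.4,
                                  truth["frame_curves"])


class TestFractionScan:
    def test_pure_asymmetric_data_prefers_f_zero(self, mixture):
        _, truth = mixture
        y = truth["frame_curves"]
        avg = ensemble_intensity(
            [ScatteringCurve(DEFAULT_Q_GRID, yi) for yi in y],
            truth["weights"])
        noise = NoiseModel()
        rng = np.random.default_rng(9)
        data = noise.apply(avg, rng)
        scan = scan_symmetric_fraction(data, truth["sym_curve"], y,
                                       f_grid=np.arange(0, 1.01, 0.1),
                                       theta_policy="fixed", theta=1.0)
        assert scan.best_f <= 0.1

    def test_pure_symmetric_data_prefers_f_one(self, mixture):
        _, truth = mixture
        noise = NoiseModel()
        rng = np.random.default_rng(10)
        data = noise.apply(truth["sym_curve"], rng)
        scan = scan_symmetric_fraction(data, truth["sym_curve"],
                                       truth["frame_curves"],
                                       f_grid=np.arange(0, 1.01, 0.1),
                                       theta_policy="fixed", theta=1.0)
        assert scan.best_f >= 0.9

    def test_mixture_recovered_within_grid_band(self, mixture):
        data, truth = mixture
        scan = scan_symmetric_fraction(data, truth["sym_curve"],
                                       truth["frame_curves"],
                                       f_grid=np.arange(0, 1.001, 0.05))
        assert 0.3 <= scan.best_f <= 0.5
        lo, hi = scan.interval
        assert lo <= scan.best_f <= hi

    def test_empty_grid_rejected(self, mixture):
        data, truth = mixture
        with pytest.raises(ValueError):
            scan_symmetric_fraction(data, truth["sym_curve"],
                                    truth["frame_curves"],
                                    f_grid=np.array([]))
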