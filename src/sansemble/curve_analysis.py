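"""Scattering-curve analysis: Guinier fits, Bayesian IFT, χ² comparison.

The Guinier approximation I(q) ≈ I(0)·exp(−q²Rg²/3) holds at low q; the
fit is a weighted straight line in (q², ln I) on the longest window from
the first positive-intensity point that satisfies q_max·Rg ≤ limit,
iterated to self-consistency since the window depends on the Rg it yields.

The indirect Fourier transform inverts

    I(q) = 4π ∫₀^Dmax p(r) sin(qr)/(qr) dr

for the pair-distance distribution p(r) under a smoothness prior on the
second differences of p (with p clamped to zero at r = 0 and r = Dmax).
The regularisation weight α and Dmax are selected by maximising a
Gaussian-approximation posterior (evidence), so no human picks either.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sans_forward import PairDistribution, ScatteringCurve

__all__ = ["GuinierResult", "IftResult", "guinier_fit", "bayesian_ift",
           "chi2", "ift_design_matrix"]


@dataclass
class GuinierResult:
    rg: float
    rg_err: float
    i0: float
    i0_err: float
    q_range: tuple[float, float]
    n_points: int


@dataclass
class IftResult:
    pr: PairDistribution
    alpha: float
    dmax: float
    chi2_red: float
    evidence: float
    trace: list[tuple[float, float, float]]  # (dmax, alpha, evidence)


def _guinier_window_fit(q, i, sigma, lo, hi):
    """Weighted LS of ln I vs q² on [lo:hi); returns rg, i0, errors."""
    x = q[lo:hi] ** 2
    y = np.log(i[lo:hi])
    w = (i[lo:hi] / sigma[lo:hi]) ** 2  # var(ln I) = (σ/I)²
    sw, swx, swy = w.sum(), (w * x).sum(), (w * y).sum()
    swxx, swxy = (w * x * x).sum(), (w * x * y).sum()
    delta = sw * swxx - swx ** 2
    slope = (sw * swxy - swx * swy) / delta
    intercept = (swxx * swy - swx * swxy) / delta
    var_slope = sw / delta
    var_intercept = swxx / delta
    if slope >= 0:
        return None
    rg = np.sqrt(-3.0 * slope)
    rg_err = 1.5 * np.sqrt(var_slope) / rg
    i0 = np.exp(intercept)
    return rg, rg_err, i0, i0 * np.sqrt(var_intercept)


def guinier_fit(curve: ScatteringCurve, qrg_limit: float = 1.3,
                min_points: int = 5, max_iter: int = 50) -> GuinierResult:
    """Automated Guinier analysis with a self-consistent q·Rg window."""
    if curve.sigma is None:
        raise ValueError("Guinier fit requires experimental errors")
    q, i, sigma = curve.q, curve.i, curve.sigma
    start = int(np.argmax(i > 0))
    if i[start] <= 0:
        raise ValueError("no positive intensities")
    n = len(q)
    hi = min(start + max(min_points, 10), n)
    if hi - start < min_points:
        raise ValueError("fewer than %d usable low-q points" % min_points)
    prev_hi = -1
    result = None
    for _ in range(max_iter):
        window = slice(start, hi)
        if np.any(i[window] <= 0):
            hi = start + int(np.argmax(i[start:hi] <= 0))
            if hi - start < min_points:
                raise ValueError("non-positive intensities inside Guinier window")
            continue
        fit = _guinier_window_fit(q, i, sigma, start, hi)
        if fit is None:
            raise ValueError("non-negative Guinier slope: no valid window")
        rg = fit[0]
        # longest window with q_max·Rg ≤ limit
        new_hi = int(np.searchsorted(q, qrg_limit / rg, side="right"))
        new_hi = max(start + min_points, min(new_hi, n))
        result = fit
        if new_hi == hi or new_hi == prev_hi:  # converged or 2-cycle
            hi = min(new_hi, hi)
            break
        prev_hi, hi = hi, new_hi
    rg, rg_err, i0, i0_err = result
    return GuinierResult(rg=float(rg), rg_err=float(rg_err), i0=float(i0),
                         i0_err=float(i0_err),
                         q_range=(float(q[start]), float(q[hi - 1])),
                         n_points=hi - start)


# ---------------------------------------------------------------------------
# χ² with analytic scale / background
# ---------------------------------------------------------------------------

def chi2(model_curve: ScatteringCurve, data_curve: ScatteringCurve,
         fit_scale: bool = True, fit_background: bool = True,
         interpolate: bool = False):
    """χ² = Σ[(a·I_model + c − I_data)/σ]² with (a, c) solved analytically.

    Returns ``(chi2, scale, background)``.  χ² is the raw (un-reduced)
    statistic; divide by the number of points for reporting.
    """
    if data_curve.sigma is None:
        raise ValueError("data curve needs errors")
    if np.any(data_curve.sigma == 0):
        raise ValueError("zero sigma in data")
    if len(model_curve.q) != len(data_curve.q) or not np.allclose(
            model_curve.q, data_curve.q):
        if not interpolate:
            raise ValueError("q-grid mismatch (interpolation disabled)")
        im = np.interp(data_curve.q, model_curve.q, model_curve.i)
    else:
        im = model_curve.i
    y, s = data_curve.i, data_curve.sigma
    w = 1.0 / s ** 2
    a, c = 1.0, 0.0
    if fit_scale and fit_background:
        sw, swx, swy = w.sum(), (w * im).sum(), (w * y).sum()
        swxx, swxy = (w * im * im).sum(), (w * im * y).sum()
        delta = sw * swxx - swx ** 2
        if abs(delta) > 1e-300:
            a = (sw * swxy - swx * swy) / delta
            c = (swxx * swy - swx * swxy) / delta
    elif fit_scale:
        denom = (w * im * im).sum()
        if denom > 0:
            a = (w * im * y).sum() / denom
    elif fit_background:
        c = ((w * (y - im)).sum()) / w.sum()
    r = (a * im + c - y) / s
    return float((r ** 2).sum()), float(a), float(c)


# ---------------------------------------------------------------------------
# Bayesian indirect Fourier transform
# ---------------------------------------------------------------------------

def ift_design_matrix(q: np.ndarray, r: np.ndarray, dr: float) -> np.ndarray:
    """Forward operator A with I = A p:  A[j,k] = 4π·Δr·sinc(q_j r_k)."""
    return 4.0 * np.pi * dr * np.sinc(np.outer(q, r) / np.pi)


def _second_difference_operator(n: int, dr: float) -> np.ndarray:
    """Second differences of the zero-padded vector [0, p₁..pₙ, 0].

    Padding makes the operator full column rank, which both enforces the
    p(0) = p(Dmax) = 0 boundary and keeps the smoothness prior proper so the
    evidence is well defined.
    """
    ext = np.zeros((n + 2, n))
    ext[1:-1] = np.eye(n)
    d2 = (ext[:-2] - 2 * ext[1:-1] + ext[2:]) / dr ** 2
    return d2


def bayesian_ift(curve: ScatteringCurve, n_r: int = 60,
                 dmax_grid: np.ndarray | None = None,
                 alpha_grid: np.ndarray | None = None) -> IftResult:
    """Regularised p(r) inversion with evidence-selected (α, Dmax).

    For each (Dmax, α) the quadratic problem
        min_p  χ²(A p, I) + α‖L p‖²
    is solved in closed form; the returned solution maximises the Gaussian
    log-evidence  ½ln det(αLᵀL) − ½ln det(H) − ½χ² − ½α‖Lp‖²  with
    H = AᵀΣ⁻¹A + αLᵀL.
    """
    if curve.sigma is None:
        raise ValueError("IFT requires errors")
    q, i, sigma = curve.q, curve.i, curve.sigma
    if dmax_grid is None:
        # rough scale from the Guinier Rg of a sphere-like particle
        try:
            rg0 = guinier_fit(curve).rg
        except ValueError:
            rg0 = 1.0 / max(q[1], 1e-3)
        d0 = 2.58 * rg0  # sphere relation Dmax = 2R = 2·√(5/3)·Rg
        dmax_grid = np.linspace(0.7 * d0, 1.6 * d0, 12)
    if alpha_grid is None:
        alpha_grid = np.logspace(-12, 2, 20)
    dmax_grid = np.asarray(dmax_grid, dtype=float)
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if len(dmax_grid) == 0 or len(alpha_grid) == 0:
        raise ValueError("empty (α, Dmax) search grid")

    w = 1.0 / sigma ** 2
    best = None
    trace = []
    for dmax in dmax_grid:
        edges = np.linspace(0.0, dmax, n_r + 2)
        r = edges[1:-1]  # interior points; boundary p fixed at 0
        dr = edges[1] - edges[0]
        a_mat = ift_design_matrix(q, r, dr)
        l_mat = _second_difference_operator(n_r, dr)
        ata = (a_mat * w[:, None]).T @ a_mat
        atb = (a_mat * w[:, None]).T @ i
        ltl = l_mat.T @ l_mat
        sign_l, logdet_ltl = np.linalg.slogdet(ltl)
        for alpha in alpha_grid:
            h = ata + alpha * ltl
            cond = np.linalg.cond(h)
            if not np.isfinite(cond) or cond > 1e14:
                continue
            p = np.linalg.solve(h, atb)
            resid = (a_mat @ p - i) / sigma
            c2 = float((resid ** 2).sum())
            pen = float(p @ ltl @ p)
            _, logdet_h = np.linalg.slogdet(h)
            evidence = 0.5 * (n_r * np.log(alpha) + logdet_ltl) \
                - 0.5 * logdet_h - 0.5 * c2 - 0.5 * alpha * pen
            trace.append((float(dmax), float(alpha), float(evidence)))
            if best is None or evidence > best[0]:
                best = (evidence, dmax, alpha, r.copy(), p.copy(), c2)
    if best is None:
        raise ValueError("all (α, Dmax) candidates ill-conditioned")
    evidence, dmax, alpha, r, p, c2 = best
    pr = PairDistribution(r=r, p=p, dmax=float(dmax))
    return IftResult(pr=pr, alpha=float(alpha), dmax=float(dmax),
                     chi2_red=c2 / max(len(q) - 1, 1), evidence=float(evidence),
                     trace=trace)
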