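"""Elastic-network normal modes with rigid-block screw extrapolation and
refinement of mode amplitudes against a SANS curve.

The elastic network is the standard Cα anisotropic network model: uniform
springs between Cα pairs within a cutoff.  Modes are computed in a
rotation-translation-block (RTB) basis — each secondary-structure segment
is one rigid block, loop residues are single-residue blocks — so the
low-frequency spectrum describes collective inter-block motions and the
basis stays small even for a pentamer.

Finite displacements along a mode are applied non-linearly: the per-block
linear displacement field is decomposed into the rigid motion (translation
t, rotation vector ω about the block centroid) that generates it, and the
block is moved by the finite screw R(a·ω)·(x − c) + c + a·t.  This
preserves intra-block geometry exactly at any amplitude and agrees with
the linear extrapolation to first order in the amplitude.

Refinement minimises T = χ² + α·S over the amplitudes of the lowest
non-rigid modes, where χ² compares the forward-computed SANS of the
deformed structure with the data (analytic scale and background) and S is
a structure-preservation penalty: the mean squared deviation of all
intra-segment Cα–Cα distances from their reference values (Å²).  The
regularisation weight α is chosen from the maximum-curvature point
("elbow") of the (log S, log χ²) L-curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .curve_analysis import chi2
from .sans_forward import ContrastModel, ScatteringCurve
from .structures import Structure

__all__ = ["ModeBasis", "RefinementResult", "LCurve", "build_enm",
           "nonlinear_extrapolate", "structure_penalty", "refine_against_sans",
           "alpha_lcurve", "lcurve_corner"]


@dataclass
class ModeBasis:
    reference: Structure
    ca_indices: np.ndarray          # atom indices of the network nodes
    blocks: list[np.ndarray]        # node indices per rigid block
    eigenvalues: np.ndarray         # ascending
    eigenvectors: np.ndarray        # (3n_nodes, n_modes), orthonormal columns
    block_motions: np.ndarray       # (n_modes, n_blocks, 6): t, ω per block

    @property
    def n_rigid(self) -> int:
        thresh = 1e-8 * max(self.eigenvalues.max(), 1.0)
        return int((np.abs(self.eigenvalues) < thresh).sum())

    def internal_mode_indices(self, n_modes: int) -> np.ndarray:
        return np.arange(self.n_rigid, self.n_rigid + n_modes)


@dataclass
class RefinementResult:
    amplitudes: np.ndarray
    structure: Structure
    chi2: float
    penalty: float
    alpha: float
    converged: bool
    trace: list[tuple[int, float]] = field(default_factory=list)


@dataclass
class LCurve:
    points: list[tuple[float, float, float]]  # (α, χ², S)
    selected: int
    degenerate: bool = False


# ---------------------------------------------------------------------------
# ENM construction
# ---------------------------------------------------------------------------

def _default_blocks(structure: Structure, ca_idx: np.ndarray) -> list[np.ndarray]:
    """Secondary-structure segments as blocks; loop residues stand alone."""
    key_of = [(str(structure.chain_ids[j]), int(structure.res_nums[j]))
              for j in ca_idx]
    assigned = np.full(len(ca_idx), -1)
    blocks: list[list[int]] = []
    for seg in structure.segments:
        members = [k for k, (c, r) in enumerate(key_of)
                   if c == seg.chain and seg.start <= r <= seg.end]
        if members:
            for m in members:
                assigned[m] = len(blocks)
            blocks.append(members)
    for k in range(len(ca_idx)):
        if assigned[k] < 0:
            blocks.append([k])
    return [np.array(b, dtype=int) for b in blocks]


def build_enm(structure: Structure, cutoff: float = 10.0,
              spring_constant: float = 1.0,
              blocks: list[np.ndarray] | None = None) -> ModeBasis:
    """Cα elastic network in a rigid-block basis, diagonalised.

    Raises if the network is disconnected at the cutoff (component count
    reported): a disconnected network has more than 6 zero modes and its
    "internal" modes are meaningless.
    """
    from scipy.sparse.csgraph import connected_components
    from scipy.spatial.distance import squareform, pdist

    ca_idx = np.flatnonzero(structure.ca_mask())
    if len(ca_idx) == 0:  # coarse models: every atom a node
        ca_idx = np.arange(structure.n_atoms)
    x = structure.positions[ca_idx]
    n = len(x)
    if n < 2:
        raise ValueError("need at least two network nodes")
    d = squareform(pdist(x))
    contact = (d < cutoff) & (d > 1e-9)
    n_comp, _ = connected_components(contact, directed=False)
    if n_comp > 1:
        raise ValueError(f"elastic network disconnected at cutoff {cutoff} Å "
                         f"({n_comp} components)")

    hessian = np.zeros((3 * n, 3 * n))
    ii, jj = np.nonzero(np.triu(contact, k=1))
    for i, j in zip(ii, jj):
        dv = x[j] - x[i]
        block = -spring_constant * np.outer(dv, dv) / (dv @ dv)
        hessian[3*i:3*i+3, 3*j:3*j+3] += block
        hessian[3*j:3*j+3, 3*i:3*i+3] += block
        hessian[3*i:3*i+3, 3*i:3*i+3] -= block
        hessian[3*j:3*j+3, 3*j:3*j+3] -= block

    if blocks is None:
        blocks = _default_blocks(structure, ca_idx)

    # rigid-motion basis per block, orthonormalised: ≤6 columns per block
    cols = []
    col_block, col_motion = [], []  # provenance: block id and (t, ω) generator
    for b_id, b in enumerate(blocks):
        xb = x[b]
        c = xb.mean(axis=0)
        raw = []
        gens = []
        for axis in np.eye(3):
            v = np.zeros((n, 3))
            v[b] = axis
            raw.append(v.ravel())
            gens.append(np.concatenate([axis, np.zeros(3)]))
        if len(b) > 1:
            for axis in np.eye(3):
                v = np.zeros((n, 3))
                v[b] = np.cross(axis, xb - c)
                raw.append(v.ravel())
                gens.append(np.concatenate([np.zeros(3), axis]))
        raw = np.array(raw).T  # (3n, ≤6)
        qmat, rmat = np.linalg.qr(raw)
        keep = np.abs(np.diag(rmat)) > 1e-10
        qmat = qmat[:, keep]
        # express each orthonormal column in the raw (t, ω) generators
        comb = np.linalg.lstsq(raw, qmat, rcond=None)[0]  # (n_raw, n_kept)
        gens = np.array(gens)
        for kcol in range(qmat.shape[1]):
            cols.append(qmat[:, kcol])
            col_block.append(b_id)
            col_motion.append(comb[:, kcol] @ gens)
    p_mat = np.array(cols).T  # (3n, m) orthonormal (blocks are disjoint)

    h_rtb = p_mat.T @ hessian @ p_mat
    evals, evecs_rtb = np.linalg.eigh(h_rtb)
    evecs = p_mat @ evecs_rtb  # orthonormal in full space

    # per-mode rigid motion of each block: t and ω generating the block's
    # linear displacement field
    n_blocks = len(blocks)
    n_modes = evecs.shape[1]
    block_motions = np.zeros((n_modes, n_blocks, 6))
    col_block_arr = np.array(col_block)
    col_motion_arr = np.array([m for m in col_motion])
    for mode in range(n_modes):
        coeffs = evecs_rtb[:, mode]
        for b_id in range(n_blocks):
            sel = col_block_arr == b_id
            block_motions[mode, b_id] = coeffs[sel] @ col_motion_arr[sel]

    return ModeBasis(reference=structure, ca_indices=ca_idx, blocks=blocks,
                     eigenvalues=evals, eigenvectors=evecs,
                     block_motions=block_motions)


# ---------------------------------------------------------------------------
# Non-linear (screw) extrapolation
# ---------------------------------------------------------------------------

def nonlinear_extrapolate(basis: ModeBasis, amplitudes: np.ndarray,
                          mode_indices: np.ndarray | None = None,
                          rms_units: bool = True) -> Structure:
    """Deform the reference by finite rigid-block screws.

    ``amplitudes[k]`` multiplies mode ``mode_indices[k]`` (default: the
    lowest internal modes).  With ``rms_units`` (default) a unit amplitude
    produces a 1 Å root-mean-square node displacement in the linear limit —
    an interpretable Å scale — by multiplying the orthonormal eigenvector
    by √n_nodes.  Per block, the amplitude-weighted (t, ω) generators of
    all active modes are summed and applied as one finite rotation about
    the block centroid plus translation, so intra-block geometry is
    preserved exactly.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    if rms_units:
        amplitudes = amplitudes * np.sqrt(len(basis.ca_indices))
    if mode_indices is None:
        mode_indices = basis.internal_mode_indices(len(amplitudes))
    mode_indices = np.asarray(mode_indices, dtype=int)
    if len(amplitudes) > basis.eigenvectors.shape[1]:
        raise ValueError("more amplitudes than modes")
    if np.any(mode_indices >= basis.eigenvectors.shape[1]):
        raise ValueError("mode index beyond basis")
    x = basis.reference.positions[basis.ca_indices].copy()
    new = basis.reference.positions.copy()
    for b_id, b in enumerate(basis.blocks):
        motion = np.zeros(6)
        for a, m in zip(amplitudes, mode_indices):
            motion += a * basis.block_motions[m, b_id]
        t, omega = motion[:3], motion[3:]
        xb = x[b]
        c = xb.mean(axis=0)
        rot = Rotation.from_rotvec(omega)
        moved = rot.apply(xb - c) + c + t
        new[basis.ca_indices[b]] = moved
    return basis.reference.with_positions(new)


def structure_penalty(structure: Structure, reference: Structure,
                      segments=None) -> float:
    """Mean squared deviation of intra-segment Cα–Cα distances, Å²."""
    segments = segments if segments is not None else reference.segments
    if not segments:
        raise ValueError("no annotated segments")
    if structure.n_atoms != reference.n_atoms:
        raise ValueError("topology mismatch")
    ca = np.flatnonzero(reference.ca_mask())
    if len(ca) == 0:
        ca = np.arange(reference.n_atoms)
    keys = [(str(reference.chain_ids[j]), int(reference.res_nums[j])) for j in ca]
    total, count = 0.0, 0
    for seg in segments:
        idx = ca[[k for k, (c, r) in enumerate(keys)
                  if c == seg.chain and seg.start <= r <= seg.end]]
        if len(idx) < 2:
            continue
        from scipy.spatial.distance import pdist
        d_new = pdist(structure.positions[idx])
        d_ref = pdist(reference.positions[idx])
        total += ((d_new - d_ref) ** 2).sum()
        count += len(d_new)
    if count == 0:
        raise ValueError("segments contain no Cα pairs")
    return float(total / count)


# ---------------------------------------------------------------------------
# Refinement against SANS
# ---------------------------------------------------------------------------

def refine_against_sans(basis: ModeBasis, n_modes: int,
                        data_curve: ScatteringCurve, alpha: float = 0.0,
                        contrast: ContrastModel | None = None,
                        seed: int = 0, maxiter: int = 200,
                        forward=None, n_starts: int = 1,
                        start_amplitude: float = 2.0) -> RefinementResult:
    """Minimise T = χ² + α·S over amplitudes of the lowest internal modes.

    T is cast as a least-squares problem — residuals [(a·I_model + c −
    I_data)/σ, √(α·S)] — and solved by trust-region least squares from zero
    amplitudes (plus ``n_starts − 1`` seeded random restarts to escape
    local minima of the non-linear screw map).  ``forward`` may override
    the default structure → ScatteringCurve map (coarse-grain + Debye on
    the data's q grid).  Deterministic for a given seed.
    """
    from scipy.optimize import least_squares

    if data_curve.sigma is None:
        raise ValueError("data curve needs errors")
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    contrast = contrast or ContrastModel()
    if forward is None:
        from .sans_forward import CoarseGrainMapper
        mapper = CoarseGrainMapper(basis.reference, contrast)

        def forward(s):
            return mapper.intensity(s.positions, data_curve.q)

    mode_idx = basis.internal_mode_indices(n_modes)
    trace = []

    def eval_point(a):
        s_struct = nonlinear_extrapolate(basis, a, mode_idx)
        c2, scale, bg = chi2(forward(s_struct), data_curve)
        pen = structure_penalty(s_struct, basis.reference)
        return s_struct, c2, pen, scale, bg

    def residuals(a):
        s_struct = nonlinear_extrapolate(basis, a, mode_idx)
        model = forward(s_struct)
        _, scale, bg = chi2(model, data_curve)
        r = (scale * model.i + bg - data_curve.i) / data_curve.sigma
        pen = structure_penalty(s_struct, basis.reference)
        trace.append((len(trace), float((r ** 2).sum() + alpha * pen)))
        return np.concatenate([r, [np.sqrt(alpha * pen)]])

    rng = np.random.default_rng(seed)
    starts = [np.zeros(n_modes)]
    for _ in range(max(0, n_starts - 1)):
        starts.append(rng.normal(0.0, start_amplitude, n_modes))
    _, t_zero, pen_zero, _, _ = eval_point(np.zeros(n_modes))
    best_a, best_t, ok = np.zeros(n_modes), t_zero + alpha * pen_zero, True
    for x0 in starts:
        res = least_squares(residuals, x0, diff_step=1e-3,
                            max_nfev=maxiter * (n_modes + 1))
        _, c2, pen, _, _ = eval_point(res.x)
        t = c2 + alpha * pen
        if t < best_t:
            best_a, best_t, ok = np.atleast_1d(res.x), t, bool(res.success)
    refined, c2, pen, _, _ = eval_point(best_a)
    return RefinementResult(amplitudes=np.atleast_1d(best_a), structure=refined,
                            chi2=float(c2), penalty=float(pen), alpha=alpha,
                            converged=ok, trace=trace)


# ---------------------------------------------------------------------------
# L-curve corner selection
# ---------------------------------------------------------------------------

def lcurve_corner(xy: np.ndarray) -> tuple[int, bool]:
    """Maximum-curvature vertex of a polyline; (index, degenerate flag).

    Curvature is the discrete Menger curvature after normalising both axes
    to [0, 1] so the corner does not depend on units.
    """
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 3:
        return 0, True
    span = xy.max(axis=0) - xy.min(axis=0)
    if np.any(span <= 0):
        return 0, True
    u = (xy - xy.min(axis=0)) / span
    best_k, best_c = 0, 0.0
    for k in range(1, len(u) - 1):
        a, b, c = u[k - 1], u[k], u[k + 1]
        area2 = abs((b[0]-a[0])*(c[1]-a[1]) - (c[0]-a[0])*(b[1]-a[1]))
        la, lb, lc = np.linalg.norm(b-a), np.linalg.norm(c-b), np.linalg.norm(c-a)
        if min(la, lb, lc) < 1e-12:
            continue
        curv = 2.0 * area2 / (la * lb * lc)
        if curv > best_c:
            best_c, best_k = curv, k
    return best_k, best_c <= 1e-12


def alpha_lcurve(basis: ModeBasis, data_curve: ScatteringCurve,
                 alpha_grid: np.ndarray, n_modes: int = 10,
                 **refine_kwargs) -> LCurve:
    """Refine at every α and pick the elbow of the (log S, log χ²) polyline."""
    alpha_grid = np.sort(np.asarray(alpha_grid, dtype=float))
    if len(alpha_grid) < 4:
        raise ValueError("need at least 4 α values")
    points = []
    for alpha in alpha_grid:
        r = refine_against_sans(basis, n_modes, data_curve, alpha=alpha,
                                **refine_kwargs)
        points.append((float(alpha), r.chi2, r.penalty))
    logs = np.array([[np.log10(max(s, 1e-12)), np.log10(max(c, 1e-12))]
                     for _, c, s in points])
    idx, degenerate = lcurve_corner(logs)
    return LCurve(points=points, selected=idx, degenerate=degenerate)
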