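"""Well-tempered metadynamics on toy systems with an Rg collective variable.

The bias protocol is the standard well-tempered scheme: every ``stride``
steps a Gaussian of width σ_G is deposited on the collective variable s,
with height damped by the bias already present,

    h_k = h · exp(−V(s_k) / (k_B ΔT)),   ΔT = (γ − 1) T,

so the bias converges to −(1 − 1/γ)·F(s) and the free-energy estimate is
F(s) ≈ −γ/(γ − 1)·V(s).  An upper wall restrains the CV:
V_wall(s) = κ·((s − s_wall)/rescale)^e for s > s_wall, 0 otherwise.

Dynamics are overdamped Langevin on deliberately small systems — an
analytic 1-D potential where the coordinate is the CV, or a harmonic
elastic-network pentamer whose CV is the radius of gyration of the
intracellular beads.  The physics engine is a toy by design; the bias
algorithm and its parameters are the point.  Defaults follow the
production protocol used for CorA-scale pentamer sampling: Gaussian width
0.05 nm, height 2.1 kJ/mol, stride 100 steps, biasfactor 15, wall at an
Rg of 4.0 nm with force constant 10000 and exponent 4, T = 303.15 K.
CV/bias quantities are in nm and kJ/mol; Cartesian coordinates elsewhere
in the package are in Å (converted explicitly here).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import Structure, radius_of_gyration

__all__ = ["KB_KJ_MOL_K", "CollectiveVariable", "MetadParams", "BiasState",
           "Trajectory", "bias_potential", "wall_energy", "wt_metad_run",
           "frame_weights", "free_energy_estimate", "Analytic1DSystem",
           "EnmBeadSystem", "write_hills"]

KB_KJ_MOL_K = 0.0083144621  # Boltzmann constant, kJ/(mol·K)
ANGSTROM_TO_NM = 0.1


@dataclass
class CollectiveVariable:
    """Radius-of-gyration CV over a bead selection (residue ranges per chain)."""

    selection: dict[str, list[tuple[int, int]]] | None = None  # chain -> ranges
    tag: str = "radius-of-gyration"

    def indices(self, structure: Structure) -> np.ndarray:
        if self.selection is None:
            return np.arange(structure.n_atoms)
        idx = []
        for j in range(structure.n_atoms):
            ch = str(structure.chain_ids[j])
            if ch in self.selection:
                r = int(structure.res_nums[j])
                if any(lo <= r <= hi for lo, hi in self.selection[ch]):
                    idx.append(j)
        if not idx:
            raise ValueError("CV selection matches no atoms")
        return np.array(idx, dtype=int)


@dataclass
class MetadParams:
    """Well-tempered metadynamics parameters (CV units nm, energy kJ/mol)."""

    gaussian_width: float = 0.05
    gaussian_height: float = 2.1
    stride: int = 100
    biasfactor: float = 15.0
    wall_at: float = 4.0
    wall_kappa: float = 10000.0
    wall_exponent: int = 4
    wall_rescale: float = 1.0
    wall_offset: float = 0.0
    temperature: float = 303.15
    timestep: float = 0.002
    friction: float = 1.0
    grid: tuple[float, float, int] = (0.0, 8.0, 4001)  # bias grid over s

    def __post_init__(self):
        if self.biasfactor <= 1:
            raise ValueError("biasfactor must exceed 1")
        if min(self.gaussian_width, self.gaussian_height, self.wall_kappa) <= 0:
            raise ValueError("width, height and κ must be positive")
        if self.wall_exponent <= 0 or self.wall_exponent % 2:
            raise ValueError("wall exponent must be a positive even integer")

    @property
    def kt(self) -> float:
        return KB_KJ_MOL_K * self.temperature

    @property
    def delta_t_energy(self) -> float:
        """k_B·ΔT with ΔT = (γ−1)T, kJ/mol."""
        return (self.biasfactor - 1.0) * self.kt


@dataclass
class BiasState:
    """Deposited Gaussians plus a running bias grid for O(1) force lookups."""

    centers: list[float] = field(default_factory=list)
    heights: list[float] = field(default_factory=list)
    width: float = 0.05
    grid_s: np.ndarray | None = None
    grid_v: np.ndarray | None = None

    def deposit(self, center: float, height: float) -> None:
        self.centers.append(float(center))
        self.heights.append(float(height))
        if self.grid_s is not None:
            self.grid_v += height * np.exp(
                -0.5 * ((self.grid_s - center) / self.width) ** 2)

    def grid_value(self, s: float) -> float:
        if self.grid_s is None or len(self.centers) == 0:
            return bias_potential(self, s)
        return float(np.interp(s, self.grid_s, self.grid_v))

    def grid_force(self, s: float, ds: float = 1e-4) -> float:
        """−dV/ds by central difference on the grid interpolant."""
        return -(self.grid_value(s + ds) - self.grid_value(s - ds)) / (2 * ds)


@dataclass
class Trajectory:
    frames: np.ndarray          # (n_rec, ...) coordinates
    times: np.ndarray
    cv_values: np.ndarray
    bias_values: np.ndarray     # instantaneous V(s_t) at record time
    seed: int
    bias: BiasState | None = None

    def __post_init__(self):
        n = len(self.times)
        if not (len(self.frames) == len(self.cv_values) == len(self.bias_values) == n):
            raise ValueError("trajectory arrays must be congruent")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must increase")


def bias_potential(bias_state: BiasState, s: float) -> float:
    """V(s) = Σₖ hₖ·exp(−(s−sₖ)²/(2σ_G²)) from the deposited Gaussian list."""
    if not bias_state.centers:
        return 0.0
    c = np.asarray(bias_state.centers)
    h = np.asarray(bias_state.heights)
    return float((h * np.exp(-0.5 * ((s - c) / bias_state.width) ** 2)).sum())


def wall_energy(params: MetadParams, s: float) -> float:
    """Upper-wall restraint: κ·((s − s_wall − offset)/rescale)^e above the wall."""
    x = (s - params.wall_at - params.wall_offset) / params.wall_rescale
    if x <= 0:
        return 0.0
    return params.wall_kappa * x ** params.wall_exponent


def _wall_force(params: MetadParams, s: float) -> float:
    x = (s - params.wall_at - params.wall_offset) / params.wall_rescale
    if x <= 0:
        return 0.0
    return -params.wall_kappa * params.wall_exponent \
        * x ** (params.wall_exponent - 1) / params.wall_rescale


# ---------------------------------------------------------------------------
# Toy systems
# ---------------------------------------------------------------------------

class Analytic1DSystem:
    """1-D potential where the coordinate *is* the CV (nm)."""

    def __init__(self, potential, force, x0: float = 0.0):
        self.potential = potential
        self.force = force
        self.x0 = float(x0)

    def initial_state(self):
        return np.array([self.x0])

    def system_force(self, x):
        return np.array([self.force(float(x[0]))])

    def cv(self, x) -> float:
        return float(x[0])

    def cv_gradient(self, x):
        return np.array([1.0])

    def energy(self, x) -> float:
        return float(self.potential(float(x[0])))


class EnmBeadSystem:
    """Harmonic elastic network around a reference bead structure.

    Coordinates in Å; the CV is the Rg (nm) of a bead selection, so forces
    from the bias are chain-ruled through ∂Rg/∂x.
    """

    def __init__(self, reference: Structure, cv: CollectiveVariable,
                 cutoff: float = 12.0, spring_constant: float = 5.0):
        from scipy.spatial.distance import squareform, pdist
        self.reference = reference
        self.x0 = reference.positions.copy()
        d = squareform(pdist(self.x0))
        self.pairs = np.column_stack(np.nonzero(np.triu((d < cutoff) & (d > 1e-9), 1)))
        self.d0 = d[self.pairs[:, 0], self.pairs[:, 1]]
        self.k = spring_constant
        self.cv_idx = cv.indices(reference)

    def initial_state(self):
        return self.x0.copy()

    def energy(self, x) -> float:
        dv = x[self.pairs[:, 0]] - x[self.pairs[:, 1]]
        d = np.linalg.norm(dv, axis=1)
        return float(0.5 * self.k * ((d - self.d0) ** 2).sum())

    def system_force(self, x):
        dv = x[self.pairs[:, 0]] - x[self.pairs[:, 1]]
        d = np.linalg.norm(dv, axis=1)
        f_pair = -self.k * (d - self.d0)[:, None] * dv / d[:, None]
        f = np.zeros_like(x)
        np.add.at(f, self.pairs[:, 0], f_pair)
        np.add.at(f, self.pairs[:, 1], -f_pair)
        return f

    def cv(self, x) -> float:
        return radius_of_gyration(x[self.cv_idx]) * ANGSTROM_TO_NM

    def cv_gradient(self, x):
        """∂Rg(nm)/∂x(Å): nonzero only on the selected beads."""
        g = np.zeros_like(x)
        sel = x[self.cv_idx]
        center = sel.mean(axis=0)
        rg_a = radius_of_gyration(sel)  # Å
        if rg_a < 1e-9:
            return g
        g[self.cv_idx] = (sel - center) / (len(sel) * rg_a) * ANGSTROM_TO_NM
        return g


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------

def wt_metad_run(system, params: MetadParams, n_steps: int, seed: int = 0,
                 record_stride: int | None = None,
                 energy_abort: float = 1e8,
                 max_drift_noise_ratio: float = 5.0) -> Trajectory:
    """Overdamped Langevin dynamics with well-tempered metadynamics bias.

    Forces: system + bias + wall, with the bias force taken from a running
    grid (O(1) per step) and the deposited height computed from the current
    bias at the walker's CV.  The deterministic drift per step is clipped
    at ``max_drift_noise_ratio`` times the thermal noise amplitude — in the
    sampled basin the drift is far below this cap, so the dynamics are
    unchanged, but a noise kick into the steep quartic wall cannot blow up
    the integrator.  Deterministic per seed.  Aborts with a diagnostic if
    the system energy still explodes (timestep instability).
    """
    rng = np.random.default_rng(seed)
    if record_stride is None:
        record_stride = params.stride
    lo, hi, npts = params.grid
    bias = BiasState(width=params.gaussian_width,
                     grid_s=np.linspace(lo, hi, int(npts)),
                     grid_v=np.zeros(int(npts)))
    x = system.initial_state().astype(float)
    dt, gamma = params.timestep, params.friction
    noise_amp = np.sqrt(2.0 * params.kt * dt / gamma)
    drift_cap = max_drift_noise_ratio * noise_amp
    frames, times, cvs, vbias = [], [], [], []
    for step in range(1, n_steps + 1):
        s = system.cv(x)
        f_cv = bias.grid_force(s) + _wall_force(params, s)
        force = system.system_force(x) + f_cv * system.cv_gradient(x)
        drift = np.clip(force * dt / gamma, -drift_cap, drift_cap)
        x = x + drift + noise_amp * rng.standard_normal(x.shape)
        if step % params.stride == 0:
            s_now = system.cv(x)
            v_now = bias.grid_value(s_now)
            h_k = params.gaussian_height * np.exp(-v_now / params.delta_t_energy)
            bias.deposit(s_now, h_k)
        if step % record_stride == 0:
            s_now = system.cv(x)
            frames.append(x.copy())
            times.append(step * dt)
            cvs.append(s_now)
            vbias.append(bias.grid_value(s_now))
            e = system.energy(x)
            if not np.isfinite(e) or abs(e) > energy_abort:
                raise RuntimeError(
                    f"energy explosion at step {step} (E = {e:.3g}): "
                    "reduce the timestep or increase friction")
    return Trajectory(frames=np.array(frames), times=np.array(times),
                      cv_values=np.array(cvs), bias_values=np.array(vbias),
                      seed=seed, bias=bias)


def frame_weights(trajectory: Trajectory, params: MetadParams,
                  equilibration_fraction: float = 0.1) -> np.ndarray:
    """Per-frame unbiasing weights wᵢ ∝ exp(V_final(sᵢ)/k_BT), normalised.

    The first ``equilibration_fraction`` of frames get zero weight; the
    final bias (after the last deposition) is evaluated at every retained
    frame's CV value.
    """
    n = len(trajectory.times)
    if n == 0:
        raise ValueError("empty trajectory")
    skip = int(np.floor(equilibration_fraction * n))
    v_final = np.array([
        trajectory.bias.grid_value(s) if trajectory.bias is not None else b
        for s, b in zip(trajectory.cv_values, trajectory.bias_values)])
    logw = v_final / (KB_KJ_MOL_K * params.temperature)
    logw[:skip] = -np.inf
    logw -= logw[skip:].max()
    w = np.exp(logw)
    return w / w.sum()


def free_energy_estimate(bias: BiasState, s_grid: np.ndarray,
                         params: MetadParams,
                         average_from: float | None = 0.5,
                         n_checkpoints: int = 10) -> np.ndarray:
    """F(s) ≈ −γ/(γ−1)·V(s), shifted so min F = 0 (kJ/mol).

    The instantaneous well-tempered estimate oscillates around the true
    profile; by default the estimate is averaged over ``n_checkpoints``
    snapshots of the bias from the ``average_from`` fraction of depositions
    onward (set ``average_from=None`` for the final-bias estimate only).
    """
    s = np.asarray(s_grid, dtype=float)
    pref = -params.biasfactor / (params.biasfactor - 1.0)
    n_hills = len(bias.centers)
    if average_from is None or n_hills < 10:
        v = np.array([bias.grid_value(x) for x in s])
        f = pref * v
        return f - f.min()
    c = np.asarray(bias.centers)
    h = np.asarray(bias.heights)
    contrib = h[:, None] * np.exp(-0.5 * ((s[None, :] - c[:, None])
                                          / bias.width) ** 2)
    cum = np.cumsum(contrib, axis=0)
    ks = np.linspace(int(average_from * n_hills), n_hills - 1,
                     n_checkpoints).astype(int)
    profiles = []
    for k in ks:
        f = pref * cum[k]
        profiles.append(f - f.min())
    return np.mean(profiles, axis=0)


def write_hills(bias: BiasState, path) -> None:
    """Gaussian hills as text rows (center, height, width), PLUMED-style."""
    arr = np.column_stack([bias.centers, bias.heights,
                           np.full(len(bias.centers), bias.width)])
    np.savetxt(path, arr, header="center height width")
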