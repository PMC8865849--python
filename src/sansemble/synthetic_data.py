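"""Synthetic ground-truth inputs for every pipeline stage.

The toy pentamer mimics the architecture of a CorA-like magnesium
channel: five protomers around a C5 axis, each with a transmembrane
helix column (TMD) sitting in a membrane slab and an intracellular
funnel domain (ICD) below it.  The symmetric state is exactly
C5-symmetric; asymmetric states displace and tilt individual protomers,
which shifts the mid-q feature of the SANS curve — the same signature
that distinguishes symmetric from protomer-displaced conformations in
experiments.  Every generator is deterministic given its seed and
returns its ground truth (true symmetric fraction, frame weights, true
rates) alongside the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .relax_fit import DELAYS_R1RHO_S, RelaxationSeries
from .sans_forward import (BeadModel, ContrastModel, ScatteringCurve,
                           structure_intensity)
from .structures import Ensemble, SecondaryStructureSegment, Structure, rotate_z

__all__ = ["PentamerSpec", "NoiseModel", "build_toy_pentamer",
           "make_asym_ensemble", "make_mixture_dataset",
           "sans_feature_separation", "simulate_decay",
           "default_sym_asym_pair", "uniform_sphere_beads", "sphere_beads",
           "fibonacci_sphere_points", "DEFAULT_Q_GRID"]

DEFAULT_Q_GRID = np.linspace(0.004, 0.35, 60)

_CHAINS = ["A", "B", "C", "D", "E"]
# residue-name cycle approximating a mixed composition
_NAME_CYCLE = ["LEU", "ALA", "GLY", "SER", "VAL", "GLU", "LYS", "ILE",
               "THR", "PHE"]


@dataclass
class PentamerSpec:
    """Geometry of the toy pentamer.

    ``radial_disp`` / ``tilt_deg`` are per-protomer perturbations (Å /
    degrees); all-zero perturbations give an exactly C5-symmetric pentamer.
    """

    n_icd: int = 42
    n_tmd: int = 28
    ring_radius: float = 11.0
    radial_disp: np.ndarray = field(default_factory=lambda: np.zeros(5))
    tilt_deg: np.ndarray = field(default_factory=lambda: np.zeros(5))
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.radial_disp = np.asarray(self.radial_disp, dtype=float)
        self.tilt_deg = np.asarray(self.tilt_deg, dtype=float)
        if len(self.radial_disp) != 5 or len(self.tilt_deg) != 5:
            raise ValueError("exactly five protomer perturbations required")
        if self.n_icd + self.n_tmd < 20:
            raise ValueError("at least 20 beads per protomer")
        if not (np.all(np.isfinite(self.radial_disp))
                and np.all(np.isfinite(self.tilt_deg))):
            raise ValueError("perturbations must be finite")

    @property
    def is_symmetric(self) -> bool:
        return (not self.radial_disp.any()) and (not self.tilt_deg.any())


@dataclass
class NoiseModel:
    """Counting-statistics-like noise: σ(q) = floor·I(0) + rel·I(q)·(1 + (q/q_scale)²)."""

    rel: float = 0.01
    floor_rel: float = 1e-4
    q_scale: float = 0.2
    seed: int = 0

    def sigma(self, curve: ScatteringCurve) -> np.ndarray:
        i0 = float(curve.i[0])
        s = self.floor_rel * abs(i0) + self.rel * np.abs(curve.i) * (
            1.0 + (curve.q / self.q_scale) ** 2)
        return np.maximum(s, 1e-12 * abs(i0) + 1e-300)

    def apply(self, curve: ScatteringCurve, rng: np.random.Generator) -> ScatteringCurve:
        s = self.sigma(curve)
        return ScatteringCurve(curve.q, curve.i + rng.normal(0.0, s), s)


def _protomer_template(spec: PentamerSpec):
    """One protomer in the frame where its radial direction is +x.

    TMD: residues n_icd+1..n_icd+n_tmd, a pore-lining helix column at the
    ring radius spanning the slab z ∈ [0, 1.5·n_tmd]; adjacent protomers'
    columns touch, so the assembled elastic network is connected.  ICD:
    residues 1..n_icd descending below the membrane as an outward-flaring
    funnel that dominates the particle's Rg.
    """
    coords = []
    n_icd, n_tmd = spec.n_icd, spec.n_tmd
    r0 = spec.ring_radius
    for k in range(n_icd):  # membrane side (z≈0) downward
        t = k / max(n_icd - 1, 1)
        radius = r0 + 4.0 + 15.0 * t                    # flares outward
        z = -1.0 - 44.0 * t
        ang = 0.25 * np.sin(3.0 * np.pi * t)            # gentle S-curve
        coords.append([radius * np.cos(ang),
                       radius * np.sin(ang) + 1.5 * np.sin(7 * t), z])
    for k in range(n_tmd):  # helix column through the slab
        phase = 2.0 * np.pi * k / 3.6
        coords.append([r0 + 2.3 * np.cos(phase), 2.3 * np.sin(phase), 1.5 * k])
    return np.array(coords)


def build_toy_pentamer(spec: PentamerSpec | None = None) -> Structure:
    """Assemble the five-protomer toy channel with annotations.

    Protomers are placed by 72° rotations about z; protomer ``p`` is first
    displaced radially by ``radial_disp[p]`` and tilted by ``tilt_deg[p]``
    about the tangential axis through its centroid.  With zero
    perturbations the result is exactly C5-symmetric.  The seed only
    drives the optional Gaussian jitter.
    """
    spec = spec or PentamerSpec()
    template = _protomer_template(spec)
    n_per = len(template)
    rng = np.random.default_rng(spec.seed)
    jitter = (rng.normal(0.0, spec.jitter, (n_per, 3))
              if spec.jitter > 0 else np.zeros((n_per, 3)))
    chain_ids, res_nums, res_names, atom_names, elements, xyz = [], [], [], [], [], []
    for p, chain in enumerate(_CHAINS):
        coords = template + jitter
        centroid = coords.mean(axis=0)
        if spec.tilt_deg[p]:
            t = np.deg2rad(spec.tilt_deg[p])
            rot = np.array([[np.cos(t), 0.0, np.sin(t)],
                            [0.0, 1.0, 0.0],
                            [-np.sin(t), 0.0, np.cos(t)]])
            coords = (coords - centroid) @ rot.T + centroid
        coords = coords + np.array([spec.radial_disp[p], 0.0, 0.0])
        coords = rotate_z(coords, 72.0 * p)
        for k in range(n_per):
            chain_ids.append(chain)
            res_nums.append(k + 1)
            res_names.append(_NAME_CYCLE[k % len(_NAME_CYCLE)])
            atom_names.append("CA")
            elements.append("C")
            xyz.append(coords[k])
    slab = (0.0, 1.5 * spec.n_tmd)
    segments = []
    domain_labels = {}
    for chain in _CHAINS:
        icd_mid = spec.n_icd // 2
        segments.append(SecondaryStructureSegment(chain, 1, icd_mid, "helix"))
        segments.append(SecondaryStructureSegment(chain, icd_mid + 1, spec.n_icd,
                                                  "helix"))
        segments.append(SecondaryStructureSegment(chain, spec.n_icd + 1,
                                                  spec.n_icd + spec.n_tmd, "helix"))
        for r in range(1, spec.n_icd + 1):
            domain_labels[(chain, r)] = "ICD"
        for r in range(spec.n_icd + 1, spec.n_icd + spec.n_tmd + 1):
            domain_labels[(chain, r)] = "TMD"
    return Structure(
        chain_ids=np.array(chain_ids), res_nums=np.array(res_nums, dtype=int),
        res_names=np.array(res_names), atom_names=np.array(atom_names),
        elements=np.array(elements), positions=np.array(xyz),
        segments=segments, membrane_slab=slab, domain_labels=domain_labels)


def make_asym_ensemble(n_frames: int, seed: int = 0,
                       disp_range: tuple[float, float] = (3.0, 7.0),
                       tilt_range: tuple[float, float] = (4.0, 10.0),
                       base_spec: PentamerSpec | None = None) -> Ensemble:
    """Ensemble of protomer-displaced conformers with uniform prior weights.

    Each frame perturbs one or two randomly chosen protomers by a random
    radial displacement and tilt, emulating the conformational diversity
    of an enhanced-sampling trajectory.
    """
    rng = np.random.default_rng(seed)
    base = base_spec or PentamerSpec()
    topology = build_toy_pentamer(base)
    frames = []
    for _ in range(n_frames):
        radial = np.zeros(5)
        tilt = np.zeros(5)
        for p in rng.choice(5, size=rng.integers(1, 3), replace=False):
            radial[p] = rng.uniform(*disp_range)
            tilt[p] = rng.uniform(*tilt_range)
        spec = PentamerSpec(n_icd=base.n_icd, n_tmd=base.n_tmd,
                            ring_radius=base.ring_radius,
                            radial_disp=radial, tilt_deg=tilt, seed=base.seed)
        frames.append(build_toy_pentamer(spec).positions)
    return Ensemble(topology=topology, frames=np.array(frames))


def default_sym_asym_pair(seed: int = 0, disp: float = 5.0, tilt: float = 8.0,
                          q_grid: np.ndarray | None = None,
                          noise: NoiseModel | None = None,
                          contrast: ContrastModel | None = None):
    """Symmetric/asymmetric structure pair with a usable mid-q difference.

    Guarantees that the two SANS curves differ by more than 3σ somewhere
    in the mid-q band at the noise model's level; if not, the perturbation
    is scaled up by 1.5× (with a warning) until they do.
    """
    q = DEFAULT_Q_GRID if q_grid is None else q_grid
    noise = noise or NoiseModel()
    sym = build_toy_pentamer(PentamerSpec(seed=seed))
    i_sym = structure_intensity(sym, q, contrast)
    sigma = noise.sigma(i_sym)
    for attempt in range(6):
        spec = PentamerSpec(radial_disp=np.array([disp, 0, 0, 0, 0]),
                            tilt_deg=np.array([tilt, 0, 0, 0, 0]), seed=seed)
        asym = build_toy_pentamer(spec)
        i_asym = structure_intensity(asym, q, contrast)
        if np.max(np.abs(i_sym.i - i_asym.i) / sigma) > 3.0:
            return sym, asym
        warnings.warn("sym/asym SANS difference below 3σ; rescaling "
                      "perturbation by 1.5x")
        disp *= 1.5
        tilt *= 1.5
    return sym, asym


def make_mixture_dataset(f_sym: float, sym_structure: Structure,
                         asym_ensemble: Ensemble, q_grid: np.ndarray,
                         noise: NoiseModel | None = None, seed: int = 0,
                         contrast: ContrastModel | None = None):
    """Two-population SANS data with known symmetric fraction.

    I = f_sym·I_sym + (1−f_sym)·⟨I_asym⟩ plus Gaussian noise from the
    noise model.  Returns ``(curve, truth)`` where ``truth`` records the
    true fraction, the frame weights, the noiseless mixture and the
    per-frame curve matrix consumed by the reweighting stage.
    """
    if not 0.0 <= f_sym <= 1.0:
        raise ValueError("f_sym must lie in [0, 1]")
    if asym_ensemble.n_frames < 1:
        raise ValueError("empty ensemble")
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    i_sym = structure_intensity(sym_structure, q_grid, contrast)
    frame_curves = np.array([
        structure_intensity(asym_ensemble.frame_structure(k), q_grid, contrast).i
        for k in range(asym_ensemble.n_frames)])
    i_asym = asym_ensemble.prior_weights @ frame_curves
    ideal = f_sym * i_sym.i + (1.0 - f_sym) * i_asym
    curve = noise.apply(ScatteringCurve(q_grid, ideal), rng)
    truth = {
        "f_sym": float(f_sym),
        "weights": asym_ensemble.prior_weights.copy(),
        "ideal": ideal,
        "sym_curve": i_sym,
        "frame_curves": frame_curves,
        "seed": seed,
    }
    return curve, truth


@dataclass
class FeatureSeparation:
    q_peak: float
    peak_ratio: float       # max |ΔI|/σ
    identical: bool


def sans_feature_separation(sym_curve: ScatteringCurve,
                            asym_curve: ScatteringCurve,
                            sigma: np.ndarray | None = None) -> FeatureSeparation:
    """Locate the q of maximal normalised difference between two curves."""
    if len(sym_curve.q) != len(asym_curve.q) or not np.allclose(
            sym_curve.q, asym_curve.q):
        raise ValueError("q-grid mismatch")
    if sigma is None:
        if asym_curve.sigma is not None:
            sigma = asym_curve.sigma
        elif sym_curve.sigma is not None:
            sigma = sym_curve.sigma
        else:
            sigma = NoiseModel().sigma(sym_curve)
    diff = np.abs(sym_curve.i - asym_curve.i) / sigma
    k = int(np.argmax(diff))
    identical = bool(diff.max() == 0.0)
    return FeatureSeparation(q_peak=float(sym_curve.q[k]),
                             peak_ratio=float(diff[k]), identical=identical)


def simulate_decay(rate: float, i0: float,
                   delays: np.ndarray | None = None, sigma: float = 0.0,
                   seed: int = 0, residue="R1") -> RelaxationSeries:
    """Mono-exponential decay I(t) = I₀·e^{−Rt} + Gaussian(0, σ) per delay."""
    if rate <= 0 or i0 <= 0:
        raise ValueError("rate and I0 must be positive")
    delays = DELAYS_R1RHO_S if delays is None else np.asarray(delays, dtype=float)
    rng = np.random.default_rng(seed)
    ideal = i0 * np.exp(-rate * delays)
    noisy = ideal + (rng.normal(0.0, sigma, len(delays)) if sigma > 0 else 0.0)
    return RelaxationSeries(residue=residue, delays=delays, intensities=noisy,
                            sigma=max(sigma, 1e-12))


def fibonacci_sphere_points(n: int) -> np.ndarray:
    """n near-uniform unit-sphere directions (Fibonacci spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta), np.cos(phi)])


def sphere_beads(n: int, radius: float, n_shells: int = 10) -> BeadModel:
    """Deterministic quadrature model of a uniform solid sphere.

    Beads sit on Gauss–Legendre radial shells (weights ∝ w_GL·r²) with
    Fibonacci-spiral angular placement, so the discrete Debye sum tracks
    the analytic sphere form factor to a few 10⁻⁴ relative even at the
    low-intensity end of the first lobe.
    """
    x, w = np.polynomial.legendre.leggauss(n_shells)
    r = radius * (x + 1.0) / 2.0
    wr = w * r ** 2
    per = max(1, n // n_shells)
    pts, bs = [], []
    for rj, wj in zip(r, wr):
        pts.append(fibonacci_sphere_points(per) * rj)
        bs.append(np.full(per, wj / per))
    pts = np.vstack(pts)
    b = np.concatenate(bs)
    return BeadModel(pts, b / b.sum() * len(b), np.array(["protein"] * len(b)))


def uniform_sphere_beads(n: int, radius: float, seed: int = 0,
                         b: float = 1.0) -> BeadModel:
    """n beads uniform in a solid sphere of the given radius, equal b."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    pts *= radius * rng.random(n)[:, None] ** (1.0 / 3.0)
    return BeadModel(pts, np.full(n, b), np.array(["protein"] * n))
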