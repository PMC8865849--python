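"""Forward SANS computation from structures.

Residue-level coarse graining with D₂O contrast, an explicit hydration
layer outside the membrane slab, and orientation-averaged Debye sums:

    I(q) = Σᵢ Σⱼ bᵢ bⱼ sin(q rᵢⱼ)/(q rᵢⱼ)

with the q → 0 and i = j limits equal to 1.  Each residue becomes one bead
whose excess scattering length is

    bᵢ = b_res(D₂O fraction, labile-H exchange) − ρ_solv · V_res

i.e. the coherent sum of its atomic scattering lengths (labile hydrogens
exchanged against the solvent at a configurable fraction) minus the
scattering of the displaced solvent volume.  Residue beads outside the
membrane slab additionally receive a hydration-shell bead carrying a small
excess water density (default 6%), mimicking the denser bound-water layer
around the solvent-exposed protein surface while the membrane-embedded
transmembrane belt stays dry.

Scattering lengths are coherent neutron values in fm; volumes in Å³;
q in Å⁻¹.  The per-residue table (Σb in H₂O, labile-H count, dry volume)
uses the standard literature values for the 20 amino acids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import Structure

__all__ = [
    "ContrastModel",
    "BeadModel",
    "ScatteringCurve",
    "PairDistribution",
    "coarse_grain",
    "add_water_layer",
    "debye_intensity",
    "pair_distribution_from_beads",
    "structure_intensity",
    "ensemble_intensity",
    "read_dat",
    "write_dat",
    "RESIDUE_TABLE",
]

# coherent scattering lengths, fm
B_H = -3.742
B_D = 6.671
_B_ELEMENT = {"H": B_H, "D": B_D, "C": 6.6511, "N": 9.37, "O": 5.803,
              "S": 2.847, "P": 5.13, "SE": 7.97}

# per-residue Σb in H₂O (fm), labile (exchangeable) H count, dry volume (Å³)
RESIDUE_TABLE: dict[str, tuple[float, float, float]] = {
    "ALA": (16.45, 1, 88.6), "ARG": (34.66, 6, 173.4), "ASN": (34.56, 3, 114.1),
    "ASP": (38.45, 1, 111.1), "CYS": (19.30, 2, 108.5), "GLN": (33.73, 3, 143.8),
    "GLU": (37.62, 1, 138.4), "GLY": (17.28, 1, 60.1), "HIS": (49.59, 2, 153.2),
    "ILE": (13.96, 1, 166.7), "LEU": (13.96, 1, 166.7), "LYS": (15.86, 4, 168.6),
    "MET": (17.63, 1, 162.9), "PHE": (41.39, 1, 189.9), "PRO": (22.27, 0, 112.7),
    "SER": (22.25, 2, 89.0), "THR": (21.42, 2, 116.1), "TRP": (60.35, 2, 227.8),
    "TYR": (47.19, 2, 193.6), "VAL": (14.79, 1, 140.0),
}

# one water molecule: Σb (fm) and volume (Å³)
_B_H2O, _B_D2O, _V_WATER = -1.678, 19.145, 29.9


@dataclass
class ContrastModel:
    """Neutron contrast parameters for the residue-level forward model."""

    d2o_fraction: float = 1.0
    exchange_fraction: float = 0.9
    water_layer_fraction: float = 0.06
    shell_volume: float = 30.0       # Å³ water-equivalent per shell bead
    shell_offset: float = 3.0        # Å outward placement of shell beads
    residue_table: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(RESIDUE_TABLE))

    def __post_init__(self):
        for name, val in (("d2o_fraction", self.d2o_fraction),
                          ("exchange_fraction", self.exchange_fraction),
                          ("water_layer_fraction", self.water_layer_fraction)):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        for res, (_, _, vol) in self.residue_table.items():
            if vol <= 0:
                raise ValueError(f"non-positive volume for {res}")

    @property
    def solvent_sld(self) -> float:
        """Solvent scattering length density, fm/Å³."""
        b = self.d2o_fraction * _B_D2O + (1.0 - self.d2o_fraction) * _B_H2O
        return b / _V_WATER

    def residue_excess_b(self, res_name: str) -> float:
        """Excess scattering length of one residue bead, fm."""
        if res_name not in self.residue_table:
            raise KeyError(f"unknown residue type {res_name!r}")
        b_h2o, n_labile, volume = self.residue_table[res_name]
        b = b_h2o + n_labile * self.exchange_fraction * self.d2o_fraction * (B_D - B_H)
        return b - self.solvent_sld * volume


@dataclass
class BeadModel:
    """Point-scatterer model: positions (Å), excess lengths b (fm), class labels."""

    positions: np.ndarray
    b: np.ndarray
    bead_class: np.ndarray  # "protein" | "water-layer"

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.bead_class = np.asarray(self.bead_class)
        if len(self.positions) < 1:
            raise ValueError("at least one bead required")
        if not (len(self.positions) == len(self.b) == len(self.bead_class)):
            raise ValueError("bead arrays must be congruent")
        if not (np.all(np.isfinite(self.positions)) and np.all(np.isfinite(self.b))):
            raise ValueError("non-finite bead data")

    @property
    def n_beads(self) -> int:
        return len(self.b)


@dataclass
class ScatteringCurve:
    """I(q) on a strictly increasing non-negative q grid (Å⁻¹)."""

    q: np.ndarray
    i: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        if len(self.q) != len(self.i):
            raise ValueError("q and I length mismatch")
        if np.any(self.q < 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be non-negative and strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if len(self.sigma) != len(self.q):
                raise ValueError("sigma length mismatch")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive")

    def __len__(self) -> int:
        return len(self.q)


@dataclass
class PairDistribution:
    """Pair-distance distribution p(r) with 4π∫p(r)dr = I(0) − Σbᵢ²."""

    r: np.ndarray
    p: np.ndarray
    dmax: float

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if len(self.r) != len(self.p):
            raise ValueError("r and p length mismatch")
        if np.any(self.r < 0):
            raise ValueError("r must be non-negative")

    def rg(self) -> float:
        """Rg from the second moment: sqrt(∫r²p dr / 2∫p dr)."""
        norm = np.trapezoid(self.p, self.r)
        if norm <= 0:
            raise ValueError("p(r) has non-positive integral")
        return float(np.sqrt(np.trapezoid(self.r ** 2 * self.p, self.r) / (2.0 * norm)))


# ---------------------------------------------------------------------------
# Coarse graining
# ---------------------------------------------------------------------------

def coarse_grain(structure: Structure, contrast: ContrastModel | None = None,
                 on_unknown: str = "fail") -> BeadModel:
    """One bead per residue at its scattering-length-weighted atom centroid.

    Atom weights use |b_element| (hydrogen's negative b would make a signed
    centroid ill-defined); for single-atom toy residues the bead sits on the
    atom.  ``on_unknown``: ``"fail"`` or ``"skip"`` residues missing from the
    contrast table.
    """
    contrast = contrast or ContrastModel()
    if structure.n_atoms == 0:
        raise ValueError("empty structure")
    positions, bs = [], []
    keys = structure.residue_keys()
    chain_res = list(zip(structure.chain_ids, structure.res_nums))
    index: dict[tuple[str, int], list[int]] = {k: [] for k in keys}
    for j, (c, r) in enumerate(chain_res):
        index[(str(c), int(r))].append(j)
    for key in keys:
        idx = index[key]
        res_name = str(structure.res_names[idx[0]])
        try:
            b_res = contrast.residue_excess_b(res_name)
        except KeyError:
            if on_unknown == "skip":
                continue
            raise
        w = np.array([abs(_B_ELEMENT.get(str(structure.elements[j]).upper(), 6.65))
                      for j in idx])
        pos = (w[:, None] * structure.positions[idx]).sum(axis=0) / w.sum()
        positions.append(pos)
        bs.append(b_res)
    if not positions:
        raise ValueError("no residues survived coarse graining")
    n = len(positions)
    return BeadModel(np.array(positions), np.array(bs), np.array(["protein"] * n))


def add_water_layer(beads: BeadModel, structure: Structure,
                    membrane_slab: tuple[float, float] | None = None,
                    contrast: ContrastModel | None = None,
                    neighbor_cutoff: float = 7.0,
                    max_neighbors: int = 14) -> BeadModel:
    """Attach hydration-shell beads to exposed residues outside the membrane.

    A protein bead is solvent-exposed when fewer than ``max_neighbors`` other
    protein beads lie within ``neighbor_cutoff`` Å.  Each exposed bead whose z
    falls outside the slab gets one shell bead ``shell_offset`` Å outward
    along the direction from the protein centroid, with
    b = water_layer_fraction × ρ_solv × shell_volume.
    """
    contrast = contrast or ContrastModel()
    slab = membrane_slab if membrane_slab is not None else structure.membrane_slab
    if slab is not None and slab[0] >= slab[1]:
        raise ValueError(f"inverted membrane slab {slab}")
    if contrast.water_layer_fraction == 0.0:
        return beads
    prot = beads.positions[beads.bead_class == "protein"]
    center = prot.mean(axis=0)
    d2 = ((prot[:, None, :] - prot[None, :, :]) ** 2).sum(axis=-1)
    neighbor_counts = (d2 < neighbor_cutoff ** 2).sum(axis=1) - 1
    b_shell = contrast.water_layer_fraction * contrast.solvent_sld * contrast.shell_volume
    new_pos, new_b = [], []
    for k, pos in enumerate(prot):
        if slab is not None and slab[0] <= pos[2] <= slab[1]:
            continue
        if neighbor_counts[k] >= max_neighbors:
            continue
        direction = pos - center
        nrm = np.linalg.norm(direction)
        direction = direction / nrm if nrm > 1e-9 else np.array([0.0, 0.0, 1.0])
        new_pos.append(pos + contrast.shell_offset * direction)
        new_b.append(b_shell)
    if not new_pos:
        return beads
    return BeadModel(
        positions=np.vstack([beads.positions, np.array(new_pos)]),
        b=np.concatenate([beads.b, np.array(new_b)]),
        bead_class=np.concatenate([beads.bead_class,
                                   np.array(["water-layer"] * len(new_b))]),
    )


# ---------------------------------------------------------------------------
# Debye sums
# ---------------------------------------------------------------------------

def _debye_exact(positions, b, q, chunk=8):
    from scipy.spatial.distance import pdist
    d = pdist(positions)
    w = np.outer(b, b)[np.triu_indices(len(b), k=1)]
    self_term = float((b ** 2).sum())
    out = np.empty(len(q))
    for start in range(0, len(q), chunk):
        qs = q[start:start + chunk, None]
        out[start:start + chunk] = self_term + 2.0 * (
            w[None, :] * np.sinc(qs * d[None, :] / np.pi)).sum(axis=1)
    return out


def _debye_histogram(positions, b, q, bin_width):
    # bin representative = b-weighted mean distance, not the bin centre:
    # first-order phase error of the binning cancels
    from scipy.spatial.distance import pdist
    d = pdist(positions)
    w = np.outer(b, b)[np.triu_indices(len(b), k=1)]
    nbins = max(1, int(np.ceil(d.max() / bin_width)))
    rng = (0.0, nbins * bin_width)
    hist, edges = np.histogram(d, bins=nbins, range=rng, weights=w)
    wd, _ = np.histogram(d, bins=nbins, range=rng, weights=w * d)
    centers = 0.5 * (edges[:-1] + edges[1:])
    occupied = hist != 0
    centers = centers.copy()
    centers[occupied] = wd[occupied] / hist[occupied]
    self_term = float((b ** 2).sum())
    return self_term + 2.0 * (hist[None, :]
                              * np.sinc(q[:, None] * centers[None, :] / np.pi)).sum(axis=1)


def debye_intensity(beads: BeadModel, q_grid: np.ndarray,
                    exact_threshold: int = 2000,
                    histogram_bin: float = 0.1) -> ScatteringCurve:
    """Orientation-averaged intensity by the Debye double sum.

    Exact pairwise evaluation up to ``exact_threshold`` beads; above it, a
    pair-distance histogram (``histogram_bin`` Å bins) approximates the sum.
    I(0) = (Σbᵢ)² exactly in both paths.
    """
    q = np.asarray(q_grid, dtype=float)
    if np.any(q < 0):
        raise ValueError("negative q")
    if beads.n_beads < 1:
        raise ValueError("empty bead model")
    if beads.n_beads == 1:
        return ScatteringCurve(q, np.full(len(q), float(beads.b[0] ** 2)))
    if beads.n_beads <= exact_threshold:
        i = _debye_exact(beads.positions, beads.b, q)
    else:
        i = _debye_histogram(beads.positions, beads.b, q, histogram_bin)
    return ScatteringCurve(q, i)


def pair_distribution_from_beads(beads: BeadModel,
                                 bin_width: float = 1.0) -> PairDistribution:
    """b-weighted pair-distance histogram, normalised so 4π∫p dr = I(0) − Σbᵢ²."""
    if beads.n_beads < 2:
        raise ValueError("need at least two beads for p(r)")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    from scipy.spatial.distance import pdist
    d = pdist(beads.positions)
    w = np.outer(beads.b, beads.b)[np.triu_indices(beads.n_beads, k=1)]
    dmax = float(d.max())
    nbins = max(1, int(np.ceil(dmax / bin_width)))
    hist, edges = np.histogram(d, bins=nbins, range=(0.0, nbins * bin_width),
                               weights=w)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = 2.0 * hist / (4.0 * np.pi * bin_width)  # i≠j pairs, per unit r
    return PairDistribution(r=centers, p=p, dmax=dmax)


class CoarseGrainMapper:
    """Reusable residue→bead mapping for repeated forward evaluations.

    Precomputes the per-residue atom weights and excess scattering lengths
    once, so deformed copies of the same topology can be coarse-grained by
    a single sparse matrix product (the refinement loop calls this many
    hundreds of times).
    """

    def __init__(self, structure: Structure, contrast: ContrastModel | None = None):
        from scipy.sparse import csr_matrix
        contrast = contrast or ContrastModel()
        ref_beads = coarse_grain(structure, contrast)
        self.b = ref_beads.b
        keys = structure.residue_keys()
        key_index = {k: i for i, k in enumerate(keys)}
        rows, cols, vals = [], [], []
        for j in range(structure.n_atoms):
            i = key_index[(str(structure.chain_ids[j]), int(structure.res_nums[j]))]
            w = abs(_B_ELEMENT.get(str(structure.elements[j]).upper(), 6.65))
            rows.append(i)
            cols.append(j)
            vals.append(w)
        m = csr_matrix((vals, (rows, cols)), shape=(len(keys), structure.n_atoms))
        norm = np.asarray(m.sum(axis=1)).ravel()
        self.matrix = m.multiply(1.0 / norm[:, None]).tocsr()

    def beads(self, positions: np.ndarray) -> BeadModel:
        pos = self.matrix @ np.asarray(positions, dtype=float)
        return BeadModel(pos, self.b, np.array(["protein"] * len(self.b)))

    def intensity(self, positions: np.ndarray, q_grid: np.ndarray) -> ScatteringCurve:
        return debye_intensity(self.beads(positions), q_grid)


def structure_intensity(structure: Structure, q_grid: np.ndarray,
                        contrast: ContrastModel | None = None,
                        water_layer: bool = False) -> ScatteringCurve:
    """Convenience pipeline: coarse-grain → (hydration layer) → Debye sum."""
    contrast = contrast or ContrastModel()
    beads = coarse_grain(structure, contrast)
    if water_layer:
        beads = add_water_layer(beads, structure, contrast=contrast)
    return debye_intensity(beads, q_grid)


def ensemble_intensity(curves: list[ScatteringCurve],
                       weights: np.ndarray) -> ScatteringCurve:
    """Pointwise weighted mean of per-frame curves on a common q grid."""
    if not curves:
        raise ValueError("no curves")
    w = np.asarray(weights, dtype=float)
    if len(w) != len(curves):
        raise ValueError("one weight per curve required")
    q0 = curves[0].q
    for c in curves[1:]:
        if len(c.q) != len(q0) or not np.allclose(c.q, q0):
            raise ValueError("q-grid mismatch between frames")
    w = w / w.sum()
    i = np.zeros_like(q0)
    for c, wi in zip(curves, w):
        i += wi * c.i
    return ScatteringCurve(q0, i)


# ---------------------------------------------------------------------------
# Curve text I/O (SASBDB-style .dat)
# ---------------------------------------------------------------------------

def read_dat(path) -> ScatteringCurve:
    """Read a 2/3/4-column whitespace curve file (q, I[, σ[, Δq]]); # comments."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: need at least q and I columns")
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return ScatteringCurve(data[:, 0], data[:, 1], sigma)


def write_dat(curve: ScatteringCurve, path, header: str = "q I(q) sigma") -> None:
    cols = [curve.q, curve.i]
    if curve.sigma is not None:
        cols.append(curve.sigma)
    np.savetxt(path, np.column_stack(cols), header=header)
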