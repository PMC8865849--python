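"""Pore-radius profiling along a channel axis.

At each slice along the axis the largest sphere centred on the slice plane
that avoids every atom's van-der-Waals sphere is found: the objective

    R(x, y; z) = min_i ( |r_i − (x, y, z)| − vdW_i )

is maximised over (x, y) by a seeded simulated-annealing search warm-
started from the previous slice's centre.  The global minimum of the
radius track is the pore constriction; a channel is classified as
conducting for a hydrated ion when that minimum is at least the ion's
hydrated radius (2.4 Å for Mg²⁺, the default threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import Structure

__all__ = ["PoreProfile", "pore_radius_profile", "pore_radius_at",
           "min_constriction", "classify_conducting", "BONDI_RADII",
           "HYDRATED_MG_RADIUS"]

BONDI_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
               "P": 1.80, "F": 1.47, "CL": 1.75}
HYDRATED_MG_RADIUS = 2.4  # Å


@dataclass
class PoreProfile:
    z: np.ndarray
    radius: np.ndarray
    centers: np.ndarray   # (n, 2) x, y of the inscribed-sphere centre
    vdw_set: str
    seed: int
    max_radius: float

    def __post_init__(self):
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("z grid must increase")
        if np.any(self.radius < 0):
            raise ValueError("negative radii")


def _atom_radii(structure: Structure, vdw_set: str, bead_radius: float):
    if vdw_set == "bead":
        return np.full(structure.n_atoms, bead_radius)
    if vdw_set == "auto":
        # coarse models (one atom per residue) carry residue-bead radii
        if structure.n_atoms == len(structure.residue_keys()):
            return np.full(structure.n_atoms, bead_radius)
        vdw_set = "bondi"
    if vdw_set != "bondi":
        raise ValueError(f"unknown vdW set {vdw_set!r}")
    return np.array([BONDI_RADII.get(str(e).upper(), 1.7)
                     for e in structure.elements])


def _axis_frame(axis):
    axis = np.asarray(axis, dtype=float)
    nrm = np.linalg.norm(axis)
    if nrm < 1e-12:
        raise ValueError("axis must be non-zero")
    z = axis / nrm
    ref = np.array([1.0, 0.0, 0.0]) if abs(z[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    x = np.cross(ref, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def pore_radius_at(coords: np.ndarray, radii: np.ndarray, center: np.ndarray,
                   max_radius: float) -> float:
    """Largest non-overlapping sphere radius at a fixed centre (≥ 0, capped)."""
    d = np.linalg.norm(coords - center[None, :], axis=1) - radii
    return float(np.clip(d.min() if len(d) else max_radius, 0.0, max_radius))


def _slice_radius_grid(sub, sub_r, z, center, shift, resolution, max_radius):
    """Deterministic max over an in-plane grid within ``shift`` of ``center``."""
    g = np.arange(-shift, shift + 0.5 * resolution, resolution)
    gx, gy = np.meshgrid(g, g)
    pts = np.column_stack([center[0] + gx.ravel(), center[1] + gy.ravel(),
                           np.full(gx.size, z)])
    if len(sub) == 0:
        return float(max_radius), center
    d = np.linalg.norm(pts[:, None, :] - sub[None, :, :], axis=2) - sub_r[None, :]
    rad = np.clip(d.min(axis=1), 0.0, max_radius)
    k = int(np.argmax(rad))
    return float(rad[k]), pts[k, :2]


def pore_radius_profile(structure: Structure, axis=(0.0, 0.0, 1.0),
                        z_range: tuple[float, float] | None = None,
                        step: float = 1.0, seed: int = 0,
                        vdw_set: str = "auto", bead_radius: float = 3.0,
                        max_radius: float = 15.0, n_anneal: int = 200,
                        max_center_shift: float | None = None,
                        grid_resolution: float = 0.5) -> PoreProfile:
    """HOLE-style largest-inscribed-sphere profile along ``axis``.

    Coordinates are rotated so the axis is z.  At each z the in-plane
    centre may move at most ``max_center_shift`` (default: the slice step)
    from the previous slice's centre — the pore path is continuous, so the
    probe cannot tunnel through a wall or escape into bulk solvent.  The
    centre is first located on a deterministic grid of ``grid_resolution``
    and then polished by seeded simulated annealing (Metropolis acceptance,
    geometric cooling), so the result always dominates the grid search.
    Slices with no atoms nearby are capped at ``max_radius``.
    Deterministic per seed.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    shift = step if max_center_shift is None else max_center_shift
    frame = _axis_frame(axis)
    coords = structure.positions @ frame  # axis now local z
    radii = _atom_radii(structure, vdw_set, bead_radius)
    if z_range is None:
        z_range = (coords[:, 2].min(), coords[:, 2].max())
    z_grid = np.arange(z_range[0], z_range[1] + 0.5 * step, step)
    if len(z_grid) == 0:
        raise ValueError("empty z range")
    rng = np.random.default_rng(seed)
    center_xy = coords[:, :2].mean(axis=0)
    out_r = np.empty(len(z_grid))
    out_c = np.empty((len(z_grid), 2))
    for k, z in enumerate(z_grid):
        near = np.abs(coords[:, 2] - z) < (radii.max() + max_radius)
        sub, sub_r = coords[near], radii[near]
        anchor = center_xy.copy()
        best, best_xy = _slice_radius_grid(sub, sub_r, z, anchor, shift,
                                           grid_resolution, max_radius)

        def rad(xy):
            return pore_radius_at(sub, sub_r, np.array([xy[0], xy[1], z]),
                                  max_radius)

        cur_xy, cur = best_xy.copy(), best
        temp, sigma = 0.5, 0.5 * grid_resolution
        for _ in range(n_anneal):
            cand = cur_xy + sigma * rng.standard_normal(2)
            if np.linalg.norm(cand - anchor) > shift:
                continue
            r_c = rad(cand)
            if r_c >= cur or rng.random() < np.exp((r_c - cur) / max(temp, 1e-9)):
                cur_xy, cur = cand, r_c
                if cur > best:
                    best_xy, best = cur_xy.copy(), cur
            temp *= 0.98
        out_r[k] = best
        out_c[k] = best_xy
        center_xy = best_xy  # warm start next slice
    return PoreProfile(z=z_grid, radius=out_r, centers=out_c,
                       vdw_set=vdw_set, seed=seed, max_radius=max_radius)


def min_constriction(profile: PoreProfile):
    """Global minimum of the radius track: (z_min, radius_min, tie_flag)."""
    if len(profile.z) == 0:
        raise ValueError("empty profile")
    k = int(np.argmin(profile.radius))
    tie = int((profile.radius == profile.radius[k]).sum()) > 1
    return float(profile.z[k]), float(profile.radius[k]), tie


def classify_conducting(profile: PoreProfile,
                        threshold_radius: float = HYDRATED_MG_RADIUS):
    """Conducting iff min radius ≥ threshold; returns (bool, margin in Å)."""
    _, r_min, _ = min_constriction(profile)
    return r_min >= threshold_radius, r_min - threshold_radius
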