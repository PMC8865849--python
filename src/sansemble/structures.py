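"""Coordinate data model, PDB I/O and geometric utilities.

The central container is :class:`Structure`, a flat per-atom table (chain,
residue number, residue name, atom name, element, position in Å) plus
structure-level annotations: secondary-structure segments, a membrane slab
(z bounds in Å) and per-residue domain labels (ICD / TMD / stalk).  It is
deliberately minimal — a pentameric channel and its coarse-grained toy
counterparts both fit it — and all downstream stages (scattering forward
model, normal modes, pore profiling) consume it.

PDB reading and writing are delegated to :mod:`gemmi`; atom order is
canonicalised on read (chain id, residue number, atom name) so that frames
of an ensemble are congruent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "Structure",
    "Ensemble",
    "ClusterResult",
    "SecondaryStructureSegment",
    "read_pdb",
    "write_pdb",
    "write_multi_model_pdb",
    "radius_of_gyration",
    "kabsch_superpose",
    "rmsd",
    "rotate_z",
    "kmeans_cluster",
]


@dataclass(frozen=True)
class SecondaryStructureSegment:
    """Contiguous helix/strand segment: residues ``start..end`` (inclusive) of one chain."""

    chain: str
    start: int
    end: int
    kind: str = "helix"

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"segment end {self.end} < start {self.start}")


@dataclass
class Structure:
    """Per-atom coordinate table with channel-specific annotations.

    Parameters
    ----------
    chain_ids, res_nums, res_names, atom_names, elements
        Per-atom metadata arrays, all of length ``n_atoms``.
    positions
        ``(n_atoms, 3)`` Cartesian coordinates in Å.
    segments
        Secondary-structure segments (used by the NMA block definition and
        the structure penalty).
    membrane_slab
        ``(z_min, z_max)`` in Å, or ``None``.  Residues whose bead falls
        inside the slab are treated as membrane-embedded by the hydration
        layer construction.
    domain_labels
        Mapping ``(chain, res_num) -> label`` with labels such as
        ``"ICD"``, ``"TMD"``, ``"stalk"``.
    """

    chain_ids: np.ndarray
    res_nums: np.ndarray
    res_names: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    positions: np.ndarray
    segments: list[SecondaryStructureSegment] = field(default_factory=list)
    membrane_slab: tuple[float, float] | None = None
    domain_labels: dict[tuple[str, int], str] = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        n = len(self.positions)
        for name in ("chain_ids", "res_nums", "res_names", "atom_names", "elements"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")
            setattr(self, name, arr)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if self.membrane_slab is not None:
            zmin, zmax = self.membrane_slab
            if zmin >= zmax:
                raise ValueError(f"inverted membrane slab ({zmin}, {zmax})")
        # residue numbers strictly increasing within each chain (per residue,
        # not per atom: consecutive atoms share the residue number)
        for ch in self.chains():
            nums = self.res_nums[self.chain_ids == ch]
            boundaries = np.flatnonzero(np.diff(nums) != 0)
            if np.any(np.diff(nums)[boundaries] < 0):
                raise ValueError(f"residue numbers not increasing in chain {ch}")

    # -- basic queries -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(str(c))
        return list(seen)

    def residue_keys(self) -> list[tuple[str, int]]:
        """Ordered unique (chain, residue number) pairs."""
        keys: dict[tuple[str, int], None] = {}
        for c, r in zip(self.chain_ids, self.res_nums):
            keys.setdefault((str(c), int(r)))
        return list(keys)

    def ca_mask(self) -> np.ndarray:
        return np.asarray(self.atom_names) == "CA"

    def select(self, mask: np.ndarray) -> "Structure":
        return Structure(
            chain_ids=self.chain_ids[mask],
            res_nums=self.res_nums[mask],
            res_names=self.res_names[mask],
            atom_names=self.atom_names[mask],
            elements=self.elements[mask],
            positions=self.positions[mask],
            segments=list(self.segments),
            membrane_slab=self.membrane_slab,
            domain_labels=dict(self.domain_labels),
        )

    def with_positions(self, positions: np.ndarray) -> "Structure":
        return replace(self, positions=np.asarray(positions, dtype=float))

    def canonical_order(self) -> "Structure":
        """Sort atoms by (chain id, residue number, atom name)."""
        order = np.lexsort(
            (np.asarray(self.atom_names), np.asarray(self.res_nums),
             np.asarray(self.chain_ids))
        )
        return self.select(order)


@dataclass
class Ensemble:
    """Fixed-topology conformational ensemble with prior weights."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    prior_weights: np.ndarray | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be (n_frames >= 1, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} != topology "
                f"{self.topology.n_atoms}"
            )
        n = self.frames.shape[0]
        if self.prior_weights is None:
            self.prior_weights = np.full(n, 1.0 / n)
        self.prior_weights = np.asarray(self.prior_weights, dtype=float)
        if len(self.prior_weights) != n:
            raise ValueError("one prior weight per frame required")
        if np.any(self.prior_weights < 0):
            raise ValueError("prior weights must be non-negative")
        if abs(self.prior_weights.sum() - 1.0) > 1e-12:
            raise ValueError("prior weights must sum to 1 within 1e-12")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_positions(self.frames[i])


@dataclass
class ClusterResult:
    """KMeans output: per-frame assignments plus real-frame centroids."""

    assignments: np.ndarray
    centroid_frames: np.ndarray
    inertia: float


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def read_pdb(path, model_index: int = 1, include_hetatm: bool = False) -> Structure:
    """Read one model of a PDB file into a :class:`Structure`.

    ``model_index`` is the 1-based PDB MODEL number.  HETATM records and
    waters are excluded unless ``include_hetatm`` is set.  Atoms are
    canonicalised to (chain, residue number, atom name) order.
    """
    import gemmi

    try:
        st = gemmi.read_pdb(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # gemmi reports the offending line in its message
        raise ValueError(f"malformed PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = None
    for m in st:
        if m.num == model_index:
            model = m
            break
    if model is None:
        available = [m.num for m in st]
        raise ValueError(f"{path}: model {model_index} absent (have {available})")

    chain_ids, res_nums, res_names, atom_names, elements, xyz = [], [], [], [], [], []
    for chain in model:
        for res in chain:
            if not include_hetatm and (res.het_flag == "H" or res.name in ("HOH", "DOD")):
                continue
            for atom in res:
                chain_ids.append(chain.name)
                res_nums.append(res.seqid.num)
                res_names.append(res.name)
                atom_names.append(atom.name)
                elements.append(atom.element.name)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not xyz:
        raise ValueError(f"{path}: model {model_index} contains no atoms")
    s = Structure(
        chain_ids=np.array(chain_ids),
        res_nums=np.array(res_nums, dtype=int),
        res_names=np.array(res_names),
        atom_names=np.array(atom_names),
        elements=np.array(elements),
        positions=np.array(xyz, dtype=float),
    )
    return s.canonical_order()


def _to_gemmi(structure: Structure, frames: np.ndarray | None = None):
    import gemmi

    st = gemmi.Structure()
    st.name = "sansemble"
    frame_list = [structure.positions] if frames is None else list(frames)
    for i, coords in enumerate(frame_list, start=1):
        model = gemmi.Model(i)
        cur_chain = None
        cur_res = None
        serial = 0
        for j in range(structure.n_atoms):
            cid = str(structure.chain_ids[j])
            rnum = int(structure.res_nums[j])
            if cur_chain is None or cur_chain.name != cid:
                cur_chain = gemmi.Chain(cid)
                model.add_chain(cur_chain)
                cur_chain = model[-1]
                cur_res = None
            if cur_res is None or cur_res.seqid.num != rnum:
                res = gemmi.Residue()
                res.name = str(structure.res_names[j])
                res.seqid = gemmi.SeqId(rnum, " ")
                cur_chain.add_residue(res)
                cur_res = cur_chain[-1]
            atom = gemmi.Atom()
            atom.name = str(structure.atom_names[j])
            atom.element = gemmi.Element(str(structure.elements[j]))
            serial += 1
            atom.serial = serial
            atom.pos = gemmi.Position(*coords[j])
            cur_res.add_atom(atom)
        st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(structure: Structure, path) -> None:
    """Write a single-model PDB (ATOM/TER records, 3-decimal coordinates)."""
    _to_gemmi(structure).write_pdb(str(path))


def write_multi_model_pdb(ensemble: Ensemble, path) -> None:
    """Write an ensemble as a multi-MODEL PDB."""
    _to_gemmi(ensemble.topology, ensemble.frames).write_pdb(str(path))


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def radius_of_gyration(points: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Weighted radius of gyration sqrt(Σwᵢ|rᵢ−r̄|²/Σwᵢ) in the units of ``points``."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 1:
        raise ValueError("at least one point required")
    if weights is None:
        w = np.ones(len(pts))
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(pts):
            raise ValueError("weights length mismatch")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("weights sum to zero")
    center = (w[:, None] * pts).sum(axis=0) / wsum
    return float(np.sqrt((w * ((pts - center) ** 2).sum(axis=1)).sum() / wsum))


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray):
    """Optimal rigid superposition of ``mobile`` onto ``target`` (Kabsch).

    Returns ``(moved, rotation, translation)`` with
    ``moved = (mobile - mobile_centroid) @ R.T + target_centroid``.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError("atom-count mismatch")
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    moved = (mobile - cm) @ r.T + ct
    return moved, r, ct - cm @ r.T


def rmsd(frame_a: np.ndarray, frame_b: np.ndarray, superpose: bool = False) -> float:
    """Root-mean-square deviation between two congruent coordinate sets (Å)."""
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"atom-count mismatch: {a.shape} vs {b.shape}")
    if superpose:
        a, _, _ = kabsch_superpose(a, b)
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


def rotate_z(points: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate coordinates about the z axis (the C5 symmetry operation at 72°)."""
    t = np.deg2rad(angle_deg)
    rot = np.array(
        [[np.cos(t), -np.sin(t), 0.0], [np.sin(t), np.cos(t), 0.0], [0.0, 0.0, 1.0]]
    )
    return np.asarray(points, dtype=float) @ rot.T


# ---------------------------------------------------------------------------
# Conformational clustering
# ---------------------------------------------------------------------------

def kmeans_cluster(ensemble: Ensemble, n_clusters: int, seed: int = 0,
                   ca_only: bool = True) -> ClusterResult:
    """KMeans clustering of ensemble frames.

    Features are the flattened coordinates (Cα-only by default) of every
    frame after rigid superposition onto frame 0, so rigid-body motion does
    not separate conformations.  Cluster centroids are reported as the real
    frame nearest each cluster mean.
    """
    if n_clusters <= 0:
        raise ValueError("n_clusters must be positive")
    if n_clusters > ensemble.n_frames:
        raise ValueError(
            f"n_clusters {n_clusters} exceeds frame count {ensemble.n_frames}")
    mask = ensemble.topology.ca_mask() if ca_only else np.ones(
        ensemble.topology.n_atoms, dtype=bool)
    if not mask.any():
        mask = np.ones(ensemble.topology.n_atoms, dtype=bool)
    ref = ensemble.frames[0][mask]
    feats = np.empty((ensemble.n_frames, mask.sum() * 3))
    for i in range(ensemble.n_frames):
        moved, _, _ = kabsch_superpose(ensemble.frames[i][mask], ref)
        feats[i] = moved.ravel()
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
    labels = km.fit_predict(feats)
    centroid_frames = np.empty(n_clusters, dtype=int)
    for k in range(n_clusters):
        members = np.flatnonzero(labels == k)
        d = np.linalg.norm(feats[members] - km.cluster_centers_[k], axis=1)
        centroid_frames[k] = members[np.argmin(d)]
    return ClusterResult(assignments=labels, centroid_frames=centroid_frames,
                         inertia=float(km.inertia_))
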