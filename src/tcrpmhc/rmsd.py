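"""Superposition and the three model-accuracy measures.

CDR RMSD: model and native are superposed on their MHC alpha-carbons; the
CA RMSD over the eight CDR loops is then computed without further
superposition, with every CDR3 residue up-weighted by a factor of 3 (weights
enter the squared sum, normalized by the weight total).

Peptide RMSD: same superposition convention, uniform weights over peptide CAs.

Docking RMSD: a sequence-independent distance between two docking geometries.
Generic per-loop CDR centers of mass (averaged over a structure database, in
TCR-frame coordinates) are placed by each geometry's TCR frame over a common
MHC frame, and the weighted point RMSD between the two placements is taken
without superposition, CDR3 centers of mass again weighted 3x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DockingGeometry, RigidTransform, build_tcr_frame, kabsch, tcr_frame_from_geometry
from .structure import CDR_LOOPS, TernaryComplex, locate_core_residues

__all__ = [
    "GenericCdrComs",
    "weighted_superpose",
    "weighted_point_rmsd",
    "cdr_rmsd",
    "peptide_rmsd",
    "compute_generic_cdr_coms",
    "docking_rmsd",
]

_CDR3_SLOTS = (CDR_LOOPS.index("cdr3a"), CDR_LOOPS.index("cdr3b"))


def default_com_weights() -> np.ndarray:
    w = np.ones(8)
    for i in _CDR3_SLOTS:
        w[i] = 3.0
    return w


@dataclass(frozen=True)
class GenericCdrComs:
    """Mean CDR-loop centers of mass in TCR-frame coordinates.

    One 3-vector per loop, ordered as CDR_LOOPS (alpha 1/2/2.5/3 then beta
    1/2/2.5/3); the two CDR3 slots carry weight 3, the rest weight 1.
    """

    points: np.ndarray
    weights: np.ndarray = None
    n_source_structures: int = 0

    def __post_init__(self):
        pts = np.asarray(self.points, float)
        if pts.shape != (8, 3):
            raise ValueError("need exactly 8 CDR centers of mass")
        w = default_com_weights() if self.weights is None else np.asarray(self.weights, float)
        if w.shape != (8,) or not np.all(np.isin(w, (1.0, 3.0))):
            raise ValueError("weights must be 8 values in {1, 3}")
        if any(w[i] != 3.0 for i in _CDR3_SLOTS):
            raise ValueError("CDR3 centers of mass must carry weight 3")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "weights", w)


def weighted_point_rmsd(p: np.ndarray, q: np.ndarray, weights: np.ndarray | None = None) -> float:
    """sqrt(sum w_i |p_i - q_i|^2 / sum w_i), no superposition."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if p.shape != q.shape:
        raise ValueError("point sets must match")
    w = np.ones(len(p)) if weights is None else np.asarray(weights, float)
    d2 = ((p - q) ** 2).sum(axis=1)
    return float(np.sqrt((w * d2).sum() / w.sum()))


def weighted_superpose(
    fixed: np.ndarray, mobile: np.ndarray, weights: np.ndarray | None = None
) -> tuple[RigidTransform, float]:
    """Optimal weighted rigid superposition of mobile onto fixed.

    Returns the transform and the residual weighted RMSD.
    """
    t = kabsch(fixed, mobile, weights)
    return t, weighted_point_rmsd(np.asarray(fixed, float), t.apply(mobile), weights)


def _mhc_superposition(native: TernaryComplex, model: TernaryComplex,
                       mhc_indices=None) -> RigidTransform:
    """Unweighted superposition of model MHC CAs onto native MHC CAs."""
    n_idx = {r.seq_index for r in native.chain("mhc")}
    m_idx = {r.seq_index for r in model.chain("mhc")}
    shared = sorted(n_idx & m_idx)
    if mhc_indices is not None:
        shared = [i for i in shared if i in set(mhc_indices)]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared MHC CA positions for superposition")
    nmap = {r.seq_index: r.ca_xyz for r in native.chain("mhc")}
    mmap = {r.seq_index: r.ca_xyz for r in model.chain("mhc")}
    fixed = np.array([nmap[i] for i in shared])
    mobile = np.array([mmap[i] for i in shared])
    return kabsch(fixed, mobile)


def _cdr_points(complex: TernaryComplex):
    """All CDR CA coordinates with per-residue weights (CDR3 residues x3)."""
    pts, weights = [], []
    ann = complex.annotation
    for loop in CDR_LOOPS:
        role = "tcra" if loop.endswith("a") else "tcrb"
        chain = complex.chain(role)
        s, e = ann.cdr_spans[loop]
        w = 3.0 if loop.startswith("cdr3") else 1.0
        for i in range(s, e):
            pts.append(chain[i].ca_xyz)
            weights.append(w)
    return np.array(pts), np.array(weights)


def cdr_rmsd(native: TernaryComplex, model: TernaryComplex, mhc_indices=None) -> float:
    """CA RMSD over the 8 CDR loops after MHC superposition, CDR3 weighted 3x.

    `mhc_indices` restricts the superposition to a subset of MHC positions
    (e.g. the 12 beta-sheet core residues); default is all shared MHC CAs.
    """
    if native.annotation.cdr_spans != model.annotation.cdr_spans:
        raise ValueError("native and model CDR spans differ")
    t = _mhc_superposition(native, model, mhc_indices)
    npts, weights = _cdr_points(native)
    mpts, _ = _cdr_points(model)
    return weighted_point_rmsd(npts, t.apply(mpts), weights)


def peptide_rmsd(native: TernaryComplex, model: TernaryComplex, mhc_indices=None) -> float:
    """Peptide CA RMSD after MHC superposition, uniform weights."""
    if len(native.chain("peptide")) != len(model.chain("peptide")):
        raise ValueError("native and model peptide lengths differ")
    t = _mhc_superposition(native, model, mhc_indices)
    npts = native.ca_array("peptide")
    mpts = model.ca_array("peptide")
    return weighted_point_rmsd(npts, t.apply(mpts))


def compute_generic_cdr_coms(
    db: list[TernaryComplex], cores_list=None, profiles=None
) -> GenericCdrComs:
    """Average CDR-loop CA centers of mass over a structure database.

    Each structure's loop COMs are expressed in its own TCR coordinate frame
    before averaging, so the result is invariant to the global placement of
    the database structures.
    """
    if not db:
        raise ValueError("empty structure database")
    if cores_list is None:
        cores_list = [locate_core_residues(c, profiles) for c in db]
    acc = np.zeros((8, 3))
    for complex, cores in zip(db, cores_list):
        frame = build_tcr_frame(complex, cores)
        for slot, loop in enumerate(CDR_LOOPS):
            role = "tcra" if loop.endswith("a") else "tcrb"
            s, e = complex.annotation.cdr_spans[loop]
            if e <= s:
                raise ValueError(f"loop {loop} unresolved")
            com = np.array([complex.chain(role)[i].ca_xyz for i in range(s, e)]).mean(axis=0)
            acc[slot] += frame.to_local(com)
    return GenericCdrComs(points=acc / len(db), n_source_structures=len(db))


def docking_rmsd(g1: DockingGeometry, g2: DockingGeometry, coms: GenericCdrComs) -> float:
    """Sequence-independent distance between two docking geometries.

    The generic CDR centers of mass are placed by the TCR frame each geometry
    implies over a common (identity) MHC frame; the weighted RMSD between the
    two 8-point sets is returned without superposition.
    """
    f1 = tcr_frame_from_geometry(g1)
    f2 = tcr_frame_from_geometry(g2)
    p1 = f1.from_local(coms.points)
    p2 = f2.from_local(coms.points)
    return weighted_point_rmsd(p1, p2, coms.weights)
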