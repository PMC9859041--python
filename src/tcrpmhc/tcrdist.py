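"""TCRdist-style sequence distances and repertoire operations built on them.

The distance between two TCR chains is an additive weighted mismatch score
over the germline CDR1, CDR2 and CDR2.5 loops (weight 1) and the
hypervariable CDR3 (weight 3).  Per-position substitution cost is
``min(4, 4 - BLOSUM62(a, b))`` clamped at zero, so identities cost 0,
conservative substitutions cost 1-3 and non-conservative ones 4; gaps cost 4.
CDR3 loops are compared after trimming fixed flanks (3 N-terminal, 2
C-terminal positions) and center-gapping the shorter loop.  The paired
distance is the sum over the alpha and beta chains; a single non-conservative
CDR3 mismatch therefore costs 12 and three of them 36.

Repertoire operations: greedy redundancy filtering of (TCR, peptide) entries
and Gaussian-kernel-density subsampling that preferentially keeps TCRs from
densely sampled regions of sequence space while enforcing a minimum pairwise
distance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from Bio.Align import substitution_matrices

__all__ = [
    "TcrChainSeq",
    "PairedTcr",
    "single_chain_tcrdist",
    "paired_tcrdist",
    "redundancy_filter",
    "kde_subsample",
    "load_v_gene_table",
    "tcrdist_matrix",
    "average_linkage_newick",
]

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

#: substitution cost cap and gap penalty of the distance
COST_CAP = 4.0
GAP_PENALTY = 4.0
CDR3_WEIGHT = 3.0
CDR3_TRIM = (3, 2)  # N-terminal / C-terminal flank positions ignored


def load_v_gene_table() -> dict:
    """Shipped V-gene -> germline CDR1/2/2.5 loop lookup (synthetic genes)."""
    text = resources.files("tcrpmhc.data").joinpath("v_gene_cdrs.json").read_text()
    raw = json.loads(text)
    return {"alpha": raw["alpha"], "beta": raw["beta"]}


@dataclass(frozen=True)
class TcrChainSeq:
    """One TCR chain as its V gene name and four CDR loop sequences."""

    v_gene: str
    cdr1: str
    cdr2: str
    cdr25: str
    cdr3: str

    def __post_init__(self):
        if len(self.cdr3) < 5:
            raise ValueError("CDR3 must be at least 5 residues")
        for name in ("cdr1", "cdr2", "cdr25"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")

    @classmethod
    def from_v_gene(cls, v_gene: str, cdr3: str, chain: str, table: dict | None = None):
        """Build a chain from a V-gene lookup plus its CDR3."""
        table = table or load_v_gene_table()
        try:
            loops = table[chain][v_gene]
        except KeyError:
            raise KeyError(f"unknown {chain} V gene {v_gene!r}")
        return cls(v_gene=v_gene, cdr3=cdr3, **loops)


@dataclass(frozen=True)
class PairedTcr:
    alpha: TcrChainSeq
    beta: TcrChainSeq
    id: str = ""


def _aa_cost(a: str, b: str) -> float:
    if a == b:
        return 0.0
    try:
        s = _BLOSUM62[a, b]
    except (KeyError, IndexError):
        return COST_CAP
    return max(0.0, min(COST_CAP, COST_CAP - float(s)))


def _center_gap_cost(s1: str, s2: str) -> float:
    """Mismatch cost of two loops, center-gapping the shorter one.

    The shorter loop keeps its first ceil(m/2) positions aligned from the
    front and the rest from the back; the length difference is charged as
    gaps at GAP_PENALTY each.
    """
    if len(s1) > len(s2):
        s1, s2 = s2, s1
    m, n = len(s1), len(s2)
    front = (m + 1) // 2
    cost = (n - m) * GAP_PENALTY
    for i in range(m):
        j = i if i < front else i + (n - m)
        cost += _aa_cost(s1[i], s2[j])
    return cost


def _cdr3_cost(c1: str, c2: str) -> float:
    lo, hi = CDR3_TRIM
    t1 = c1[lo: len(c1) - hi]
    t2 = c2[lo: len(c2) - hi]
    if not t1 or not t2:
        # degenerate short loop: compare untrimmed
        t1, t2 = c1, c2
    return _center_gap_cost(t1, t2)


def single_chain_tcrdist(a: TcrChainSeq, b: TcrChainSeq) -> float:
    """Weighted CDR mismatch distance between two chains of the same type."""
    d = (
        _center_gap_cost(a.cdr1, b.cdr1)
        + _center_gap_cost(a.cdr2, b.cdr2)
        + _center_gap_cost(a.cdr25, b.cdr25)
        + CDR3_WEIGHT * _cdr3_cost(a.cdr3, b.cdr3)
    )
    return float(d)


def paired_tcrdist(t1: PairedTcr, t2: PairedTcr) -> float:
    """Sum of the alpha-chain and beta-chain distances."""
    return single_chain_tcrdist(t1.alpha, t2.alpha) + single_chain_tcrdist(t1.beta, t2.beta)


def redundancy_filter(entries, pep_thresh: int = 3, dist_thresh: float = 120.0) -> list:
    """Greedy scan keeping only entries not redundant with an earlier kept one.

    An entry is redundant with a kept entry when it has fewer than
    `pep_thresh` peptide mismatches AND a paired distance <= `dist_thresh`
    (peptides of different length never count as similar).  Keeping the
    earlier entry makes deposit-date-ordered input reproduce a
    first-deposited-wins policy.
    """
    from .structure import peptide_mismatches

    kept = []
    for tcr, peptide in entries:
        redundant = False
        for ktcr, kpep in kept:
            if (
                peptide_mismatches(peptide, kpep) < pep_thresh
                and paired_tcrdist(tcr, ktcr) <= dist_thresh
            ):
                redundant = True
                break
        if not redundant:
            kept.append((tcr, peptide))
    return kept


def tcrdist_matrix(tcrs) -> np.ndarray:
    n = len(tcrs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = paired_tcrdist(tcrs[i], tcrs[j])
    return d


def kde_subsample(
    tcrs,
    n: int = 50,
    bandwidth: float = 120.0,
    min_dist: float = 24.0,
    seed: int = 0,
    dist_matrix: np.ndarray | None = None,
):
    """Density-biased subsampling of a repertoire to at most n representatives.

    Candidates are scored by a Gaussian kernel density over the paired
    distance matrix (sigma = bandwidth) and picked greedily, densest first,
    skipping any candidate within min_dist of an already-selected TCR.
    Density ties break on the TCR's own sequences and id (so the result is
    invariant to input order); the seed only resolves exact residual ties
    between indistinguishable entries.  Returns indices into `tcrs`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    m = len(tcrs)
    if m == 0:
        return []
    d = tcrdist_matrix(tcrs) if dist_matrix is None else np.asarray(dist_matrix, float)
    density = np.exp(-(d ** 2) / (2.0 * bandwidth ** 2)).sum(axis=1)
    rng = np.random.default_rng(seed)
    tiebreak = rng.permutation(m)
    order = sorted(
        range(m),
        key=lambda i: (
            -density[i],
            tcrs[i].alpha.cdr3,
            tcrs[i].beta.cdr3,
            tcrs[i].id,
            tiebreak[i],
        ),
    )
    selected: list[int] = []
    for i in order:
        if len(selected) >= n:
            break
        if all(d[i, j] > min_dist for j in selected):
            selected.append(i)
    return selected


def average_linkage_newick(tcrs, labels=None) -> str:
    """Average-linkage tree over the paired distance matrix, as newick text."""
    from scipy.cluster.hierarchy import average, to_tree
    from scipy.spatial.distance import squareform

    if labels is None:
        labels = [t.id or f"tcr{i}" for i, t in enumerate(tcrs)]
    if len(tcrs) < 2:
        return f"({labels[0]});" if tcrs else ";"
    z = average(squareform(tcrdist_matrix(tcrs), checks=False))
    root = to_tree(z)

    def render(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = node.get_left(), node.get_right()
        lb = max(node.dist - left.dist, 0.0)
        rb = max(node.dist - right.dist, 0.0)
        return f"({render(left)}:{lb:.6g},{render(right)}:{rb:.6g})"

    return render(root) + ";"
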