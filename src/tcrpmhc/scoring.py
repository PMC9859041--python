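"""Epitope-specificity scoring from predicted-aligned-error (PAE) matrices.

A structure predictor run on every (TCR, peptide) pairing yields an N x P
matrix of mean interface PAE values (rows = TCRs, columns = peptides, one of
which is the wild type).  Raw interface PAE carries strong TCR-intrinsic and
pMHC-intrinsic offsets; the binding-score correction removes both:

    B[i, j] = (PAE[i, j] - bg[j]) - mean_j(PAE[i, .] - bg[.])

where bg[j] is the mean interface PAE of peptide j docked against a panel of
irrelevant background TCRs.  Every row of B has mean zero; lower scores mean
stronger predicted binding.  Downstream: per-TCR rank of the wild-type
peptide, repertoire-averaged per-peptide scores, ROC analysis of binder vs
decoy recovery, alanine-scan deltas, and MHC-binder decoy selection through a
pluggable peptide-scoring predictor.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "PaeMatrix",
    "BackgroundMeans",
    "BindingScoreMatrix",
    "mean_interface_pae",
    "select_best_model",
    "binding_scores",
    "wt_rank",
    "repertoire_scores",
    "auroc",
    "alanine_scan_peptides",
    "scan_deltas",
    "select_decoys",
    "MockBindingPredictor",
]


@dataclass(frozen=True)
class PaeMatrix:
    """N x P mean interface PAE values for N TCRs against P peptides."""

    values: np.ndarray
    tcr_ids: tuple
    peptides: tuple
    wt_index: int

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.ndim != 2:
            raise ValueError("PAE values must be a 2-D matrix")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("PAE values must be finite and non-negative")
        n, p = v.shape
        if len(self.tcr_ids) != n or len(self.peptides) != p:
            raise ValueError("label counts do not match matrix shape")
        if not (0 <= self.wt_index < p):
            raise ValueError("wt_index out of range")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "tcr_ids", tuple(self.tcr_ids))
        object.__setattr__(self, "peptides", tuple(self.peptides))


@dataclass(frozen=True)
class BackgroundMeans:
    """Per-peptide mean interface PAE over a panel of irrelevant TCRs."""

    values: np.ndarray
    n_background: int

    def __post_init__(self):
        v = np.asarray(self.values, float).ravel()
        if self.n_background < 1:
            raise ValueError("n_background must be >= 1")
        if not np.all(np.isfinite(v)):
            raise ValueError("background means must be finite")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class BindingScoreMatrix:
    """Corrected binding scores; every row mean is zero, lower = stronger."""

    values: np.ndarray
    tcr_ids: tuple = ()
    peptides: tuple = ()
    wt_index: int = 0
    derivation: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.ndim != 2:
            raise ValueError("binding scores must be a 2-D matrix")
        if np.abs(v.mean(axis=1)).max() > 1e-9:
            raise ValueError("binding-score rows must have zero mean")
        object.__setattr__(self, "values", v)


def mean_interface_pae(pae_full: np.ndarray, tcr_span, pmhc_span) -> float:
    """Mean PAE over all TCR:pMHC residue pairs, pooling both directions.

    Spans are half-open (start, stop) residue index ranges into the square
    per-residue PAE matrix and must not overlap.  Both orderings (i, j) and
    (j, i) of each inter-chain pair enter the mean, since PAE is asymmetric.
    """
    m = np.asarray(pae_full, float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("pae_full must be square")
    ts, te = tcr_span
    ps, pe = pmhc_span
    if not (0 <= ts < te <= m.shape[0] and 0 <= ps < pe <= m.shape[0]):
        raise ValueError("spans out of range")
    if max(ts, ps) < min(te, pe):
        raise ValueError("tcr_span and pmhc_span overlap")
    block_a = m[ts:te, ps:pe]
    block_b = m[ps:pe, ts:te]
    return float((block_a.sum() + block_b.sum()) / (block_a.size + block_b.size))


def select_best_model(interface_paes, models=None):
    """Pick the model with the lowest interface PAE; ties go to the lowest index."""
    paes = np.asarray(interface_paes, float)
    if paes.ndim != 1 or len(paes) == 0:
        raise ValueError("need a 1-D sequence of interface PAEs")
    idx = int(np.argmin(paes))  # argmin returns the first minimum
    return idx if models is None else models[idx]


def binding_scores(pae: PaeMatrix, bg: BackgroundMeans) -> BindingScoreMatrix:
    """Background-subtract per peptide, then center each TCR row at zero.

    Invariant to any per-row constant added to the PAE matrix and to any
    per-column constant added simultaneously to the PAE matrix and the
    background means.
    """
    if bg.values.shape[0] != pae.values.shape[1]:
        raise ValueError("background length does not match peptide count")
    adjusted = pae.values - bg.values[None, :]
    b = adjusted - adjusted.mean(axis=1, keepdims=True)
    return BindingScoreMatrix(
        values=b,
        tcr_ids=pae.tcr_ids,
        peptides=pae.peptides,
        wt_index=pae.wt_index,
        derivation={"n_background": bg.n_background},
    )


def wt_rank(row: np.ndarray, wt_index: int) -> int:
    """Rank of the wild-type score within a row: number of strictly better peptides.

    0 means the wild type has the (strictly) best score; ties do not count
    against the wild type.  Invariant under strictly monotone transforms.
    """
    row = np.asarray(row, float)
    return int(np.sum(row < row[wt_index]))


def repertoire_scores(b: BindingScoreMatrix, rows=None) -> np.ndarray:
    """Per-peptide mean binding score over a repertoire (or a row subset)."""
    v = b.values if rows is None else b.values[np.asarray(rows, int)]
    if v.shape[0] == 0:
        raise ValueError("empty row subset")
    return v.mean(axis=0)


def auroc(scores, labels) -> float:
    """Probability a random binder scores below a random decoy (ties count 1/2).

    `labels` is a boolean array, True for binders; lower score = predicted
    binder.  Equals the normalized Wilcoxon-Mann-Whitney statistic.
    """
    labels = np.asarray(labels, bool)
    scores = np.asarray(scores, float)
    if labels.all() or not labels.any():
        raise ValueError("need both binders and decoys")
    return float(roc_auc_score(labels, -scores))


def alanine_scan_peptides(wt: str) -> list[tuple[int, str]]:
    """All single-position alanine mutants of a peptide (alanine -> glycine).

    Returns (position, mutant) for every position, so an L-residue peptide
    yields L mutants, none identical to the wild type.
    """
    if not wt:
        raise ValueError("empty peptide")
    out = []
    for i, aa in enumerate(wt):
        sub = "G" if aa == "A" else "A"
        out.append((i, wt[:i] + sub + wt[i + 1:]))
    return out


def scan_deltas(rep_scores: np.ndarray, wt_index: int = 0) -> np.ndarray:
    """Mutant-minus-wild-type repertoire score deltas, in column order.

    Positive delta = the mutation is predicted to weaken recognition at that
    position.
    """
    rep_scores = np.asarray(rep_scores, float)
    deltas = np.delete(rep_scores, wt_index) - rep_scores[wt_index]
    return deltas


class MockBindingPredictor:
    """Deterministic hash-based stand-in for an MHC binding predictor.

    Maps a peptide to a pseudo-score in [0, 1), lower = better predicted
    binder.  Purely synthetic: scores carry no biochemical meaning, but they
    are reproducible across runs and platforms, which is what the decoy
    selection tests need.
    """

    def __init__(self, allele: str = "SYN-A*01:01"):
        self.allele = allele

    def __call__(self, peptide: str) -> float:
        digest = hashlib.sha256(f"{self.allele}|{peptide}".encode()).digest()
        return int.from_bytes(digest[:8], "big") / 2 ** 64


def select_decoys(
    antigens,
    predictor,
    length: int,
    k: int = 9,
    pool_len: int = 1500,
    seed: int = 0,
    exclude=(),
) -> list[str]:
    """Select k decoy peptides from a shuffled artificial source antigen.

    The antigen sequences are concatenated, character-shuffled with the given
    seed, and truncated to pool_len residues; every length-mer is scored with
    the predictor (a callable peptide -> score, lower = better binder) and the
    top k unique peptides are returned best-first, excluding any peptide in
    `exclude` (e.g. the wild-type epitopes).
    """
    concat = "".join(antigens)
    if len(concat) < pool_len:
        raise ValueError(f"concatenated antigens shorter than pool_len ({len(concat)} < {pool_len})")
    rng = np.random.default_rng(seed)
    chars = np.array(list(concat))
    pool = "".join(chars[rng.permutation(len(chars))][:pool_len])
    excluded = set(exclude)
    seen = {}
    for i in range(pool_len - length + 1):
        kmer = pool[i: i + length]
        if kmer in excluded or kmer in seen:
            continue
        seen[kmer] = predictor(kmer)
    ranked = sorted(seen.items(), key=lambda kv: (kv[1], kv[0]))
    if len(ranked) < k:
        raise ValueError(f"only {len(ranked)} unique candidate peptides, need {k}")
    return [pep for pep, _ in ranked[:k]]
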