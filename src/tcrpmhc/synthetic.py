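"""Synthetic ternary complexes, PAE matrices, and repertoires.

This module generates the study inputs that would otherwise require PDB
downloads and a GPU-scale structure predictor:

* idealized CA-trace ternary complexes with a *prescribed* docking geometry --
  the MHC beta-sheet core is built as two exactly C2-related half-sheets (so
  the computed MHC frame is the identity frame by construction), the peptide
  lies on the +x side, and the TCR construct (two C2-related 13-residue cores
  plus eight CDR loops on its +x side) is placed by the rigid transform the
  requested geometry implies;
* synthetic PAE matrices with planted TCR-intrinsic and pMHC-intrinsic
  offsets plus a cognate-pair binding signal, emulating the systematic
  per-TCR and per-pMHC trends seen in predictor confidence outputs;
* synthetic paired-TCR repertoires sampled around seed sequences.

Residue spacing is a generic 3.8 Angstrom CA-CA distance on idealized grids
and helices; no attempt is made at physically realistic protein geometry,
which is adequate because all in-scope computation uses CA coordinates only.
All randomness flows from one seeded generator per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import DockingGeometry, geometry_to_transform, _rotation_about_axis
from .scoring import BackgroundMeans, PaeMatrix
from .structure import (
    ChainAnnotation,
    Residue,
    TernaryComplex,
    load_core_profiles,
)
from .tcrdist import PairedTcr, TcrChainSeq, load_v_gene_table
from .rmsd import GenericCdrComs

__all__ = [
    "SyntheticSpec",
    "PaeSimSpec",
    "consensus_geometry",
    "random_docking_geometry",
    "make_synthetic_complex",
    "make_synthetic_pae",
    "make_synthetic_repertoire",
    "random_synthetic_specs",
    "canonical_generic_coms",
    "build_tcr_chain",
    "DEFAULT_CHAIN_MAP",
    "AA_ALPHABET",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
DEFAULT_CHAIN_MAP = {"mhc": "A", "peptide": "C", "tcra": "D", "tcrb": "E"}

# --- canonical chain layouts ------------------------------------------------
# frameworks are fixed; CDR loops come from the V-gene table / the CDR3 given,
# so core indices found by alignment stay correct for any gene combination
_FRAMEWORKS = {
    "alpha": ("GQSVTQ", "WYRQDP", "KGLT", "DRFSVE", "FGKGT"),
    "beta": ("DAGVTQ", "WYRQDT", "KGEV", "NRFSAE", "FGEGS"),
}
# core positions as (framework segment, offset-within-segment)
_CORE_SLOTS = [(0, 1), (0, 2), (0, 3), (0, 4), (1, 1), (1, 2), (1, 3), (1, 4),
               (3, 1), (3, 2), (3, 3), (4, 1), (4, 2)]

_CANONICAL_GENES = {"alpha": "TRAV-SYN1*01", "beta": "TRBV-SYN1*01"}
_X180 = _rotation_about_axis(np.array([1.0, 0.0, 0.0]), np.pi)


def build_tcr_chain(v_gene: str, cdr3: str, chain: str, table=None):
    """Assemble a full synthetic TCR chain sequence.

    Returns (sequence, spans) where spans maps cdr1/cdr2/cdr25/cdr3 to
    half-open index ranges, and core_indices, the 13 framework core positions.
    """
    table = table or load_v_gene_table()
    loops = table[chain][v_gene]
    fw = _FRAMEWORKS[chain]
    segments = [fw[0], loops["cdr1"], fw[1], loops["cdr2"], fw[2], loops["cdr25"],
                fw[3], cdr3, fw[4]]
    starts = np.concatenate([[0], np.cumsum([len(s) for s in segments])])
    seq = "".join(segments)
    spans = {
        "cdr1": (int(starts[1]), int(starts[2])),
        "cdr2": (int(starts[3]), int(starts[4])),
        "cdr25": (int(starts[5]), int(starts[6])),
        "cdr3": (int(starts[7]), int(starts[8])),
    }
    fw_starts = {0: starts[0], 1: starts[2], 2: starts[4], 3: starts[6], 4: starts[8]}
    cores = tuple(int(fw_starts[seg] + off) for seg, off in _CORE_SLOTS)
    return seq, spans, cores


def _centered(offsets: np.ndarray, center: np.ndarray) -> np.ndarray:
    offsets = np.asarray(offsets, float)
    return offsets - offsets.mean(axis=0) + np.asarray(center, float)


# fixed, non-degenerate point patterns for the symmetric cores
_MHC_HALF_OFFSETS = np.array([
    [-1.5, -3.5, -1.2], [0.8, -2.1, 0.9], [-0.6, -0.2, -0.8],
    [1.4, 1.3, 1.1], [-1.2, 2.6, -0.5], [1.1, 3.9, 0.5],
])
_TCR_HALF_OFFSETS = np.array([
    [-1.8, -4.6, -1.0], [0.9, -3.8, 0.8], [-0.7, -2.9, -0.6], [1.5, -1.9, 1.1],
    [-1.1, -0.9, -0.9], [0.6, 0.0, 0.7], [-1.4, 0.9, -0.4], [1.2, 1.9, 0.9],
    [-0.5, 2.8, -1.1], [1.0, 3.7, 0.4], [-1.6, 4.5, 0.2], [0.4, 5.2, -0.7],
    [-0.9, 5.8, 1.0],
])
_MHC_HALF_SEP = 8.0   # half-sheet COM offset from the frame origin, Angstrom
_TCR_HALF_SEP = 9.0


def _helix(n: int, y0: float, z0: float) -> np.ndarray:
    """Generic filler helix with ~3.8 A CA spacing, off the binding face."""
    t = np.arange(n, dtype=float)
    return np.column_stack([
        -8.0 + 2.3 * np.cos(1.7 * t),
        y0 + 1.5 * t,
        z0 + 2.3 * np.sin(1.7 * t),
    ])


def consensus_geometry() -> DockingGeometry:
    """A canonical diagonal-docking-mode geometry used as simulation center."""
    return DockingGeometry.from_vector(
        np.array([28.0, 1.2, 0.35, 0.6, 0.40, -0.8])
    )


def random_docking_geometry(rng: np.random.Generator, spread: float = 1.0) -> DockingGeometry:
    """Sample a docking geometry around the consensus mode.

    Distances and angles are drawn from normal distributions centered on the
    consensus 6-vector; polar angles are kept in a (0.05, 1.4) rad band so the
    direction vectors stay away from the parameterization poles, emulating
    the concentration of natural binding modes around the diagonal consensus.
    """
    center = consensus_geometry().as_vector()
    sd = spread * np.array([3.0, 0.5, 0.15, 0.5, 0.15, 0.5])
    v = rng.normal(center, sd)
    v[0] = np.clip(v[0], 18.0, 45.0)
    v[2] = np.clip(v[2], 0.05, 1.4)
    v[4] = np.clip(v[4], 0.05, 1.4)
    return DockingGeometry.from_vector(v)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic ternary complex."""

    geometry: DockingGeometry = field(default_factory=consensus_geometry)
    coordinate_noise: float = 0.0
    peptide: str = "GILGFVFTL"
    va: str = "TRAV-SYN1*01"
    ja: str = "TRAJ-SYN1*01"
    vb: str = "TRBV-SYN1*01"
    jb: str = "TRBJ-SYN1*01"
    cdr3a: str = "CAVSDLEPNSSYK"
    cdr3b: str = "CASSIRSSYEQYF"
    mhc_class: int = 1
    mhc_allele: str = "SYN-A*01:01"
    organism: str = "synthetic"
    pdb_id: str = "SYN1"
    deposit_date: str = "2020-01-01"
    seed: int = 0

    def __post_init__(self):
        if self.coordinate_noise < 0:
            raise ValueError("coordinate noise must be >= 0")


def _loop_points(spans: dict, chain_sign: float) -> dict:
    """CDR loop CA coordinates on the +x (CDR) face of the TCR construct."""
    out = {}
    for k, loop in enumerate(("cdr1", "cdr2", "cdr25", "cdr3")):
        s, e = spans[loop]
        n = e - s
        j = np.arange(n, dtype=float)
        out[loop] = np.column_stack([
            6.5 + 1.2 * k + 0.6 * (j % 2),
            (k - 1.5) * 4.2 + (j - (n - 1) / 2.0) * 1.6,
            chain_sign * 4.5 + 0.3 * (j % 3),
        ])
    return out


def _build_tcr_construct(spec: SyntheticSpec, table):
    """TCR alpha/beta chains in the TCR local frame (frame == identity)."""
    chains = {}
    spans_by_chain = {}
    for chain, sign, cdr3, v_gene in (
        ("alpha", -1.0, spec.cdr3a, spec.va),
        ("beta", 1.0, spec.cdr3b, spec.vb),
    ):
        seq, spans, cores = build_tcr_chain(v_gene, cdr3, chain, table)
        half = _centered(_TCR_HALF_OFFSETS, [0.0, 0.0, -_TCR_HALF_SEP])
        if chain == "beta":
            half = half @ _X180.T
        coords = np.zeros((len(seq), 3))
        placed = np.zeros(len(seq), bool)
        for pt, idx in zip(half, cores):
            coords[idx] = pt
            placed[idx] = True
        for loop, pts in _loop_points(spans, sign).items():
            s, e = spans[loop]
            coords[s:e] = pts
            placed[s:e] = True
        filler_idx = np.flatnonzero(~placed)
        filler = _helix(len(filler_idx), y0=-10.0, z0=sign * _TCR_HALF_SEP)
        coords[filler_idx] = filler
        chains[chain] = (seq, coords)
        spans_by_chain[chain] = spans
    return chains, spans_by_chain


def make_synthetic_complex(spec: SyntheticSpec) -> TernaryComplex:
    """Generate an idealized ternary complex realizing spec.geometry.

    At zero coordinate noise the docking geometry recovered by parsing the
    complex, locating cores, and building frames equals spec.geometry to
    numerical precision.  A fixed seed gives bit-identical coordinates.
    """
    profiles = load_core_profiles()
    prof = profiles[spec.mhc_class]
    table = load_v_gene_table()
    rng = np.random.default_rng(spec.seed)

    # --- MHC construct in the MHC local frame (== global frame) ---
    mhc_seq = prof.mhc_sequence
    n_half = _centered(_MHC_HALF_OFFSETS, [0.0, 0.0, -_MHC_HALF_SEP])
    c_half = n_half @ _X180.T
    mhc_coords = np.zeros((len(mhc_seq), 3))
    placed = np.zeros(len(mhc_seq), bool)
    for pt, idx in zip(n_half, prof.mhc_n_half):
        mhc_coords[idx] = pt
        placed[idx] = True
    for pt, idx in zip(c_half, prof.mhc_c_half):
        mhc_coords[idx] = pt
        placed[idx] = True
    filler_idx = np.flatnonzero(~placed)
    mhc_coords[filler_idx] = _helix(len(filler_idx), y0=-27.0, z0=0.0)

    lp = len(spec.peptide)
    pep_coords = np.column_stack([
        np.full(lp, 6.5),
        (np.arange(lp) - (lp - 1) / 2.0) * 3.2,
        0.4 * (-1.0) ** np.arange(lp),
    ])

    # --- TCR construct placed by the requested geometry ---
    tcr_chains, spans_by_chain = _build_tcr_construct(spec, table)
    t = geometry_to_transform(spec.geometry)
    coords = {
        "mhc": mhc_coords,
        "peptide": pep_coords,
        "tcra": t.apply(tcr_chains["alpha"][1]),
        "tcrb": t.apply(tcr_chains["beta"][1]),
    }
    seqs = {
        "mhc": mhc_seq,
        "peptide": spec.peptide,
        "tcra": tcr_chains["alpha"][0],
        "tcrb": tcr_chains["beta"][0],
    }
    if spec.coordinate_noise > 0:
        for role in coords:
            coords[role] = coords[role] + rng.normal(
                0.0, spec.coordinate_noise, coords[role].shape
            )

    # steric sanity: the requested geometry must not drive roles into each other
    roles = list(coords)
    for i, ra in enumerate(roles):
        for rb in roles[i + 1:]:
            diff = coords[ra][:, None, :] - coords[rb][None, :, :]
            if np.sqrt((diff ** 2).sum(axis=2)).min() < 1.0:
                raise ValueError(
                    f"geometry places roles {ra!r} and {rb!r} closer than 1 Angstrom"
                )

    cdr_spans = {}
    for chain, tag in (("alpha", "a"), ("beta", "b")):
        for loop, span in spans_by_chain[chain].items():
            cdr_spans[f"{loop}{tag}"] = span
    annotation = ChainAnnotation(
        organism=spec.organism,
        mhc_class=spec.mhc_class,
        mhc_allele=spec.mhc_allele,
        peptide=spec.peptide,
        va=spec.va, ja=spec.ja, vb=spec.vb, jb=spec.jb,
        cdr3a=spec.cdr3a, cdr3b=spec.cdr3b,
        cdr_spans=cdr_spans,
    )
    chains = {}
    for role in ("mhc", "peptide", "tcra", "tcrb"):
        label = DEFAULT_CHAIN_MAP[role]
        chains[role] = [
            Residue(chain_id=label, seq_index=i, aa=aa, ca_xyz=xyz)
            for i, (aa, xyz) in enumerate(zip(seqs[role], coords[role]))
        ]
    return TernaryComplex(chains, annotation, pdb_id=spec.pdb_id,
                          deposit_date=spec.deposit_date)


def canonical_generic_coms() -> GenericCdrComs:
    """Generic CDR centers of mass of the canonical construct, in TCR-frame coords.

    Lets docking-RMSD computation run without a structure database.
    """
    table = load_v_gene_table()
    pts = np.zeros((8, 3))
    slot = 0
    for chain, sign, cdr3 in (
        ("alpha", -1.0, "CAVSDLEPNSSYK"),
        ("beta", 1.0, "CASSIRSSYEQYF"),
    ):
        _, spans, _ = build_tcr_chain(_CANONICAL_GENES[chain], cdr3, chain, table)
        loop_pts = _loop_points(spans, sign)
        for loop in ("cdr1", "cdr2", "cdr25", "cdr3"):
            pts[slot] = loop_pts[loop].mean(axis=0)
            slot += 1
    return GenericCdrComs(points=pts, n_source_structures=1)


def random_synthetic_specs(rng: np.random.Generator, n: int) -> list["SyntheticSpec"]:
    """Random complex recipes: varied peptides, V genes, CDR3s, geometries."""
    table = load_v_gene_table()
    alphas = sorted(table["alpha"])
    betas = sorted(table["beta"])
    specs = []
    for i in range(n):
        pep_len = int(rng.choice([9, 10]))
        peptide = "".join(AA_ALPHABET[j] for j in rng.integers(0, 20, pep_len))
        cdr3a = "CA" + "".join(
            AA_ALPHABET[j] for j in rng.integers(0, 20, rng.integers(7, 12))
        ) + "F"
        cdr3b = "CAS" + "".join(
            AA_ALPHABET[j] for j in rng.integers(0, 20, rng.integers(7, 12))
        ) + "F"
        specs.append(SyntheticSpec(
            geometry=random_docking_geometry(rng),
            peptide=peptide,
            va=str(rng.choice(alphas)), vb=str(rng.choice(betas)),
            cdr3a=cdr3a, cdr3b=cdr3b,
            pdb_id=f"syn{i:03d}",
            deposit_date=f"20{10 + i % 10:02d}-0{1 + i % 9}-01",
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        ))
    return specs


@dataclass(frozen=True)
class PaeSimSpec:
    """Recipe for a synthetic interface-PAE matrix with planted effects."""

    n_tcrs: int = 50
    n_peptides: int = 10
    base_pae: float = 15.0
    tcr_effect_sd: float = 1.5
    peptide_effect_sd: float = 1.0
    binder_signal: float = 3.0  # PAE reduction for cognate pairs
    noise: float = 1.0
    n_background: int = 50
    wt_index: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if not (0 <= self.wt_index < self.n_peptides):
            raise ValueError("wt_index out of range")


def make_synthetic_pae(spec: PaeSimSpec):
    """Simulate PAE = base + tau_i + pi_j - beta*[cognate] + noise.

    Every TCR is cognate to the wild-type peptide column.  Background means
    are generated from the same per-peptide effects pi_j over n_background
    irrelevant TCRs (fresh tau and noise, no binder signal).  Returns
    (PaeMatrix, BackgroundMeans, cognate mask).
    """
    rng = np.random.default_rng(spec.seed)
    tau = rng.normal(0.0, spec.tcr_effect_sd, spec.n_tcrs)
    pi = rng.normal(0.0, spec.peptide_effect_sd, spec.n_peptides)
    cognate = np.zeros((spec.n_tcrs, spec.n_peptides), bool)
    cognate[:, spec.wt_index] = True
    pae = (
        spec.base_pae
        + tau[:, None]
        + pi[None, :]
        - spec.binder_signal * cognate
        + rng.normal(0.0, spec.noise, (spec.n_tcrs, spec.n_peptides))
    )
    bg_tau = rng.normal(0.0, spec.tcr_effect_sd, spec.n_background)
    bg_rows = (
        spec.base_pae
        + bg_tau[:, None]
        + pi[None, :]
        + rng.normal(0.0, spec.noise, (spec.n_background, spec.n_peptides))
    )
    peptides = tuple(f"pep{j}" if j != spec.wt_index else "WT" for j in range(spec.n_peptides))
    pae_matrix = PaeMatrix(
        values=np.clip(pae, 0.0, None) if pae.min() < 0 else pae,
        tcr_ids=tuple(f"tcr{i}" for i in range(spec.n_tcrs)),
        peptides=peptides,
        wt_index=spec.wt_index,
    )
    bg = BackgroundMeans(values=bg_rows.mean(axis=0), n_background=spec.n_background)
    return pae_matrix, bg, cognate


def make_synthetic_repertoire(
    n: int,
    cluster_centers,
    spread: float = 0.05,
    seed: int = 0,
    weights=None,
) -> list[PairedTcr]:
    """Sample paired TCRs around center sequences.

    Each draw picks a center (probability proportional to `weights`, uniform
    by default) and mutates every CDR3 position independently with
    probability `spread`; germline loops (V genes) are inherited unchanged.
    """
    rng = np.random.default_rng(seed)
    centers = list(cluster_centers)
    if weights is None:
        w = np.ones(len(centers)) / len(centers)
    else:
        w = np.asarray(weights, float)
        w = w / w.sum()

    def mutate(s: str) -> str:
        out = list(s)
        for i in range(len(out)):
            if rng.random() < spread:
                out[i] = AA_ALPHABET[rng.integers(0, len(AA_ALPHABET))]
        return "".join(out)

    out = []
    for i in range(n):
        c = centers[int(rng.choice(len(centers), p=w))]
        alpha = replace(c.alpha, cdr3=mutate(c.alpha.cdr3))
        beta = replace(c.beta, cdr3=mutate(c.beta.cdr3))
        out.append(PairedTcr(alpha=alpha, beta=beta, id=f"tcr{i:04d}"))
    return out
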