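"""Ternary TCR:peptide-MHC complex structures: parsing, annotation, core residues.

A ternary complex holds the alpha-carbon trace of an MHC (optionally with
beta-2 microglobulin), the bound peptide, and the TCR alpha and beta chains,
together with a sequence-level annotation (organism, MHC allele, V/J genes,
CDR loop spans).  All internal indexing is 0-based and half-open; author
residue numbering exists only at the PDB I/O boundary.

Conserved "core" residues -- 6+6 in the MHC beta-sheet floor, 13 in each TCR
variable domain -- anchor the coordinate-frame construction in
:mod:`tcrpmhc.geometry`.  Their positions in a new structure are found by
mapping shipped reference index sets through a BLOSUM62 global alignment of
the target chain sequence to a reference sequence.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import gemmi
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "Residue",
    "ChainAnnotation",
    "TernaryComplex",
    "CoreResidueSet",
    "CoreProfile",
    "load_core_profiles",
    "read_ternary_pdb",
    "write_pdb",
    "locate_core_residues",
    "peptide_mismatches",
    "align_and_map",
    "CDR_LOOPS",
]

AA1 = "ACDEFGHIKLMNPQRSTVWY"
ROLE_ORDER = ("mhc", "b2m", "peptide", "tcra", "tcrb")
#: loop labels; the 'a'/'b' suffix names the TCR chain the span indexes into
CDR_LOOPS = ("cdr1a", "cdr2a", "cdr25a", "cdr3a", "cdr1b", "cdr2b", "cdr25b", "cdr3b")


@dataclass(frozen=True)
class Residue:
    chain_id: str
    seq_index: int
    aa: str
    ca_xyz: np.ndarray
    backbone_xyz: dict | None = None  # optional N/C/O positions

    def __post_init__(self):
        xyz = np.asarray(self.ca_xyz, float).reshape(3)
        if not np.all(np.isfinite(xyz)):
            raise ValueError(f"non-finite CA coordinate at {self.chain_id}:{self.seq_index}")
        if self.aa not in AA1 and self.aa != "X":
            raise ValueError(f"unknown amino acid {self.aa!r}")
        object.__setattr__(self, "ca_xyz", xyz)


@dataclass(frozen=True)
class ChainAnnotation:
    organism: str
    mhc_class: int
    mhc_allele: str
    peptide: str
    va: str
    ja: str
    vb: str
    jb: str
    cdr3a: str
    cdr3b: str
    cdr_spans: dict  # loop label -> (start, stop), half-open, 0-based in-chain

    def __post_init__(self):
        if self.mhc_class not in (1, 2):
            raise ValueError("mhc_class must be 1 or 2")
        if not (8 <= len(self.peptide) <= 13):
            raise ValueError(f"peptide length {len(self.peptide)} outside 8-13")
        if not self.cdr3a or not self.cdr3b:
            raise ValueError("cdr3a and cdr3b must be non-empty")
        missing = [k for k in CDR_LOOPS if k not in self.cdr_spans]
        if missing:
            raise ValueError(f"cdr_spans missing loops: {missing}")
        for chain_tag in ("a", "b"):
            spans = sorted(
                self.cdr_spans[k] for k in CDR_LOOPS if k.endswith(chain_tag)
            )
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise ValueError("overlapping CDR spans")
            for s, e in spans:
                if s < 0 or e <= s:
                    raise ValueError(f"invalid CDR span ({s}, {e})")

    def loops_for(self, role: str):
        tag = "a" if role == "tcra" else "b"
        return [k for k in CDR_LOOPS if k.endswith(tag)]


@dataclass
class TernaryComplex:
    """Annotated CA trace of one TCR:peptide-MHC ternary complex."""

    chains: dict  # role -> list[Residue]
    annotation: ChainAnnotation
    pdb_id: str = ""
    deposit_date: str = ""

    def __post_init__(self):
        for role in ("mhc", "peptide", "tcra", "tcrb"):
            if role not in self.chains or not self.chains[role]:
                raise ValueError(f"missing required chain for role {role!r}")
        for role, loops in (("tcra", "a"), ("tcrb", "b")):
            n = len(self.chains[role])
            for loop in self.annotation.loops_for(role):
                s, e = self.annotation.cdr_spans[loop]
                if e > n:
                    raise ValueError(f"CDR span {loop} {s, e} outside chain of length {n}")

    def chain(self, role: str):
        return self.chains[role]

    def sequence(self, role: str) -> str:
        return "".join(r.aa for r in self.chains[role])

    def ca_array(self, role: str) -> np.ndarray:
        return np.array([r.ca_xyz for r in self.chains[role]])

    def roles(self):
        return [r for r in ROLE_ORDER if r in self.chains and self.chains[r]]

    def transformed(self, t) -> "TernaryComplex":
        """Copy with all coordinates moved by a rigid transform."""
        new = {
            role: [
                Residue(r.chain_id, r.seq_index, r.aa, t.apply(r.ca_xyz))
                for r in residues
            ]
            for role, residues in self.chains.items()
        }
        return TernaryComplex(new, self.annotation, self.pdb_id, self.deposit_date)


@dataclass(frozen=True)
class CoreResidueSet:
    """Conserved core residue indices (0-based, per chain)."""

    mhc_n_half: tuple
    mhc_c_half: tuple
    tcra_core: tuple
    tcrb_core: tuple

    def __post_init__(self):
        if len(self.mhc_n_half) != 6 or len(self.mhc_c_half) != 6:
            raise ValueError("MHC halves must each hold 6 indices")
        if len(self.tcra_core) != 13 or len(self.tcrb_core) != 13:
            raise ValueError("TCR cores must each hold 13 indices")
        for idx in (*self.mhc_n_half, *self.mhc_c_half, *self.tcra_core, *self.tcrb_core):
            if idx < 0:
                raise ValueError("negative core index")
        object.__setattr__(self, "mhc_n_half", tuple(self.mhc_n_half))
        object.__setattr__(self, "mhc_c_half", tuple(self.mhc_c_half))
        object.__setattr__(self, "tcra_core", tuple(self.tcra_core))
        object.__setattr__(self, "tcrb_core", tuple(self.tcrb_core))


@dataclass(frozen=True)
class CoreProfile:
    """Reference sequences and core index sets for one MHC class.

    Shipped profiles are synthetic: they describe the idealized complexes the
    fixture generator emits, not crystallographic consensus numbering.  Real
    reference tables drop in as data-only replacements.
    """

    mhc_class: int
    mhc_sequence: str
    mhc_n_half: tuple
    mhc_c_half: tuple
    tcra_sequence: str
    tcra_core: tuple
    tcrb_sequence: str
    tcrb_core: tuple


def load_core_profiles() -> dict:
    """Load the shipped per-MHC-class reference core profiles."""
    text = resources.files("tcrpmhc.data").joinpath("core_profiles.json").read_text()
    raw = json.loads(text)
    out = {}
    for key, p in raw.items():
        if key.startswith("_"):
            continue
        out[int(key)] = CoreProfile(
            mhc_class=int(key),
            mhc_sequence=p["mhc_sequence"],
            mhc_n_half=tuple(p["mhc_n_half"]),
            mhc_c_half=tuple(p["mhc_c_half"]),
            tcra_sequence=p["tcra_sequence"],
            tcra_core=tuple(p["tcra_core"]),
            tcrb_sequence=p["tcrb_sequence"],
            tcrb_core=tuple(p["tcrb_core"]),
        )
    return out


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def align_and_map(target_seq: str, ref_seq: str) -> dict:
    """Global BLOSUM62 alignment; returns {ref_index: target_index} over aligned columns."""
    aligner = _make_aligner()
    aln = aligner.align(target_seq, ref_seq)[0]
    mapping = {}
    for (t_start, t_end), (r_start, r_end) in zip(*aln.aligned):
        for offset in range(t_end - t_start):
            mapping[r_start + offset] = t_start + offset
    return mapping


def locate_core_residues(complex: TernaryComplex, profiles: dict | None = None) -> CoreResidueSet:
    """Map the shipped reference core indices onto a target complex.

    Each chain (MHC, TCR alpha, TCR beta) is globally aligned to the matching
    reference sequence for the complex's MHC class; core indices are carried
    through the alignment.  Raises if any core position lands on a gap.
    """
    if profiles is None:
        profiles = load_core_profiles()
    try:
        prof = profiles[complex.annotation.mhc_class]
    except KeyError:
        raise ValueError(f"no core profile for MHC class {complex.annotation.mhc_class}")

    def map_indices(role, ref_seq, indices):
        mapping = align_and_map(complex.sequence(role), ref_seq)
        missing = [i for i in indices if i not in mapping]
        if missing:
            raise ValueError(
                f"core positions unmapped in {role} alignment: {sorted(missing)}"
            )
        return tuple(mapping[i] for i in indices)

    return CoreResidueSet(
        mhc_n_half=map_indices("mhc", prof.mhc_sequence, prof.mhc_n_half),
        mhc_c_half=map_indices("mhc", prof.mhc_sequence, prof.mhc_c_half),
        tcra_core=map_indices("tcra", prof.tcra_sequence, prof.tcra_core),
        tcrb_core=map_indices("tcrb", prof.tcrb_sequence, prof.tcrb_core),
    )


def peptide_mismatches(p1: str, p2: str) -> float:
    """Hamming distance for equal-length peptides; +inf if lengths differ.

    The infinite sentinel makes cross-length pairs fail every "fewer than k
    mismatches" similarity test.
    """
    if len(p1) != len(p2):
        return math.inf
    return float(sum(a != b for a, b in zip(p1, p2)))


_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}
_AA1 = {v: k for k, v in _AA3.items()}


def read_ternary_pdb(path, annotation: ChainAnnotation, chain_map: dict,
                     pdb_id: str = "", deposit_date: str = "") -> TernaryComplex:
    """Parse a ternary complex from a PDB file.

    chain_map maps roles (mhc, peptide, tcra, tcrb, optionally b2m) to chain
    labels in the file.  Residues are kept in author order; alternate CA
    locations resolve to the highest-occupancy conformer.
    """
    for role in ("mhc", "peptide", "tcra", "tcrb"):
        if role not in chain_map:
            raise ValueError(f"chain_map missing required role {role!r}")
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    model = st[0]
    by_name = {ch.name: ch for ch in model}
    chains = {}
    for role, label in chain_map.items():
        if label not in by_name:
            raise ValueError(f"chain {label!r} for role {role!r} not found in {path}")
        residues = []
        missing_ca = []
        for i, res in enumerate(by_name[label]):
            best = None
            for atom in res:
                if atom.name == "CA":
                    if best is None or atom.occ > best.occ:
                        best = atom
            if best is None:
                missing_ca.append(f"{label}:{res.seqid.num}{res.seqid.icode or ''}")
                continue
            aa = _AA1.get(res.name, "X")
            residues.append(
                Residue(
                    chain_id=label,
                    seq_index=len(residues),
                    aa=aa,
                    ca_xyz=np.array([best.pos.x, best.pos.y, best.pos.z]),
                )
            )
        if missing_ca:
            raise ValueError(
                f"residues without CA coordinates in role {role!r}: {missing_ca}"
            )
        chains[role] = residues
    return TernaryComplex(chains, annotation, pdb_id=pdb_id, deposit_date=deposit_date)


def _iter_pdb_chains(obj):
    """Yield (chain_label, residues) in canonical role order for any writable object."""
    default_labels = {"mhc": "A", "b2m": "B", "peptide": "C", "tcra": "D", "tcrb": "E"}
    chains = obj.chains if hasattr(obj, "chains") else obj
    for role in ROLE_ORDER:
        if role in chains and chains[role]:
            residues = chains[role]
            label = residues[0].chain_id or default_labels[role]
            yield label, residues


def write_pdb(complex_or_template, path) -> None:
    """Write CA-trace ATOM records, chains in mhc(,b2m),peptide,tcra,tcrb order.

    Round trip through read_ternary_pdb preserves coordinates to the PDB
    format precision of 0.001 Angstrom.
    """
    # hybrid templates carry a 'pmhc' role holding mhc+peptide residues split
    # by chain_id; normalize to the canonical role dict first
    if hasattr(complex_or_template, "as_role_chains"):
        chains = complex_or_template.as_role_chains()
    elif hasattr(complex_or_template, "chains"):
        chains = complex_or_template.chains
    else:
        chains = complex_or_template

    st = gemmi.Structure()
    st.name = getattr(complex_or_template, "pdb_id", "") or "complex"
    model = gemmi.Model("1")
    serial = 1
    used = set()
    default_labels = iter("ABCDEFGH")
    for role in ROLE_ORDER:
        if role not in chains or not chains[role]:
            continue
        residues = chains[role]
        label = residues[0].chain_id
        while not label or label in used:
            label = next(default_labels)
        used.add(label)
        ch = gemmi.Chain(label)
        for i, r in enumerate(residues):
            xyz = np.asarray(r.ca_xyz, float)
            if not np.all(np.isfinite(xyz)):
                raise ValueError(f"non-finite coordinate in role {role!r} residue {i}")
            res = gemmi.Residue()
            res.name = _AA3.get(r.aa, "UNK")
            res.seqid = gemmi.SeqId(i + 1, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            atom.serial = serial
            serial += 1
            res.add_atom(atom)
            ch.add_residue(res)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
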