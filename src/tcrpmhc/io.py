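"""TSV/JSON serialization for annotations, geometries, repertoires, and PAE data."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import DockingGeometry
from .scoring import BackgroundMeans, BindingScoreMatrix, PaeMatrix
from .structure import ChainAnnotation
from .tcrdist import PairedTcr, TcrChainSeq

__all__ = [
    "annotation_to_row",
    "annotation_from_row",
    "read_annotation_table",
    "write_annotation_table",
    "geometry_to_row",
    "geometry_from_row",
    "read_geometry_table",
    "write_geometry_table",
    "read_repertoire",
    "write_repertoire",
    "load_pae_json",
    "read_pae_table",
    "write_scores_table",
]

ANNOTATION_COLUMNS = [
    "pdbid", "organism", "mhc_class", "mhc", "peptide",
    "va", "ja", "cdr3a", "vb", "jb", "cdr3b", "chain_map", "deposit_date",
]
GEOMETRY_COLUMNS = [
    "pdbid", "mhc_class", "d", "torsion",
    "mhc_unit_x", "mhc_unit_y", "mhc_unit_z",
    "tcr_unit_x", "tcr_unit_y", "tcr_unit_z",
]


def _chain_map_to_str(chain_map: dict) -> str:
    return ",".join(f"{role}:{label}" for role, label in sorted(chain_map.items()))


def _chain_map_from_str(s: str) -> dict:
    out = {}
    for part in str(s).split(","):
        role, label = part.split(":")
        out[role.strip()] = label.strip()
    return out


def annotation_to_row(ann: ChainAnnotation, pdb_id: str, chain_map: dict,
                      deposit_date: str = "") -> dict:
    return {
        "pdbid": pdb_id,
        "organism": ann.organism,
        "mhc_class": ann.mhc_class,
        "mhc": ann.mhc_allele,
        "peptide": ann.peptide,
        "va": ann.va, "ja": ann.ja, "cdr3a": ann.cdr3a,
        "vb": ann.vb, "jb": ann.jb, "cdr3b": ann.cdr3b,
        "chain_map": _chain_map_to_str(chain_map),
        "deposit_date": deposit_date,
    }


def annotation_from_row(row, cdr_spans: dict) -> tuple[ChainAnnotation, dict]:
    """Rebuild (annotation, chain_map); CDR spans are layout-dependent and supplied."""
    ann = ChainAnnotation(
        organism=row["organism"],
        mhc_class=int(row["mhc_class"]),
        mhc_allele=row["mhc"],
        peptide=row["peptide"],
        va=row["va"], ja=row["ja"], vb=row["vb"], jb=row["jb"],
        cdr3a=row["cdr3a"], cdr3b=row["cdr3b"],
        cdr_spans=cdr_spans,
    )
    return ann, _chain_map_from_str(row["chain_map"])


def write_annotation_table(rows: list[dict], path) -> None:
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_annotation_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"mhc_class": int})


def geometry_to_row(g: DockingGeometry, pdb_id: str, mhc_class: int) -> dict:
    return {
        "pdbid": pdb_id,
        "mhc_class": mhc_class,
        "d": g.d,
        "torsion": g.torsion,
        "mhc_unit_x": g.mhc_unit[0], "mhc_unit_y": g.mhc_unit[1], "mhc_unit_z": g.mhc_unit[2],
        "tcr_unit_x": g.tcr_unit[0], "tcr_unit_y": g.tcr_unit[1], "tcr_unit_z": g.tcr_unit[2],
    }


def geometry_from_row(row) -> DockingGeometry:
    mu = np.array([row["mhc_unit_x"], row["mhc_unit_y"], row["mhc_unit_z"]], float)
    tu = np.array([row["tcr_unit_x"], row["tcr_unit_y"], row["tcr_unit_z"]], float)
    return DockingGeometry(
        d=float(row["d"]), torsion=float(row["torsion"]),
        mhc_unit=mu / np.linalg.norm(mu), tcr_unit=tu / np.linalg.norm(tu),
    )


def write_geometry_table(entries: list[tuple[str, int, DockingGeometry]], path) -> None:
    rows = [geometry_to_row(g, pdbid, mhc_class) for pdbid, mhc_class, g in entries]
    pd.DataFrame(rows, columns=GEOMETRY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_geometry_table(path) -> list[tuple[str, int, DockingGeometry]]:
    df = pd.read_csv(path, sep="\t")
    return [
        (str(r["pdbid"]), int(r["mhc_class"]), geometry_from_row(r))
        for _, r in df.iterrows()
    ]


REPERTOIRE_COLUMNS = ["id", "organism", "va", "ja", "cdr3a", "vb", "jb", "cdr3b", "epitope"]


def write_repertoire(tcrs: list[PairedTcr], path, organism: str = "synthetic",
                     epitope: str = "") -> None:
    rows = [
        {
            "id": t.id, "organism": organism,
            "va": t.alpha.v_gene, "ja": "", "cdr3a": t.alpha.cdr3,
            "vb": t.beta.v_gene, "jb": "", "cdr3b": t.beta.cdr3,
            "epitope": epitope,
        }
        for t in tcrs
    ]
    pd.DataFrame(rows, columns=REPERTOIRE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_repertoire(path, v_gene_table=None) -> list[PairedTcr]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        out.append(
            PairedTcr(
                alpha=TcrChainSeq.from_v_gene(r["va"], r["cdr3a"], "alpha", v_gene_table),
                beta=TcrChainSeq.from_v_gene(r["vb"], r["cdr3b"], "beta", v_gene_table),
                id=str(r["id"]),
            )
        )
    return out


def load_pae_json(path) -> tuple[np.ndarray, tuple, tuple]:
    """Per-complex PAE JSON: square matrix plus half-open tcr/pmhc spans."""
    with open(path) as fh:
        data = json.load(fh)
    matrix = np.asarray(data["pae"], float)
    return matrix, tuple(data["tcr_span"]), tuple(data["pmhc_span"])


def read_pae_table(path, wt_column: str | None = None) -> PaeMatrix:
    """Pre-pooled N x P interface-PAE TSV (rows = TCR ids, columns = peptides)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    peptides = tuple(df.columns)
    wt_index = 0 if wt_column is None else peptides.index(wt_column)
    return PaeMatrix(
        values=df.to_numpy(float),
        tcr_ids=tuple(str(i) for i in df.index),
        peptides=peptides,
        wt_index=wt_index,
    )


def write_scores_table(b: BindingScoreMatrix, path, extra: dict | None = None) -> None:
    df = pd.DataFrame(
        b.values,
        index=list(b.tcr_ids) or None,
        columns=list(b.peptides) or None,
    )
    if extra:
        for name, col in extra.items():
            df[name] = col
    df.to_csv(path, sep="\t", index_label="tcr_id")
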