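"""Template selection, exclusion rules, and hybrid template assembly.

A modeling target (sequences only) is matched against a database of solved
ternary complexes.  Four single-chain templates are picked per role --
peptide-MHC by total sequence identity over MHC plus peptide, TCR chains by
single-chain TCRdist -- and twelve representative docking geometries are
chosen by hierarchically clustering the class-matched geometry database on
docking RMSD, cutting the tree into twelve clusters and taking each cluster's
medoid.  Chain templates and geometries combine into twelve hybrid complexes
distributed over three predictor runs of four templates each; the same chain
templates appear in every run, only the docking geometry varies.

In benchmark mode, templates too similar to the target are masked out:
peptide-MHC templates with fewer than 3 peptide mismatches, TCR chain
templates with single-chain TCRdist <= 36, and docking geometries from
structures with fewer than 3 peptide mismatches or paired TCRdist <= 48.
In production mode only the deposit-date cutoff applies.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .geometry import (
    DockingGeometry,
    RigidTransform,
    build_frame_from_halves,
    build_mhc_frame,
    build_tcr_frame,
    compute_docking_geometry,
    geometry_to_transform,
    kabsch,
)
from .rmsd import GenericCdrComs, docking_rmsd, weighted_point_rmsd
from .structure import (
    CoreResidueSet,
    Residue,
    TernaryComplex,
    align_and_map,
    locate_core_residues,
    peptide_mismatches,
    write_pdb,
)
from .tcrdist import PairedTcr, TcrChainSeq, paired_tcrdist, single_chain_tcrdist

__all__ = [
    "TemplateRecord",
    "ModelingTarget",
    "TemplateMask",
    "HybridTemplate",
    "RunManifest",
    "exclusion_mask",
    "select_chain_templates",
    "select_representative_geometries",
    "assemble_hybrid_template",
    "build_run_manifest",
    "chain_seqs_from_complex",
]

# benchmark-mode similarity thresholds
PEPTIDE_MISMATCH_MIN = 3
CHAIN_TCRDIST_MAX = 36.0
GEOMETRY_TCRDIST_MAX = 48.0


def chain_seqs_from_complex(complex: TernaryComplex) -> tuple[TcrChainSeq, TcrChainSeq]:
    """Extract alpha/beta CDR loop sequences from an annotated complex."""
    ann = complex.annotation
    out = []
    for role, tag, v_gene in (("tcra", "a", ann.va), ("tcrb", "b", ann.vb)):
        seq = complex.sequence(role)
        loops = {
            name: seq[slice(*ann.cdr_spans[f"{name}{tag}"])]
            for name in ("cdr1", "cdr2", "cdr25", "cdr3")
        }
        out.append(TcrChainSeq(v_gene=v_gene, **loops))
    return tuple(out)


@dataclass
class TemplateRecord:
    """One solved ternary complex in the template database."""

    pdb_id: str
    complex: TernaryComplex
    geometry: DockingGeometry
    deposit_date: str = ""
    cores: CoreResidueSet | None = None
    _chains: tuple | None = field(default=None, repr=False)

    @property
    def peptide(self) -> str:
        return self.complex.annotation.peptide

    @property
    def mhc_class(self) -> int:
        return self.complex.annotation.mhc_class

    def chain_seqs(self) -> tuple[TcrChainSeq, TcrChainSeq]:
        if self._chains is None:
            self._chains = chain_seqs_from_complex(self.complex)
        return self._chains

    def paired(self) -> PairedTcr:
        a, b = self.chain_seqs()
        return PairedTcr(alpha=a, beta=b, id=self.pdb_id)

    @classmethod
    def from_complex(cls, complex: TernaryComplex, profiles=None) -> "TemplateRecord":
        cores = locate_core_residues(complex, profiles)
        geometry = compute_docking_geometry(
            build_mhc_frame(complex, cores), build_tcr_frame(complex, cores)
        )
        return cls(
            pdb_id=complex.pdb_id,
            complex=complex,
            geometry=geometry,
            deposit_date=complex.deposit_date,
            cores=cores,
        )


@dataclass(frozen=True)
class ModelingTarget:
    """Sequences of the complex to be modeled."""

    peptide: str
    mhc_sequence: str
    alpha: TcrChainSeq
    beta: TcrChainSeq
    mhc_class: int = 1
    mhc_allele: str = ""
    tcra_sequence: str = ""
    tcrb_sequence: str = ""
    name: str = "target"


@dataclass(frozen=True)
class TemplateMask:
    """Per-record usability flags for the three template uses."""

    pmhc: bool
    tcra: bool
    tcrb: bool
    geometry: bool


def exclusion_mask(
    target: ModelingTarget,
    db: list[TemplateRecord],
    mode: str = "benchmark",
    date_cutoff: str | None = None,
    pep_thresh: int = PEPTIDE_MISMATCH_MIN,
    chain_thresh: float = CHAIN_TCRDIST_MAX,
    geom_thresh: float = GEOMETRY_TCRDIST_MAX,
) -> list[TemplateMask]:
    """Flag which database records may serve as templates for a target.

    Production mode applies only the deposit-date cutoff.  Benchmark mode
    additionally masks records too similar to the target (see module
    docstring).  Raises if nothing remains usable in any role.
    """
    if mode not in ("benchmark", "production"):
        raise ValueError("mode must be 'benchmark' or 'production'")
    if not db:
        raise ValueError("empty template database")
    target_paired = PairedTcr(alpha=target.alpha, beta=target.beta)
    masks = []
    for rec in db:
        date_ok = date_cutoff is None or (rec.deposit_date or "") <= date_cutoff
        if mode == "production":
            masks.append(TemplateMask(date_ok, date_ok, date_ok, date_ok))
            continue
        pep_mm = peptide_mismatches(target.peptide, rec.peptide)
        rec_a, rec_b = rec.chain_seqs()
        da = single_chain_tcrdist(target.alpha, rec_a)
        db_ = single_chain_tcrdist(target.beta, rec_b)
        paired = paired_tcrdist(target_paired, rec.paired())
        masks.append(
            TemplateMask(
                pmhc=date_ok and pep_mm >= pep_thresh,
                tcra=date_ok and da > chain_thresh,
                tcrb=date_ok and db_ > chain_thresh,
                geometry=date_ok and pep_mm >= pep_thresh and paired > geom_thresh,
            )
        )
    if not any(m.pmhc or m.tcra or m.tcrb or m.geometry for m in masks):
        raise ValueError("no usable templates after exclusion masking")
    return masks


def _identity_over_alignment(seq_a: str, seq_b: str) -> int:
    mapping = align_and_map(seq_a, seq_b)
    return sum(1 for b_idx, a_idx in mapping.items() if seq_b[b_idx] == seq_a[a_idx])


def select_chain_templates(
    target: ModelingTarget,
    db: list[TemplateRecord],
    mask: list[TemplateMask],
    n: int = 4,
) -> dict:
    """Top-n templates per role.

    Peptide-MHC templates rank by total sequence identity over MHC plus
    peptide (descending); TCR chain templates rank by single-chain TCRdist
    (ascending).  Ties break by earlier deposit date, then pdb id.
    """
    allowed = {
        "pmhc": [r for r, m in zip(db, mask) if m.pmhc],
        "tcra": [r for r, m in zip(db, mask) if m.tcra],
        "tcrb": [r for r, m in zip(db, mask) if m.tcrb],
    }
    short = {k: len(v) for k, v in allowed.items() if len(v) < n}
    if short:
        raise ValueError(f"fewer than {n} allowed templates: {short}")

    def pmhc_key(rec: TemplateRecord):
        ident = _identity_over_alignment(rec.complex.sequence("mhc"), target.mhc_sequence)
        if len(rec.peptide) == len(target.peptide):
            ident += sum(a == b for a, b in zip(rec.peptide, target.peptide))
        return (-ident, rec.deposit_date or "9999", rec.pdb_id)

    def tcr_key(which: int):
        def key(rec: TemplateRecord):
            tgt = target.alpha if which == 0 else target.beta
            d = single_chain_tcrdist(tgt, rec.chain_seqs()[which])
            return (d, rec.deposit_date or "9999", rec.pdb_id)
        return key

    return {
        "pmhc": sorted(allowed["pmhc"], key=pmhc_key)[:n],
        "tcra": sorted(allowed["tcra"], key=tcr_key(0))[:n],
        "tcrb": sorted(allowed["tcrb"], key=tcr_key(1))[:n],
    }


def select_representative_geometries(
    db_geoms: list[DockingGeometry],
    coms: GenericCdrComs,
    k: int = 12,
    linkage_method: str = "single",
    return_indices: bool = False,
):
    """Medoid representatives of k docking-geometry clusters.

    The pairwise docking-RMSD matrix is hierarchically clustered and the tree
    cut at the threshold giving exactly k clusters; each cluster contributes
    the member with the smallest mean distance to its co-members (singletons
    return their only member).  Output is ordered by decreasing cluster size,
    ties by first appearance in the input.
    """
    m = len(db_geoms)
    if m < k:
        raise ValueError(f"need at least {k} geometries, got {m}")
    dmat = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            dmat[i, j] = dmat[j, i] = docking_rmsd(db_geoms[i], db_geoms[j], coms)
    z = linkage(squareform(dmat, checks=False), method=linkage_method)
    labels = fcluster(z, t=k, criterion="maxclust")
    cluster_ids = np.unique(labels)
    if len(cluster_ids) != k:
        raise ValueError(
            f"tree cut produced {len(cluster_ids)} clusters instead of {k} "
            "(duplicate geometries?)"
        )
    clusters = []
    for cid in cluster_ids:
        members = np.flatnonzero(labels == cid)
        if len(members) == 1:
            medoid = int(members[0])
        else:
            sub = dmat[np.ix_(members, members)]
            mean_d = sub.sum(axis=1) / (len(members) - 1)
            medoid = int(members[int(np.argmin(mean_d))])
        clusters.append((len(members), int(members[0]), medoid))
    clusters.sort(key=lambda c: (-c[0], c[1]))
    indices = [medoid for _, _, medoid in clusters]
    geoms = [db_geoms[i] for i in indices]
    return (geoms, indices) if return_indices else geoms


@dataclass
class HybridTemplate:
    """Chimeric template: pMHC, TCRA and TCRB chains in one docked pose.

    Coordinates are grouped by the four writable chains; conceptually the
    template has three roles (pmhc, tcra, tcrb).  `alignment` maps target
    residue positions to template positions per chain.
    """

    chains: dict  # mhc / peptide / tcra / tcrb -> list[Residue]
    source_ids: tuple  # (pmhc_pdb, tcra_pdb, tcrb_pdb, geometry_pdb)
    alignment: dict
    geometry_index: int
    realized_geometry: DockingGeometry | None = None

    roles = ("pmhc", "tcra", "tcrb")

    def as_role_chains(self) -> dict:
        return self.chains


def _move_residues(residues, t: RigidTransform, chain_id=None):
    return [
        Residue(
            chain_id if chain_id is not None else r.chain_id,
            r.seq_index,
            r.aa,
            t.apply(r.ca_xyz),
        )
        for r in residues
    ]


def assemble_hybrid_template(
    pmhc_t: TemplateRecord,
    tcra_t: TemplateRecord,
    tcrb_t: TemplateRecord,
    rep_geom: DockingGeometry,
    geometry_pdb: str = "",
    geometry_index: int = 0,
    target: ModelingTarget | None = None,
    profiles=None,
    superpose_warn_rmsd: float = 5.0,
) -> HybridTemplate:
    """Assemble one hybrid template complex realizing rep_geom.

    The TCRB donor structure is rigidly superposed onto the TCRA template via
    the 13 TCRA core residues and its beta chain appended; the pMHC template
    is rigidly mapped so the realized MHC-to-TCR geometry equals rep_geom.
    """
    recs = {}
    for name, rec in (("pmhc", pmhc_t), ("tcra", tcra_t), ("tcrb", tcrb_t)):
        if rec.cores is None:
            rec.cores = locate_core_residues(rec.complex, profiles)
        recs[name] = rec

    # beta donor -> alpha template, via the alpha-chain cores of both
    a_cores_fixed = np.array(
        [tcra_t.complex.chain("tcra")[i].ca_xyz for i in tcra_t.cores.tcra_core]
    )
    a_cores_mobile = np.array(
        [tcrb_t.complex.chain("tcra")[i].ca_xyz for i in tcrb_t.cores.tcra_core]
    )
    t_ba = kabsch(a_cores_fixed, a_cores_mobile)
    sup_rmsd = weighted_point_rmsd(a_cores_fixed, t_ba.apply(a_cores_mobile))
    if sup_rmsd > superpose_warn_rmsd:
        warnings.warn(
            f"TCRA-core superposition RMSD {sup_rmsd:.2f} A exceeds "
            f"{superpose_warn_rmsd} A; proceeding", stacklevel=2,
        )
    tcra_res = list(tcra_t.complex.chain("tcra"))
    tcrb_res = _move_residues(tcrb_t.complex.chain("tcrb"), t_ba)

    # hybrid TCR frame from the merged alpha/beta cores
    half_a = np.array([tcra_res[i].ca_xyz for i in tcra_t.cores.tcra_core])
    half_b = np.array([tcrb_res[i].ca_xyz for i in tcrb_t.cores.tcrb_core])
    cdr3_pts = []
    for res_list, rec, loop in ((tcra_res, tcra_t, "cdr3a"), (tcrb_res, tcrb_t, "cdr3b")):
        s, e = rec.complex.annotation.cdr_spans[loop]
        cdr3_pts.extend(res_list[i].ca_xyz for i in range(s, e))
    tcr_frame = build_frame_from_halves(half_a, half_b, np.asarray(cdr3_pts).mean(axis=0))

    # place the pMHC so that compute_docking_geometry(mhc, tcr) == rep_geom
    mhc_frame_cur = build_mhc_frame(pmhc_t.complex, pmhc_t.cores)
    g_tcr = RigidTransform(tcr_frame.rotation, tcr_frame.origin)
    t_rel = geometry_to_transform(rep_geom)
    g_mhc_desired = g_tcr.compose(t_rel.inverse())
    g_mhc_cur = RigidTransform(mhc_frame_cur.rotation, mhc_frame_cur.origin)
    move = g_mhc_desired.compose(g_mhc_cur.inverse())
    mhc_res = _move_residues(pmhc_t.complex.chain("mhc"), move)
    pep_res = _move_residues(pmhc_t.complex.chain("peptide"), move)

    # verify the realized geometry matches the request
    realized = compute_docking_geometry(mhc_frame_cur.transformed(move), tcr_frame)
    dv = realized.as_vector() - rep_geom.as_vector()
    for idx in (1, 3, 5):
        dv[idx] = np.angle(np.exp(1j * dv[idx]))
    if abs(dv[0]) > 1e-3 or np.abs(dv[1:]).max() > 1e-5:
        raise RuntimeError("assembled hybrid does not realize the requested geometry")

    alignment = {}
    if target is not None:
        pairs = [
            ("mhc", target.mhc_sequence, pmhc_t.complex.sequence("mhc")),
            ("peptide", target.peptide, pmhc_t.complex.sequence("peptide")),
            ("tcra", target.tcra_sequence, tcra_t.complex.sequence("tcra")),
            ("tcrb", target.tcrb_sequence, tcrb_t.complex.sequence("tcrb")),
        ]
        for chain_name, tgt_seq, tpl_seq in pairs:
            if tgt_seq:
                # align_and_map(template, target) yields {target_pos: template_pos}
                alignment[chain_name] = align_and_map(tpl_seq, tgt_seq)

    return HybridTemplate(
        chains={"mhc": mhc_res, "peptide": pep_res, "tcra": tcra_res, "tcrb": tcrb_res},
        source_ids=(pmhc_t.pdb_id, tcra_t.pdb_id, tcrb_t.pdb_id, geometry_pdb),
        alignment=alignment,
        geometry_index=geometry_index,
        realized_geometry=realized,
    )


@dataclass
class RunManifest:
    """Three predictor runs of four hybrid templates each."""

    runs: list  # 3 lists of 4 HybridTemplate
    target_name: str
    target_sequence: str = ""  # chain-break markers '/' between chains
    template_paths: list = field(default_factory=list)
    msa_mode: str = "single_sequence"

    def __post_init__(self):
        if len(self.runs) != 3 or any(len(r) != 4 for r in self.runs):
            raise ValueError("manifest must hold exactly 3 runs of 4 templates")
        geoms = [h.geometry_index for run in self.runs for h in run]
        if sorted(geoms) != list(range(12)):
            raise ValueError("each of the 12 representative geometries must be used once")

    def all_templates(self):
        return [h for run in self.runs for h in run]

    def to_json(self) -> dict:
        return {
            "target": self.target_name,
            "target_sequence": self.target_sequence,
            "msa_mode": self.msa_mode,
            "runs": [
                [
                    {
                        "path": self.template_paths[4 * r + i] if self.template_paths else None,
                        "source_ids": list(h.source_ids),
                        "geometry_index": h.geometry_index,
                        "alignment": {
                            ch: [[int(a), int(b)] for a, b in sorted(m.items())]
                            for ch, m in h.alignment.items()
                        },
                    }
                    for i, h in enumerate(run)
                ]
                for r, run in enumerate(self.runs)
            ],
        }


def build_run_manifest(
    target: ModelingTarget,
    chain_templates: dict,
    rep_geoms: list[DockingGeometry],
    rep_geom_sources: list[str] | None = None,
    out_dir=None,
    profiles=None,
    n_runs: int = 3,
    n_per_run: int = 4,
) -> RunManifest:
    """Pair ranked chain templates with the 12 representative geometries.

    Geometry j (0-based) goes to run j // 4 and is assembled with the rank
    (j mod 4) chain templates, so the same four chain-template sets recur in
    every run while the docking geometry varies.  Optionally writes the 12
    hybrid PDB files plus a JSON manifest to out_dir.
    """
    for role in ("pmhc", "tcra", "tcrb"):
        if len(chain_templates.get(role, [])) != n_per_run:
            raise ValueError(f"need exactly {n_per_run} templates for role {role!r}")
    if len(rep_geoms) != n_runs * n_per_run:
        raise ValueError(f"need exactly {n_runs * n_per_run} representative geometries")
    sources = rep_geom_sources or [""] * len(rep_geoms)
    runs = []
    for r in range(n_runs):
        run = []
        for i in range(n_per_run):
            j = n_per_run * r + i
            rank = j % n_per_run
            run.append(
                assemble_hybrid_template(
                    chain_templates["pmhc"][rank],
                    chain_templates["tcra"][rank],
                    chain_templates["tcrb"][rank],
                    rep_geoms[j],
                    geometry_pdb=sources[j],
                    geometry_index=j,
                    target=target,
                    profiles=profiles,
                )
            )
        runs.append(run)

    target_sequence = "/".join(
        s for s in (target.mhc_sequence, target.peptide,
                    target.tcra_sequence, target.tcrb_sequence) if s
    )
    manifest = RunManifest(runs=runs, target_name=target.name,
                           target_sequence=target_sequence)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for r, run in enumerate(manifest.runs):
            for i, h in enumerate(run):
                p = out_dir / f"{target.name}_run{r + 1}_template{i + 1}.pdb"
                write_pdb(h, p)
                paths.append(str(p))
        manifest.template_paths = paths
        with open(out_dir / f"{target.name}_manifest.json", "w") as fh:
            json.dump(manifest.to_json(), fh, indent=1)
    return manifest
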