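"""Exclusion rules, template ranking, representative geometries, hybrid assembly."""

import itertools

import numpy as np
import pytest

from tcrpmhc.geometry import DockingGeometry
from tcrpmhc.rmsd import docking_rmsd
from tcrpmhc.structure import peptide_mismatches
from tcrpmhc.synthetic import (
    SyntheticSpec,
    make_synthetic_complex,
    random_synthetic_specs,
)
from tcrpmhc.tcrdist import paired_tcrdist, single_chain_tcrdist
from tcrpmhc.templates import (
    ModelingTarget,
    TemplateRecord,
    assemble_hybrid_template,
    build_run_manifest,
    exclusion_mask,
    select_chain_templates,
    select_representative_geometries,
)


def target_from_record(rec, name="target"):
    alpha, beta = rec.chain_seqs()
    return ModelingTarget(
        peptide=rec.peptide,
        mhc_sequence=rec.complex.sequence("mhc"),
        alpha=alpha,
        beta=beta,
        mhc_class=rec.mhc_class,
        tcra_sequence=rec.complex.sequence("tcra"),
        tcrb_sequence=rec.complex.sequence("tcrb"),
        name=name,
    )


class TestExclusionMask:
    def test_self_record_fully_masked_in_benchmark_mode(self, small_db):
        target = target_from_record(small_db[0])
        mask = exclusion_mask(target, small_db, mode="benchmark")
        assert not any(
            (mask[0].pmhc, mask[0].tcra, mask[0].tcrb, mask[0].geometry)
        )

    def test_production_mode_applies_only_date_cutoff(self, small_db):
        target = target_from_record(small_db[0])
        mask = exclusion_mask(target, small_db, mode="production", date_cutoff="2014-12-31")
        for rec, m in zip(small_db, mask):
            expected = rec.deposit_date <= "2014-12-31"
            assert m.pmhc == m.tcra == m.tcrb == m.geometry == expected

    def test_identical_peptide_blocks_pmhc_and_geometry(self, small_db):
        rec = small_db[3]
        alpha, beta = small_db[0].chain_seqs()  # distant TCR, same peptide
        target = ModelingTarget(
            peptide=rec.peptide,
            mhc_sequence=rec.complex.sequence("mhc"),
            alpha=alpha, beta=beta, mhc_class=rec.mhc_class,
        )
        m = exclusion_mask(target, small_db, mode="benchmark")[3]
        assert not m.pmhc and not m.geometry

    def test_exhaustive_threshold_check(self, small_db):
        """Every allowed flag must be consistent with a brute-force recheck."""
        target = target_from_record(small_db[7])
        mask = exclusion_mask(target, small_db, mode="benchmark")
        tp = target.peptide
        for rec, m in zip(small_db, mask):
            mm = peptide_mismatches(tp, rec.peptide)
            ra, rb = rec.chain_seqs()
            da = single_chain_tcrdist(target.alpha, ra)
            db_ = single_chain_tcrdist(target.beta, rb)
            dp = da + db_
            assert m.pmhc == (mm >= 3)
            assert m.tcra == (da > 36)
            assert m.tcrb == (db_ > 36)
            assert m.geometry == (mm >= 3 and dp > 48)


class TestChainTemplateSelection:
    def test_identical_record_ranks_first_in_production(self, small_db):
        target = target_from_record(small_db[5])
        mask = exclusion_mask(target, small_db, mode="production")
        picked = select_chain_templates(target, small_db, mask, n=4)
        assert picked["pmhc"][0].pdb_id == small_db[5].pdb_id
        assert picked["tcra"][0].pdb_id == small_db[5].pdb_id

    def test_tcr_ranking_is_by_ascending_chain_distance(self, small_db):
        target = target_from_record(small_db[5])
        mask = exclusion_mask(target, small_db, mode="benchmark")
        picked = select_chain_templates(target, small_db, mask, n=4)
        dists = [
            single_chain_tcrdist(target.alpha, r.chain_seqs()[0])
            for r in picked["tcra"]
        ]
        assert dists == sorted(dists)
        allowed = [r for r, m in zip(small_db, mask) if m.tcra]
        best_allowed = min(
            single_chain_tcrdist(target.alpha, r.chain_seqs()[0]) for r in allowed
        )
        assert dists[0] == best_allowed

    def test_tie_broken_by_earlier_deposit_date(self, small_db):
        import copy

        # plant an exact tie: duplicate record with a different id and later date
        rec = small_db[2]
        dup = copy.deepcopy(rec)
        dup.pdb_id = "zzz_dup"
        dup.deposit_date = "2030-01-01"
        db = small_db + [dup]
        target = target_from_record(small_db[5])
        mask = exclusion_mask(target, db, mode="production")
        picked = select_chain_templates(target, db, mask, n=len(db))
        ia = [r.pdb_id for r in picked["tcra"]].index(rec.pdb_id)
        ib = [r.pdb_id for r in picked["tcra"]].index("zzz_dup")
        assert ia < ib

    def test_too_few_templates_reports_counts(self, small_db):
        target = target_from_record(small_db[0])
        mask = exclusion_mask(target, small_db, mode="production", date_cutoff="2010-06-01")
        with pytest.raises(ValueError, match="fewer than"):
            select_chain_templates(target, small_db, mask, n=4)


def planted_geometry_clusters(rng, k=12, members=3, jitter=0.01):
    """k well-separated geometry clusters with `members` samples each.

    Jitter must stay small: a perturbation of the angular components moves the
    generic CDR points by roughly jitter * 40 Angstrom, and the planted
    centers are ~6-20 Angstrom apart.
    """
    base = np.array([28.0, 1.0, 0.5, 0.3, 0.6, -0.4])
    centers = []
    for d in (20.0, 26.0, 32.0, 38.0):
        for torsion in (-2.2, 0.0, 2.2):
            v = base.copy()
            v[0], v[1] = d, torsion
            centers.append(v)
    centers = centers[:k]
    geoms, labels = [], []
    for ci, c in enumerate(centers):
        for _ in range(members):
            geoms.append(DockingGeometry.from_vector(c + rng.normal(0, jitter, 6)))
            labels.append(ci)
    return geoms, labels


class TestRepresentativeGeometries:
    def test_planted_clusters_recovered_one_each(self, coms, rng):
        geoms, labels = planted_geometry_clusters(rng)
        reps, idx = select_representative_geometries(geoms, coms, k=12, return_indices=True)
        assert len(reps) == 12
        assert sorted(labels[i] for i in idx) == list(range(12))

    def test_exactly_k_distinct_inputs_returned_as_is(self, coms, rng):
        geoms, _ = planted_geometry_clusters(rng, members=1)
        reps, idx = select_representative_geometries(geoms, coms, k=12, return_indices=True)
        assert sorted(idx) == list(range(12))

    def test_medoid_property_by_brute_force(self, coms, rng):
        geoms, labels = planted_geometry_clusters(rng, members=4, jitter=0.015)
        reps, idx = select_representative_geometries(geoms, coms, k=12, return_indices=True)
        labels = np.array(labels)
        assert sorted(labels[i] for i in idx) == list(range(12))
        for rep_idx in idx:
            members = np.flatnonzero(labels == labels[rep_idx])
            means = {
                int(i): np.mean([
                    docking_rmsd(geoms[i], geoms[j], coms) for j in members if j != i
                ])
                for i in members
            }
            assert means[int(rep_idx)] == min(means.values())

    def test_fewer_than_k_inputs_rejected(self, coms, random_geometries):
        with pytest.raises(ValueError, match="at least 12"):
            select_representative_geometries(random_geometries[:5], coms, k=12)


class TestHybridAssembly:
    def test_self_assembly_reproduces_source(self, small_db):
        rec = small_db[1]
        h = assemble_hybrid_template(rec, rec, rec, rec.geometry, geometry_pdb=rec.pdb_id)
        for role in ("mhc", "peptide", "tcra", "tcrb"):
            orig = np.array([r.ca_xyz for r in rec.complex.chain(role)])
            new = np.array([r.ca_xyz for r in h.chains[role]])
            assert np.abs(orig - new).max() < 1e-3

    def test_realized_geometry_matches_request(self, small_db, random_geometries):
        for rep_geom, (p, a, b) in zip(
            random_geometries[:5],
            itertools.permutations(small_db[:5], 3),
        ):
            h = assemble_hybrid_template(p, a, b, rep_geom)
            dv = h.realized_geometry.as_vector() - rep_geom.as_vector()
            for i in (1, 3, 5):
                dv[i] = np.angle(np.exp(1j * dv[i]))
            assert abs(dv[0]) < 1e-3
            assert np.abs(dv[1:]).max() < 1e-5

    def test_beta_donor_from_same_structure_moves_nothing(self, small_db):
        rec = small_db[2]
        h = assemble_hybrid_template(rec, rec, rec, rec.geometry)
        orig = np.array([r.ca_xyz for r in rec.complex.chain("tcrb")])
        new = np.array([r.ca_xyz for r in h.chains["tcrb"]])
        assert np.abs(orig - new).max() < 1e-9

    def test_alignment_maps_are_injective_and_monotone(self, small_db):
        rec = small_db[1]
        target = target_from_record(small_db[4])
        h = assemble_hybrid_template(rec, rec, rec, rec.geometry, target=target)
        for chain_name, mapping in h.alignment.items():
            tgt = sorted(mapping)
            tpl = [mapping[i] for i in tgt]
            assert len(set(tpl)) == len(tpl)
            assert tpl == sorted(tpl)


@pytest.fixture(scope="module")
def manifest(small_db, tmp_path_factory):
    target = target_from_record(small_db[0], name="tgt")
    mask = exclusion_mask(target, small_db, mode="benchmark")
    picked = select_chain_templates(target, small_db, mask, n=4)
    geom_recs = [r for r, m in zip(small_db, mask)
                 if m.geometry and r.mhc_class == target.mhc_class]
    from tcrpmhc.synthetic import canonical_generic_coms

    geoms = select_representative_geometries(
        [r.geometry for r in geom_recs], canonical_generic_coms(), k=12
    )
    out = tmp_path_factory.mktemp("manifest")
    return build_run_manifest(target, picked, geoms, out_dir=out), out


class TestRunManifest:
    def test_three_runs_of_four_templates(self, manifest):
        man, _ = manifest
        assert len(man.runs) == 3
        assert all(len(r) == 4 for r in man.runs)
        assert len(man.template_paths) == 12

    def test_each_geometry_used_exactly_once(self, manifest):
        man, _ = manifest
        indices = [h.geometry_index for run in man.runs for h in run]
        assert sorted(indices) == list(range(12))

    def test_chain_templates_identical_across_runs(self, manifest):
        man, _ = manifest
        per_run_sources = [
            [h.source_ids[:3] for h in run] for run in man.runs
        ]
        assert per_run_sources[0] == per_run_sources[1] == per_run_sources[2]

    def test_manifest_json_written(self, manifest):
        import json

        man, out = manifest
        data = json.loads((out / "tgt_manifest.json").read_text())
        assert data["msa_mode"] == "single_sequence"
        assert len(data["runs"]) == 3
        assert "/" in data["target_sequence"]

    def test_selected_templates_respect_thresholds(self, small_db):
        """No selected template may violate the benchmark exclusion rules."""
        target = target_from_record(small_db[0])
        mask = exclusion_mask(target, small_db, mode="benchmark")
        picked = select_chain_templates(target, small_db, mask, n=4)
        for rec in picked["pmhc"]:
            assert peptide_mismatches(target.peptide, rec.peptide) >= 3
        for rec in picked["tcra"]:
            assert single_chain_tcrdist(target.alpha, rec.chain_seqs()[0]) > 36
        for rec in picked["tcrb"]:
            assert single_chain_tcrdist(target.beta, rec.chain_seqs()[1]) > 36
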