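# tcrpmhc

Computational machinery for template-based structural modeling of T cell
receptor (TCR) : peptide-MHC (pMHC) complexes and for turning predictor
confidence estimates into epitope-specificity calls. The package implements
everything *around* a deep-learning structure predictor — the predictor itself
is abstracted behind file formats and a pluggable scoring interface, so the
pipeline runs end to end on synthetic data with no GPU and no downloads.

It is aimed at computational immunologists who want to

* parameterize how a TCR docks onto a pMHC as an interpretable 6-vector,
* build hybrid multi-chain templates that sample diverse native-like docking
  modes for a predictor that only accepts per-run template sets, and
* convert per-complex predicted-aligned-error (PAE) matrices into corrected
  binding scores for peptide decoy discrimination and alanine scanning.

## The model

**Docking geometry.** Both the MHC peptide-binding domain and the TCR
variable-domain heterodimer carry an approximate internal two-fold symmetry.
For each, the least-squares rigid transform that swaps the two symmetric
halves (6+6 β-sheet core residues for the MHC, 13+13 conserved framework
residues for the TCRα/β pair) defines a coordinate frame: the symmetry
rotation axis — signed toward the peptide, or toward the CDR loops — is
**x**; the vector between the half centers of mass, orthogonalized against
x, is **z**; y = z × x. The relative pose of the two frames is charted by

  g = (d, τ, θ_m, φ_m, θ_t, φ_t)

with d the inter-origin distance, τ the dihedral about the connecting axis,
and (θ, φ) the polar/azimuth angles of the origin-to-origin direction
expressed in each frame. The chart has an exact inverse (`geometry_to_transform`),
round-tripping to < 1e-6. A multivariate normal fit over a structure database
gives each geometry a Mahalanobis **docking Z score**, Z² ~ χ²(6), measuring
deviation from the consensus diagonal binding mode of its MHC class.

**Docking RMSD.** A sequence-independent distance between two geometries:
generic per-loop CDR centers of mass are placed by each geometry's TCR frame
over a common MHC frame and compared without superposition, CDR3 weighted ×3.
This drives hierarchical clustering of the geometry database; cutting the tree
at 12 clusters and taking each cluster's medoid yields the 12 representative
geometries used for hybrid templates (3 predictor runs × 4 templates).

**Binding scores.** Raw interface PAE carries TCR-intrinsic and pMHC-intrinsic
offsets. With bg(j) the mean interface PAE of peptide j against a panel of
irrelevant background TCRs,

  B[i,j] = (PAE[i,j] − bg[j]) − mean_j (PAE[i,·] − bg[·])

so every row of B has mean zero and lower means stronger predicted binding.
Downstream: per-TCR rank of the wild-type peptide among decoys,
repertoire-averaged per-peptide scores, AUROC of binder-vs-decoy recovery,
and per-position alanine-scan deltas (alanine → glycine at native alanines).

Supporting machinery includes TCRdist-style sequence distances (BLOSUM62
mismatch costs capped at 4, gaps 4, CDR3 ×3) used for template exclusion
(similarity thresholds 3 peptide mismatches / single-chain 36 / paired 48),
benchmark redundancy filtering (≥3 peptide mismatches OR paired distance
> 120), and Gaussian-kernel-density repertoire subsampling.

## Worked example

Everything below runs on generated data. Create a synthetic structure
database plus a simulated PAE benchmark, then run the two workflows:

```bash
tcrpmhc simulate --n-structures 30 --seed 11 --out-dir db --pae
tcrpmhc parse-structure db/pdb/syn007.pdb --annotations db/annotations.tsv --out geometry.tsv
```

```
syn007  docking Z score = 0.900
wrote 1 geometries to geometry.tsv
```

The geometry TSV holds the 6-vector per structure (distance in Å, torsion in
radians, two unit vectors); `syn007` docks ~28.9 Å from the MHC frame origin
with a Z score of 0.9 — an unremarkable, consensus-like binding mode:

```
pdbid   mhc_class  d       torsion  mhc_unit_x ...
syn007  1          28.948  1.246    0.960      ...
```

Template setup for that target (benchmark mode, so any database entry too
similar to the target is excluded before selection):

```bash
tcrpmhc setup-templates --db-annotations db/annotations.tsv --pdb-dir db/pdb \
    --target-id syn007 --out-dir templates
# wrote 12 hybrid templates and manifest to templates
```

yielding `syn007_run{1..3}_template{1..4}.pdb` — 12 chimeric complexes, the
same four chain-template sets in every run, one representative docking
geometry each — plus a JSON manifest with per-chain target→template alignment
maps. Scoring the simulated PAE benchmark (50 TCRs × 10 peptides, planted
cognate signal):

```bash
tcrpmhc score --pae db/pae.tsv --background db/background.tsv --wt-column WT --out-dir scores
# AUROC = 0.9895
```

`scores/repertoire_scores.tsv` shows the wild-type epitope winning the
repertoire average (−2.57, decoys near 0), and `binding_scores.tsv` carries
per-TCR scores (rows mean-centered at 0) with each TCR's wild-type rank.

The same operations are importable — `tcrpmhc.geometry.compute_docking_geometry`,
`tcrpmhc.templates.build_run_manifest`, `tcrpmhc.scoring.binding_scores`, … —
for use without the CLI.

## Layout

| module | contents |
| --- | --- |
| `tcrpmhc.structure` | PDB I/O (Cα traces), annotations, core-residue location |
| `tcrpmhc.geometry` | frames, the 6-parameter chart, distribution fit, Z score |
| `tcrpmhc.rmsd` | weighted superposition; CDR, peptide and docking RMSD |
| `tcrpmhc.tcrdist` | sequence distances, redundancy filter, KDE subsampling |
| `tcrpmhc.templates` | exclusion rules, template selection, hybrid assembly |
| `tcrpmhc.scoring` | PAE pooling, binding scores, ranks, ROC, decoys, scans |
| `tcrpmhc.synthetic` | synthetic complexes, PAE matrices, repertoires |
| `tcrpmhc.cli` | the `tcrpmhc` command |
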