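# Methods

## Coordinate frames from internal pseudo-symmetry

The MHC class I/II peptide-binding platform and the TCR Vα/Vβ heterodimer each
relate their two halves by an approximate 180° rotation. We compute the
least-squares proper rigid transform mapping the concatenated core point set
(a, b) onto (b, a) by the closed-form SVD (Kabsch) solution with determinant
correction; reflections are never returned, and point sets whose second
singular value vanishes (collinear cores) are rejected. For an exactly
C2-symmetric set the residual is zero and the rotation is exactly 180°; with
0.1 Å coordinate noise on realistic core layouts the recovered angle stays
within 2° of 180° (tested by simulation).

Frame conventions, fixed here because only the x and z directions are pinned
by the construction itself: **x** is the symmetry rotation axis with its sign
chosen so that x points from the core center of mass toward the peptide (MHC)
or toward the pooled CDR3 Cα (TCR); **z** is the unit vector from the N-half
(or α-core) COM to the C-half (β-core) COM, Gram–Schmidt-orthogonalized
against x; **y = z × x**, giving a right-handed frame; the origin is the COM
of all core Cα. Core residues are 6+6 per MHC and 13 per TCR chain.

Core positions in a new structure are found by mapping shipped reference
index sets through a global pairwise alignment (BLOSUM62, gap open −11,
extend −1) of each chain to a reference sequence, keyed by MHC class. The
shipped reference profiles are **synthetic**: they describe the idealized
complexes the fixture generator emits, and exist so the alignment machinery
is exercised exactly as it would be with crystallographic reference tables,
which can replace them as a data-only change.

## The 6-parameter docking chart

The relative pose of the two frames is parameterized as
(d, τ, θ_m, φ_m, θ_t, φ_t): inter-origin distance (Å); the dihedral of
(MHC x-tip, MHC origin, TCR origin, TCR x-tip) about the connecting axis;
and, for the origin-to-origin direction expressed in each frame, a polar
angle from the frame x-axis and an azimuth in the frame's y–z plane. Because
both x-axes point roughly toward the binding partner, natural complexes sit
at moderate polar angles, away from the two chart singularities (θ = 0, π).
If an x-axis is exactly parallel to the connecting axis the torsion is
undefined; we fix it to 0 by convention in that degenerate case.

The inverse map places the TCR frame against an identity MHC frame: the
minimal rotation takes the TCR-frame direction vector onto the connecting
axis, and the residual spin about that axis is solved from the requested
torsion. Forward∘inverse closes to < 1e-6 over 1,000 random parameter
vectors, and the parameters are invariant to any global rigid motion applied
to both frames (< 1e-8).

**Distribution fit and Z score.** Geometries of one MHC class are summarized
by the sample mean and covariance of their 6-vectors. The three circular
components (torsion, both azimuths) are unwrapped into the 2π window around
their circular mean before moments are taken, so distributions straddling ±π
are handled correctly. The covariance receives a +1e-6·I ridge for
small-sample stability, and at least 7 samples are required (rank). The
docking Z score is the Mahalanobis distance of a geometry from this fit; for
in-distribution samples mean(Z²) is within 5% of 6 at n = 10,000, matching
χ²(6). The priors shipped as package data were fit to synthetic geometries
sampled around the consensus mode and are labelled as such.

## RMSD measures

* **CDR RMSD** — model and native are superposed on their shared MHC Cα
  (unweighted; configurable to the 12-core subset — which of the two the
  field's reference tooling uses is not documented, so the more inclusive
  default was chosen); the Cα RMSD over the eight CDR loops is then computed
  without further superposition. Each CDR3 residue carries weight 3; weights
  enter the squared sum and the normalizer (√(Σw·d²/Σw)), so a uniform 2 Å
  displacement of the TCR gives exactly 2.0.
* **Peptide RMSD** — same superposition, uniform weights over peptide Cα.
* **Docking RMSD** — generic per-loop CDR centers of mass (database averages
  expressed in each structure's TCR frame) are placed by the two geometries'
  TCR frames over a common MHC frame and compared without superposition,
  CDR3 COMs weighted 3. This is a pseudometric (identity, symmetry exactly;
  triangle inequality verified empirically) and correlates with CDR RMSD at
  Spearman ρ > 0.9 on geometry-perturbed model/native pairs. The fixture
  module ships canonical COMs so docking RMSD runs without a database.

## TCRdist and repertoire operations

Per-position substitution cost is max(0, min(4, 4 − BLOSUM62)), gap 4; CDR1,
CDR2 and CDR2.5 enter with weight 1 and CDR3 with weight 3, after trimming 3
N-terminal and 2 C-terminal CDR3 flank positions and center-gapping the
shorter loop (front half aligned from the start, back half from the end, the
split at ⌈m/2⌉). One non-conservative CDR3 substitution therefore costs 12
and three cost 36 — the single-chain exclusion threshold. The paired distance
is the α + β sum.

Redundancy filtering greedily scans entries in input (deposit-date) order and
drops an entry only when *both* conditions hold against an already-kept
entry: fewer than 3 peptide mismatches (peptides of different length never
count as similar — the mismatch count is an infinite sentinel) and paired
distance ≤ 120. Keeping the earlier entry is our choice; the convention is
not otherwise pinned down.

KDE subsampling scores each TCR by a Gaussian kernel density over the paired
distance matrix and selects greedily, densest first, skipping candidates
within `min_dist` of an already-selected TCR. Bandwidth defaults to 120 and
min_dist to 24 (one and one-fifth of the paired redundancy radius; the
underlying subsampling procedure's constants are not published, so these are
package defaults, exposed as parameters). Ties break on the TCR's own
sequences/id, making selection invariant to input order; the seed resolves
only exact residual ties.

## Template engine

Benchmark-mode exclusions: pMHC templates with < 3 peptide mismatches to the
target; TCR chain templates with single-chain distance ≤ 36; docking
geometries from structures with < 3 peptide mismatches *or* paired distance
≤ 48. Production mode applies only a deposit-date cutoff (default
2021-08-05). pMHC templates rank by total aligned sequence identity over
MHC + peptide (descending); TCR chain templates rank by single-chain distance
(ascending) — chosen for consistency with the exclusion thresholds; ties
break by earlier deposit date, then id.

Representative geometries: the pairwise docking-RMSD matrix is clustered with
scipy's `hierarchy.linkage` (single linkage, the routine's default, is our
default; average/complete are options) and cut with `fcluster(maxclust)` at
exactly 12 clusters; each cluster contributes its medoid (smallest mean
distance to co-members). Output is ordered by decreasing cluster size.

Hybrid assembly: the β-donor structure is rigidly superposed onto the
α-template via the 13 TCRα core residues (a superposition RMSD above 5 Å
warns but proceeds); the hybrid TCR frame is built from the merged α/β cores;
the pMHC template is rigidly mapped so that the realized MHC→TCR geometry
equals the requested representative (verified on every assembly to
1e-3 Å / 1e-5 rad; self-assembly reproduces the source structure to 1e-3 Å).
The manifest pairs chain-template rank (j mod 4) with geometry j, run
j div 4 — three runs of four templates, the same chain templates in every
run. The exact rank↔geometry pairing is underdetermined by the workflow being
mirrored; this rank-aligned scheme is fixed and documented here. The manifest
records single-sequence (no-MSA) mode.

## Specificity scoring

Interface PAE is the mean over all TCR:pMHC residue pairs, pooling both
matrix orientations (i,j) and (j,i) since PAE is asymmetric; whether to pool
both directions is not externally documented, so both are used. The mean
(not the sum) is adopted because it is invariant to complex size; a sum
option exists, and per-row ranks are unaffected for fixed sizes. The
best-of-three model selection is the arg-min of interface PAE, ties to the
lowest run index.

Binding scores subtract the per-peptide background mean and then center each
row, so B is exactly invariant to per-TCR constants and to per-peptide
constants shared with the background. Wild-type rank counts strictly better
peptides (0 = best; ties do not count against the wild type), matching a 0–9
rank scale, and is invariant under monotone row transforms. AUROC is the
midrank Wilcoxon–Mann–Whitney probability (computed via scikit-learn, verified
against brute-force pairwise concordance in tests).

Decoy selection concatenates the source antigens, character-shuffles with the
given seed, truncates to 1,500 residues, scores every k-mer with a pluggable
predictor (callable peptide → score, lower = better) and returns the top k
unique peptides, excluding supplied wild-type epitopes; duplicate k-mers are
collapsed (the behavior for duplicates is not otherwise specified). The
built-in mock predictor is a deterministic hash score — reproducible but
biochemically meaningless, which is all the procedural tests require.

## Synthetic data

`make_synthetic_complex` builds an idealized Cα-trace complex realizing a
*prescribed* docking geometry: the MHC core is two exactly C2-related
6-residue half-sheets (so its frame is the identity by construction), the
peptide strand lies on the +x side, and the TCR construct — two C2-related
13-residue cores plus eight CDR loops on its +x face — is placed by the
geometry's rigid transform. Filler residues sit on generic 3.8 Å helices away
from the interface; a minimum 1 Å inter-role separation is enforced. The
generator emulates what the geometry/template machinery needs — exact frames,
alignable sequences, realistic inter-domain distances — and **not** real
protein geometry: no side chains, no β-sheet hydrogen-bonding topology, no
peptide–groove chemistry. Tests passing on these fixtures validate the
computational machinery, not predictions about real complexes.

`make_synthetic_pae` plants the additive structure observed in predictor
confidence outputs: PAE = base + τ_i + π_j − β·1[cognate] + ε, with defaults
base 15 (typical interface-PAE magnitude), τ ~ N(0, 1.5²), π ~ N(0, 1²),
β = 3, ε ~ N(0, 1), 50 TCRs × 10 peptides, 50 background TCRs — the
benchmark's repertoire and candidate-set sizes. At β = 0 and zero noise the
corrected scores vanish identically; at β/σ = 3, pooling ten replicate
simulations (a single 50-row draw carries ~4% binomial noise), the wild type
ranks first for > 90% of TCRs and pooled AUROC exceeds 0.95.

Random docking geometries are sampled around a consensus mode
(d = 28 Å, torsion 1.2 rad, polar angles 0.35–0.40 rad) with polar angles
kept in (0.05, 1.4) rad — emulating the concentration of natural binding
modes around the diagonal consensus and keeping samples away from the chart
poles. All generators draw from a single seeded generator per call; fixed
seeds give byte-identical outputs.

## Numerical choices and limitations

* Rotation fitting: closed-form SVD with determinant correction throughout;
  degenerate geometry detected via the singular-value spectrum.
* Tolerances: frame orthonormality 1e-8; chart round trip 1e-6; hybrid
  realized-geometry check 1e-3 Å / 1e-5 rad; binding-score row means 1e-9.
* The 6-vector chart is local: geometries with the inter-origin direction
  near a frame x-axis (polar → 0) have ill-conditioned azimuths, and a
  reversed-polarity docking mode can wrap the torsion; the Z score is only
  meaningful within the consensus basin.
* Single linkage on small geometry sets can chain clusters whose separation
  is comparable to their internal spread; representative selection raises if
  the tree cannot be cut into exactly k clusters (e.g. duplicate geometries).
* All structure handling is Cα-only by design; all-atom RMSDs, DockQ-style
  interface quality, and physically realistic model geometry are out of scope.
* Problem sizes used by the test-suite and the reproduction script (24-
  geometry clustering sets, 20–30-structure synthetic databases, 50×10 PAE
  matrices, 10,000-sample calibration sweeps) were chosen as the smallest
  sizes at which the checked statistics are stable.
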