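# Methods

## Overview

`pmvnet` implements a motif-based analysis of individual brain
connectomes built from regional morphometry. The pipeline is:

1. **R2SN construction.** Each subject is described by a regions ×
   features table of radiomic-style measurements. Features are min-max
   normalized per subject, a cohort-level correlation-based selection
   retains a non-redundant subset (default 25 features, redundancy cap
   |r| ≤ 0.90), and the subject's Regional Radiomics Similarity Network
   (R2SN) is the region × region matrix of Pearson correlations between
   regional feature profiles.
2. **Edge labeling and triangle census.** Every edge carries a strength
   (R2SN weight) and a length (Euclidean distance between region
   centroids, mm). Both are dichotomized at cohort medians — strength
   pooled over all subjects' upper-triangle weights, length from the
   fixed atlas geometry — giving four edge classes (strong/weak ×
   long/short). A triangle's motif type is the *multiset* of its three
   edge classes; with 4 classes there are exactly C(6,3) = 20 types.
   Since the R2SN is complete, every region triple is a triangle; each
   triangle is credited once to each of its three member regions,
   yielding a 20 × N count matrix per subject whose columns each sum to
   C(N−1, 2).
3. **Principal Motif Value (PMV).** Each subject's count matrix is
   standardized per motif type (mean 0, variance 1 across regions,
   population-SD convention; zero-variance rows map to zeros). The
   cohort model pools the standardized region columns of all reference
   subjects as observations of a 20-dimensional motif variable,
   eigendecomposes the 20 × 20 covariance (n−1 divisor), and keeps the
   leading eigenvector as the loading. A region's PMV is the projection
   of its standardized motif profile onto this loading.
4. **Group statistics.** Shapiro–Wilk normality screening; per-region
   Kruskal–Wallis across diagnostic groups with Bonferroni correction
   (α/N); post-hoc Mann–Whitney Z-maps restricted to the significant
   set; Pearson clinical-correlation maps; Pearson agreement between
   Z-maps; Stouffer weighted-Z multi-site meta-analysis; partition
   (lobe / functional-network) summaries.
5. **Spatial association.** One-component PLS between a region × gene
   matrix and a target map (typically the NC-vs-AD Z-map) with add-one
   permutation significance, bootstrap gene Z-scores with top-k export,
   and a Pearson correlation panel against named receptor/gene maps.

## Key modeling choices

**PCA orientation.** The motif count matrix can be read with either
motifs or regions as variables. We standardize per motif type and build
the 20 × 20 motif covariance, because only this orientation produces a
per-region score (one PMV per region) and per-motif contribution
fractions (squared loadings). The opposite, region-as-variable
orientation is available for comparison as `pmv.literal_region_pca`; its
projection lives in motif space and cannot feed the regional group
statistics.

**Sign convention.** An eigenvector's sign is arbitrary, which would
make group comparisons irreproducible. The loading is sign-fixed so that
the homogeneous weak-short triangle type has a nonnegative loading; a
more positive PMV therefore marks regions whose triangles are dominated
by weaker, shorter connections. Repeated fits on identical input are
bit-identical.

**Cohort-common loading.** One loading vector is fitted on a reference
cohort (default: all subjects; configurable, e.g. controls only, or a
discovery dataset whose model is then applied to validation subjects)
and applied to everyone. Per-subject PCA would leave per-subject sign
and rotation ambiguity and break between-group comparability.
`pmv.per_subject_variance_explained` reports the per-subject leading
eigenvalue share for descriptive use.

**Tie handling.** Edge values exactly equal to a median fall on the
WEAK/SHORT side (≤ convention). Ties are measure-zero for
correlation-valued weights, so the convention only matters for
degenerate inputs; it is applied consistently.

**Negative weights** are classified purely by the threshold rule (no
absolute value is taken).

**Mann–Whitney Z.** Z = (U − n₁n₂/2) / √(n₁n₂(n₁+n₂+1)/12), without tie
correction: PMV values are continuous, making exact ties measure-zero.
A tie-corrected σ_U is available (`tie_correction=True`) for discretized
inputs. U is oriented as the statistic of the first group, so swapping
groups negates Z.

**Posthoc universe.** Mann–Whitney Bonferroni correction is applied over
the Kruskal–Wallis-significant region set by default; passing
`restrict_to=None` gives whole-brain maps (used for Z-map replication
comparisons, where restriction would misalign region sets).

**Meta-analysis.** Multi-site combination uses Stouffer's weighted Z
with default weights √(site sample size); weights are configurable.

**Feature selection rule.** "Correlation-based selection" is made
concrete as greedy elimination on the cohort-mean absolute feature
correlation: while any surviving pair exceeds the cap or more than the
target number remain, drop the feature with the highest mean absolute
correlation to the other survivors; ties drop the higher original index.
Both the target count (25) and the cap (0.90) are configurable. Note
the procedure can legitimately return fewer than the target count when
redundancy above the cap persists.

**PLS1.** With a single response, the first PLS component is closed
form: w ∝ Xᵀy (the direction NIPALS converges to in one step), scores
t = Xw, predictor-block variance share ‖t pᵀ‖²_F / ‖X‖²_F. The
implementation was cross-checked against scikit-learn's iterative fit
(agreement to 1e-10) and the closed form is what permutation and
bootstrap loops execute. Permutation p-values use the add-one rule
p = (1 + #{|r_perm| ≥ |r_obs|}) / (1 + n_perm), which is conservative by
construction. True spin tests require spherical cortical coordinates the
synthetic atlas lacks; the functions accept precomputed permutation
index rows from any external spatial-null tool and fall back to uniform
permutation, recording the mode in the result.

**Bootstrap gene Z-scores.** Regions are resampled with replacement,
each replicate's weight vector is sign-aligned to the original
component, and Z_g = original weight / bootstrap SE (n_boot default
1000). The top-k list (default 500, capped at the gene count) is
exported one symbol per line for external enrichment services.

## The synthetic cohort generator

The generator exists so every downstream stage is testable with known
ground truth; it emulates the *structure* of morphometric cohort data,
not any particular dataset.

- **Atlas.** Centroids uniform in an ellipsoid with semi-axes
  (65, 85, 60) mm; the innermost 15% of regions (by normalized radius)
  are labeled `subcortex` (functional label `none`), the next shell
  `limbic`, and the remaining cortex is split into lobe-like sectors by
  position and into 7 functional networks by azimuthal sector.
- **Feature archetype.** Regional profiles mix 5 smooth spatial
  gradients (linear coordinates, radius, one interaction) into features,
  plus region offsets and feature-specific regional idiosyncrasy
  (SD 0.6). One gradient loads positively on every feature
  (U(1.0, 2.0)), mimicking the shared morphometric component that gives
  real similarity networks their positive-median edge weights, while the
  idiosyncrasy keeps the 47 default features from being mutual
  near-duplicates (selection retains ≈ 25 at cap 0.90). Subject noise is
  i.i.d. Gaussian, SD 0.30 relative to per-feature scale.
- **Planted effects.** `strength-shift` adds a fixed feature-space
  direction (RMS 1 per feature, scaled by the subject's dose) to the
  target regions' rows, shifting their R2SN edges; `profile-decorrelation`
  adds dose-scaled subject-specific noise to the target rows only. The
  per-subject dose is effect_size × U(0.5, 1.5) for affected groups and
  0 otherwise, and is recorded on the SubjectRecord as ground truth.
  The default effect size 3.0 was calibrated once so that a 5-of-60-region
  strength shift at n = 20/group is recovered (≥ 4/5 regions) in ≈ 90%
  of replicates; the generator's defaults are frozen study conditions,
  not per-test dials.
- **Clinical scores** follow score = baseline + slope × dose + N(0, sd),
  so cognitive-style scores (negative slope) are lower in affected
  groups and correlate with regional alterations.
- **Spatial maps** use the mixture construction c·z(target) +
  √(1−c²)·z(noise), giving expected correlation c; `exact_corr=True`
  orthogonalizes the noise first (Gram–Schmidt) so the *sample*
  correlation is exactly c — used for planted-signal validation where
  "uncorrelated" must hold in-sample.

**What the generator does not emulate:** image acquisition and
site/scanner effects, real anatomical geometry and parcel adjacency,
spatial autocorrelation of gene-expression maps, realistic demographic
structure, longitudinal drift, and missing-data patterns. Passing tests
demonstrate the machinery is correct and calibrated under these
idealized conditions; they do not certify effect sizes or significance
levels on real cohort data.

## Numerical details

- Standardization uses population SD (÷N); covariance uses ÷(n−1).
- Constant features are hard errors in normalization (named, so callers
  can drop them); zero-variance regional profiles are hard errors in
  R2SN construction; zero-variance motif rows standardize to zeros.
- Degenerate permutation inputs (non-permutation rows) are rejected.
- Serialized matrices are written with 12 significant digits; R2SN
  symmetry and unit diagonal are restored exactly on read.
- Region order is always atlas order; tables arriving permuted are
  reordered (logged), mismatched region sets are errors naming the file
  and regions.

## Problem sizes used in validation

Test-suite simulations use 40–100 region atlases, 8–90 subject cohorts,
and 10–500 map panels; the error-calibration suites use 200 null
cohorts (3 × 30 subjects, 60 regions) and 50 recovery replicates, sized
so the whole suite completes in a couple of minutes while keeping
binomial confidence bands meaningful. The acceptance script runs a
90-region, 90-subject discovery + replication design with 500 genes,
999 permutations and 1000 bootstrap replicates.

## Known limitations

- The catalog's 1..20 type indexing is lexicographic in the edge-class
  order (SL < SS < WL < WS); published figure orderings of the same 20
  types may differ, so type indices are not comparable across software
  without checking the triple labels.
- The strength median is a pooled cohort property; applying a model to a
  new dataset either reuses the discovery thresholds (pass `thresholds=`)
  or re-pools within the new cohort — both modes are exposed, and they
  answer different questions.
- Uniform permutation nulls understate spatial autocorrelation; for real
  cortical maps, supply spin/variogram permutations from a dedicated
  tool.
- PLS variance-explained is reported for the predictor block; target-side
  shares differ and are not reported.
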