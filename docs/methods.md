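# Methods

## Scope and data model

The package starts from an aligned feature table — rows are molecular
features (an m/z, retention-time pair), columns are samples, entries are
relative intensities with missing values allowed — plus sample metadata
(season, cluster type, measurement batch, injection volume, replicate
structure), a samples x 15 sensory-attribute score table, and a compound
table for annotation. Raw-chromatogram processing (baseline correction,
noise removal, alignment) is out of scope: it happens upstream, in
vendor software. Positive- and negative-mode tables are treated as
separate datasets end to end.

Missing intensities are `NaN`; zero is a measured value. All summary
statistics (means, medians, variances) are computed over observed
entries only, because the missingness filter must see missingness, not
zeros.

## Preprocessing

Filters run in a fixed order, each with a strict inequality at its
boundary, and every removed feature is attributed to the first filter
that removes it (so report counts are additive):

1. *Low intensity*: mean observed intensity strictly below
   `frac = 0.001` of the highest per-feature mean.
2. *Missingness*: strictly more than `max_missing = 0.30` missing.
3. *Early elution*: retention time strictly below `min_rt = 0.45` min
   (the unretained solvent front); rt = 0.45 is kept.

Normalization is volume -> per-sample median -> within-batch per-feature
median. Dividing by volume first and the median second is mathematically
immaterial for the subsequent median division but fixes the convention.
Identities that hold exactly (and are tested to 1e-9): after the
per-sample step, every sample's median observed intensity is 1; after
the batch step, every feature's median within each batch is 1. The batch
step necessarily perturbs sample medians again, so the two identities
are per-stage, not simultaneous. A zero or undefined median (all-missing
sample, or feature unobserved within a batch) is an error naming the
offending sample/feature rather than a silent NaN.

## PCA (NIPALS with missing values)

Features are centered and scaled to unit variance (ddof = 1) over
observed entries; a zero-variance feature is an error. Components are
extracted sequentially by NIPALS alternating regressions in which each
regression sums over observed cells only — no imputation. Per-component
explained variance is the drop in residual sum of squares over the total
scaled sum of squares. On complete data this equals SVD-based PCA; the
suite asserts scores/loadings to 1e-6 and variance fractions to 1e-8
against an independent SVD oracle.

Numerical choices: scores are initialized from the residual column of
largest observed variance; convergence is a relative score change below
1e-12 with at most 5000 iterations (looser settings leave power
iterations visibly short of the SVD fixed point when trailing
eigenvalues nearly coincide); the sign convention makes each component's
largest-magnitude loading positive, so runs are bit-reproducible.

## Sparse PLS, sPLS-DA and VIP

X and Y are column-centered and unit-variance scaled (ddof = 1). Per
component, the dominant singular pair of the current cross-covariance
matrix `X_dᵀY_d` is found by alternating power iterations; at each step
the X-weight is soft-thresholded so that exactly `keepX` entries remain
nonzero (threshold = the (keepX+1)-th largest magnitude; boundary ties
break by feature order, falling back to hard selection when shrinkage
would annihilate a tied survivor), then renormalized. Scores are
`t = X_d u`; both blocks are deflated by regression on `t` (regression
mode), making score vectors mutually orthogonal. With `keepX = p` the
procedure is ordinary NIPALS PLS regression; the suite checks
prediction equality at 1e-8 against a closed-form SVD-based dense PLS
and against scikit-learn's `PLSRegression`.

Categorical responses (season, cluster type) are one-hot encoded and fit
through the same engine; prediction assigns the class with the largest
predicted indicator value. Each class needs at least two samples.

VIP for feature j over A components:

    VIP_j = sqrt( p * Σ_a SSY_a (w_aj / ‖w_a‖)² / Σ_a SSY_a ),
    SSY_a = ‖q_a‖² t_aᵀ t_a

Unit-norm weights give mean(VIP²) = 1 exactly — the scale that makes
VIP > 1 mean "above-average importance". A consequence worth knowing:
any feature with |w| > 1/sqrt(p) in a dominant component lands above 1,
so the number of supra-threshold features tracks `keepX` closely.

X must be complete for fitting; residual missing values (at most 30% per
feature survive the filters) are imputed with the per-feature median,
and the imputation is logged. Sensory scores are wine-level quantities;
every technical replicate inherits its wine's score, and one univariate
sPLS model is fitted per attribute. Solver tolerance is 1e-12 with at
most 500 iterations per component (univariate responses converge in one
step).

## Cross-validated hyperparameter search

For each (components, keepX) grid point, `n_repeats` independent k-fold
partitions (stratified by class for sPLS-DA) are scored: mean held-out
misclassification rate (sPLS-DA, minimized) or held-out Q² pooled over
folds (sPLS, maximized), averaged over repeats. The conventional full
grid is components 1–12 (1–3 for sPLS-DA) x keepX
{50, 100, 200, 300, 500, 1000} with 100 repeats of 5-fold CV; the
pipeline default is a reduced desk-scale grid (components 1–3, keepX
{50, 100, 200}, 10 repeats), with the full search behind
`--paper-grid`. keepX values above the feature count are clamped with a
warning; ties on the criterion resolve to fewer components, then smaller
keepX; everything is deterministic given the seed. Fold partitions come
from scikit-learn's `KFold`/`StratifiedKFold`.

## Networks

Per-attribute VIP vectors over a common feature universe become a
bipartite graph: an edge wherever VIP > threshold (default 1.0,
strictly), weighted by the VIP. Feature nodes appear only when incident
to an edge; attributes with no supra-threshold feature are kept and
flagged. Aroma (11 attributes) and taste (4) networks are built
separately by default. A zero threshold ("any positive VIP draws an
edge") is available as an explicit variant, but the default follows the
VIP > 1.0 convention used for reported networks. Raising the threshold
can only remove edges (tested). Summaries report edges per attribute and
features shared by two or more attributes as the connectivity measures.

## Annotation

Monoisotopic masses come from the NIST table via `pyteomics.mass`;
supported elements are C, H, N, O, P, S, Na. Adduct shifts are derived
at import time from the same table, electron mass included: M+H
+1.0072765, M+Na +22.9892207, M+NH4 +18.0338254, M−H −1.0072765,
M+AcOH−H +59.0138536 Da. Intrinsically cationic compounds (flavylium
anthocyanins, flagged `intrinsic_charge = +1`) are matched only as M+
(mass − electron) in positive mode — under neutral-M adducts alone they
could never match. The ppm error uses the theoretical m/z in the
denominator; a candidate matches when |ppm| ≤ 5 (inclusive). MSI levels:
2 when all candidates share one molecular formula, 3 when several
formulas fall in a single compound class, 4 otherwise (including no
candidate).

## Synthetic data generator

The generator emulates the study design, not any particular instrument:

* **Design**: 2 seasons x 3 cluster types x 4 biological x 3 technical
  replicates (72 samples); a wine = one biological replicate of one
  season/cluster cell; technical replicates share the wine's biology
  plus small technical noise (0.05 log10 units; biological noise 0.15).
* **Baselines**: per-feature log10 intensity from N(5, 1) truncated at
  ±1.25 sd. Truncation keeps the whole table inside the 3-decade window
  of the 0.1%-of-max filter so that the filter removes exactly the
  planted low-intensity features; a post-hoc guard lifts any non-planted
  feature that still lands within 2x of the threshold (rare).
* **Effects**: a fraction (0.30) of features carries per-season shifts
  ~ N(0, 0.6 log10), centered across seasons; a disjoint fraction (0.10)
  carries per-cluster shifts ~ N(0, 0.25). Effect sets are disjoint from
  biomarkers and from filter plants so every planted signal is
  attributable.
* **Sensory biomarkers**: each attribute owns 20 features (disjoint
  across attributes). The attribute's features load (±0.3 log10, random
  sign) on a latent per-wine factor — co-varying as co-regulated wine
  chemistry does — and the wine's score is the spec'd linear read-out:
  the signed sum of effect x standardized log intensity (averaged over
  the wine's replicates) plus N(0, 1) panel noise, on an arbitrary
  continuous scale (the real panel's scale is not public). Without the
  shared factor, 20 independent summands would cap each feature's
  score correlation at 1/sqrt(20) ≈ 0.22 and no method could rank 16 of
  20 markers into the top 50 at n = 72; the latent factor is what makes
  the planted truth recoverable at realistic sample sizes.
* **Batches**: per-(feature, batch) multiplicative sensitivity shifts
  (sd 0.10 log10). Batch membership is randomized but stratified by
  season x cluster type — a balanced block design, as randomizing run
  order before acquisition produces. This matters: season-imbalanced
  batches let the within-batch median normalization inject a
  season-correlated common offset that caps the PC1–season correlation
  near 0.8; balanced blocks restore it to ~0.998.
* **Missingness**: Bernoulli at 0.05, doubled for the lowest decile of
  intensities. Planted high-missing features get an exact 40% missing
  fraction; background features are capped at 28% so the strict 30%
  filter removes exactly the plants.
* **Planted annotations**: 10 features take the exact adduct m/z of
  bundled wine compounds (plus a configurable ppm offset); the bundled
  compound table is a synthetic fixture of ~30 well-known wine
  phenolics, anthocyanins and acids, not a database export.

Everything flows from one seeded generator: identical seed and
configuration give byte-identical outputs.

What the generator does **not** emulate: chromatographic peak shape,
isotope patterns, adduct cross-talk between co-eluting features,
nonlinear detector saturation, drift within a batch, panel-to-panel
scoring bias, or correlated missingness across samples. Passing tests
therefore demonstrate correctness of the statistical machinery under the
planted model, not performance on any specific real instrument's
quirks.

## Verification choices

* Filter exactness, normalization identities, determinism and the
  PC1-season pattern are checked on the default generator conditions
  over multiple seeds.
* The biomarker-recovery check runs the cross-validated per-attribute
  sPLS at the reduced grid (10 repeats) on 2000 features / 72 samples
  and requires ≥ 16 of 20 planted features in the top 50 by VIP for
  every attribute, in at least 4 of 5 seeds.
* The permutation-null check compares sPLS-DA CV error on effect-free,
  label-permuted data against chance (2/3 for three balanced classes).
  One permutation's CV error is approximately Binomial(72, 2/3)/72 —
  repeated CV on the same permutation does not shrink that — so the test
  averages 6 permutations and uses a 3-standard-error band.
* The network-modularity check (≥ 90% of edges within each attribute's
  own planted set) parameterizes the per-attribute model at one
  component with keepX = 20, the planted cardinality. This isolates the
  network rule from an artifact of the VIP scale: with keepX = 50, every
  selected feature with |w| > 1/sqrt(p) clears VIP > 1, so over-selected
  models dilute within-set fractions to ~40–55% regardless of effect
  size.
* Problem sizes in the suite (tables up to 2000 x 72, grids of 9 points
  x 10 repeats) are chosen so the whole suite runs in a couple of
  minutes on one CPU; they match the generator's default study size.

## Known limitations

* sPLS assumes complete X; median imputation of residual missingness is
  crude (adequate below the 30% filter ceiling, biased beyond it).
* The CV criterion for sPLS is held-out Q² pooled per repeat; attributes
  with near-zero signal can give negative Q² across the whole grid, and
  the selected pair is then merely the least bad.
* Annotation is exact-mass only: isomers are indistinguishable (hence
  MSI levels), and MS2 confirmation is out of scope.
* The VIP > 1 edge rule inherits the VIP scale's dependence on keepX
  (see above); compare networks only across models with comparable
  sparsity.
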