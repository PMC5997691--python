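# Methods

`tsradiomics` implements a CT-radiomics analysis chain for a binary tumor
phenotype — thymidylate synthase (TS) expression status in advanced lung
adenocarcinoma — and a synthetic-phantom generator that makes every stage of
the chain testable without patient data.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
validation does and does not demonstrate.

## The feature panel

Each lesion is an aligned pair (CT volume in HU, binary ROI mask) with
physical voxel spacing.  The extractor emits exactly 60 named features,
fixed by the shipped manifest (`manifest.yaml`, version 1):

| family | count | content |
|---|---|---|
| whole-ROI histogram | 19 | mean, median, min, max, range, sd, variance, skewness, kurtosis, energy, entropy, RMS, IQR, MAD, UPP, percentiles 2.5/25/75/97.5 |
| outer rim | 9 | mean, median, sd, min, max, skewness, kurtosis, energy, entropy of the rim sub-ROI |
| delta (core − rim) | 9 | the same nine statistics, core minus rim |
| shape | 10 | volume, surface area, surface/volume, compactness, sphericity, convexity, max 3D diameter, elongation, density, mass |
| GLCM | 11 | autocorrelation, contrast, correlation, dissimilarity, energy, entropy, homogeneity, cluster shade, cluster prominence, sum average, variance |
| ISZ | 2 | intensity variability, size-zone variability |

Conventions that a reimplementation must match to reproduce values:

* **Moments.** Population (1/N) central moments; skewness = m3/m2^1.5;
  kurtosis = m4/m2² (Pearson, non-excess, Gaussian = 3).  The Pearson
  convention is what makes double-digit kurtosis values typical for
  heavy-tailed tumor histograms.
* **Energy and RMS.** Energy = Σx² over raw HU (intensity-based, following
  the common open-source radiomics convention); RMS = √(Σx²/N).
* **Histogram entropy / UPP.** 256 fixed-width bins spanning the ROI's own
  [min, max]; entropy in bits with 0·log 0 := 0; UPP sums squared bin
  probabilities over bins whose *center* exceeds 0 HU.  Because the binning
  range tracks [min, max], entropy is invariant under a constant HU shift.
* **MAD** is the mean absolute deviation from the mean (not the median-based
  variant).  Percentiles interpolate linearly.
* **Density / mass.** density = mean HU + 1000 (a water-referenced linear
  rescale, so air ≈ 0 and water ≈ 1000), mass = volume · density.  Units are
  nominal; the features act as intensity–volume composites.
* **Degenerate inputs.** A statistic whose definition collapses (skewness of
  a constant sub-ROI, correlation of a single-gray-level GLCM, hull of a
  coplanar mask) is reported as NaN with a recorded reason, never dropped:
  a feature vector always carries exactly 60 keys.

### Core/rim partition

The ROI is split purely by volume: every foreground voxel is ranked by its
exact Euclidean distance (physical mm, anisotropy-aware, array boundary
counted as background) to the nearest background voxel, and the floor(N/3)
voxels nearest the boundary form the outer rim; the rest are the core.
Distance ranking realizes "1/3 of the volume, geometrically outside" with an
exact, deterministic count; ties are broken by lexicographic (z, y, x) voxel
index so the split is bit-reproducible across platforms.  Disconnected ROIs
share one global distance field.  Masks with fewer than 27 foreground voxels
are rejected as too small to partition meaningfully.

### Texture matrices

The GLCM discretizes ROI intensities to 256 fixed-width bins over the ROI's
[min, max], accumulates co-occurrences over the 13 unique distance-1
direction offsets (the 26-neighborhood modulo sign), symmetrizes and
normalizes each direction's matrix to unit sum, and averages the matrices of
all directions with at least one in-mask pair.  GLCM feature formulas use
1-based bin labels.  The ISZ (size-zone) matrix discretizes to 32 levels and
counts 26-connected components of constant level; intensity variability and
size-zone variability are the squared row/column sums divided by the total
zone count.  Both matrix builders are validated against brute-force
nested-loop enumeration on random 8³ phantoms (exact equality).

### Shape

Surface area triangulates the 0.5-isosurface of the (zero-padded) binary
mask via marching cubes.  Convexity compares voxel counts inside the mask
and inside the convex hull of foreground voxel centers (a voxelized hull);
this keeps convexity ≤ 1 and scores a convex digital shape ≈ 1, where
dividing a voxel-count volume by a continuous hull volume would not.  The
maximal 3D diameter is the farthest foreground pair, found on the hull
vertices.  Elongation is √(λ₂/λ₁) of the physical-coordinate covariance
(sphere ≈ 1).

## Patient-level analysis

Per patient, at most five lesions enter (always the single primary; other
lesions ranked by longest diameter, ties by lesion id), and the patient
vector is the element-wise mean of the selected lesions' vectors with NaNs
excluded pairwise.

**Screening.** Each clinical variable (age, sex, smoking, EGFR by default)
and each of the 60 features is screened against the TS label with a
univariate logistic model (Newton/IRLS, tolerance 1e-8, ≤ 50 iterations).
Continuous predictors are standardized first, so odds ratios are per SD;
binary predictors keep their 0/1 coding, which makes the fitted OR equal the
2×2 cross-product ratio.  Wald 95% intervals and two-sided Wald p-values;
significance at p < 0.05 with no multiplicity correction by default
(Benjamini–Hochberg behind a flag).  Complete separation is flagged, not
raised.

**Prediction.** A seeded 10-fold cross-validation: shuffle + round-robin
fold assignment (optionally label-stratified — recommended at small n, used
by the acceptance analysis); per fold, variable selection on the nine
training folds, a 500-tree random forest on the selected variables, and
out-of-fold probabilities; all out-of-fold probabilities are pooled into a
single ROC whose AUC (computed as the Mann–Whitney statistic, ties counted
half) summarizes the model.  Two models on the same patients are compared
with the DeLong structural-component test; its variance estimator is exactly
the per-class delete-one jackknife, which the tests verify to 1e-10.

**Variable selection.** A two-stage forest-based procedure in the spirit of
Genuer-style selection: (1) *thresholding* — 25 forests are grown, each with
a pure-noise probe column (a permuted copy of a real column) appended and
with permutation importances scored on a held-out third of the training
rows; variables whose mean importance does not exceed the probe's mean are
discarded.  (2) *interpretation* — survivors are ordered by importance and
nested forests are grown over importance-ranked prefixes (up to 12); the
smallest prefix whose out-of-bag error is within one binomial standard error
of the best is kept.  The one-SE rule (rather than a plain arg-min over
prefixes) is what collapses the selection to one or two variables on pure
noise — OOB error under the null is flat, so its arg-min is essentially
uniform over prefix lengths — while leaving genuinely informative variables
in: a planted 1.5-SD mean shift among 20 noise variables is recovered in
over 90% of runs.  Forest sizes (25 selection forests × 25 trees, 50-tree
nested forests, 500-tree final model) balance selection stability against
single-CPU runtime.

**Survival.** Kaplan–Meier product-limit curves and the two-group log-rank
test (events precede censorings at tied times), delegated to lifelines, with
per-group observed/expected event counts recomputed from the hypergeometric
risk tables (they satisfy Σ(O−E) = 0 and match a hand-built risk-table
oracle to 1e-10).

## The synthetic cohort generator

The generator emulates the cohort structure the analysis assumes, not real
CT physics.  Defaults (the study conditions used throughout the tests and
the acceptance script):

* 169 patients, TS-positive fraction 85/169.
* Age ~ Normal(60, 8) years; smoking ~ Bernoulli(0.5); the TS label follows
  logit p = β₀ + 0.5·z_age + 0.84·smoke, with β₀ solved by bisection
  (tolerance 1e-4) so the marginal TS-positive fraction is exact.  The
  smoking coefficient is the log crude odds ratio of a 52/32 vs 35/50
  never/ever split; both effects point the observed way (older, smoking →
  TS-positive).
* 1–5 lesions per patient (first is the primary) with count distribution
  {1: 0.55, 2: 0.25, 3: 0.12, 4: 0.05, 5: 0.03}, mean 1.76.
* Each lesion is a volume-preserving ellipsoidal perturbation of a sphere
  (radius 6–12 voxels, primaries drawn from the upper half), HU profile:
  core 60 HU over the inner 2/3 of the volume, linear ramp to 20 HU at the
  surface, Gaussian noise (sd 15 HU), and a low-HU tail mixture — each
  foreground voxel is replaced with probability ε by a Uniform[−900, −400]
  draw (an air/necrosis surrogate).
* Survival: exponential OS with TS-negative median 25 months and hazard
  ratio 2.0 for TS-positive; PFS median 8 months with HR 1.3; independent
  Uniform(0, 48) censoring.  All in months.

**The tail-fraction dial.** For a far-outlier mixture the moments are
dominated by the tail: skewness ≈ −(1−2ε)/√(ε(1−ε)) and kurtosis ≈ 1/ε.
Both *magnitudes therefore shrink* as ε grows beyond the extreme-rarity
regime.  Turning the dial up from zero makes skewness more negative and
kurtosis larger (the property the tests check pairwise at 0 vs 0.05), but
between two non-zero settings the *smaller* fraction gives the more extreme
moments.  The group defaults — ε = 0.05 for TS-positive vs 0.065 for
TS-negative, with a per-patient Normal(group mean, 0.015) spread truncated
to [0, 0.45] — give the TS-positive group the more negative skewness and the
larger kurtosis, i.e. the published direction of the group difference.  The
per-patient spread exists because without it group membership is an almost
deterministic function of texture and cross-validated AUCs saturate at 1.0,
which no clinical cohort resembles.

**What the phantoms do not model:** scanner PSF and reconstruction-kernel
effects, correlated (non-white) CT noise, partial-volume effects at the
mask boundary, respiratory motion, and anatomically realistic lesion shape.
Passing tests therefore demonstrate that the *pipeline machinery* is
correct and calibrated (exact matrix construction, honest cross-validation,
nominal type-I error, recovery of planted effects of known size) — not that
the features would discriminate TS status on real CT at any particular AUC.

## Randomness and reproducibility

One master seed drives everything through named `numpy` SeedSequence
substreams (clinical, phantoms, survival; per-fold forest seeds derived by
counter).  A cohort, a fold assignment, and a CV result are each
bit-reproducible from their seed.  Hypothesis-based property tests run
derandomized.

## Problem sizes used in validation

The statistical checks run at sizes chosen for single-CPU execution:
type-I error of the DeLong and log-rank tests at 2,000 null simulations
(n = 200 each); null cross-validated AUC as the mean over 20 seeds at
n = 400 with 10 noise features (the band 0.44–0.56 is ±2 SE of a single
run's AUC, so individual seeds scatter more widely than the mean);
selection recovery over 50 replicates at n = 400 with 21 variables; AUC
monotonicity in effect size at shifts {0, 0.6, 1.5} SD, six seeds each at
n = 200; log-rank power at HR 2 with n = 300 over 200 simulations.  The
acceptance script runs the full pipeline once at the default cohort size
(169 patients, ~290 lesions).

## Known limitations

* The 60-feature identity list fixes reasonable members for panel slots the
  published feature families name only by example; renaming or swapping a
  member is a manifest edit, not a code change.
* The variable-selection procedure is a simplified two-stage realization;
  the original CART-based importance-threshold step is not implemented.
* Odds-ratio scales from univariate screening are per-SD for continuous
  predictors by construction and are not comparable to crude per-unit ORs.
* The log-rank and KM implementations handle exactly two groups.
* No DICOM ingestion; NIfTI-1 is the only image format read or written.
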