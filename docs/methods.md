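# Methods

## Rating data model

Ratings live in a three-way array (items × features × raters, or
items × features × rounds for the machine annotator) with NaN marking
missing cells. All analyses run on a bounded scale, by default [0, 10];
input on another scale (e.g. a 0–100 slider) is mapped affinely. Means
over raters or rounds are missing-aware: a cell's mean uses whichever
raters responded, and is missing only when none did. Items the machine
refused in every round are dropped from all machine–human pairing.
Features are excluded before any correlation stage when their human
mean is at the scale minimum for every item (the feature was never
perceived) or constant across items (its correlations are undefined).

All pairwise statistics use pairwise-complete items and require at
least 3 complete pairs; a correlation that cannot be formed (too few
pairs, or a constant vector) is NaN and is excluded from averages, with
exclusion counts surfaced where they matter.

## Agreement indices

* **Machine agreement**: per-feature Pearson correlation between the
  machine mean (over rounds) and the human mean (over raters) across
  shared items.
* **Intersubject consistency**: for each rater, the correlation of
  their ratings with the mean of all other raters; the per-feature
  index is the mean over raters with a defined correlation. This is the
  leave-one-out reliability of a single human against the population
  average.
* **Group consistency**: raters are split into two disjoint groups of
  size g; the two group means are correlated; the index averages over
  all unordered disjoint pairs of size-g subsets,
  C(R,g)·C(R−g,g)/2 of them (126 for R = 10, g = 5 — each unordered
  pair is counted once, since the ordered enumeration counts it twice).

Sets of per-feature indices are compared with a Welch (unequal
variance) two-sample t-test on Fisher-z (artanh) transformed values,
two-sided, with the direction reported as the sign of the mean
difference. The pooled-variance form and the tail convention are
genuinely open choices; Welch/two-sided is the conservative default.
Correlations at ±1 are clipped to ±(1 − 1e−7) before the transform,
with a warning. Exceedance fractions ("agreement higher than the
benchmark for X % of features") use strict inequality and drop
feature pairs where either index is undefined.

## Representational structure

Feature × feature Pearson correlation matrices are computed
pairwise-complete across items. Two matrices are compared by the
Pearson correlation of their strict upper triangles (F(F−1)/2 values).
Significance comes from a Mantel permutation test: the same random
permutation is applied jointly to the rows and columns of the second
matrix, and p = (#{null r ≥ r_obs} + 1)/(N + 1). The permutation loop
is vectorised in blocks, the generator is seeded, and an exhaustive
mode enumerates all F! permutations for small F (used to validate the
Monte-Carlo path). Only the second matrix is permuted; the statistic is
identical to the plain matrix similarity.

PCoA (classical MDS) uses the correlation distance d = 1 − r. The
alternative chordal form sqrt(2(1 − r)) is available behind a
parameter but is not the default: 1 − r stays closest to treating the
correlation itself as the distance, and the downstream loading
comparisons are insensitive to the monotone change. Squared distances
are double-centred with the Gower projector B = −½ J D² J; coordinates
are eigenvectors scaled by the square root of their eigenvalues.
Because 1 − r is not guaranteed Euclidean, negative eigenvalues can
occur; they are dropped and counted rather than imaginary-scaled, and
variance fractions are taken over the positive part of the spectrum
only. Eigenvalues within 1e−10 (relative) of zero are treated as null
and excluded, so a request for more components than the matrix supports
truncates with a warning.

Loading concordance correlates the loadings of every component pair
across features and reports |r| — the sign of an eigenvector is
arbitrary, so only magnitude is meaningful — with two-sided p-values
from the exact t-transform of r on F − 2 degrees of freedom and a
significance mask at α = 0.001 by default.

## fMRI encoding

The canonical double-gamma HRF is the difference of two gamma
densities (response peak delay 6 s, undershoot delay 16 s, unit
dispersions, peak:undershoot ratio 6, 32 s support), normalised to
unit peak. Feature regressors are built as boxcars at 16 microtime
bins per TR carrying each clip's rated intensity over its duration,
convolved with the HRF, sampled at volume onsets t = n·TR, and
mean-centred.

First-level fits are simple regressions — one feature at a time, an
intercept plus the feature regressor, independently at every voxel —
so collinearity between features never enters a fit by construction.
Group maps are one-sample t-tests across subjects (df = n − 1) with
one-sided p-values for positive effects, since the comparison targets
positive feature tuning. Thresholding is p < α uncorrected or
Bonferroni voxel-level FWE at α/V over the V in-mask voxels; Bonferroni
is a deliberately conservative voxel-level family-wise error control
and slightly undershoots less conservative corrections. Zero-variance
voxels are flagged NaN rather than thresholded.

Two stimulus models are compared by (i) the spatial Pearson
correlation of unthresholded group beta maps per feature, (ii) PPV =
TP/(TP+FP) and NPV = TN/(TN+FN) of the test model's thresholded maps
with the reference model's maps as ground truth (undefined when the
positive or negative set is empty, flagged NaN), and (iii) the spatial
correlation of cumulative maps — the per-voxel count of features
passing the lenient threshold.

## Synthetic data

The generator plants a K-dimensional latent structure (default K = 8):
feature loadings are Gaussian with component strengths decaying
linearly from 1.6 to 0.6 so the planted components have distinct
variances and a stable recovery order; item scores are standard
normal. True intensities are the affine image of scores·loadingsᵀ
centred at 5 with across-item sd 1.5, clipped to [0, 10] — mild
clipping (values sit mostly within 2 sd of the midpoint) that
reproduces the floor compression of bounded rating scales. Rater noise
is Gaussian with per-feature sd solved from the target single-rater
consistency ρ via ρ = 1/√((1+v)(1+v/(R−1))), v the noise-to-signal
variance ratio; the default ρ = 0.6 with 10 raters matches a
mid-reliability rating study. The noise form is a modelling choice —
real rating noise is not stated anywhere — and the calibration is
validated by Monte-Carlo in the tests (empirical consistency within
±0.05 of the target).

The machine annotator re-rates the true intensities over 5 rounds
(default), each round applying a compressive low-end bias — values
below the scale midpoint 5 are multiplied by (1 − floor_bias), values
at or above 5 pass unchanged, continuous at 5 when floor_bias = 0 —
plus Gaussian round noise, clipped; a fail_rate fraction of items is
refused in all rounds. The bias sits on the machine side only,
mirroring the asymmetry it emulates: machine annotators tend to
under-rate weak feature presence while agreeing on strong presence.

Synthetic BOLD uses the study's acquisition dimensions (TR 2.6 s, 467
volumes) with clips packed 8 s on / 4 s off (≈ 90 clips per run). A
sparse tuned_fraction (default 5 %) of voxel × feature cells carries a
positive true beta; subject betas add Gaussian jitter and the signal
is the subject-beta-weighted sum of the convolved regressors plus
white noise. Noise and jitter default to a calibration that puts the
group-level effect size at tuned voxels at d = 1.1 with 40 % of the
between-subject sd from genuine subject variability: with 20 subjects
and a one-sided p < 0.001 threshold, d = 1.1 gives a-priori power
≈ 0.88, comfortably above the 0.8 sensitivity the recovery checks
demand, whereas d = 1.0 sits at ≈ 0.79 — right on the boundary, which
would make recovery a coin flip rather than a property. Recovery tests
use zero-mean per-feature amplitudes (modulation around the stimulus
mean): with a common positive amplitude mean, every regressor shares
the stimulus-on envelope, the simple-regression model is misspecified
for the planted single-feature tuning, and cross-feature leakage
inflates the false-positive rate against the planted truth — an
artefact of measuring against a planted truth, not of the method.

### What the synthetic data does not emulate

Real stimuli, prompts and annotator internals; non-Gaussian and
rater-specific response styles (scale use, anchoring); temporal
autocorrelation, drift and motion structure in BOLD; spatial
correlation between voxels (voxels are independent here, so
cluster-level behaviour is out of reach by design); negative voxel
tuning. Passing tests therefore demonstrate the correctness and
calibration of the statistics under the planted model, not performance
on any real dataset.

## Problem sizes

Validation runs use 200 items × 136–200 features × 10 raters for the
rating stages, 10,000 Mantel permutations (the production default of
10⁶ is a parameter), 20 subjects × 2000 voxels for tuning recovery and
10 subjects × 500–800 voxels for map comparisons; these sizes give
stable estimates of every index while keeping a full run in minutes on
one core.

## Known limitations

* Pairwise-complete correlations can use different item subsets per
  feature pair; with heavy missingness the correlation matrix need not
  be positive semidefinite (PCoA handles this via the negative
  eigenvalue policy).
* Bonferroni FWE is conservative relative to random-field or
  permutation-based FWE; conservative PPV/NPV values shift accordingly.
* The Mantel test permutes features jointly in both axes of the second
  matrix; it assumes exchangeability of features under the null, as
  usual.
* The encoding stage models no nuisance regressors; BOLD inputs are
  assumed preprocessed.
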