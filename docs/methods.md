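# Methods

`crossnum` implements a complete analysis chain for a two-group
(children with mathematical disabilities, MD, vs typically developing
controls, TD), two-session (pre-/post-tutoring) study of cross-format
number processing: behavioral comparison-task scoring, first-level GLM
estimation of the neural distance effect, searchlight cross-format
neural representational similarity (NRS), group inference with
cluster-extent family-wise error (FWE) control and FDR-corrected ROI
follow-up, and linear-SVM classification with permutation testing.
Because no subject-level data are deposited for this paradigm, the
package ships synthetic-data generators that plant known effects, so
every stage is validated by parameter recovery rather than by
reproducing undeposited numbers.

## Task design

The comparison task is a two-alternative forced choice over digit pairs
drawn from 1–9 excluding 5, crossing pair size (little: sum < 10; big:
sum > 10) with numerical distance (near: |a−b| = 1; far: |a−b| = 5).
Each run holds 64 trials, 16 per cell. The admissible pairs per cell are
few (2–3), so cells are filled by balanced repetition (counts differing
by at most one) and the larger number's side is balanced 8/8 within each
cell — the side balance is an assumption, stated as an invariant. Trial
order is pseudorandomized deterministically from the seed.

## Behavioral model and statistics

Trials faster than 150 ms are discarded. Efficiency E = accuracy /
median RT (1/s) guards against speed–accuracy trade-offs; accuracy uses
the post-filter trial count and median RT is taken over correct
post-filter trials (a convention choice — the source conventions are
unstated). Between-format dissimilarity D = |E_nonsymbolic −
E_symbolic|; an RT-based variant is available behind a flag.

Group tests are Welch t (Satterthwaite df — the non-integer dfs the
design reports imply unequal-variance tests) with pooled-SD Cohen's d;
within-group change uses the paired t with d = mean(diff)/sd(diff); the
2×2 mixed ANOVA (between: group; within: time) reports generalized eta
squared η²_G = SS_effect / (SS_effect + all subject-level and error SS).
The tabular ANOVA is computed by pingouin and is cross-checked in the
test suite against an explicit sums-of-squares decomposition; the
voxelwise interaction map uses the identity (exact for two timepoints,
including unbalanced groups) F_interaction = t², where t is the pooled
two-sample t on per-subject post-minus-pre differences.

The behavioral generator draws per-trial RTs log-normally (positive,
right-skewed, the standard RT family) around subject-level medians,
accuracy Bernoulli per trial around subject-level rates, and injects a
2% rate of sub-150 ms guesses so the trial filter has real work. Default
cell means plant: MD-pre dissimilarity ≈ 0.34 (1/s) vs TD-pre ≈ 0.06,
with MD decreasing and TD increasing after tutoring (a crossover
interaction); arithmetic-fluency standard scores MD 84 ± 7 with mean
gain ≈ 6 (paired d ≈ 0.9) vs TD 102 ± 8 (group gap d ≈ 2.3). A latent
per-subject responder factor couples the MD fluency gain to
post-tutoring symbolic-RT improvement (`responder_rt_sigma` = 0.10 log
units per SD), which makes fluency gains negatively correlated with
dissimilarity change. The absolute value in D folds the coupling
whenever the format gap changes sign, capping the attainable
correlation near −0.2 to −0.4 — matching the weak coupling such designs
report. Rosters default to 25 MD / 28 TD (behavioral) and 19 MD / 21 TD
(imaging).

## First-level GLM

Each of the four correct-trial conditions is a 2500 ms boxcar convolved
with a double-gamma canonical hemodynamic response (response gamma
shape 6, undershoot shape 16, ratio 1/6 — the standard
parameterization; its shape is cross-checked against nilearn's SPM-style
response) plus its temporal derivative; incorrect trials form an error
regressor with the same two bases (dropped, with a warning, when no
errors exist — an all-zero column would be rank-deficient); six motion
series and an intercept complete the 17-column layout. Serial
correlation is handled with a single pooled lag-1 autoregressive
coefficient estimated from in-mask OLS residuals followed by one-pass
Cochrane–Orcutt prewhitening with Prais–Winsten scaling of the first
sample; per-voxel AR estimation is out of scope. The Near-vs-Far
contrast applies ±½ weights to the four canonical condition betas only
(derivative betas excluded — the canonical-only reading of the
contrast), averaging over the size factor. No high-pass filter is
applied by default. The time-series simulator adds AR(1) noise and
linear leakage of random-walk motion series; overlapping events raise
rather than being merged.

## Searchlight NRS

For every in-mask voxel, the Pearson correlation between the
nonsymbolic and symbolic Near-vs-Far contrast patterns is computed over
a 6 mm sphere (inclusive boundary: 123 voxels on a 2 mm grid; a strict
boundary would give 93) intersected with the mask. Centers with fewer
than `min_voxels` = 10 valid voxels, or a constant pattern, are missing;
missing values propagate and a voxel enters group maps only when valid
for every contributing subject. The correlated quantity is one contrast
value per voxel per task. Fisher z is available as an optional monotone
transform; group statistics run on raw r by default.

## Contrast-map generator

Per subject and session, map pairs come from the shared-field mixture
x_ns = √ρ·s + √(1−ρ)·e₁, x_sym = sign(ρ)·√|ρ|·s + √(1−|ρ|)·e₂ with
independent unit-variance Gaussian fields, so the voxelwise cross-map
correlation equals ρ exactly in expectation; |ρ| = 1 is kept exact as
the degenerate mixture. Fields may be smoothed to a given FWHM and are
re-standardized so smoothing preserves ρ. ρ varies by ROI, group and
session; defaults plant the inverted-U structure: ROI ρ = 0.45 for
TD-pre and MD-post, 0.15 for MD-pre and TD-post, background 0.10
throughout.

Between-subject variability of ρ is drawn in Fisher-z space (a shared
subject component plus independent per-ROI components), which keeps ρ
inside (−1, 1) without clipping; sessions are drawn independently (no
within-subject carryover is modeled). Two dispersion regimes are used:

* the volumetric generator defaults (shared 0.03, per-ROI 0.06, field
  FWHM 3 mm) are deliberately **validation-scale** — small enough that
  the planted group contrast is unambiguous at conventional
  cluster-corrected thresholds with ~20 subjects per group. These were
  fixed by a design-phase power pilot of the full pipeline, before any
  recovery checks were frozen.
* region-level feature simulation (`simulate_roi_features`, used for
  the classification read-outs) uses a weak shared component (0.05) and
  dominant per-region dispersion (0.28) plus the sampling noise of a
  123-voxel correlation, calibrated so a planted group difference of
  0.30 corresponds to a per-region d ≈ 1 — the regime in which a ~0.85
  cross-validated accuracy over 20 regions is expected rather than
  saturated.

The default grid is 30³ voxels at 2 mm with an ellipsoidal mask
(~11,000 voxels) holding three radius-4-voxel spherical ROIs at the
vertices of an equilateral triangle, mutually ~13.5 voxels apart. The
geometry matters: searchlight maps smear planted effects by the sphere
radius (3 voxels), so ROI edges must stay ≥ ~5 voxels apart or
suprathreshold clusters bridge between regions — bridging both confuses
detection accounting and inflates the circularity bias of the
normalization read-out (bridge voxels are maximally noise-selected). A
24³ grid cannot hold three such ROIs with that separation plus a mask
margin, which is why the default is 30³.

## Group inference

Voxelwise two-sample maps use pooled-variance t (the mass-univariate
convention; Welch is available by flag, and the behavioral tests default
to Welch). Cluster-forming thresholds are applied two-tailed to |t| with
face (6-neighbor) connectivity; positive and negative suprathreshold
sets are labeled separately so opposite-sign clusters never merge.
Cluster labels are deterministic (descending peak |statistic|, ties by
lexicographic peak coordinate).

The cluster-extent threshold k is the smallest extent such that the
fraction of simulated null fields containing any suprathreshold cluster
≥ k is ≤ the FWE level (defaults: voxel p < 0.005, FWE p < 0.01). The
default null model is white Gaussian noise smoothed to a configurable
FWHM (6 mm), masked and variance-normalized. For statistic maps derived
from searchlight correlations this Gaussian null is anticonservative:
the sphere-overlap covariance of searchlight maps is compact and
near-linear in distance, so a Gaussian field of matched local smoothness
under-produces large null clusters (piloted: k = 40 under a 6 mm
Gaussian vs k ≈ 58 under the matched null on the same mask, with
background false clusters surviving the Gaussian k). The pipeline
therefore passes `searchlight_radius_mm`, which additionally convolves
the null fields with the searchlight's uniform ball kernel plus the
residual Gaussian FWHM/√2 carried by products of smoothed fields. The
extent threshold is a procedure, not a constant: its value depends on
the mask and smoothness in use. Estimating k at FWE 0.01 is a tail
problem: choosing the smallest k whose empirical exceedance falls below
0.01 from only ~1000 null fields rides the sampling noise of the 99th
percentile and lands on an anticonservatively small k; about 5000
calibration fields are needed before the chosen k's true exceedance
reliably sits inside 0.01 + 2 MC-SE.

ROI follow-up compares per-subject ROI-mean NRS (MD-post vs TD-pre)
with Welch tests and Benjamini–Hochberg FDR across ROIs; the
"normalization" read-out is the absence of FDR-significant differences.
Because the ROI set is selected from the pre-tutoring TD>MD contrast,
the comparison is mildly circular: suprathreshold voxels are enriched
for high TD-pre noise, inflating TD-pre ROI means by a few hundredths of
a correlation unit. This selection bias is a real property of the
circular design (present in any reuse of selection data) and is the
main reason the read-out's false-positive rate sits slightly above the
nominal Simes rate; the package mitigates it only through geometry (no
cluster bridging) and documents it as a limitation. The inverted-U
summary averages per-ROI means (unweighted across regions) per subject
and runs paired t tests per group plus the 2×2 interaction on the
summary scores.

## Classification

Linear SVM (C = 1), stratified k-fold cross-validation (default 10)
with seeded shuffling, and per-fold feature standardization fit on
training folds only. Features are ROI-mean NRS at a stated session or
post-minus-pre changes, with manifest-ordered columns. Significance uses
label permutations with the full cross-validation re-run per
permutation and the add-one estimator p = (1 + #{perm ≥ observed}) /
(n_perm + 1), so p ≥ 1/(n_perm + 1) and is never zero. Accuracy ties
between permutations and the observed value count against rejection,
making the test slightly conservative on coarse accuracy grids (small
samples, few folds).

## Numerical choices and problem sizes

Tolerances: searchlight equals a brute-force per-center loop to 1e-12;
all scalar statistics match independent sums-of-squares/formula oracles
to 1e-10; Fisher z clips |r| at 1 − 1e-7. Degenerate inputs are errors
(zero-variance samples, subjects missing a session, empty ROIs, events
outside the scan, rank-deficient designs) rather than silent repairs,
except where a zero is the mathematically correct value (identical
samples in a two-sample test; no change anywhere in the interaction
map).

The shipped validation sizes are: 2000 vectorized null datasets for the
mixed-ANOVA type-I check; 500 null datasets × 39 permutations × 5 folds
for the SVM permutation type-I check; 1000 calibration + 1000 fresh
null fields (24³, FWHM 6 mm) for the FWE check; and 20 simulated
cohorts of 19 + 21 subjects at the default 30³ grid (200 Monte-Carlo
fields and 199 permutations per cohort) for the end-to-end recovery
checks. The acceptance script runs one cohort at 1000 Monte-Carlo
fields and 5000 permutations.

## What the generators do and do not emulate

The generators reproduce the *structure* of the study — the factorial
design, the two-group × two-session roster, planted dissimilarity and
cross-format-correlation effects, AR(1) noise and motion leakage — but
not scanner physics, preprocessing artifacts, anatomical variability,
non-Gaussian RT contamination beyond fast guesses, or any model of the
tutoring process itself. Passing recovery tests therefore demonstrates
that the analysis chain is correct and calibrated under its stated
assumptions, not that those assumptions hold in any particular real
dataset. Known limitations: the circular-selection bias of the
normalization read-out described above; a single pooled AR(1)
coefficient rather than per-voxel noise models; session independence of
subject-level variability (no test–retest correlation); and unweighted
ROI averaging in the inverted-U summary (ROI sizes are similar by
construction; a size-weighted alternative would differ for very unequal
regions).
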