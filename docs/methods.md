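# Methods

## Problem and scope

`samplecast` treats one question: given n cases with p numeric features
and a binary outcome, decide whether the features carry information for
the classification task and estimate the Youden index (YI) or AUC a
model could reach with enough cases. It consumes already-extracted
feature tables (CSV or the bundled breast-FNA table); image reading and
feature extraction are out of scope, as are nonlinear or deep models.

## Estimators being extrapolated

*Univariate path.* For a single feature, the performance estimate at a
given sample size is the resubstitution Youden index: the cutoff
maximizing Se + Sp − 1 over all midpoints between consecutive distinct
values (± infinity), scanning both orientations so the training YI is
never negative. This estimator is deliberately optimistic at small n —
that optimism, decaying with n, is the signal the extrapolation uses.
AUC is orientation-corrected (max(AUC, 1 − AUC)) for the same reason.
In repeated-split set-up analyses the cutoff is frozen on the
training+validation part and applied unchanged to the held-out test
part; a test value equal to the cutoff counts as the positive side.

*Cross-validated path.* The nine protocols pair a linear base learner
(logistic regression, linear SVM, LASSO on 0/1 targets thresholded at
0.5) with a reducer (none, RFE, PCA, univariate ROC retention).
Stratified K folds; per fold, features are z-scored with the fold-train
mean and sample SD (constant columns map to 0 with a warning) and the
reducer is fitted on the fold-train only. Class imbalance is handled by
inverse-frequency class weights (sample weights for LASSO).
Hyperparameters are tuned jointly across the K folds: every candidate
configuration is scored by its mean fold-validation YI and one winner
survives (ties resolved to the first, i.e. most-regularized, candidate).
The per-run estimate Y^VS is the winner's mean fold-validation YI; the
winning configuration's single best fold model — its normalization
statistics, reducer and fitted weights frozen — is what gets applied to
a test subset. An earlier design scored each fold by its own best
configuration; on label-permuted data that left a selection bias of
about +0.15 YI that did not decay with sample size, contradicting the
near-zero cross-validated YI that permuted labels must produce, so the
joint-tuning design was adopted.

## Downsampling and extrapolation

From the available pool, each run draws a stratified subsample chain:
the top size N is drawn once, then S cases are removed at a time
(classes kept at the pool ratio, nearest integer, at least one per
class) down to `min_size`, giving P ≥ 3 sizes N_p = N − (p−1)S. Chains
are the default rather than independent draws per size because the
shared sampling noise cancels in the size-to-size differences: with
independent draws the slope of the SD-vs-size fit at P = 3 is dominated
by Monte-Carlo noise and the zero crossing N_c is unstable by an order
of magnitude. Independent draws remain available (`nested=False`). The
pool may be larger than N (e.g. predicting from 84 of 88 available
cases), in which case the top point also varies across runs.

Fits, with natural logarithms throughout (the zero crossing
N_c = exp(a′/b′) and the extrapolated value are invariant to the base,
verified in tests):

* SD decay: OLS of SY on N_p (univariate) or ln N_p (cross-validated);
  N_c solves SY = 0. A non-decaying fit (b ≤ 0) is flagged
  `no_zero_crossing` and N_c capped at 10·N (configurable); a crossing
  beyond the cap is flagged `clamped`.
* Performance: weighted least squares of mean Y on ln N_p with weights
  1/max(SY, 10⁻³); the floor keeps degenerate zero-SD points (e.g. a
  top size equal to the pool size in the univariate path) finite while
  letting them dominate the fit, which is the behavior one wants: the
  fitted curve then passes through the one point that is known exactly.
  A slope contradicting the expected direction (univariate d < 0,
  cross-validated d > 0) is flagged `wrong_sign_slope` but still used.

Yec = c + d·ln N_c, clamped to [−1, 1] (YI) or [0, 1] (AUC) with a
flag. Stability of a mean curve is declared at the smallest size from
which *every* subsequent consecutive change is ≤ 0.01 (a single-pair
mode is available); the tolerance is fixed, the all-subsequent reading
is the stricter of the two possible ones.

## Set-ups and defaults

Set-up grids fix per-class training+validation counts, fixed test
counts and K. Presets cover the two reference designs: the lung-lesion
grid (S1–S9 unbalanced 30/10 steps with its published hand-chosen K
values, S10–S14 balanced) and the breast-FNA grid (S1–S8 unbalanced
10 MM/17 BM steps, S9 = 160/270, S10–S17 balanced 10–80 per class,
S18 = 160/160, test 42 MM/71 BM). Where K is not given, K =
clamp(floor(minority/10), 2, 10) keeps roughly ten minority cases per
fold and reproduces the published triplets at minority 10/20/30. Splits
are drawn without replacement, stratified, both subsets redrawn every
run; every draw is a pure function of (base seed, set-up id, run
index).

Default hyperparameter grids span under- to over-regularized regimes:
C ∈ 10⁻³…10³ (7 log-spaced points) for LR and SVM, α ∈ 10⁻⁴…10⁰ (9
points) for LASSO. RFE tunes its retained fraction over {25%, 50%,
75%} inside the same grid; PCA keeps the smallest component count
explaining ≥ 95% variance (capped at fold-train rows − 1); ROC
retention keeps features with train YI above a threshold (0.20 by
default, 0.75 for strongly separable data like the breast-FNA cohort),
falling back, flagged, to the single best feature.

The full-cohort reference protocol for the breast-FNA table is plain
maximum-likelihood logistic regression (no penalty, no weighting, raw
features) with stratified 10-fold CV, Se/Sp/YI from pooled out-of-fold
predictions — the literal reading of how that cohort's published
benchmark was produced; regularized/standardized variants move the
pooled YI by up to ±0.04.

## Synthetic data

Two generators back the tests. Label permutation keeps the real feature
matrix and class fractions while destroying every feature-label
association; note that one *fixed* permutation retains accidental
associations of order 1/√n, so multivariate predictions on a permuted
cohort are near zero but not exactly zero — occasional predicted YI
slightly above 0.1 is expected behavior, not leakage. Gaussian
simulation draws class-conditional normals with standardized mean
differences (AUC = Φ(e/√2), used as a closed-form oracle), optional
equicorrelated feature blocks with unit-variance marginals, and
configurable imbalance. Neither generator emulates heavy tails,
batch effects or within-patient correlation between lesions (every row
is treated as independent), so passing tests say nothing about those
aspects of real data.

## Problem sizes used in tests

The bundled suite runs the full 569-case cohort for screens and
references; repeated-split analyses use 10–50 runs; null-specificity
extrapolations use 25 runs over 21 curve points; the quality sweep uses
all 19 condition sizes × 30 features at 50 runs. These sizes keep the
suite at a few minutes while leaving Monte-Carlo noise well inside the
asserted tolerances.

## Known limitations

* N_c is an extrapolated zero crossing of a one-parameter decay model;
  with flat SD curves it is capped, not estimated.
* The method screens for the presence of information and the reachable
  performance; it does not rank classifiers.
* At least ~40 cases per class are needed for reliable predictions;
  below that the three-point minimum still runs but flags accumulate.
* The LASSO "classifier" is a convention (regression on 0/1 targets,
  0.5 threshold); a different convention shifts its YI slightly.
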