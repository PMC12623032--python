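# Methods

## Synthetic cohorts

**Covariates.** Continuous predictors are drawn from a Gaussian copula:
latent multivariate normal with unit diagonal, transformed per-variable
through (possibly truncated) normal or lognormal quantile functions.
Defaults for the trial-like cohort: age 51 (11) y, HbA1c 5.78 (0.40) %,
BMI 34 (7) kg/m², triglycerides lognormal with median 144 and quartiles
(101, 205) mg/dL, 67% female, and three equal randomized arms.  Fasting
glucose is a [95, 125] mg/dL truncated normal (underlying mean 102.5,
SD 10) whose *observed* moments are ≈106 (7): the truncation mirrors the
impaired-fasting-glucose eligibility window of a prevention trial and is
load-bearing — with unbounded FPG, the much steeper no-intervention FPG
slope (HR 1.90/SD vs 1.47 for lifestyle) would make "no intervention"
the lowest-risk scenario for very-low-FPG subjects who cannot occur in
the eligible population, breaking the structural property that an active
arm is always optimal.  The observational cohort is older and leaner
(age 64 (10), BMI 30 (6), FPG 101 (10), HbA1c 5.75 (0.30), TG median 118,
50% female) and entirely untreated.

Pairwise copula correlations default to 0.2 for FPG–HbA1c, FPG–BMI and
BMI–triglycerides and 0 elsewhere.  True correlations in the emulated
cohorts are unpublished; this knob is freely configurable and the
defaults are a deliberately mild, physiologically plausible choice.

**Event process.** Time to incident diabetes follows a proportional-
hazards model with *constant* baseline hazard, sampled by inverse
transform `T = −log U / (h0 · exp(lp))`.  The linear predictor uses
per-SD standardized covariates (age 10.6 y, BMI 6.6 kg/m², FPG
6.7 mg/dL, HbA1c 0.40%, log-TG 0.5247) centred at the *trial* covariate
means, which stay fixed for the observational cohort so that one
generating model covers both populations; slopes for age, FPG and BMI
are arm-specific, and the untreated arm follows the placebo hazard.
Observed time is the minimum of the event time, an independent
exponential dropout time (default rate 0.02/y), and administrative
censoring at 3.2 y.  The horizon is short enough that baseline-hazard
shape is secondary; the constant-rate choice makes closed forms
available for calibration and testing.

**Calibration.** Arm main effects and the baseline hazard are not
published; they are set by `calibrate_generating_model`, which solves —
by Brent root-finding on the Monte-Carlo marginal 3-year event-time CDF
over a fixed 200 000-draw covariate sample (common random numbers, so
the solve is deterministic given the seed) — for the baseline hazard
hitting the target marginal placebo risk (default 0.227, the
optimal-strategy-stratum-weighted mean of the published counterfactual
placebo risks), then for each arm's main effect hitting the target
relative reduction (defaults 0.58 and 0.31).  When all covariate effects
are zero the exponential closed form is used instead and the solution is
exact.  The calibration targets are censoring-free event-time
probabilities; simulated cumulative incidence is therefore measured by
Kaplan–Meier, not by the raw event fraction, wherever dropout is active.

**Missingness** is injected MCAR per predictor column (never on arm,
time or event), reproducibly from a seed.

**What the generator does not emulate.** Eligibility screening by oral
glucose tolerance testing; interval-censored (exam-based) ascertainment
in the observational cohort, which is simulated in continuous time;
adherence, crossover, and any secular drift; the true (unpublished)
covariate correlation structure.  Passing tests therefore demonstrate
internal statistical correctness of the pipeline under a plausible
generating mechanism, not agreement with the controlled-access data.

## Imputation

Missing predictors are filled by the 5 nearest neighbours under Gower's
distance: per-variable dissimilarity |a−b|/range for continuous and 0/1
mismatch for categorical variables, averaged over the variables observed
on both rows; pairs with either side missing drop out of numerator and
denominator.  Continuous targets take the donor mean and categorical
targets the donor mode (ties to the alphabetically lowest label);
equidistant donors break by table order, so results are deterministic.
Ranges come from the donor cohort itself; constant columns are excluded
with a warning.  Donor values are always originally observed values (no
chaining), and outcome columns and arm are neither distance variables
nor imputation targets — the conservative reading where the source
procedure is silent.  With an external reference frame (cross-validation
training folds), donors are restricted to the reference, so no held-out
outcome information leaks into training-fold models.  Gower distance
with missingness violates the triangle inequality; no routine here
relies on metric properties beyond symmetry.

## Proportional-hazards estimation

The Cox partial likelihood is maximized by Newton–Raphson with
step-halving; risk-set sums are suffix cumulative sums over
time-sorted data, so one iteration is O(n·p²).  Convergence requires
max |score| < 1e−8 or relative log-likelihood change < 1e−10.  Efron tie
handling is the default (event ascertainment at discrete visits makes
ties common in real data); Breslow is selectable for comparability with
software whose default it is.  Diverging coefficients with nondecreasing
likelihood (monotone likelihood) are flagged by name; a singular
information matrix is an error naming the columns.  Covariance is the
inverse observed information; CIs are Wald on the log scale.  Both
choices (tie method, CI method) are unstated in the source analysis.

The conditional-on-treatment ("one slope per arm") parameterization is
used rather than reference-plus-interaction coding because per-arm
hazard ratios are the reporting convention; the two are linear
reparameterizations and a test asserts identical likelihoods and implied
effects.  Standardization defaults to the published per-SD units rather
than cohort SDs so reported hazard ratios align with that convention;
cohort-SD mode is available (`ModelSpec(std_units=None)`).

The Breslow baseline cumulative hazard H0(t) = Σ d_j / Σ_risk exp(lp) is
anchored at the fitting cohort's covariate means (male, placebo), the
usual centring when the original anchoring constants are unavailable.
Risk at a horizon past follow-up uses the last baseline step with a
warning.

## Counterfactual risk and policies

Counterfactual risks are pure covariate functions — three predictions
per subject with the arm switched, the observed arm ignored.  Optimal-
arm ties break toward lifestyle (the guideline first-line strategy),
then metformin.  NNT is computed from mean *predicted* counterfactual
risks, not observed events: the source computation is not spelled out,
and this reading makes all three policies evaluable on identical
footing, including for subjects never randomized to the policy arm.  For
untreated cohorts the placebo prediction plays the "no intervention"
role.  The argmin construction guarantees the model-guided policy's mean
assigned risk (hence NNT) is no worse than either blanket policy; tests
assert rather than assume this.

## Validation metrics

Binary status at the 3-year horizon uses IPCW by default: weight
1/G(T−) for events by the horizon, 1/G(horizon−) for subjects still
under observation (censoring exactly at the horizon counts event-free),
0 for earlier censoring, with G the Kaplan–Meier censoring-distribution
estimate; this makes the weighted prevalence agree exactly with 1 −
KM(horizon) and reduces to unit weights when no one is censored early.
A simple-exclusion scheme is available and agrees exactly in that case.
Subjects whose censoring survival is 0 are excluded with a count.

Concordance is the weighted fraction of case–noncase pairs ranked
correctly (ties ½), computed in O(n log n) and bootstrapped (percentile,
default 1000 subject resamples, seeded).  Calibration bins subjects by
interior deciles of predicted risk (boundary ties to the lower bin) and
compares mean predicted risk with 1 − KM within bin, with Greenwood
normal intervals.  Net benefit is TPR − FPR · odds(threshold) with both
rates per subject screened, so 100·NB is net true positives per 100
screened; treat-all and treat-none references are returned, and the
curve grid is 0.01–0.50 in steps of 0.01.  NRI uses default risk
categories (0.10, 0.20) — aligned with the 20% decision threshold used
for net benefit and fairness, the category set being configurable since
the original cut-points are unknown — and returns event/nonevent
components, their sum, a bootstrap CI, and both reclassification
matrices.  Fairness reports per-group TPR/FPR at the threshold with the
equal-opportunity gap (max pairwise TPR difference) and equalized-odds
gap (max of TPR and FPR gaps); groups lacking cases or noncases are
excluded from the respective gap and flagged.  IPA is 1 −
Brier(model)/Brier(null) with the null predicting the weighted
prevalence.

Cross-validation is stratified by event status into folds whose sizes
differ by at most one; imputation and fitting happen inside each
training fold, held-out folds are imputed against training donors only,
and all metrics are computed once on the pooled out-of-fold predictions.
Both the pooled C-statistic and the mean of per-fold C-statistics are
reported.  `compare_models` runs the individualized and
nonindividualized specifications through identical internal/external
validation and scores the individualized model as "new" in the NRI.

## Problem sizes in the shipped studies

The recovery study uses 100 replicate trials at n = 2640 (the derivation
sample size); the calibration check and the exchangeable-groups fairness
check use n = 100 000; decile calibration of the well-specified model
uses n = 50 000.  At these sizes the full test suite runs in about half
a minute and the acceptance script in well under a minute on one CPU.

## Known limitations

The shipped default model is simulation-derived, not the published
scoring equation.  Per-coefficient 95% CI coverage is checked pooled
across coefficients in the recovery study (per-column banding at 100
replicates would reject a correct implementation too often).  Fitted
models at n = 2640 can, through sampling noise in the arm-specific
slopes, assign a handful of subjects a lowest-risk "no intervention"
scenario even though the generating model never does; this is an
estimation-noise phenomenon, visible in the worked example's
observational summary, and deliberately not suppressed.
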