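# ipirisk — individualized preventive-intervention diabetes risk modelling

`ipirisk` is a research package for building and validating type 2
diabetes risk prediction models whose predictions are *conditional on the
preventive intervention a person starts*: intensive lifestyle
intervention, metformin therapy, or no intervention.  It is aimed at
biostatisticians and epidemiologists studying individualized treatment
rules in diabetes prevention, and at anyone who needs a fully synthetic,
end-to-end testbed for such analyses when the underlying trial data are
controlled-access.

## The model

Incident diabetes over a 3-year horizon is modelled by Cox proportional
hazards regression on seven clinically available predictors — fasting
plasma glucose (FPG), glycated hemoglobin (HbA1c), body mass index (BMI),
triglycerides (log-transformed), age, sex, and intervention arm.  The
*individualized* specification gives age, FPG and BMI one slope per arm
(equivalently, pairwise arm-by-covariate interactions):

    h(t | x, arm) = h0(t) · exp( β_arm + β'_arm z(age, FPG, BMI) + γ' z(HbA1c, log TG, sex) )

with continuous predictors standardized per SD (age 10.6 y, BMI
6.6 kg/m², FPG 6.7 mg/dL), so hazard ratios read per 1-SD change.
Absolute risk comes from the Breslow baseline cumulative hazard:
`risk(3y) = 1 − exp(−H0(3) · exp(lp))`.  Each subject's **counterfactual
risks** are the three predictions obtained by switching the arm while
holding covariates fixed; the **optimal preventive intervention** is the
arm with the lowest predicted risk, and treatment policies (treat all
with lifestyle, treat all with metformin, treat per model) are compared
by the number needed to treat, NNT = 1 / (mean placebo risk − mean
assigned risk).

Everything statistical in the core path is implemented from scratch and
tested against independent oracles: Newton–Raphson partial-likelihood
maximization with Efron or Breslow tie handling, Gower-distance 5-NN
imputation, Kaplan–Meier/IPCW machinery, time-horizon concordance,
decile calibration, categorical NRI with reclassification matrices,
decision-curve net benefit, equal-opportunity/equalized-odds fairness
gaps, Brier score and IPA, and stratified 10-fold cross-validation.

Because the source trial and validation cohort are controlled-access,
the package ships a synthetic-data module that emulates them: a
three-arm randomized trial (middle-aged, high-BMI, impaired fasting
glucose) and an older, leaner untreated observational cohort, both drawn
from a Gaussian copula with published marginal moments and an
exponential proportional-hazards event process whose arm effects are
calibrated to the published marginal 58% (lifestyle) and 31% (metformin)
3-year risk reductions.

## Worked example

```bash
ipirisk simulate --out sim --seed 7                  # trial + observational CSVs
ipirisk develop  --cohort sim/trial.csv --out model --seed 7
ipirisk validate --model model/model_individualized.json \
                 --cohort sim/observational.csv --out val --seed 7
ipirisk risk     --model model/model_individualized.json \
                 --age 45 --sex female --fpg 110 --hba1c 6.0 \
                 --bmi 36 --triglycerides 180
```

`develop` prints the fitted per-SD hazard-ratio table (excerpt):

```
Glycated hemoglobin                      1.28 (1.16, 1.41)
Triglycerides                            1.21 (1.10, 1.34)
...
Fasting glucose — lifestyle              1.44 (1.18, 1.77)
Fasting glucose — metformin              1.49 (1.26, 1.76)
Fasting glucose — placebo                1.88 (1.65, 2.14)
Body mass index — lifestyle              1.34 (1.07, 1.68)
Body mass index — metformin              0.92 (0.78, 1.10)
...
Sex: Male                                1.00 (reference)
```

— the steep placebo FPG slope and the lifestyle-vs-metformin BMI
asymmetry are the two pieces of effect heterogeneity that drive
individualized assignment.  The internal 10-fold cross-validated
C-statistic on this run is 0.717.  `validate` on the observational
cohort prints the optimal-strategy summary and policy NNTs:

```
optimal_arm    n  pct_sample  mean_risk_lifestyle  mean_risk_metformin  mean_risk_placebo
  lifestyle 2064        98.1                  5.6                 11.7               15.9
  metformin   13         0.6                 14.7                 13.3               20.7
  ...
       policy  mean_assigned_risk   arr    nnt
all-lifestyle               0.056 0.102  9.817
all-metformin               0.116 0.042 23.870
 model-guided               0.056 0.102  9.806
External C-statistic: 0.769
```

Lifestyle is optimal for nearly all subjects in the older, leaner
cohort; the model-guided policy attains an NNT no worse than either
blanket policy (here essentially tying all-lifestyle, because metformin
is rarely optimal).  `risk` scores one person:

```
Predicted 3-year diabetes risk:
  lifestyle intervention :  11.4%
  metformin therapy      :  19.7%
  no intervention        :  31.8%
Optimal prevention strategy: lifestyle
```

The same functionality is available as a library — see
`ipirisk.simulate_trial_cohort`, `ipirisk.fit_model`,
`ipirisk.counterfactual_risks`, `ipirisk.crossvalidate`, and
`ipirisk.compare_models`.  Fitted models serialize to a versioned JSON
(coefficients, covariance, SD units, centring constants, baseline-hazard
steps) sufficient for standalone prediction.

## Limitations

The default shipped model is simulation-derived: its coefficients
recover the published per-SD hazard ratios by construction of the
generator, but it is **not** the published risk equation, whose exact
scoring constants are not public.  See `docs/methods.md` for modelling
assumptions, parameter defaults, and what the synthetic cohorts do and
do not emulate.
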