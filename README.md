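# rerand

Simulation and analysis of **re-randomisation clinical trial designs** —
trials in which a patient who has completed the follow-up of one treatment
episode may be independently randomised again for the next one.  The design
recruits a target number of *observations* rather than patients, which can
rescue recruitment in settings where patients need treatment repeatedly
(recurrent pain crises, migraine episodes, fertility cycles) and where
parallel-group trials routinely miss their sample size.

The package is aimed at trial statisticians and methodologists who want to

- simulate re-randomisation trials under configurable enrolment mixes,
  randomisation schemes and outcome models (including selective re-enrolment
  and treatment carryover),
- analyse trial datasets with the design's two standard estimators,
- compute analytic power for both estimators, and
- replay the design's operating characteristics (bias, type I error, power)
  by Monte Carlo.

## Model and estimators

Outcomes follow a Gaussian random-intercept model

```
Y_ij = α + β·X_ij + u_i + ε_ij,   u_i ~ N(0, σ_u²),  ε_ij ~ N(0, σ_ε²)
```

for patient *i* in randomisation period *j*, with treatment indicator `X_ij`
and intraclass correlation `ICC = σ_u²/(σ_u²+σ_ε²)`.  The design is valid
when (a) periods do not overlap, (b) each randomisation is independent of the
patient's previous allocations, and (c) the treatment effect is constant
across periods.

Two analyses are provided:

- **unadjusted** — OLS of `Y` on `X`, treating observations as independent.
  Under independent allocation the within-patient clustering is *ignorable*:
  the estimator is unbiased, the type I error is correct, and
  `Var(β̂) = 4σ²/n` exactly equals a parallel-group trial of the same size.
- **patient-adjusted** — a linear mixed model with a random intercept per
  patient, fitted by a profiled REML specific to the random-intercept
  structure (one-dimensional optimisation with closed-form GLS at each
  step), with p-values from a t distribution on
  `n_obs − n_patients − n_fixed` degrees of freedom.  It gains power from
  within-patient comparisons; when treatment effects carry over into later
  periods it must additionally adjust for the counts of previous
  intervention/control allocations (indicator-coded `A_ij`, `B_ij`) to stay
  unbiased.

## Worked example

```python
from rerand import (AnalysisSpec, build_scenario_design, fit_patient_adjusted,
                    fit_unadjusted, simulate_trial)

design, scenario = build_scenario_design("base", icc=0.5, beta=0.4)
table = simulate_trial(design, scenario, seed=2015)   # 100 pts x1 + 50 pts x2
print(fit_unadjusted(table).beta_hat)
print(fit_patient_adjusted(table, AnalysisSpec(adjust_for_patient=True)).se)
```

Running `python examples/02_analyse_trial.py` prints:

```
true effect 0.4, ICC 0.5, 200 obs / 150 patients
unadjusted:       beta = 0.370  se = 0.136  df = 198  p = 0.0072
patient-adjusted: beta = 0.419  se = 0.128  df = 48  p = 0.0020
estimated ICC = 0.46  (sigma_u^2 = 0.42, sigma_e^2 = 0.50)
```

Both estimators recover the true effect of 0.4 within sampling error; the
patient-adjusted standard error is smaller because 50 of the 150 patients
contribute within-patient information.  The other `examples/` scripts cover
building and auditing a design, analytic power curves, the carryover
scenario study, and CSV import/validation.

A thin CLI mirrors the library: `rerand simulate`, `rerand analyse`,
`rerand power`, `rerand experiment --config table3 --reps 500 --seed 1 --out
results/`, `rerand validate`.

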