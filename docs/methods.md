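# Methods

## The re-randomisation design

A re-randomisation trial enrols each treatment episode as its own
randomisation: a patient who has completed the follow-up period of one
enrolment may be randomised again for the next.  The sample-size unit is the
observation (episode), not the patient.  The design's validity rests on
three conditions: (a) no overlapping follow-up periods (`t_j > t_{j−1} + m`
for follow-up length `m`), (b) every randomisation is independent of the
patient's earlier allocations, and (c) a constant treatment effect across
periods.  `TrialDesign`/`ObservationTable` encode the design and data;
`check_validity` audits (a) directly and (b) via a pooled 2×2 chi-square
independence test of consecutive within-patient allocations.  Simulated
tables satisfy (a) structurally — periods are generated sequentially — so
calendar time is optional and checked only on imported data.

Randomisation engines: simple (Bernoulli per observation), permuted blocks
stratified by randomisation period (default block size 4; an incomplete
trailing block is a truncated permuted block), and — as a deliberately
invalid anti-pattern that demonstrates why condition (b) matters — a
patient-stratified alternating scheme, usable only behind an explicit
acknowledgement flag.

## Outcome model and scenarios

Outcomes follow the Gaussian random-intercept model
`Y_ij = α + β X_ij + u_i + ε_ij` with `u_i ⟂ ε_ij`, ICC
`σ_u²/(σ_u²+σ_ε²)`, and total variance fixed at 1 in every shipped study
condition (ICC and total variance are the tunable knobs; `icc_to_variances`
performs the exact split).  α is 0 throughout: the intercept is irrelevant
to every contrast studied.

Seven scenario variants perturb this base model.  Their designs and
coefficients are the package's study conditions, fixed once:

| scenario | design | perturbation |
|---|---|---|
| s1 sicker patients | 100×1 + 25×4 | mean shift θ·Z, θ=−0.5, Z=1 for every period of multi-enrolled patients |
| s2 poor outcome | 150×1 → selective 2nd period | re-enrol if α+u+ε < −0.44 (≈33%) |
| s3 / s4 | 130×1 → selective 2nd period | re-enrol intervention-first / control-first patients |
| s5 period effect | 50×4 | mean shift π·(j−1), π=0.5; analyses adjust for period indicators |
| s6 intervention carryover | 50×4 | θ·A_ij, θ=0.4 |
| s7 differential carryover | 50×4 | θ·A_ij + λ·B_ij, θ=0.6, λ=0.2 |

`A_ij`/`B_ij` count the patient's previous intervention/control allocations
(`A+B = j−1`).  All scenarios run at ICC 0.50.

Two generative choices deserve a note:

- **Scenario 2's selection acts on the treatment-free outcome component**
  (`Y − βX = α + u + ε`), not the realised outcome.  Selecting on the
  realised outcome would make the re-enrolled fraction depend on the
  treatment effect (≈26.6% instead of 33% at β=0.4, shrinking the trial to
  ≈190 observations); selecting on the underlying response keeps the
  fraction at Φ(−0.44) ≈ 33% and the expected trial size at 200 in every
  effect mode, which is the regime the study design describes.  The
  selection still conditions on the patient effect and the period-1 noise,
  so it violates the ignorable-re-enrolment condition exactly as intended.
- **Scenario 1's Z marks the patient, not the period**: all four periods of
  a multi-enrolled patient carry the −0.5 shift, including the first —
  "needs repeated treatment" is a patient characteristic.

For s2–s4 the trial is generated in two stages (first periods → selection →
freshly randomised second periods), re-using each patient's `u_i` so repeated
observations keep the configured ICC.

## Estimators

**Unadjusted**: OLS of outcome on treatment plus any requested covariates;
with no covariates the estimate is exactly the difference in arm means;
inference uses residual degrees of freedom.  Clustering within patients is
ignorable under independent allocation, so the type I error is
asymptotically correct even though repeated observations are correlated.

**Patient-adjusted**: the random-intercept mixed model, REML by default (ML
available).  The implementation profiles the likelihood down to one
parameter: for a fixed variance ratio ρ = σ_u²/σ_ε², Woodbury reduces all
GLS cross-products to per-patient sums (`X'W⁻¹X = X'X − Σ_i c_i S_i S_i'`,
`c_i = ρ/(1+n_i ρ)`), leaving a bounded one-dimensional Brent optimisation
over h = ρ/(1+ρ) ∈ [0, 1) with closed-form β̂, σ̂_ε² and both
log-determinants at each step.  This is numerically equivalent to a general
mixed-model fit (it matches statsmodels' MixedLM to ≥5 decimals in the test
suite) at a fraction of the cost, which is what makes 10⁵-fit Monte Carlo
runs practical on one CPU.  h = 0 is evaluated explicitly: at the boundary
(σ̂_u² = 0), and on all-singleton tables where ρ is unidentified and the
small-sample df rule below would be nonpositive, the fit falls back to OLS
inference and says so (`boundary`/`message`).

Inference uses the design's small-sample rule: a t reference with
`df = n_obs − n_patients − n_fixed` (e.g. 200 − 150 − 2 = 48).  Two-sided
tests at α = 0.05 throughout.

**Covariates** are indicator-coded with reference level 0 (period 0, zero
prior allocations); carryover counts can alternatively be linear-coded.
Collinear columns are dropped deterministically left-to-right with a logged
note.  The total-enrolment count is refused as a covariate: it conditions on
the patient's future need for treatment (a post-randomisation factor) and
biases the treatment effect.

## Analytic power

The unadjusted estimator has variance `4σ²_total/n_obs` for *any*
enrolment-count distribution — the precision lost on patients re-randomised
to the same arm is exactly offset by patients re-randomised to the opposite
arm — so its power equals a parallel-group trial's.  The patient-adjusted
variance is computed by expected-information averaging: for each patient
with k periods, average the GLS information for (intercept, treatment) under
the exchangeable covariance over the 2^k equiprobable allocation vectors,
accumulate over patients, invert.  An exact enumeration over the joint
allocation space of a tiny trial and 20,000-replication simulations agree
with this quantity to well within Monte Carlo resolution; it is always ≤ the
unadjusted variance, with equality iff ICC = 0 or nobody is re-randomised.

Two SD conventions are exposed, because power is quoted under both in
practice: `sd_mode="total"` (σ_u²+σ_ε² = sd², the simulation convention)
and `sd_mode="within"` (σ_ε² = sd², σ_u² = icc/(1−icc)·sd², the convention
of analytic power curves).  Power uses the two-sided normal approximation;
`solve_effect_for_power` inverts it exactly (closed form plus one Brent
polish, so solve→power round-trips to 10⁻⁶).  Designs on the
re-randomisation-proportion axis follow `n_patients = total/(1+proportion)`
with the twice-enrolled stratum rounded to the nearest integer and the
remainder assigned to the single-enrolment stratum.

## Monte Carlo experiments

Each replication runs the full generative pipeline and every analysis in the
scenario's menu; summaries report the mean estimate, the empirical SE, the
rejection rate with its Monte Carlo SE `√(p(1−p)/R)`, and the power
difference against a parallel-group benchmark.  Non-convergent fits are
counted and excluded (never re-drawn — that would bias the summaries); any
analysis failing on more than 5% of replications aborts the experiment.
A master seed spawns one child stream per (scenario, effect-mode) cell via
`numpy.random.SeedSequence`, and within a cell one grandchild pair per
replication (trial, comparator), so runs are bit-reproducible and the
simulated parallel comparator is paired with its re-randomisation trial.

**Benchmarks.**  The scenario study quotes power differences against the
nominal 80% its effect sizes target; the grid experiments simulate the
200-independent-patient parallel comparator on the paired stream, which is
the cleaner comparison when the ICC itself varies.

**Powered effects.**  The scenario study carries the working effect
β = 0.4: the exact 80%-power solves at its trial sizes (0.396 at 200
observations, 0.401 at 195) equal 0.4 at the study's one-decimal working
precision, and the operating characteristics are quoted at that round value.
The one exception is scenario 1, where the θZ shift is a patient-population
feature carried by half of the observation pool: its parallel benchmark has
outcome SD √(1+θ²/4), and the effect is solved exactly against it (≈0.408).
Solving scenario 1's effect at unit SD would build a ~2pp power loss into
both of its analyses that has nothing to do with re-randomisation.  Grid
experiments use the exact unit-SD solve, since their comparator is simulated
with the same effect and only differences matter.

**Problem sizes.**  Shipped configurations use 5000 replications (MC SEs
0.3pp for a 5% rate, 0.6pp for 80% power).  The acceptance script runs the
scenario study at 5000 and the grids at 2000; the test suite's Monte Carlo
checks run at 2000 (tolerances of 3 combined MC SEs), with two exceptions
chosen for resolution rather than speed: the variance-equality check at
20,000 replications (a 5% band needs ~1% resolution on a variance ratio)
and the small-sample inflation cell at 12,000 (the inflation is ~1.5pp, so
3 MC SEs at 2000 replications could not distinguish it from the null).

**Small-sample study.**  5–30 patients × {2, 4, 8} periods, ICC 0.75, null
effect, simple vs period-stratified permuted-block randomisation, unadjusted
analysis with and without period indicators.  It reproduces the design's
known small-sample pathology: blocked randomisation without period
adjustment inflates the type I error at very small patient counts (≈6–7% at
5 patients × 8 periods), while simple randomisation or period adjustment
holds the 5% level.

## What the generator does and does not emulate

The generator reproduces the study conditions exactly: Gaussian random
effects, fixed total variance, non-overlapping periods by construction,
selection rules acting on the first period only, and carryover that is
linear in prior-allocation counts.  Real re-randomisation trials add
features deliberately out of scope here — binary or time-to-event outcomes,
informative dropout within a period, calendar-time recruitment dynamics,
unequal allocation ratios, heavy-tailed patient effects, and consent or
adherence behaviour in open-label settings.  Passing tests therefore
establish the estimators' properties under the stated model, not robustness
to those departures.

## Known limitations

- The profiled REML fitter covers exactly one random intercept per patient —
  the model this design calls for — not general random-effects structures.
- GEE estimation is not provided (for continuous outcomes its point
  estimates coincide with the mixed model's).
- Kenward–Roger / Satterthwaite degrees of freedom are not implemented; the
  design's own df rule is used for the mixed model.
- Analytic power treats the variance components as known; simulated power
  with estimated components runs ~0.5–1.5pp below it at these sample sizes
  (t reference and REML noise), which is visible when comparing the
  analytic curves with simulation output.
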