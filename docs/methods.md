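# Methods

## The estimation problem

In maintenance hemodialysis, weekly epoetin-α (ESA) dose and hemoglobin
(Hb) are locked in a feedback loop: the prescribed dose responds to the
current Hb, and the achieved Hb responds to past dose.  Hb also predicts
survival, so it is simultaneously a confounder of the dose–mortality
association and an intermediate on the causal path — the textbook
treatment–confounder feedback situation in which neither crude comparison
nor conventional covariate adjustment recovers the causal effect of a
sustained dosing policy.  The same time-varying labs predict informative
censoring (transplantation, modality change, transfer out), which a naive
analysis treats as non-informative.

`esamsm` implements the standard remedy: a marginal structural model (MSM)
fitted by inverse-probability weighting.  The estimand is the discrete-time
hazard odds ratio of death under "always dose in category *k*" versus
"always dose in the reference category", where the six ordinal categories
are the fixed bands `[0, 6000)`, `[6000, 12000)`, `[12000, 18000)`,
`[18000, 24000)`, `[24000, 30000)`, `[30000, ∞)` U/week, with
`< 6000 U/week` as reference.

## Panel construction

Time is measured in calendar quarters, modelled as exactly 13 weeks; doses
are averaged over the at-risk weeks of a quarter (partial final quarters
average over the at-risk weeks only, avoiding artificial dilution).  Doses
during hospitalization are imputed by carrying the most recent
pre-hospital weekly dose forward.  Cohort inclusion requires age ≥ 18,
≥ 90 days of hemodialysis before entry, and complete entry-quarter data on
dose and Hb; exclusions are tallied per criterion.  The incident subcohort
is vintage < 6 months.  Time-varying labs are completed by
last-observation-carried-forward (LOCF, no look-ahead); baseline
covariates by chained-equation multiple imputation (below).

## Weights

**Treatment (IPTW).**  The 6-level exposure is modelled with
proportional-odds (cumulative-logit) regression.  The stabilized weight at
quarter *t* is the cumulative product over quarters *s* ≤ *t* of

  r_s = P(A_s = a_s | A_{s-1}, V) / P(A_s = a_s | A_{s-1}, V, L_s, L_{s-1}),

with V the baseline covariates and L_s the current-quarter labs (default
Hb and albumin plus their one-quarter lags).  An interval mode (w_t = r_t
alone) is available behind a flag and always recorded in outputs.  Because
the numerator conditions on V, the outcome model must adjust for V; this
construction trades a fully marginal estimand for much lighter weight
tails.  At the entry quarter the "time-varying" labs are the baseline labs
themselves, so numerator and denominator coincide and r_0 ≡ 1; models are
fitted on quarters ≥ 1.

A `numerator="marginal"` option replaces the numerator with the
unconditional category distribution.  That is the construction under which
the weighted pseudo-population is *marginally* balanced, and it is what
the balance diagnostic (`covariate_balance`) expects: time-specific
(interval) marginal-numerator weights on quarters ≥ 1 drive the
standardized mean difference of Hb across dose categories from ≈ 0.9 to
below 0.05 in the default scenario.

**Censoring (IPCW).**  Binary logistic models of *informative* censoring
(transplant, modality change, transfer) with the same numerator /
denominator covariate split; the weight is the cumulative ratio of
probabilities of remaining uncensored.  Administrative end of follow-up is
deterministic given the calendar and is excluded from the censoring event.
A panel without informative censoring yields IPCW ≡ 1 (logged, not an
error).  IPCW are never truncated.

**Truncation.**  IPTW are truncated at the pooled 1st/99th percentiles.
Bounds are nearest-rank order statistics, making truncation a projection
(idempotent); the weight-distribution summary table reports
linear-interpolation percentiles, the convention under which such tables
are bit-for-bit reproducible.  Both conventions are fixed and documented
because they genuinely differ: linear-interpolation clipping is *not*
idempotent (clipping moves the interpolated percentile inward).

**Positivity.**  Denominator probabilities below 1e-12 raise a hard error
naming the record; a dose category never observed in the fitting window
triggers an explicit warning.  Extreme weights and means far from 1 are
the practical symptoms of positivity failure, which is why the summary
table and the mean weight are first-class outputs.

## Outcome models

The outcome model is a pooled logistic regression of the quarterly death
indicator on dose-category indicators plus baseline covariates, weighted
by the final stabilized weight (IPTW × IPCW), with repeated measures
clustered on patient.  The default engine is a binomial GLM with frequency
weights and a cluster-robust sandwich — numerically the same estimator as
GEE with independence working correlation, but without statsmodels GEE's
per-cluster Python loop; `engine="gee"` runs statsmodels GEE directly and
the test suite asserts agreement between the two.  Time-varying covariates
never enter the outcome model; they act only through the weights.

Cause-specific mortality (cardiovascular, infectious) uses the
cause-specific hazard convention: competing-cause deaths end follow-up as
non-events.  The ≥ 30 000 U/week dichotomized analysis re-estimates
weights on the binary exposure within each subgroup (sex, age 65, race,
diabetes, ischemic heart disease, BMI 23, albumin 3.8), skipping subgroups
below a configurable minimum size.

**Multiple imputation.**  Baseline missingness is handled by
chained-equation MI: linear draws (parameter draw from the normal
approximation plus a predictive draw) for continuous covariates,
logistic/multinomial draws for categoricals, 10 chained iterations, m = 5
completed tables, combined with Rubin's rules (pooled log-OR = mean;
total variance = within + (1 + 1/m)·between; t-based CI with the standard
degrees-of-freedom correction).  This is written in-package because the
installed MI implementations do not draw categorical covariates properly;
it targets the < 5% missingness regime the pipeline is designed for.

## The synthetic cohort generator

The generator is first-class, tested code: it defines the study conditions
under which every calibration property is evaluated.  Per patient *i* with
frailty u_i ~ N(0, σ_u²) (default σ_u = 0.8):

* Hb_t = Hb_base,i + 0.6·u_i + φ·(A_{t-1} − 2) + ε_t, φ the dose→Hb
  feedback (default 0.25 g/dL per category step), ε_t ~ N(0, 0.5);
  Hb_base ~ N(12.1, 0.7) g/dL.
* A_t follows a proportional-odds model on centred Hb (−0.9 per g/dL),
  albumin (−0.5 per g/dL) and the prior category (+0.8 per step), with
  cutpoints calibrated to category frequencies ≈ (5, 18, 21, 17, 12, 27)%.
* Death: logit = α + θ_{A_t} + γ·(Hb_t − 12) + u_i, α = −3.3 (≈ 3.5%
  per quarter), θ the true direct category effects.
* Informative censoring: logit = −3.9 + 0.15·(Hb_t − 12) (≈ 2% per
  quarter; healthier patients likelier to be transplanted/transferred),
  reasons multinomial (0.5, 0.3, 0.2); survivors of the last quarter are
  administratively censored.  Cause of death is multinomial
  (CV 0.45, infectious 0.15, other 0.40), optionally shifted with dose so
  cause-specific effects can be planted.
* Missingness: MCAR masks on baseline covariates (3%) and post-entry labs
  (5%) in the default scenario; the entry quarter stays complete so LOCF
  is well-defined.

Baseline demographics use cohort-scale marginals (age ~ N(62, 15)
truncated at 18, 55% female, race 43/32/14/3/8%, diabetes 57%, 44%
incident).  The generator emulates the confounding *structure*, not the
joint covariate distribution of any real cohort: passing tests shows the
pipeline removes the planted feedback confounding at these scales, not
that any particular clinical estimate is correct.

**Ground truth** comes from Monte-Carlo g-computation: the structural
equations are re-run with the dose forced to one category at every quarter
and censoring disabled, pooling deaths over person-quarters; the odds
ratio versus the forced reference regime is the estimand the MSM targets.
Degenerate runs (zero deaths or survivors in either arm) raise rather than
return an undefined ratio.

Two scenario choices matter and were made deliberately:

* In the *null* and *effect-recovery* scenarios the direct Hb→death
  coefficient γ is set to 0 and confounding is carried entirely by the
  frailty (u raises Hb, hence lowers the prescribed dose, and raises
  death).  With γ ≠ 0 and feedback active, a forced high-dose regime would
  causally lower mortality through Hb — the truth would not be null, and
  the counterfactual hazard would depend on the prior dose, so a
  current-dose-only MSM would be misspecified.  With γ = 0 the null is
  exact, the crude estimate is still strongly biased (top-category crude
  OR ≈ 0.55 at the default settings), and sequential exchangeability holds
  given observed Hb — the cleanest possible test of the weighting
  machinery.
* The *default* scenario keeps γ = −0.35 per g/dL and plants direct
  effects on the scale of the published estimates
  (ORs 1.02 … 1.52); it exercises the full pipeline (missingness, MI,
  cause labels) and is used for descriptive outputs and balance
  diagnostics, not exact-recovery assertions.

## Numerical choices

* Proportional-odds fitting uses an in-package MLE with analytic
  gradients (internally standardized design, L-BFGS with a tight restart
  polish, gradient check ≤ 1e-6 per observation).  statsmodels'
  `OrderedModel` differentiates numerically and needs minutes per fit at
  10⁵ rows; the test suite cross-checks coefficients and probabilities
  against it on moderate data.
* Binary propensity and censoring models use Newton (machine-precision at
  saturated MLEs, required by the exact oracle tests) with a quasi-Newton
  fallback for rich designs with few events.
* Percentiles: nearest-rank for truncation bounds, linear interpolation
  for summary tables (see above).
* Missing covariates in any model design raise immediately (no silent
  row dropping); imputation is an explicit upstream step.
* Calibration scales: weight calibration and effect recovery run at
  n = 20 000 patients × 8 quarters; null-coverage uses 100 replicates at
  n = 5 000 × 8; g-computation uses 4 × 10⁵ forced trajectories per arm.
  These sizes hold Monte-Carlo error well below the asserted tolerances.

## Known limitations

* The exposure model is proportional-odds by construction in both the
  generator and the estimator; the package does not diagnose
  non-proportionality of the prescribing process.
* Competing risks are handled by the cause-specific hazard convention
  only; no subdistribution (Fine–Gray-type) estimand is provided.
* The MI engine targets low missingness (< 5%) with simple conditional
  models; it is not a general-purpose imputer.
* Cumulative weights grow noisier with follow-up length; beyond ~16
  quarters truncation becomes increasingly consequential and the interval
  mode should be examined alongside.
* The generator does not model pharmacokinetics, within-quarter dosing
  dynamics, or real joint covariate distributions.
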