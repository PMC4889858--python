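# esamsm

Marginal structural models (MSMs) for the effect of weekly
erythropoiesis-stimulating-agent (ESA, epoetin-α) dose on mortality in
hemodialysis cohorts.

In maintenance hemodialysis, hemoglobin (Hb) is a time-varying confounder
that is itself affected by treatment: the prescribed ESA dose responds to
the current Hb, the achieved Hb responds to past dose, and Hb predicts
both survival and informative censoring (transplantation, modality change,
transfer).  Under such treatment–confounder feedback neither crude
comparison nor standard covariate adjustment identifies the effect of a
sustained dosing policy.  `esamsm` implements the inverse-probability-
weighted discrete-time MSM used for this problem, end to end:

* **Panel construction** — long-format patient-quarter panels; quarterly
  dose averaging with hospital-dose carry-forward; the six pre-specified
  ordinal dose bands (`<6000`, `6000–<12000`, …, `≥30000` U/week,
  reference `<6000`); inclusion filters (age ≥ 18, ≥ 90 days of dialysis,
  complete dose/Hb); incident-subcohort filter; LOCF for time-varying labs.
* **Weights** — stabilized inverse-probability-of-treatment weights from
  proportional-odds models of the 6-level exposure
  (sw_t = Π_{s≤t} P_num(a_s)/P_den(a_s)), stabilized
  inverse-probability-of-censoring weights from logistic models of
  informative censoring, 1st/99th-percentile truncation of the IPTW (never
  the IPCW), final weight = product, weight-distribution summary tables
  and covariate-balance diagnostics.
* **Estimation** — pooled logistic regression of the quarterly death
  indicator on dose-category indicators plus baseline covariates, weighted
  and cluster-robust on patient (GEE with independence working
  correlation); cause-specific (cardiovascular / infectious) fits; the
  `≥30 000 U/week` dichotomized subgroup analysis; chained-equation
  multiple imputation of baseline covariates with Rubin's-rules pooling.
* **Synthetic cohorts** — a seeded generator with the Hb↔dose feedback,
  patient frailty, informative censoring and missingness structure the
  analysis assumes, plus a Monte-Carlo g-computation oracle that computes
  the true "always treat at level k" odds ratios, so causal recovery can
  be tested against known truth.

See `docs/methods.md` for the model, its assumptions, and all numerical
conventions.

## Worked example

Simulate a confounded *null* cohort — the true effect of dose on death is
zero in every category, but a latent frailty raises Hb (hence lowers the
prescribed dose) and raises mortality, so the crude association is
spuriously protective — then remove the bias by weighting:

```python
from esamsm import (null_truth, simulate_cohort, estimate_weights,
                    fit_msm_gee)

truth = null_truth(n_patients=5000, n_quarters=8, seed=7)
panel, _ = simulate_cohort(truth)

crude = fit_msm_gee(panel, weights=None, baseline_terms=None)
ws = estimate_weights(panel)              # stabilized IPTW x IPCW
msm = fit_msm_gee(panel, weights=ws)

print("mean final stabilized weight:", round(ws.final_weight.mean(), 3))
for c in (3, 4, 5):
    ce, me = crude.estimates.loc[c], msm.estimates.loc[c]
    print(f"category {c}: crude OR {ce.odds_ratio:.2f} "
          f"({ce.ci_low:.2f}-{ce.ci_high:.2f})   "
          f"MSM OR {me.odds_ratio:.2f} ({me.ci_low:.2f}-{me.ci_high:.2f})")
```

prints

```
mean final stabilized weight: 0.973
category 3: crude OR 0.79 (0.62-1.01)   MSM OR 1.03 (0.78-1.37)
category 4: crude OR 0.57 (0.43-0.75)   MSM OR 0.93 (0.67-1.29)
category 5: crude OR 0.55 (0.45-0.67)   MSM OR 0.90 (0.69-1.17)
```

The crude fit reports up to 45% *lower* odds of death in the top dose
band — pure confounding, since the generator's true odds ratio is 1.0
everywhere.  The weighted MSM estimates sit near 1 with confidence
intervals covering 1, and the mean stabilized weight near 1 indicates the
weight models are well specified.

The same analysis is available from the shell:

```sh
esamsm simulate --scenario null --n 5000 --quarters 8 --seed 7 \
    --out-panel panel.csv --out-baseline base.csv --out-truth truth.yaml
esamsm weights --panel panel.csv --baseline base.csv \
    --out-weights w.csv --out-summary wsummary.tsv
esamsm fit --panel panel.csv --baseline base.csv --weights w.csv --out or.tsv
esamsm run --seed 7 --out results/      # full configured pipeline
```

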