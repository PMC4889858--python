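"""Synthetic hemodialysis cohorts with treatment–confounder feedback.

The generator emulates the data-generating structure the weighting analysis
is built for: hemoglobin (Hb) responds to the previous quarter's ESA dose,
drives the next dose through a proportional-odds prescribing model, and a
latent patient frailty raises both Hb and the death hazard, so the crude
dose–mortality association is confounded.  Informative censoring
(transplant / modality change / transfer) follows its own logistic hazard.
Every structural constant lives in :class:`SimulationTruth`; there are no
hidden parameters.

Ground truth for the marginal "always treat at level k" estimand is
computed by Monte-Carlo g-computation (:func:`gcompute_truth`), which
re-runs the structural equations with the dose forced to one category and
censoring switched off.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .panel import (
    COMORBIDITIES,
    DOSE_EDGES,
    INSURANCE_LEVELS,
    MARITAL_LEVELS,
    PanelDataset,
    RACE_LEVELS,
    TIME_VARYING_LABS,
    VINTAGE_LEVELS,
)


class ParameterizationError(ValueError):
    """Structurally invalid simulation parameters."""


class DegenerateHazardError(RuntimeError):
    """No events occurred; an odds ratio is undefined."""


#: Marginal means/SDs used for the non-structural labs (cohort-scale values).
LAB_MARGINALS = {
    "creatinine": (8.2, 3.0),
    "calcium": (9.3, 0.6),
    "phosphorus": (5.6, 1.3),
    "bicarbonate": (22.0, 3.0),
    "tibc": (203.0, 41.0),
    "ferritin": (540.0, 280.0),
    "wbc": (7.4, 2.4),
    "lymphocyte_pct": (20.3, 7.3),
    "npna": (1.0, 0.2),
    "spktv": (1.6, 0.3),
    "bmi": (26.6, 6.7),
}

#: Baseline comorbidity prevalences.
COMORBIDITY_PREV = {
    "diabetes": 0.57,
    "hypertension": 0.79,
    "ischemic_heart_disease": 0.21,
    "congestive_heart_failure": 0.28,
    "cerebrovascular_disease": 0.07,
    "peripheral_vascular_disease": 0.11,
    "copd": 0.05,
    "malignancy": 0.04,
    "nonambulatory": 0.05,
    "current_smoking": 0.05,
}

RACE_PROBS = (0.43, 0.32, 0.14, 0.03, 0.08)
MARITAL_PROBS = (0.48, 0.08, 0.28, 0.16)
INSURANCE_PROBS = (0.63, 0.05, 0.09, 0.23)
VINTAGE_PROBS = (0.44, 0.16, 0.25, 0.15)
VINTAGE_DAY_RANGES = ((90, 182), (183, 730), (731, 1825), (1826, 3650))


@dataclass
class SimulationTruth:
    """Complete structural specification of a synthetic cohort.

    Hazards are discrete-time (one Bernoulli per quarter).  The death logit
    for a patient with frailty ``u ~ N(0, frailty_sd^2)`` in category ``k``
    is ``baseline_death_logit + true_log_or[k-1] (k>0) +
    hb_effect_on_death*(Hb - 12) + u``; Hb is
    ``hb_base + frailty_on_hb*u + confounding_feedback*(prior_cat - 2) +
    noise``; the prescribed category follows a proportional-odds model with
    linear predictor ``treatment_response`` applied to centred Hb, albumin
    and the prior category.
    """

    n_patients: int = 20_000
    n_quarters: int = 12
    #: Marginal structural log-ORs for categories 1–5 vs the <6 000 reference.
    true_log_or: tuple = (0.0, 0.0, 0.0, 0.0, 0.0)
    #: g/dL change in next-quarter Hb per dose-category step above 2.
    confounding_feedback: float = 0.25
    #: Proportional-odds coefficients for dose assignment:
    #: (per g/dL Hb above 12, per g/dL albumin above 3.7, per prior category
    #: step above 2).  Negative Hb coefficient = higher Hb, lower dose.
    treatment_response: tuple = (-0.9, -0.5, 0.8)
    #: Death log-odds per g/dL Hb above 12 (0 disables the indirect path).
    hb_effect_on_death: float = 0.0
    #: Censoring logit terms: intercept and per-g/dL Hb slope (healthier
    #: patients are likelier to be transplanted or transferred).
    censoring_coeffs: tuple = (-3.9, 0.15)
    baseline_death_logit: float = -3.3
    #: SD of the shared patient frailty on the death-logit scale.
    frailty_sd: float = 0.8
    #: g/dL of Hb per unit of frailty.
    frailty_on_hb: float = 0.6
    hb_base_mean: float = 12.1
    hb_base_sd: float = 0.7
    hb_noise_sd: float = 0.5
    albumin_mean: float = 3.7
    albumin_sd: float = 0.35
    albumin_noise_sd: float = 0.1
    #: Proportional-odds cutpoints giving roughly (5, 18, 21, 17, 12, 27)%
    #: category frequencies at a neutral linear predictor.
    dose_cutpoints: tuple = (-2.944, -1.208, -0.241, 0.447, 0.995)
    #: P(cause | death) for (cardiovascular, infectious, other) at the
    #: reference category; slopes shift the CV and infectious log-weights
    #: per category step.
    cause_probs: tuple = (0.45, 0.15, 0.40)
    cause_cv_slope: float = 0.0
    cause_inf_slope: float = 0.0
    censor_reason_probs: tuple = (0.5, 0.3, 0.2)  # transplant, modality, transfer
    missingness_rates: tuple = (0.0, 0.0)  # (baseline, time-varying)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1 or self.n_quarters < 1:
            raise ParameterizationError("n_patients and n_quarters must be >= 1")
        lor = np.asarray(self.true_log_or, dtype=float)
        if lor.shape != (5,) or not np.all(np.isfinite(lor)):
            raise ParameterizationError("true_log_or must be 5 finite values")
        for r in self.missingness_rates:
            if not (0.0 <= r < 1.0):
                raise ParameterizationError("missingness rates must be in [0, 1)")
        if not np.all(np.diff(self.dose_cutpoints) > 0):
            raise ParameterizationError("dose_cutpoints must be increasing")
        probs = np.asarray(self.cause_probs, dtype=float)
        if probs.shape != (3,) or abs(probs.sum() - 1.0) > 1e-8 or (probs < 0).any():
            raise ParameterizationError("cause_probs must be a 3-simplex point")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationTruth":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ParameterizationError(f"unknown truth fields: {sorted(extra)}")
        t = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})
        t.validate()
        return t


# -- canonical scenarios ----------------------------------------------------

def default_truth(n_patients: int = 20_000, n_quarters: int = 12, seed: int = 0) -> SimulationTruth:
    """Confounded scenario with a dose effect on the cohort's scale.

    True marginal ORs track the magnitudes reported for the upper dose
    categories (1.02, 1.08, 1.17, 1.27, 1.52); Hb affects death directly, so
    this scenario is for descriptive/diagnostic use, not exact-recovery tests.
    """
    return SimulationTruth(
        n_patients=n_patients,
        n_quarters=n_quarters,
        true_log_or=tuple(np.log([1.02, 1.08, 1.17, 1.27, 1.52])),
        hb_effect_on_death=-0.35,
        missingness_rates=(0.03, 0.05),
        seed=seed,
    )


def null_truth(n_patients: int = 5_000, n_quarters: int = 8, seed: int = 0) -> SimulationTruth:
    """Confounded null: no causal dose effect, active Hb feedback.

    Frailty raises Hb (hence lowers the prescribed dose) and raises the
    death hazard, so the crude pooled OR is biased downward for high doses
    while every forced-regime OR is exactly 1.
    """
    return SimulationTruth(
        n_patients=n_patients,
        n_quarters=n_quarters,
        true_log_or=(0.0,) * 5,
        hb_effect_on_death=0.0,
        seed=seed,
    )


def randomized_truth(n_patients: int = 20_000, n_quarters: int = 8, seed: int = 0) -> SimulationTruth:
    """Dose assigned independently of all covariates (randomized regime)."""
    return SimulationTruth(
        n_patients=n_patients,
        n_quarters=n_quarters,
        treatment_response=(0.0, 0.0, 0.0),
        hb_effect_on_death=0.0,
        seed=seed,
    )


def effect_truth(
    odds_ratios=(1.0, 1.0, 1.0, 1.2, 1.3, 1.5),
    n_patients: int = 20_000,
    n_quarters: int = 8,
    seed: int = 0,
) -> SimulationTruth:
    """Confounded scenario with known direct dose effects and no Hb→death path.

    With ``hb_effect_on_death = 0`` the marginal forced-category OR is fully
    determined by the direct effect, so parameter-recovery tests can compare
    the weighted fit against the g-computation oracle without an indirect
    pathway through Hb.
    """
    ors = np.asarray(odds_ratios, dtype=float)
    if ors.shape != (6,) or ors[0] != 1.0:
        raise ParameterizationError("odds_ratios must be 6 values with reference 1.0")
    return SimulationTruth(
        n_patients=n_patients,
        n_quarters=n_quarters,
        true_log_or=tuple(np.log(ors[1:])),
        hb_effect_on_death=0.0,
        seed=seed,
    )


SCENARIOS = {
    "default": default_truth,
    "null": null_truth,
    "randomized": randomized_truth,
    "effect": effect_truth,
}


# -- generator --------------------------------------------------------------

def _draw_baselines(truth: SimulationTruth, rng: np.random.Generator) -> pd.DataFrame:
    n = truth.n_patients
    age = rng.normal(62.0, 15.0, size=n)
    while True:  # truncate at the adult inclusion bound
        under = age < 18.0
        if not under.any():
            break
        age[under] = rng.normal(62.0, 15.0, size=int(under.sum()))
    vint_cat = rng.choice(len(VINTAGE_LEVELS), size=n, p=VINTAGE_PROBS)
    lo = np.array([r[0] for r in VINTAGE_DAY_RANGES])[vint_cat]
    hi = np.array([r[1] for r in VINTAGE_DAY_RANGES])[vint_cat]
    base = {
        "patient_id": np.array([f"P{i:06d}" for i in range(n)]),
        "age": np.round(age, 1),
        "sex": np.where(rng.random(n) < 0.55, "female", "male"),
        "race": rng.choice(RACE_LEVELS, size=n, p=RACE_PROBS),
        "marital_status": rng.choice(MARITAL_LEVELS, size=n, p=MARITAL_PROBS),
        "insurance": rng.choice(INSURANCE_LEVELS, size=n, p=INSURANCE_PROBS),
        "vintage_days": rng.integers(lo, hi + 1),
        "vintage_category": np.asarray(VINTAGE_LEVELS, dtype=object)[vint_cat],
        "entry_quarter": rng.integers(0, 20, size=n),
    }
    for name in COMORBIDITIES:
        base[name] = (rng.random(n) < COMORBIDITY_PREV[name]).astype(int)
    return pd.DataFrame(base)


def _draw_category(truth: SimulationTruth, eta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Proportional-odds draw: P(cat <= k) = expit(c_k - eta)."""
    cum = expit(np.subtract.outer(np.asarray(truth.dose_cutpoints), eta)).T  # (n, 5)
    u = rng.random(eta.shape[0])[:, None]
    return (u > cum).sum(axis=1)


def _draw_dose_within(cat: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    edges = np.asarray(DOSE_EDGES[:-1] + (45_000.0,))  # top band capped for sampling
    lower = edges[cat]
    upper = edges[cat + 1]
    return lower + rng.random(cat.shape[0]) * (upper - lower)


def _draw_cause(truth: SimulationTruth, cat: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    logw = np.log(np.maximum(np.asarray(truth.cause_probs, dtype=float), 1e-300))
    w = np.tile(logw, (cat.shape[0], 1))
    w[:, 0] += truth.cause_cv_slope * cat
    w[:, 1] += truth.cause_inf_slope * cat
    p = np.exp(w - w.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(cat.shape[0])[:, None]
    idx = (u > p.cumsum(axis=1)).sum(axis=1)
    return np.asarray(["cardiovascular", "infectious", "other"], dtype=object)[idx]


def simulate_cohort(
    truth: SimulationTruth, seed: int | None = None
) -> tuple[PanelDataset, SimulationTruth]:
    """Simulate one cohort under the structural model in ``truth``.

    Returns the panel (satisfying every panel invariant) together with the
    truth record used, so estimates can be compared to stored ground truth.
    Identical ``truth`` + seed give byte-identical output.
    """
    truth.validate()
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    n = truth.n_patients
    theta = np.concatenate([[0.0], np.asarray(truth.true_log_or, dtype=float)])
    b_hb, b_alb, b_prior = truth.treatment_response
    cens_int, cens_hb = truth.censoring_coeffs

    baselines = _draw_baselines(truth, rng)
    frailty = rng.normal(0.0, truth.frailty_sd, size=n) if truth.frailty_sd > 0 else np.zeros(n)
    hb_base = rng.normal(truth.hb_base_mean, truth.hb_base_sd, size=n)
    alb_base = rng.normal(truth.albumin_mean, truth.albumin_sd, size=n)
    lab_base = {
        lab: np.maximum(rng.normal(m, s, size=n), 0.05 * m)
        for lab, (m, s) in LAB_MARGINALS.items()
    }

    alive = np.arange(n)
    prior_cat = np.full(n, -1)  # -1 encodes "no prior dose" (entry quarter)
    rows: list[pd.DataFrame] = []
    base_lab_record: dict[str, np.ndarray] = {}

    for t in range(truth.n_quarters):
        idx = alive
        if idx.size == 0:
            break
        prior_term = np.where(prior_cat[idx] >= 0, prior_cat[idx] - 2.0, 0.0)
        hb = (
            hb_base[idx]
            + truth.frailty_on_hb * frailty[idx]
            + truth.confounding_feedback * prior_term
            + rng.normal(0.0, truth.hb_noise_sd, size=idx.size)
        ).clip(5.0, 18.0)
        alb = (alb_base[idx] + rng.normal(0.0, truth.albumin_noise_sd, size=idx.size)).clip(1.5, 5.5)

        eta = b_hb * (hb - 12.0) + b_alb * (alb - 3.7) + b_prior * prior_term
        cat = _draw_category(truth, eta, rng)
        dose = _draw_dose_within(cat, rng)

        death_logit = (
            truth.baseline_death_logit
            + theta[cat]
            + truth.hb_effect_on_death * (hb - 12.0)
            + frailty[idx]
        )
        died = rng.random(idx.size) < expit(death_logit)

        cens_logit = cens_int + cens_hb * (hb - 12.0)
        censored = (~died) & (rng.random(idx.size) < expit(cens_logit))
        admin_end = (~died) & (~censored) & (t == truth.n_quarters - 1)

        cause = np.full(idx.size, "none", dtype=object)
        if died.any():
            cause[died] = _draw_cause(truth, cat[died], rng)
        reason = np.full(idx.size, "none", dtype=object)
        if censored.any():
            reason[censored] = rng.choice(
                ["transplant", "modality_change", "transfer"],
                size=int(censored.sum()),
                p=truth.censor_reason_probs,
            )
        reason[admin_end] = "admin_end"

        q = {
            "patient_id": baselines["patient_id"].to_numpy()[idx],
            "quarter_index": np.full(idx.size, t),
            "weekly_dose": dose,
            "dose_category": cat,
            "prior_dose_category": np.where(prior_cat[idx] >= 0, prior_cat[idx], np.nan),
            "hb": np.round(hb, 3),
            "albumin": np.round(alb, 3),
            "died": died.astype(int),
            "cause_of_death": cause,
            "censored": (censored | admin_end).astype(int),
            "censor_reason": reason,
        }
        for lab, (m, s) in LAB_MARGINALS.items():
            q[lab] = np.round(
                np.maximum(lab_base[lab][idx] + rng.normal(0.0, 0.2 * s, size=idx.size), 0.05 * m),
                3,
            )
        if t == 0:
            base_lab_record = {"base_hb": q["hb"], "base_albumin": q["albumin"]}
            for lab in LAB_MARGINALS:
                base_lab_record[f"base_{lab}"] = q[lab]
        rows.append(pd.DataFrame(q))

        prior_cat = prior_cat.copy()
        prior_cat[idx] = cat
        alive = idx[~died & ~censored]

    records = pd.concat(rows, ignore_index=True)
    # q0 uses rounded labs, so dose_category stays derived from the true hb draw
    for col, vals in base_lab_record.items():
        baselines[col] = vals

    records, baselines = _apply_missingness(truth, records, baselines, rng)

    cols = [c for c in records.columns]
    order = [
        "patient_id", "quarter_index", "weekly_dose", "dose_category",
        "prior_dose_category",
        "hb", "albumin",
        *[lab for lab in TIME_VARYING_LABS if lab not in ("hb", "albumin")],
        "died", "cause_of_death", "censored", "censor_reason",
    ]
    records = records[[c for c in order if c in cols]]
    panel = PanelDataset(
        records.sort_values(["patient_id", "quarter_index"]).reset_index(drop=True),
        baselines,
        {"scenario_seed": int(truth.seed if seed is None else seed),
         "n_quarters": truth.n_quarters},
    )
    return panel, truth


def _apply_missingness(truth, records, baselines, rng):
    base_rate, tv_rate = truth.missingness_rates
    if base_rate > 0:
        maskable = ["marital_status", "insurance"] + [
            c for c in baselines.columns if c.startswith("base_") and c != "base_hb"
        ]
        for col in maskable:
            m = rng.random(len(baselines)) < base_rate
            baselines.loc[m, col] = np.nan
    if tv_rate > 0:
        later = records["quarter_index"] > 0  # entry quarter stays complete for LOCF
        for lab in TIME_VARYING_LABS:
            if lab in records.columns:
                m = later & (rng.random(len(records)) < tv_rate)
                records.loc[m, lab] = np.nan
    return records, baselines


# -- g-computation oracle ---------------------------------------------------

@dataclass
class GcomputeResult:
    category: int
    odds: float
    odds_reference: float
    odds_ratio: float
    log_or: float
    se_log_or: float
    n_deaths: int
    n_quarters_at_risk: int


def _forced_regime_counts(
    truth: SimulationTruth, category: int, mc_reps: int, rng: np.random.Generator,
    outcome: str = "all_cause",
) -> tuple[int, int]:
    """Deaths and at-risk person-quarters when dose is forced to ``category``.

    Censoring is switched off (the estimand intervenes on censoring as well);
    for cause-specific outcomes, deaths from other causes end follow-up as
    non-events.
    """
    theta = np.concatenate([[0.0], np.asarray(truth.true_log_or, dtype=float)])
    frailty = (
        rng.normal(0.0, truth.frailty_sd, size=mc_reps)
        if truth.frailty_sd > 0
        else np.zeros(mc_reps)
    )
    hb_base = rng.normal(truth.hb_base_mean, truth.hb_base_sd, size=mc_reps)
    alive = np.ones(mc_reps, dtype=bool)
    events = 0
    at_risk = 0
    for t in range(truth.n_quarters):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        prior_term = 0.0 if t == 0 else (category - 2.0)
        hb = (
            hb_base[idx]
            + truth.frailty_on_hb * frailty[idx]
            + truth.confounding_feedback * prior_term
            + rng.normal(0.0, truth.hb_noise_sd, size=idx.size)
        ).clip(5.0, 18.0)
        death_logit = (
            truth.baseline_death_logit
            + theta[category]
            + truth.hb_effect_on_death * (hb - 12.0)
            + frailty[idx]
        )
        died = rng.random(idx.size) < expit(death_logit)
        at_risk += idx.size
        if outcome == "all_cause":
            events += int(died.sum())
        else:
            cat_arr = np.full(int(died.sum()), category)
            cause = _draw_cause(truth, cat_arr, rng)
            target = "cardiovascular" if outcome == "cardiovascular" else "infectious"
            events += int((cause == target).sum())
        alive[idx[died]] = False
    return events, at_risk


def gcompute_truth(
    truth: SimulationTruth,
    category: int,
    mc_reps: int = 200_000,
    seed: int = 0,
    outcome: str = "all_cause",
) -> GcomputeResult:
    """Marginal pooled death odds and OR vs reference under "always category k".

    Simulates the structural model ``mc_reps`` times with the dose held at
    ``category`` every quarter and censoring disabled, pooling deaths over
    person-quarters; the same is done at the reference category and the
    odds ratio returned with its Monte-Carlo standard error.  Raises
    :class:`DegenerateHazardError` when either arm has zero deaths (or zero
    survivors), in which case the odds ratio is undefined.
    """
    truth.validate()
    if not (0 <= category <= 5):
        raise ParameterizationError("category must be 0..5")
    rng = np.random.default_rng(seed)
    d_k, n_k = _forced_regime_counts(truth, category, mc_reps, rng, outcome)
    rng_ref = np.random.default_rng(seed + 1)
    d_0, n_0 = _forced_regime_counts(truth, 0, mc_reps, rng_ref, outcome)
    s_k, s_0 = n_k - d_k, n_0 - d_0
    if min(d_k, d_0, s_k, s_0) == 0:
        raise DegenerateHazardError(
            f"degenerate hazards (deaths {d_k}/{d_0}, survivors {s_k}/{s_0}); "
            "odds ratio undefined"
        )
    odds_k, odds_0 = d_k / s_k, d_0 / s_0
    log_or = float(np.log(odds_k / odds_0))
    se = float(np.sqrt(1 / d_k + 1 / s_k + 1 / d_0 + 1 / s_0))
    return GcomputeResult(
        category=category,
        odds=float(odds_k),
        odds_reference=float(odds_0),
        odds_ratio=float(odds_k / odds_0),
        log_or=log_or,
        se_log_or=se,
        n_deaths=d_k,
        n_quarters_at_risk=n_k,
    )
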