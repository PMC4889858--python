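"""Longitudinal patient-quarter panels: data model, I/O, filters, imputation.

The analysis operates on long-format panels with one row per patient per
calendar quarter.  Weekly erythropoiesis-stimulating-agent (ESA) dose is
averaged within each quarter and binned into six pre-specified ordinal
categories; the lowest category (<6 000 U/week) is the reference level in
every downstream model.  Quarters are modelled as exactly 13 weeks so that
dose averaging is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Weekly-dose category boundaries in U/week; intervals are left-closed,
#: right-open, so 6 000 U/week falls in category 1.
DOSE_EDGES = (0.0, 6000.0, 12000.0, 18000.0, 24000.0, 30000.0, np.inf)

#: Number of weeks used for quarterly dose averaging.
WEEKS_PER_QUARTER = 13

#: Time-varying laboratory covariates carried on every patient-quarter row.
TIME_VARYING_LABS = (
    "hb",
    "albumin",
    "creatinine",
    "calcium",
    "phosphorus",
    "bicarbonate",
    "tibc",
    "ferritin",
    "wbc",
    "lymphocyte_pct",
    "npna",
    "spktv",
    "bmi",
)

#: Fixed vocabularies for baseline categoricals.
SEX_LEVELS = ("male", "female")
RACE_LEVELS = ("Caucasian", "African American", "Hispanic", "Asian", "other")
MARITAL_LEVELS = ("married", "divorced", "single", "widowed")
INSURANCE_LEVELS = ("Medicare", "Medicaid", "private", "other")
VINTAGE_LEVELS = ("<6mo", "6-<24mo", "2-<5y", ">=5y")
COMORBIDITIES = (
    "diabetes",
    "hypertension",
    "ischemic_heart_disease",
    "congestive_heart_failure",
    "cerebrovascular_disease",
    "peripheral_vascular_disease",
    "copd",
    "malignancy",
    "nonambulatory",
    "current_smoking",
)

CAUSE_LEVELS = ("cardiovascular", "infectious", "other", "none")
CENSOR_REASONS = ("transplant", "modality_change", "transfer", "admin_end", "none")
#: Censoring reasons treated as informative (modelled by IPCW); the
#: administrative end of follow-up is deterministic and excluded.
INFORMATIVE_CENSOR_REASONS = ("transplant", "modality_change", "transfer")

PANEL_COLUMNS = (
    "patient_id",
    "quarter_index",
    "weekly_dose",
    "dose_category",
    "prior_dose_category",
    *TIME_VARYING_LABS,
    "died",
    "cause_of_death",
    "censored",
    "censor_reason",
)

BASELINE_COLUMNS = (
    "patient_id",
    "age",
    "sex",
    "race",
    "marital_status",
    "insurance",
    "vintage_days",
    "vintage_category",
    "entry_quarter",
    *COMORBIDITIES,
    *[f"base_{lab}" for lab in TIME_VARYING_LABS],
)


class PanelError(ValueError):
    """Structural problem in a patient-quarter panel."""


@dataclass(frozen=True)
class DoseCategory:
    """One ordinal weekly-dose band: ``[lower_bound, upper_bound)`` U/week."""

    index: int
    lower_bound: float
    upper_bound: float

    def __contains__(self, dose: float) -> bool:
        return self.lower_bound <= dose < self.upper_bound


DOSE_CATEGORIES = tuple(
    DoseCategory(i, DOSE_EDGES[i], DOSE_EDGES[i + 1]) for i in range(6)
)

#: Reference dose category in all estimation (<6 000 U/week).
REFERENCE_CATEGORY = 0


def categorize_dose(weekly_dose):
    """Map weekly ESA dose (U/week) to its ordinal category 0–5.

    Accepts a scalar or array; intervals are left-closed, so a dose exactly
    on a boundary falls into the upper category.  Negative or non-finite
    doses raise ``PanelError``.
    """
    arr = np.asarray(weekly_dose, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0):
        raise PanelError("weekly_dose must be finite and >= 0")
    cat = np.digitize(arr, DOSE_EDGES[1:-1], right=False)
    if np.isscalar(weekly_dose) or arr.ndim == 0:
        return int(cat)
    return cat.astype(int)


def average_quarterly_dose(
    administrations: Sequence[tuple],
    quarter: tuple | None = None,
    at_risk_weeks: float = WEEKS_PER_QUARTER,
    carried_forward: float | None = None,
):
    """Average administered ESA over the weeks of a quarter.

    Parameters
    ----------
    administrations
        ``(time, units)`` pairs; ``time`` may be any orderable stamp (date,
        day offset, week index).  All must fall within ``quarter`` when a
        ``(start, end)`` interval is given (half-open on the right).
    quarter
        Optional ``(start, end)`` pair used only to validate stamps.
    at_risk_weeks
        Weeks of the quarter during which the patient was at risk (13 for a
        full quarter; fewer for a partial final quarter).
    carried_forward
        Weekly dose carried forward from the previous quarter; used when no
        administrations were recorded.

    Returns
    -------
    float or None
        Weekly dose in U/week, or ``None`` when there were no
        administrations and nothing to carry forward (the record is then
        excluded by the completeness rule).
    """
    if at_risk_weeks <= 0:
        raise PanelError("at_risk_weeks must be positive")
    if quarter is not None:
        start, end = quarter
        for stamp, _ in administrations:
            if not (start <= stamp < end):
                raise PanelError(f"administration at {stamp!r} outside quarter")
    if not administrations:
        return carried_forward
    total = float(sum(units for _, units in administrations))
    return total / float(at_risk_weeks)


def impute_hospital_dose(
    weekly_doses: pd.Series,
    hospitalization_intervals: Iterable[tuple[int, int]],
) -> pd.Series:
    """Fill hospitalized weeks with the most recent pre-hospital dose.

    ``weekly_doses`` is indexed by week; ``hospitalization_intervals`` are
    half-open ``[start_week, end_week)`` index ranges that must not overlap.
    A hospitalization with no recorded dose before it is left missing and
    logged.  Non-hospital weeks are never altered.
    """
    intervals = sorted(hospitalization_intervals)
    for (s1, e1), (s2, _) in zip(intervals, intervals[1:]):
        if s2 < e1:
            raise PanelError("hospitalization intervals overlap")
    out = weekly_doses.copy()
    for start, end in intervals:
        prior = weekly_doses.loc[: start - 1].dropna() if start > 0 else weekly_doses.iloc[:0]
        if prior.empty:
            logger.warning(
                "hospitalization [%s, %s) precedes any recorded dose; left missing",
                start,
                end,
            )
            continue
        fill = prior.iloc[-1]
        weeks = [w for w in out.index if start <= w < end]
        out.loc[weeks] = fill
    return out


@dataclass
class PanelDataset:
    """A patient-quarter panel plus its baseline covariate table.

    ``records`` has one row per patient-quarter (``PANEL_COLUMNS``);
    ``baselines`` one row per patient (``BASELINE_COLUMNS``).  ``meta``
    carries the study window and provenance notes.
    """

    records: pd.DataFrame
    baselines: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def n_patients(self) -> int:
        return self.baselines["patient_id"].nunique()

    @property
    def n_person_quarters(self) -> int:
        return len(self.records)

    def copy(self) -> "PanelDataset":
        return PanelDataset(
            self.records.copy(), self.baselines.copy(), dict(self.meta)
        )


def validate_panel(panel: PanelDataset) -> None:
    """Check the structural invariants of a panel; raise ``PanelError``.

    Invariants: baseline/record patient sets match; quarter indices are
    consecutive from 0 within patient; death and censoring are mutually
    exclusive and terminal; cause of death is present iff died; the stored
    dose category matches ``categorize_dose`` wherever dose is observed.
    """
    rec, base = panel.records, panel.baselines
    rec_ids = set(rec["patient_id"].unique())
    base_ids = set(base["patient_id"].unique())
    if rec_ids != base_ids:
        raise PanelError("patient_id mismatch between records and baselines")
    if base["patient_id"].duplicated().any():
        raise PanelError("duplicate patient_id in baselines")

    g = rec.sort_values(["patient_id", "quarter_index"]).groupby(
        "patient_id", sort=False
    )
    q = g["quarter_index"]
    first, last, count = q.first(), q.last(), q.count()
    if (first != 0).any() or (last != count - 1).any():
        raise PanelError("quarter_index must be consecutive from 0 per patient")

    if ((rec["died"] == 1) & (rec["censored"] == 1)).any():
        raise PanelError("died and censored are mutually exclusive")
    nonterminal = rec.sort_values(["patient_id", "quarter_index"]).groupby(
        "patient_id", sort=False
    ).apply(
        lambda d: (d["died"].iloc[:-1].any() or d["censored"].iloc[:-1].any()),
        include_groups=False,
    )
    if nonterminal.any():
        raise PanelError("event/censoring flags may be set only in the final record")

    bad_cause = (rec["died"] == 1) != (rec["cause_of_death"] != "none")
    if bad_cause.any():
        raise PanelError("cause_of_death must be set iff died == 1")

    obs = rec["weekly_dose"].notna()
    if obs.any():
        expect = categorize_dose(rec.loc[obs, "weekly_dose"].to_numpy())
        if (rec.loc[obs, "dose_category"].to_numpy() != expect).any():
            raise PanelError("dose_category inconsistent with weekly_dose")


def add_lagged_labs(records: pd.DataFrame, labs: Sequence[str] = TIME_VARYING_LABS) -> pd.DataFrame:
    """Return records with ``<lab>_lag`` columns (previous quarter's value)."""
    out = records.sort_values(["patient_id", "quarter_index"]).copy()
    g = out.groupby("patient_id", sort=False)
    for lab in labs:
        if lab in out.columns:
            out[f"{lab}_lag"] = g[lab].shift(1)
    return out


def locf_impute(panel: PanelDataset, labs: Sequence[str] = TIME_VARYING_LABS) -> PanelDataset:
    """Last-observation-carried-forward for time-varying labs.

    Missing lab values are replaced by the patient's most recent observed
    value (no look-ahead); observed values are untouched.  Idempotent.
    """
    out = panel.copy()
    out.records = out.records.sort_values(["patient_id", "quarter_index"]).reset_index(
        drop=True
    )
    cols = [c for c in labs if c in out.records.columns]
    g = out.records.groupby("patient_id", sort=False)
    out.records[cols] = g[cols].ffill()
    return out


def apply_inclusion_filters(
    panel: PanelDataset,
    min_age: float = 18.0,
    min_hd_days: float = 90.0,
) -> tuple[PanelDataset, dict]:
    """Apply cohort inclusion rules; return filtered panel and exclusion tally.

    Rules, applied sequentially so each excluded patient is tallied under the
    first criterion failed: age >= 18 at entry; >= 90 days of hemodialysis
    before entry; complete data on the exposure (weekly dose) and core
    covariate (hemoglobin) in the entry quarter.  Raises ``PanelError`` when
    no patient survives the filters.
    """
    base = panel.baselines
    tally = {"age": 0, "hd_duration": 0, "missing_exposure_or_hb": 0}

    ok_age = base["age"] >= min_age
    tally["age"] = int((~ok_age).sum())
    ok_vintage = base["vintage_days"] >= min_hd_days
    tally["hd_duration"] = int((ok_age & ~ok_vintage).sum())

    q0 = panel.records[panel.records["quarter_index"] == 0].set_index("patient_id")
    complete = q0["weekly_dose"].notna() & q0["hb"].notna()
    complete = base["patient_id"].map(complete).fillna(False)
    tally["missing_exposure_or_hb"] = int((ok_age & ok_vintage & ~complete).sum())

    keep = base.loc[ok_age & ok_vintage & complete, "patient_id"]
    if keep.empty:
        raise PanelError("no eligible patients after inclusion filters")
    out = PanelDataset(
        panel.records[panel.records["patient_id"].isin(set(keep))].reset_index(drop=True),
        base[base["patient_id"].isin(set(keep))].reset_index(drop=True),
        dict(panel.meta, inclusion_tally=tally),
    )
    logger.info("inclusion filters: %s excluded, %d retained", tally, len(keep))
    return out, tally


def filter_incident(panel: PanelDataset) -> PanelDataset:
    """Restrict to the incident subcohort (dialysis vintage < 6 months)."""
    base = panel.baselines
    keep = set(base.loc[base["vintage_category"] == "<6mo", "patient_id"])
    return PanelDataset(
        panel.records[panel.records["patient_id"].isin(keep)].reset_index(drop=True),
        base[base["patient_id"].isin(keep)].reset_index(drop=True),
        dict(panel.meta, incident_only=True),
    )


def drop_incomplete_records(panel: PanelDataset) -> tuple[PanelDataset, int]:
    """Drop trailing records still missing exposure or Hb after imputation.

    Only a patient's trailing incomplete quarters can be dropped without
    breaking the consecutive-quarter invariant; an interior gap raises
    ``PanelError`` (it indicates an upstream imputation failure).
    """
    rec = panel.records.sort_values(["patient_id", "quarter_index"])
    bad = rec["weekly_dose"].isna() | rec["hb"].isna()
    if not bad.any():
        return panel, 0
    # keep the complete prefix of each patient's series; only a trailing
    # run of incomplete records can be dropped without breaking consecutiveness
    keep = (~bad).groupby(rec["patient_id"], sort=False).cummin()
    interior_gap = (~bad) & (~keep)
    if interior_gap.any():
        raise PanelError("interior record missing exposure/Hb after imputation")
    n_dropped = int((~keep).sum())
    out_rec = rec[keep].reset_index(drop=True)
    survivors = set(out_rec["patient_id"].unique())
    out = PanelDataset(
        out_rec,
        panel.baselines[panel.baselines["patient_id"].isin(survivors)].reset_index(
            drop=True
        ),
        dict(panel.meta, dropped_incomplete=n_dropped),
    )
    logger.info("dropped %d incomplete records", n_dropped)
    return out, n_dropped


# ---------------------------------------------------------------------------
# I/O: long-format CSV, one row per patient-quarter + a baseline table.

def write_panel(panel: PanelDataset, panel_path, baseline_path) -> None:
    """Write the panel as two CSV files (records + baselines)."""
    panel.records.to_csv(panel_path, index=False)
    panel.baselines.to_csv(baseline_path, index=False)


def read_panel(panel_path, baseline_path, meta: Mapping | None = None) -> PanelDataset:
    """Read a panel written by :func:`write_panel`; validates structure."""
    records = pd.read_csv(panel_path)
    baselines = pd.read_csv(baseline_path)
    missing = [c for c in ("patient_id", "quarter_index", "weekly_dose") if c not in records.columns]
    if missing:
        raise PanelError(f"panel file missing columns: {missing}")
    if "patient_id" not in baselines.columns:
        raise PanelError("baseline file missing patient_id")
    panel = PanelDataset(records, baselines, dict(meta or {}))
    validate_panel(panel)
    return panel
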