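"""Shared fixtures: small synthetic cohorts and hand-built panels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from esamsm.panel import PanelDataset, categorize_dose
from esamsm.simulate import null_truth, simulate_cohort

settings.register_profile("stable", derandomize=True)
settings.load_profile("stable")


def make_panel(rows, baseline_extra=None):
    """Build a PanelDataset from per-record dicts with minimal defaults.

    Each row needs patient_id and quarter_index; weekly_dose defaults to
    3000 (category 0), labs to plausible constants, flags to 0.
    """
    defaults = {
        "weekly_dose": 3000.0, "hb": 11.5, "albumin": 3.8,
        "died": 0, "cause_of_death": "none",
        "censored": 0, "censor_reason": "none",
    }
    recs = []
    for row in rows:
        r = dict(defaults, **row)
        r["dose_category"] = categorize_dose(r["weekly_dose"])
        recs.append(r)
    records = pd.DataFrame(recs).sort_values(["patient_id", "quarter_index"])
    records["prior_dose_category"] = records.groupby("patient_id", sort=False)[
        "dose_category"
    ].shift(1)
    ids = records["patient_id"].unique()
    base = pd.DataFrame({
        "patient_id": ids,
        "age": 60.0,
        "sex": "female",
        "race": "Caucasian",
        "vintage_days": 400.0,
        "vintage_category": "6-<24mo",
        "diabetes": 0,
        "base_hb": 12.0,
        "base_albumin": 3.8,
    })
    if baseline_extra:
        for col, vals in baseline_extra.items():
            base[col] = vals
    return PanelDataset(records.reset_index(drop=True), base)


@pytest.fixture(scope="session")
def small_null_cohort():
    """Confounded-null cohort, small enough for quick model fits."""
    panel, truth = simulate_cohort(null_truth(n_patients=1200, n_quarters=6), seed=101)
    return panel, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
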