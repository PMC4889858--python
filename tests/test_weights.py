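"""Weight estimation: oracle equivalence, stabilization, truncation, summary."""

import numpy as np
import pandas as pd
import pytest

from esamsm.simulate import randomized_truth, simulate_cohort
from esamsm.weights import (
    PositivityError,
    SUMMARY_ROWS,
    combine_weights,
    compute_stabilized_iptw,
    estimate_weights,
    fit_censoring_model_and_ipcw,
    fit_treatment_models,
    summarize_weights,
    truncate_weights,
)

from conftest import make_panel

DOSE0, DOSE1 = 3000.0, 8000.0  # categories 0 and 1


def _iptw_oracle_panel():
    """10 patients x 3 quarters, binary dose, binary Hb; every treatment-model
    cell holds both dose levels so the saturated MLE equals cell proportions."""
    plan = {  # patient -> (dose_q0, (hb_q1, dose_q1), (hb_q2, dose_q2))
        "p0": (0, (10, 0), (10, 1)),
        "p1": (0, (10, 1), (13, 0)),
        "p2": (0, (13, 0), (10, 0)),
        "p3": (0, (13, 1), (13, 1)),
        "p4": (0, (10, 0), (13, 0)),
        "p5": (1, (10, 0), (10, 1)),
        "p6": (1, (10, 1), (13, 1)),
        "p7": (1, (13, 0), (10, 1)),
        "p8": (1, (13, 1), (13, 0)),
        "p9": (1, (13, 0), (10, 0)),
    }
    rows = []
    for pid, (d0, q1, q2) in plan.items():
        rows.append({"patient_id": pid, "quarter_index": 0,
                     "weekly_dose": DOSE1 if d0 else DOSE0, "hb": 11.0})
        for t, (hb, d) in [(1, q1), (2, q2)]:
            rows.append({"patient_id": pid, "quarter_index": t,
                         "weekly_dose": DOSE1 if d else DOSE0, "hb": float(hb)})
    return make_panel(rows)


class TestIptwOracle:
    def test_saturated_pipeline_matches_cell_proportions(self):
        """Stabilized IPTW from the fitted pipeline equals brute-force
        probability ratios computed from cell counts, to 1e-10."""
        panel = _iptw_oracle_panel()
        models = fit_treatment_models(
            panel,
            baseline_terms="1",
            time_varying_terms="C(hb) + C(prior_cat):C(hb)",
            prior_terms="C(prior_cat)",
            include_quarter=False,
        )
        out = compute_stabilized_iptw(panel, models, mode="cumulative")

        rec = panel.records.sort_values(["patient_id", "quarter_index"])
        later = rec[rec.quarter_index >= 1].copy()
        later["prior"] = later["prior_dose_category"].astype(int)
        p_num = later.groupby(["prior"])["dose_category"].transform(
            lambda s: s.map(s.value_counts(normalize=True))
        )
        p_den = later.groupby(["prior", "hb"])["dose_category"].transform(
            lambda s: s.map(s.value_counts(normalize=True))
        )
        later["r"] = p_num / p_den
        expected = {}
        for pid, g in later.groupby("patient_id"):
            expected[pid] = [1.0, *np.cumprod(g.sort_values("quarter_index")["r"])]
        for _, row in out.iterrows():
            exp = expected[row.patient_id][int(row.quarter_index)]
            assert row.sw_iptw == pytest.approx(exp, abs=1e-10)

    def test_interval_mode_is_single_quarter_ratio(self):
        panel = _iptw_oracle_panel()
        models = fit_treatment_models(
            panel, baseline_terms="1",
            time_varying_terms="C(hb) + C(prior_cat):C(hb)",
            prior_terms="C(prior_cat)", include_quarter=False,
        )
        cum = compute_stabilized_iptw(panel, models, mode="cumulative")
        itv = compute_stabilized_iptw(panel, models, mode="interval")
        assert np.allclose(itv["sw_iptw"], itv["ratio"])
        g = cum.sort_values(["patient_id", "quarter_index"]).groupby("patient_id")
        recon = g["ratio"].cumprod()
        assert np.allclose(cum.sort_values(["patient_id", "quarter_index"])["sw_iptw"], recon)


class TestIpcwOracle:
    def _panel(self):
        # 10 patients x 2 quarters; 3 informative censoring events at q1,
        # rate 2/5 among hb=10 rows and 1/5 among hb=13 rows
        rows = []
        hbs = [10, 10, 10, 10, 10, 13, 13, 13, 13, 13]
        censored = {"p0", "p1", "p5"}
        for i, hb in enumerate(hbs):
            pid = f"p{i}"
            rows.append({"patient_id": pid, "quarter_index": 0, "hb": 11.0})
            rows.append({
                "patient_id": pid, "quarter_index": 1, "hb": float(hb),
                "censored": int(pid in censored),
                "censor_reason": "transfer" if pid in censored else "none",
            })
        return make_panel(rows)

    def test_saturated_ipcw_matches_hand_ratios(self):
        panel = self._panel()
        out = fit_censoring_model_and_ipcw(
            panel, baseline_terms="1", time_varying_terms="C(hb)",
            prior_terms="1", include_quarter=False, mode="cumulative",
        ).set_index(["patient_id", "quarter_index"])
        p_num = 3 / 10
        for i, hb in enumerate([10, 10, 10, 10, 10, 13, 13, 13, 13, 13]):
            p_den = 2 / 5 if hb == 10 else 1 / 5
            expected = (1 - p_num) / (1 - p_den)
            assert out.loc[(f"p{i}", 0), "sw_ipcw"] == pytest.approx(1.0, abs=1e-12)
            assert out.loc[(f"p{i}", 1), "sw_ipcw"] == pytest.approx(expected, abs=1e-10)

    def test_zero_censoring_gives_unit_weights(self):
        rows = [
            {"patient_id": f"p{i}", "quarter_index": t, "hb": 11.0 + i * 0.1}
            for i in range(6) for t in range(3)
        ]
        panel = make_panel(rows)
        out = fit_censoring_model_and_ipcw(panel)
        assert (out["sw_ipcw"] == 1.0).all()


class TestStabilizedWeightCalibration:
    def test_randomized_assignment_mean_weight_one(self):
        """With treatment independent of covariates, E[stabilized IPTW] = 1
        at every quarter (checked within 3 Monte-Carlo SEs)."""
        panel, _ = simulate_cohort(randomized_truth(n_patients=4000, n_quarters=5), seed=17)
        models = fit_treatment_models(panel)
        out = compute_stabilized_iptw(panel, models, mode="cumulative")
        for _, g in out.groupby("quarter_index"):
            se = g["sw_iptw"].std() / np.sqrt(len(g))
            assert abs(g["sw_iptw"].mean() - 1.0) <= max(3 * se, 1e-6)

    def test_positivity_error_names_unseen_category(self):
        train = _iptw_oracle_panel()  # only categories 0 and 1
        models = fit_treatment_models(
            train, baseline_terms="1",
            time_varying_terms="C(hb) + C(prior_cat):C(hb)",
            prior_terms="C(prior_cat)", include_quarter=False,
        )
        other = make_panel([
            {"patient_id": "x", "quarter_index": 0, "weekly_dose": 3000.0, "hb": 10.0},
            {"patient_id": "x", "quarter_index": 1, "weekly_dose": 20000.0, "hb": 10.0},
        ])
        with pytest.raises(PositivityError, match="3"):
            compute_stabilized_iptw(other, models)


class TestTruncation:
    def test_integer_vector_against_order_statistics(self):
        w = np.arange(1, 101, dtype=float)
        clipped, (lo, hi) = truncate_weights(w)

        def pct(v, p):  # independent nearest-rank percentile
            s = np.sort(v)
            return s[round(p / 100 * (len(s) - 1))]

        assert lo == pct(w, 1) == 2.0
        assert hi == pct(w, 99) == 99.0
        # exactly the extreme values are clipped, onto the bounds
        assert clipped[0] == lo and clipped[-1] == hi
        assert (clipped[1:-1] == w[1:-1]).all()
        assert clipped.min() == lo and clipped.max() == hi

    def test_all_equal_vector_unchanged(self):
        clipped, (lo, hi) = truncate_weights(np.full(50, 2.5))
        assert (clipped == 2.5).all() and lo == hi == 2.5

    def test_idempotent(self, rng):
        w = rng.lognormal(0, 1, size=500)
        once, bounds = truncate_weights(w)
        twice, _ = truncate_weights(once)
        assert np.allclose(once, twice)

    def test_rank_order_of_unclipped_preserved(self, rng):
        w = rng.lognormal(0, 1, size=500)
        clipped, (lo, hi) = truncate_weights(w)
        interior = (w > lo) & (w < hi)
        assert (np.argsort(w[interior], kind="stable")
                == np.argsort(clipped[interior], kind="stable")).all()

    def test_invalid_percentiles_rejected(self):
        with pytest.raises(ValueError):
            truncate_weights(np.ones(10), 99, 1)
        with pytest.raises(ValueError):
            truncate_weights(np.array([]))


class TestCombineAndSummarize:
    def test_final_weight_is_exact_product(self, rng):
        n = 40
        keys = pd.DataFrame({
            "patient_id": [f"p{i//4}" for i in range(n)],
            "quarter_index": [i % 4 for i in range(n)],
        })
        iptw = keys.assign(sw_iptw=rng.lognormal(0, 0.5, n))
        ipcw = keys.assign(sw_ipcw=rng.lognormal(0, 0.2, n))
        out = combine_weights(iptw, ipcw)
        assert np.allclose(out["final_weight"], out["sw_iptw"] * out["sw_ipcw"],
                           rtol=0, atol=0)

    def test_unit_ipcw_leaves_iptw(self):
        keys = pd.DataFrame({"patient_id": ["a", "a"], "quarter_index": [0, 1]})
        iptw = keys.assign(sw_iptw=[0.5, 1.2])
        ipcw = keys.assign(sw_ipcw=[1.0, 1.0])
        out = combine_weights(iptw, ipcw)
        assert out["final_weight"].tolist() == [0.5, 1.2]

    def test_mismatched_records_rejected(self):
        iptw = pd.DataFrame({"patient_id": ["a"], "quarter_index": [0], "sw_iptw": [1.0]})
        ipcw = pd.DataFrame({"patient_id": ["b"], "quarter_index": [0], "sw_ipcw": [1.0]})
        with pytest.raises(ValueError):
            combine_weights(iptw, ipcw)

    def test_summary_rows_and_percentile_oracle(self):
        frame = pd.DataFrame({
            "sw_iptw": np.arange(1, 1001, dtype=float),
            "sw_ipcw": np.ones(1000),
            "final_weight": np.arange(1, 1001, dtype=float),
        })
        table = summarize_weights(frame)
        assert list(table.index) == list(SUMMARY_ROWS)
        s = np.sort(frame["sw_iptw"].to_numpy())
        for row, p in [("99th", 99), ("50th (Median)", 50), ("1st", 1)]:
            i = p / 100 * 999
            f = int(np.floor(i))
            exp = s[f] + (i - f) * (s[f + 1] - s[f])
            assert table.loc[row, "sw_iptw"] == pytest.approx(exp)
        assert table.loc["Maximum", "sw_iptw"] == 1000
        assert table.loc["Mean", "sw_ipcw"] == 1.0

    def test_constant_vector_constant_rows(self):
        frame = pd.DataFrame({"final_weight": np.full(20, 3.0)})
        table = summarize_weights(frame, columns=("final_weight",))
        assert (table["final_weight"] == 3.0).all()


class TestEndToEndWeights:
    def test_zero_censoring_final_equals_iptw(self):
        truth = randomized_truth(n_patients=400, n_quarters=4)
        truth.censoring_coeffs = (-np.inf, 0.0)
        panel, _ = simulate_cohort(truth, seed=23)
        ws = estimate_weights(panel)
        assert (ws.frame["sw_ipcw"] == 1.0).all()
        assert (ws.frame["final_weight"] == ws.frame["sw_iptw"]).all()

    def test_truncation_bounds_recorded_and_respected(self, small_null_cohort):
        panel, _ = small_null_cohort
        ws = estimate_weights(panel, truncate_pcts=(5.0, 95.0))
        lo, hi = ws.truncation_bounds
        assert ws.frame["sw_iptw"].min() == pytest.approx(lo)
        assert ws.frame["sw_iptw"].max() == pytest.approx(hi)

    def test_single_exposure_level_rejected(self):
        rows = [{"patient_id": f"p{i}", "quarter_index": t}
                for i in range(5) for t in range(2)]
        with pytest.raises(ValueError, match="2 observed"):
            fit_treatment_models(make_panel(rows))
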