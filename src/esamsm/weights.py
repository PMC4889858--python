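"""Stabilized inverse-probability weights for treatment and censoring.

Treatment weights come from proportional-odds (cumulative logit) models of
the 6-level ordinal dose category: the stabilized weight at quarter *t* is
the (cumulative or per-interval) product of ratios
``P_num(A_s = a_s) / P_den(A_s = a_s)``, where the numerator conditions on
the previous dose category and baseline covariates and the denominator
additionally on current-quarter labs and their one-quarter lags.  Censoring
weights use binary logistic models of informative censoring with the same
numerator/denominator covariate split; they are never truncated.

At the entry quarter the time-varying labs coincide with the baseline lab
values, so the numerator and denominator condition on the same information
and the entry-quarter ratio is identically 1; models are therefore fitted
on quarters >= 1 only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm

from ._ordinal import OrdinalFitError, ProportionalOddsModel
from .panel import INFORMATIVE_CENSOR_REASONS, PanelDataset, add_lagged_labs

logger = logging.getLogger(__name__)

#: Default covariate term strings (patsy syntax) for the weight models.
DEFAULT_BASELINE_TERMS = (
    "age + C(sex) + C(race) + C(vintage_category) + diabetes"
    " + base_hb + base_albumin"
)
DEFAULT_TIME_VARYING_TERMS = "hb + albumin + hb_lag + albumin_lag"
DEFAULT_PRIOR_TERMS = "C(prior_cat)"

#: Hard floor on denominator probabilities; falling below it indicates a
#: positivity violation and raises rather than silently clipping.
POSITIVITY_FLOOR = 1e-12

#: Row labels of the weight-distribution summary table.
SUMMARY_ROWS = (
    "Maximum", "99th", "95th", "90th", "75th", "50th (Median)",
    "25th", "10th", "5th", "1st", "Minimum", "Mean",
)
_SUMMARY_PCTS = {
    "99th": 99, "95th": 95, "90th": 90, "75th": 75, "50th (Median)": 50,
    "25th": 25, "10th": 10, "5th": 5, "1st": 1,
}


class PositivityError(RuntimeError):
    """An estimated assignment probability collapsed toward zero."""


class ConvergenceError(RuntimeError):
    """A weight model failed to converge."""


def _fit_logit(y, X):
    """Logistic fit at machine precision when possible.

    Newton converges quadratically on well-conditioned (e.g. saturated)
    designs; on a singular Hessian — rich designs with few events — fall
    back to quasi-Newton, which still yields usable probabilities.
    """
    try:
        return sm.Logit(y, X).fit(method="newton", maxiter=200, tol=1e-12, disp=0)
    except (np.linalg.LinAlgError, Exception) as first:
        if isinstance(first, KeyboardInterrupt):
            raise
        try:
            return sm.Logit(y, X).fit(method="bfgs", maxiter=2000, gtol=1e-6, disp=0)
        except Exception as exc:
            raise ConvergenceError(f"logistic fit failed: {exc}") from exc


def build_model_frame(panel: PanelDataset) -> pd.DataFrame:
    """Flat modelling frame: records + lagged labs + baseline covariates.

    Adds ``prior_cat`` (integer previous-quarter category, -1 at entry) so
    formulas can use ``C(prior_cat)`` without NaN handling.
    """
    rec = add_lagged_labs(panel.records)
    frame = rec.merge(panel.baselines, on="patient_id", how="left", validate="m:1")
    frame = frame.sort_values(["patient_id", "quarter_index"]).reset_index(drop=True)
    frame["prior_cat"] = frame["prior_dose_category"].fillna(-1).astype(int)
    return frame


class CategoricalPropensityModel:
    """Probability model for an ordinal/binary category given covariates.

    Uses a proportional-odds model when three or more levels are observed
    and plain logistic regression (Newton, machine-precision convergence)
    when exactly two are; a single observed level degenerates to
    probability one with a positivity warning.
    """

    def __init__(self, formula: str):
        self.formula = formula
        self.levels_: np.ndarray | None = None
        self._design_info = None
        self._result = None
        self._kind = None

    def fit(self, frame: pd.DataFrame, endog: pd.Series) -> "CategoricalPropensityModel":
        y = endog.astype(int).to_numpy()
        self.levels_ = np.unique(y)
        X = patsy.dmatrix("1 + " + self.formula, frame, return_type="dataframe",
                          NA_action=patsy.NAAction(on_NA="raise"))
        self._design_info = X.design_info
        if len(self.levels_) == 1:
            logger.warning(
                "only category %s observed; probabilities degenerate to 1",
                self.levels_[0],
            )
            self._kind = "constant"
            return self
        if len(self.levels_) == 2:
            self._kind = "logit"
            ybin = (y == self.levels_[1]).astype(float)
            self._result = _fit_logit(ybin, X)
        else:
            self._kind = "ordinal"
            Xo = X.drop(columns="Intercept")  # cutpoints play the intercept role
            try:
                self._result = ProportionalOddsModel().fit(Xo.to_numpy(), y)
            except OrdinalFitError as exc:
                raise ConvergenceError(str(exc)) from exc
        return self

    def prob_observed(self, frame: pd.DataFrame, observed: pd.Series) -> np.ndarray:
        """P(category = observed value | covariates) per row."""
        obs = observed.astype(int).to_numpy()
        unknown = ~np.isin(obs, self.levels_)
        if unknown.any():
            raise PositivityError(
                f"category {np.unique(obs[unknown]).tolist()} never observed "
                "in the propensity fit"
            )
        (X,) = patsy.build_design_matrices([self._design_info], frame,
                                           return_type="dataframe",
                                           NA_action=patsy.NAAction(on_NA="raise"))
        if self._kind == "constant":
            return np.ones(len(frame))
        if self._kind == "logit":
            p1 = np.asarray(self._result.predict(X))
            return np.where(obs == self.levels_[1], p1, 1.0 - p1)
        Xo = X.drop(columns="Intercept")
        probs = self._result.predict_proba(Xo.to_numpy())
        col = np.searchsorted(self.levels_, obs)
        return probs[np.arange(len(obs)), col]


@dataclass
class TreatmentModels:
    numerator: CategoricalPropensityModel
    denominator: CategoricalPropensityModel
    baseline_terms: str
    time_varying_terms: str


@dataclass
class WeightSet:
    """Per patient-quarter weights, joinable on (patient_id, quarter_index).

    ``frame`` columns: ``p_num``/``p_den`` (observed-treatment probabilities),
    ``sw_iptw``, ``sw_ipcw``, ``final_weight`` (exact product).  IPTW may be
    percentile-truncated (bounds recorded); IPCW never is.
    """

    frame: pd.DataFrame
    mode: str = "cumulative"
    truncation_bounds: tuple | None = None
    meta: dict = field(default_factory=dict)

    @property
    def final_weight(self) -> pd.Series:
        return self.frame["final_weight"]


def _check_positivity(p: np.ndarray, frame: pd.DataFrame, label: str) -> None:
    low = p < POSITIVITY_FLOOR
    if low.any():
        i = int(np.flatnonzero(low)[0])
        raise PositivityError(
            f"{label} probability {p[i]:.3e} below floor for patient "
            f"{frame['patient_id'].iloc[i]} quarter {frame['quarter_index'].iloc[i]}"
        )


def fit_treatment_models(
    panel: PanelDataset,
    baseline_terms: str = DEFAULT_BASELINE_TERMS,
    time_varying_terms: str = DEFAULT_TIME_VARYING_TERMS,
    prior_terms: str = DEFAULT_PRIOR_TERMS,
    include_quarter: bool = True,
    numerator: str = "baseline",
) -> TreatmentModels:
    """Fit the stabilized-IPTW numerator and denominator ordinal models.

    Both are fitted on quarters >= 1 (the entry-quarter ratio is 1 by
    construction).  With ``numerator="baseline"`` (the analysis default) the
    numerator conditions on the prior category and baseline covariates,
    which must then also be adjusted for in the outcome model; with
    ``numerator="marginal"`` it is the unconditional category distribution,
    the construction under which the weighted pseudo-population is
    marginally balanced (used for balance diagnostics).  The denominator
    always adds the time-varying terms.  With fewer than two observed
    exposure levels the panel cannot identify a treatment model and a
    ``ValueError`` is raised.
    """
    frame = build_model_frame(panel)
    later = frame[frame["quarter_index"] >= 1]
    if frame["dose_category"].nunique() < 2:
        raise ValueError("need >= 2 observed exposure levels to fit treatment models")
    qterm = " + quarter_index" if include_quarter else ""
    if numerator == "baseline":
        num_formula = f"{prior_terms} + {baseline_terms}{qterm}"
    elif numerator == "marginal":
        num_formula = "1"
    else:
        raise ValueError(f"unknown numerator {numerator!r}")
    den_formula = f"{prior_terms} + {baseline_terms}{qterm} + {time_varying_terms}"
    observed = set(int(c) for c in later["dose_category"].unique())
    never_seen = sorted(set(range(6)) - observed)
    if never_seen and max(observed) > min(never_seen):
        logger.warning("positivity: dose categories %s never observed", never_seen)
    num = CategoricalPropensityModel(num_formula).fit(later, later["dose_category"])
    den = CategoricalPropensityModel(den_formula).fit(later, later["dose_category"])
    return TreatmentModels(num, den, baseline_terms, time_varying_terms)


def _cumulate(frame: pd.DataFrame, ratio: np.ndarray, mode: str) -> np.ndarray:
    if mode == "interval":
        return ratio
    if mode != "cumulative":
        raise ValueError(f"unknown weight mode {mode!r}")
    s = pd.Series(ratio, index=frame.index)
    return s.groupby(frame["patient_id"], sort=False).cumprod().to_numpy()


def compute_stabilized_iptw(
    panel: PanelDataset,
    models: TreatmentModels,
    mode: str = "cumulative",
) -> pd.DataFrame:
    """Per-record stabilized IPTW (untruncated).

    Returns a frame with ``p_num``, ``p_den``, ``ratio`` and ``sw_iptw``;
    in cumulative mode the weight is the running product of ratios within
    patient, in interval mode the single-quarter ratio.
    """
    frame = build_model_frame(panel)
    later = frame["quarter_index"] >= 1
    p_num = np.ones(len(frame))
    p_den = np.ones(len(frame))
    sub = frame[later]
    if len(sub):
        p_num[later.to_numpy()] = models.numerator.prob_observed(sub, sub["dose_category"])
        p_den[later.to_numpy()] = models.denominator.prob_observed(sub, sub["dose_category"])
    _check_positivity(p_den, frame, "treatment denominator")
    ratio = p_num / p_den
    out = frame[["patient_id", "quarter_index"]].copy()
    out["p_num"] = p_num
    out["p_den"] = p_den
    out["ratio"] = ratio
    out["sw_iptw"] = _cumulate(frame, ratio, mode)
    out.attrs["mode"] = mode
    return out


def truncate_weights(
    weights, lower_pct: float = 1.0, upper_pct: float = 99.0
) -> tuple[np.ndarray, tuple[float, float]]:
    """Clip weights at the given percentiles.

    Bounds are nearest-rank order statistics, so truncation is a projection:
    applying it twice equals applying it once (linear interpolation lacks
    this property because clipping moves the interpolated percentile).
    Returns the clipped array and the ``(lower, upper)`` bounds used; never
    reorders unclipped values.
    """
    if lower_pct >= upper_pct:
        raise ValueError("lower_pct must be < upper_pct")
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("empty weight vector")
    lo = np.percentile(w, lower_pct, method="nearest")
    hi = np.percentile(w, upper_pct, method="nearest")
    return np.clip(w, lo, hi), (float(lo), float(hi))


def fit_censoring_model_and_ipcw(
    panel: PanelDataset,
    baseline_terms: str = DEFAULT_BASELINE_TERMS,
    time_varying_terms: str = DEFAULT_TIME_VARYING_TERMS,
    prior_terms: str = DEFAULT_PRIOR_TERMS,
    mode: str = "cumulative",
    include_quarter: bool = True,
) -> pd.DataFrame:
    """Stabilized IPCW per record; never truncated.

    The censoring event is informative censoring (transplant, modality
    change, transfer) — administrative end of follow-up is deterministic and
    not modelled.  The weight is the (cumulative) ratio of numerator to
    denominator probabilities of remaining uncensored through each quarter.
    A panel with no informative censoring yields weights identically 1.
    """
    frame = build_model_frame(panel)
    event = (
        (frame["censored"] == 1)
        & frame["censor_reason"].isin(INFORMATIVE_CENSOR_REASONS)
    ).astype(float)
    out = frame[["patient_id", "quarter_index"]].copy()
    if event.sum() == 0:
        logger.info("no informative censoring events; all IPCW set to 1")
        out["sw_ipcw"] = 1.0
        out.attrs["mode"] = mode
        return out

    later = frame["quarter_index"] >= 1
    p_unc_num = np.ones(len(frame))
    p_unc_den = np.ones(len(frame))
    sub = frame[later]
    if len(sub) and event[later].sum() > 0:
        qterm = " + quarter_index" if include_quarter else ""
        num_formula = f"{prior_terms} + {baseline_terms}{qterm}"
        den_formula = f"{num_formula} + {time_varying_terms}"
        for formula, store in ((num_formula, p_unc_num), (den_formula, p_unc_den)):
            X = patsy.dmatrix("1 + " + formula, sub, return_type="dataframe",
                              NA_action=patsy.NAAction(on_NA="raise"))
            res = _fit_logit(event[later].to_numpy(), X)
            store[later.to_numpy()] = 1.0 - np.asarray(res.predict(X))
    _check_positivity(p_unc_den, frame, "uncensored denominator")
    ratio = p_unc_num / p_unc_den
    out["sw_ipcw"] = _cumulate(frame, ratio, mode)
    out.attrs["mode"] = mode
    return out


def combine_weights(iptw: pd.DataFrame, ipcw: pd.DataFrame) -> pd.DataFrame:
    """Element-wise product of stabilized IPTW and IPCW on matched records."""
    keys = ["patient_id", "quarter_index"]
    if len(iptw) != len(ipcw):
        raise ValueError("IPTW and IPCW cover different record sets")
    merged = iptw.merge(ipcw[keys + ["sw_ipcw"]], on=keys, how="inner", validate="1:1")
    if len(merged) != len(iptw):
        raise ValueError("IPTW/IPCW record indices do not match")
    merged["final_weight"] = merged["sw_iptw"] * merged["sw_ipcw"]
    return merged


def estimate_weights(
    panel: PanelDataset,
    mode: str = "cumulative",
    truncate_pcts: tuple | None = (1.0, 99.0),
    baseline_terms: str = DEFAULT_BASELINE_TERMS,
    time_varying_terms: str = DEFAULT_TIME_VARYING_TERMS,
    prior_terms: str = DEFAULT_PRIOR_TERMS,
    numerator: str = "baseline",
) -> WeightSet:
    """Full weight pipeline: fit, stabilize, truncate IPTW, combine with IPCW."""
    models = fit_treatment_models(
        panel, baseline_terms, time_varying_terms, prior_terms, numerator=numerator
    )
    iptw = compute_stabilized_iptw(panel, models, mode=mode)
    bounds = None
    if truncate_pcts is not None:
        iptw = iptw.copy()
        iptw["sw_iptw"], bounds = truncate_weights(iptw["sw_iptw"], *truncate_pcts)
    ipcw = fit_censoring_model_and_ipcw(
        panel, baseline_terms, time_varying_terms, prior_terms, mode=mode
    )
    frame = combine_weights(iptw, ipcw)
    return WeightSet(
        frame=frame,
        mode=mode,
        truncation_bounds=bounds,
        meta={"baseline_terms": baseline_terms, "time_varying_terms": time_varying_terms},
    )


def summarize_weights(weights, columns=("sw_iptw", "sw_ipcw", "final_weight")) -> pd.DataFrame:
    """Percentile table (max, 99th … 1st, min, mean) per weight column."""
    frame = weights.frame if isinstance(weights, WeightSet) else weights
    cols = [c for c in columns if c in frame.columns]
    if not cols or frame.empty:
        raise ValueError("no weight columns to summarize")
    out = {}
    for c in cols:
        w = frame[c].to_numpy(dtype=float)
        vals = {"Maximum": w.max(), "Minimum": w.min(), "Mean": w.mean()}
        for row, p in _SUMMARY_PCTS.items():
            vals[row] = np.percentile(w, p)
        out[c] = [vals[r] for r in SUMMARY_ROWS]
    return pd.DataFrame(out, index=list(SUMMARY_ROWS))


def covariate_balance(
    panel: PanelDataset,
    weights: pd.DataFrame | WeightSet | None = None,
    covariate: str = "hb",
    weight_col: str = "sw_iptw",
    reference: int = 0,
    min_quarter: int = 0,
) -> pd.Series:
    """Standardized mean difference of a confounder across dose categories.

    For each non-reference category, the (weighted) mean difference of
    ``covariate`` versus the reference category divided by the pooled SD —
    the usual pseudo-population balance diagnostic.  Meaningful marginal
    balance requires weights built with ``numerator="marginal"`` in
    interval mode, restricted to quarters >= 1 (``min_quarter=1``): the
    entry-quarter ratio is 1 by construction, so entry-quarter confounding
    is handled by outcome-model adjustment, not by the weights.
    """
    rec = panel.records[panel.records["quarter_index"] >= min_quarter]
    if weights is None:
        w = np.ones(len(rec))
        df = rec.assign(_w=w)
    else:
        wf = weights.frame if isinstance(weights, WeightSet) else weights
        df = rec.merge(
            wf[["patient_id", "quarter_index", weight_col]],
            on=["patient_id", "quarter_index"],
            validate="1:1",
        ).rename(columns={weight_col: "_w"})
    ref = df[df["dose_category"] == reference]
    out = {}
    for k in sorted(df["dose_category"].unique()):
        if k == reference:
            continue
        g = df[df["dose_category"] == k]
        m1 = np.average(g[covariate], weights=g["_w"])
        m0 = np.average(ref[covariate], weights=ref["_w"])
        v1 = np.average((g[covariate] - m1) ** 2, weights=g["_w"])
        v0 = np.average((ref[covariate] - m0) ** 2, weights=ref["_w"])
        out[int(k)] = (m1 - m0) / np.sqrt((v1 + v0) / 2.0)
    return pd.Series(out, name=f"smd_{covariate}")
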