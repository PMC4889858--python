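"""Configured end-to-end runs: simulate → panel → weights → fit → report.

A :class:`PipelineConfig` plus a single seed reproduces every output: the
seed fans out to per-stage seeds through ``numpy.random.SeedSequence`` with
a fixed stage index, so any stage can be rerun in isolation.  All tables
are written as both TSV and JSON, together with a manifest recording the
config, stage seeds and SHA-256 of each output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import estimation, simulate as sim, weights as wt
from .panel import (
    PanelDataset,
    apply_inclusion_filters,
    filter_incident,
    locf_impute,
    read_panel,
    write_panel,
)

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "impute", "weights", "fit")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Serializable description of one analysis run."""

    out_dir: str = "results"
    #: Synthetic scenario name (see ``esamsm.simulate.SCENARIOS``) or None
    #: to read an existing panel from ``panel_path``/``baseline_path``.
    scenario: str | None = "default"
    truth_overrides: dict = field(default_factory=dict)
    panel_path: str | None = None
    baseline_path: str | None = None
    n_patients: int = 20_000
    n_quarters: int = 12
    incident_only: bool = False
    weight_mode: str = "cumulative"
    truncate_pcts: tuple | None = (1.0, 99.0)
    outcomes: tuple = ("all_cause",)
    dichotomize_at: float | None = None
    subgroups: bool = False
    mi_m: int = 5
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence([self.seed, _STAGES.index(stage)])
        return int(ss.generate_state(1)[0] % (2**31 - 1))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["truncate_pcts"] = list(self.truncate_pcts) if self.truncate_pcts else None
        d["outcomes"] = list(self.outcomes)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(raw) - known
        if extra:
            raise PipelineError(f"unknown config keys: {sorted(extra)}")
        for key in ("truncate_pcts", "outcomes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_table(df: pd.DataFrame, out_dir: Path, stem: str, index_label: str) -> list[Path]:
    tsv = out_dir / f"{stem}.tsv"
    js = out_dir / f"{stem}.json"
    df.to_csv(tsv, sep="\t", index_label=index_label)
    df.reset_index(names=index_label).to_json(js, orient="records", indent=1)
    return [tsv, js]


def _result_frame(res: estimation.MSMResult) -> pd.DataFrame:
    df = res.estimates.copy()
    df["outcome"] = res.outcome
    df["n_patients"] = res.n_patients
    df["n_person_quarters"] = res.n_person_quarters
    df["weight_mode"] = res.weight_mode
    if res.subgroup_label:
        df["subgroup"] = res.subgroup_label
    return df


def _build_panel(config: PipelineConfig) -> tuple[PanelDataset, dict]:
    info: dict = {}
    if config.scenario is not None:
        if config.scenario not in sim.SCENARIOS:
            raise PipelineError(f"unknown scenario {config.scenario!r}")
        truth = sim.SCENARIOS[config.scenario](
            n_patients=config.n_patients, n_quarters=config.n_quarters,
            seed=config.stage_seed("simulate"),
        )
        for k, v in config.truth_overrides.items():
            if not hasattr(truth, k):
                raise PipelineError(f"unknown truth field {k!r}")
            setattr(truth, k, tuple(v) if isinstance(v, list) else v)
        panel, truth = sim.simulate_cohort(truth)
        info["truth"] = truth.to_dict()
    else:
        if not (config.panel_path and config.baseline_path):
            raise PipelineError("need panel_path and baseline_path without a scenario")
        for p in (config.panel_path, config.baseline_path):
            if not Path(p).exists():
                raise PipelineError(f"input file not found: {p}")
        panel = read_panel(config.panel_path, config.baseline_path)

    panel, tally = apply_inclusion_filters(panel)
    info["exclusions"] = tally
    if config.incident_only:
        panel = filter_incident(panel)
    panel = locf_impute(panel)
    info["n_patients"] = panel.n_patients
    info["n_person_quarters"] = panel.n_person_quarters
    return panel, info


def _fit_all(config: PipelineConfig, panel: PanelDataset) -> tuple[list, pd.DataFrame]:
    """Weights + outcome fits, with Rubin pooling across imputations when
    baseline covariates are missing."""
    missing = panel.baselines.drop(columns=["patient_id"]).isna().any().any()
    m = config.mi_m if missing else 1
    if missing:
        completed = estimation.multiple_impute_baseline(
            panel.baselines, m=m, seed=config.stage_seed("impute")
        )
    else:
        completed = [panel.baselines]

    per_imp: dict[tuple, list] = {}
    summary = None
    for baselines in completed:
        p = PanelDataset(panel.records, baselines, dict(panel.meta))
        ws = wt.estimate_weights(
            p, mode=config.weight_mode, truncate_pcts=config.truncate_pcts
        )
        if summary is None:
            summary = wt.summarize_weights(ws)
        if config.dichotomize_at is not None:
            groups = estimation.default_subgroups() if config.subgroups else None
            for res in estimation.dichotomize_and_subgroup(
                p, threshold=config.dichotomize_at, subgroups=groups,
                weight_kwargs={"mode": config.weight_mode,
                               "truncate_pcts": config.truncate_pcts},
            ):
                per_imp.setdefault(("all_cause", res.subgroup_label), []).append(res)
        else:
            for outcome in config.outcomes:
                res = estimation.fit_msm_gee(p, weights=ws, outcome=outcome)
                per_imp.setdefault((outcome, None), []).append(res)

    results = [
        fits[0] if len(fits) == 1 else estimation.pool_mi_results(fits)
        for fits in per_imp.values()
    ]
    return results, summary


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    panel, info = _build_panel(config)
    write_panel(panel, out_dir / "panel.csv", out_dir / "baselines.csv")
    written += [out_dir / "panel.csv", out_dir / "baselines.csv"]

    results, weight_summary = _fit_all(config, panel)
    written += _write_table(weight_summary, out_dir, "weight_summary", "percentile")
    or_table = pd.concat([_result_frame(r) for r in results])
    written += _write_table(or_table, out_dir, "odds_ratios", "category")

    manifest = {
        "config": config.to_dict(),
        "stage_seeds": {s: PipelineConfig.stage_seed(config, s) for s in _STAGES},
        "panel": info,
        "outputs": {p.name: _sha256(p) for p in written},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
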