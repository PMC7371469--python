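"""The full simulation study: develop under informative missingness, apply
under four mechanisms, tabulate predictive performance.

One replication of the study:

1. generate a development cohort and impose informative missingness;
2. for each handling strategy, prepare the data and fit ``Y ~ P [+ R]``;
3. generate an independent application cohort; for each scenario impose its
   mechanism (1 = same informative mechanism, 2 = nothing missing, 3 = a
   random half missing, 4 = everything missing), re-apply the same handling
   strategy, predict, and score against both the generating risk and the
   realized outcomes;
4. as a reference, fit the model on the development cohort without any
   missing values and evaluate it on the fully observed application cohort.

Cells where a strategy cannot be applied (e.g. nothing observed to average or
to donate when every value is missing) are recorded as not-applicable and the
run continues. Multi-replication mode repeats the whole study on independent
seed streams and reports per-cell Monte Carlo means and standard errors.
"""

from __future__ import annotations

import datetime
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .cohort import GenerationParams, MissingnessMechanism, apply_missingness, generate_cohort
from .handlers import (
    METHOD_LABELS,
    METHODS,
    HandlerInapplicableError,
    prepare,
    prepare_complete_case,
)
from .metrics import (
    REPORT_COLUMNS,
    PerformanceReport,
    UndefinedMetricError,
    summarize,
)
from .model import FittedModel, fit_logistic, predict_probability

__all__ = [
    "SCENARIO_LABELS",
    "StudyConfig",
    "StudyResult",
    "scenario_mechanism",
    "run_study",
    "render_table",
    "parse_table",
    "export_plot_data",
]

logger = logging.getLogger(__name__)

SCENARIO_LABELS = {
    1: "Scenario 1 (informative missingness)",
    2: "Scenario 2 (no missing values)",
    3: "Scenario 3 (MCAR 50%)",
    4: "Scenario 4 (all missing)",
}

REFERENCE_KEY = ("reference", "none")


def scenario_mechanism(scenario: int, mcar_rate: float = 0.5) -> MissingnessMechanism:
    """The missingness mechanism imposed on the application cohort."""
    if scenario == 1:
        return MissingnessMechanism.informative()
    if scenario == 2:
        return MissingnessMechanism.none()
    if scenario == 3:
        return MissingnessMechanism.mcar(mcar_rate)
    if scenario == 4:
        return MissingnessMechanism.all_missing()
    raise ValueError(f"unknown scenario {scenario!r}; expected 1-4")


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one study run; defaults reproduce the published table."""

    n_dev: int = 20_000
    n_app: int = 20_000
    seed: int = 0
    replications: int = 1
    methods: Tuple[str, ...] = METHODS
    scenarios: Tuple[int, ...] = (1, 2, 3, 4)
    donor_count: int = 5
    mcar_rate: float = 0.5
    generation: GenerationParams = GenerationParams(n=1)  # n fields used below

    def __post_init__(self) -> None:
        if self.n_dev < 1 or self.n_app < 1:
            raise ValueError("cohort sizes must be positive")
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")
        unknown_s = set(self.scenarios) - {1, 2, 3, 4}
        if unknown_s:
            raise ValueError(f"unknown scenarios {sorted(unknown_s)}")

    def dev_params(self) -> GenerationParams:
        return replace(self.generation, n=self.n_dev)

    def app_params(self) -> GenerationParams:
        return replace(self.generation, n=self.n_app)


def _stream_seeds(seed: int, n_replications: int) -> list:
    """Per-replication named integer seed streams, spawned deterministically.

    Stream order within a replication: development generation, development
    missingness, development imputation, application generation, then one
    (missingness, imputation) pair per scenario 1-4 — fixed regardless of
    which scenarios are requested, so any cell is reproducible in isolation.
    """
    names = ["dev_gen", "dev_miss", "dev_mi", "app_gen"]
    for s in (1, 2, 3, 4):
        names += [f"s{s}_miss", f"s{s}_mi"]
    reps = np.random.SeedSequence(seed).spawn(n_replications)
    out = []
    for rep_ss in reps:
        children = rep_ss.spawn(len(names))
        out.append(
            {name: int(c.generate_state(1)[0]) for name, c in zip(names, children)}
        )
    return out


@dataclass
class _SingleRun:
    reference: PerformanceReport
    cells: Dict[Tuple[int, str], Optional[PerformanceReport]]
    na_reasons: Dict[Tuple[int, str], str]
    models: Dict[str, FittedModel]
    reference_model: FittedModel
    predictions: Dict[Tuple, pd.DataFrame]
    dev_info: Dict[str, float]


def _run_once(config: StudyConfig, seeds: Dict[str, int]) -> _SingleRun:
    dev = generate_cohort(config.dev_params(), seeds["dev_gen"])
    dev_missing = apply_missingness(
        dev, MissingnessMechanism.informative(), seeds["dev_miss"]
    )
    dev_r1 = dev_missing["R"].to_numpy() == 1
    dev_info = {
        "dev_outcome_prevalence": float(dev_missing["Y"].mean()),
        "dev_missing_rate": float(dev_missing["R"].mean()),
        "dev_outcome_rate_missing": float(dev_missing.loc[dev_r1, "Y"].mean())
        if dev_r1.any()
        else float("nan"),
    }

    models: Dict[str, FittedModel] = {}
    na_reasons: Dict[Tuple[int, str], str] = {}
    dev_failed: Dict[str, str] = {}
    for method in config.methods:
        try:
            _, prep = prepare(
                method, dev_missing, donor_count=config.donor_count, seed=seeds["dev_mi"]
            )
            models[method] = fit_logistic(prep)
            logger.info(
                "fit method=%s n_fit=%d converged=%s",
                method,
                models[method].n_fit,
                models[method].converged,
            )
        except HandlerInapplicableError as exc:
            dev_failed[method] = f"development: {exc}"

    # reference model: development data without missing values (R = 0 as drawn)
    ref_prep = prepare_complete_case(dev)
    reference_model = fit_logistic(ref_prep)

    app = generate_cohort(config.app_params(), seeds["app_gen"])
    app_prep = prepare_complete_case(app)
    ref_pred = predict_probability(reference_model, app_prep)
    reference = summarize(ref_pred, app["true_risk"].to_numpy(), app_prep.outcome)
    predictions: Dict[Tuple, pd.DataFrame] = {
        REFERENCE_KEY: pd.DataFrame(
            {
                "id": app_prep.ids,
                "true_risk": app["true_risk"].to_numpy(),
                "predicted": ref_pred,
            }
        )
    }

    cells: Dict[Tuple[int, str], Optional[PerformanceReport]] = {}
    for scenario in config.scenarios:
        mechanism = scenario_mechanism(scenario, config.mcar_rate)
        app_s = apply_missingness(app, mechanism, seeds[f"s{scenario}_miss"])
        truth_all = app_s["true_risk"].to_numpy()
        for method in config.methods:
            key = (scenario, method)
            if method in dev_failed:
                cells[key] = None
                na_reasons[key] = dev_failed[method]
                continue
            try:
                _, prep = prepare(
                    method,
                    app_s,
                    donor_count=config.donor_count,
                    seed=seeds[f"s{scenario}_mi"],
                )
                if len(prep) == 0:
                    raise HandlerInapplicableError("no subjects receive a prediction")
                pred = predict_probability(models[method], prep)
                truth = truth_all[prep.ids]
                cells[key] = summarize(pred, truth, prep.outcome)
                predictions[key] = pd.DataFrame(
                    {"id": prep.ids, "true_risk": truth, "predicted": pred}
                )
                logger.info(
                    "cell scenario=%d method=%s n_evaluated=%d c=%.3f",
                    scenario,
                    method,
                    cells[key].n_evaluated,
                    cells[key].c_statistic,
                )
            except (HandlerInapplicableError, UndefinedMetricError) as exc:
                cells[key] = None
                na_reasons[key] = str(exc)
                logger.info("cell scenario=%d method=%s not applicable: %s",
                            scenario, method, exc)
    return _SingleRun(
        reference=reference,
        cells=cells,
        na_reasons=na_reasons,
        models=models,
        reference_model=reference_model,
        predictions=predictions,
        dev_info=dev_info,
    )


@dataclass
class StudyResult:
    """Everything one call to :func:`run_study` produced.

    ``reference`` and ``cells`` come from the first replication (the
    paper-faithful single run); ``replicate_values`` holds every metric of
    every replication for Monte Carlo summaries. ``predictions`` (first
    replication only) back the plot-data export.
    """

    config: StudyConfig
    reference: PerformanceReport
    cells: Dict[Tuple[int, str], Optional[PerformanceReport]]
    na_reasons: Dict[Tuple[int, str], str]
    models: Dict[str, FittedModel] = field(default_factory=dict)
    reference_model: Optional[FittedModel] = None
    predictions: Dict[Tuple, pd.DataFrame] = field(default_factory=dict)
    dev_info: Dict[str, float] = field(default_factory=dict)
    replicate_values: Dict[Tuple, Dict[str, list]] = field(default_factory=dict)
    provenance: Dict[str, str] = field(default_factory=dict)

    def cell(self, scenario: int, method: str) -> Optional[PerformanceReport]:
        return self.cells.get((scenario, method))

    def mc_summary(self) -> pd.DataFrame:
        """Per-cell, per-metric Monte Carlo mean and standard error.

        The standard error is the sample standard deviation across
        replications divided by the square root of the replication count.
        """
        rows = []
        for key, metrics_dict in self.replicate_values.items():
            scenario, method = key
            for metric, values in metrics_dict.items():
                arr = np.asarray(values, dtype=float)
                arr = arr[~np.isnan(arr)]
                if arr.size == 0:
                    continue
                se = (
                    float(arr.std(ddof=1) / np.sqrt(arr.size))
                    if arr.size > 1
                    else float("nan")
                )
                rows.append(
                    {
                        "scenario": scenario,
                        "method": method,
                        "metric": metric,
                        "mean": float(arr.mean()),
                        "mc_se": se,
                        "n_replications": int(arr.size),
                    }
                )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        def report_dict(r: Optional[PerformanceReport]):
            return None if r is None else r.as_dict()

        payload = {
            "config": {
                "n_dev": self.config.n_dev,
                "n_app": self.config.n_app,
                "seed": self.config.seed,
                "replications": self.config.replications,
                "methods": list(self.config.methods),
                "scenarios": list(self.config.scenarios),
                "donor_count": self.config.donor_count,
                "mcar_rate": self.config.mcar_rate,
            },
            "reference": report_dict(self.reference),
            "cells": {f"{s}:{m}": report_dict(r) for (s, m), r in self.cells.items()},
            "na_reasons": {f"{s}:{m}": v for (s, m), v in self.na_reasons.items()},
            "dev_info": self.dev_info,
            "replicate_values": {
                f"{k[0]}:{k[1]}": v for k, v in self.replicate_values.items()
            },
            "provenance": self.provenance,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "StudyResult":
        d = json.loads(text)

        def parse_report(rd):
            return None if rd is None else PerformanceReport(**rd)

        def parse_key(k: str):
            s, m = k.split(":")
            return (s if s == "reference" else int(s), m)

        cfg = StudyConfig(
            n_dev=d["config"]["n_dev"],
            n_app=d["config"]["n_app"],
            seed=d["config"]["seed"],
            replications=d["config"]["replications"],
            methods=tuple(d["config"]["methods"]),
            scenarios=tuple(d["config"]["scenarios"]),
            donor_count=d["config"]["donor_count"],
            mcar_rate=d["config"]["mcar_rate"],
        )
        return cls(
            config=cfg,
            reference=parse_report(d["reference"]),
            cells={parse_key(k): parse_report(v) for k, v in d["cells"].items()},
            na_reasons={parse_key(k): v for k, v in d["na_reasons"].items()},
            dev_info=d.get("dev_info", {}),
            replicate_values={
                parse_key(k): v for k, v in d.get("replicate_values", {}).items()
            },
            provenance=d.get("provenance", {}),
        )


def run_study(config: StudyConfig) -> StudyResult:
    """Run the full study; deterministic for a fixed configuration."""
    all_seeds = _stream_seeds(config.seed, config.replications)
    first: Optional[_SingleRun] = None
    replicate_values: Dict[Tuple, Dict[str, list]] = {}

    def record(key, report: Optional[PerformanceReport]) -> None:
        slot = replicate_values.setdefault(
            key, {metric: [] for metric in REPORT_COLUMNS}
        )
        for metric in REPORT_COLUMNS:
            slot[metric].append(
                float("nan") if report is None else float(getattr(report, metric))
            )

    for rep, seeds in enumerate(all_seeds):
        run = _run_once(config, seeds)
        if rep == 0:
            first = run
        record(REFERENCE_KEY, run.reference)
        for key, report in run.cells.items():
            record(key, report)

    assert first is not None
    return StudyResult(
        config=config,
        reference=first.reference,
        cells=first.cells,
        na_reasons=first.na_reasons,
        models=first.models,
        reference_model=first.reference_model,
        predictions=first.predictions,
        dev_info=first.dev_info,
        replicate_values=replicate_values,
        provenance={
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "package": "missshift",
        },
    )


# ---------------------------------------------------------------------------
# table rendering

_TABLE_COLUMNS = ["group", "method"] + list(REPORT_COLUMNS) + ["n_evaluated"]


def render_table(result: StudyResult):
    """Render the scenario x method performance table.

    Returns ``(frame, text)``: a dataframe with one row per cell (numbers
    rounded to 3 decimals, not-applicable cells rendered as ``NA``) and an
    aligned plain-text version. Rows are grouped reference first, then
    scenarios in order, with methods ordered zero, mean, CCA, MI.
    """
    rows = []

    def add_row(group: str, method_label: str, report: Optional[PerformanceReport]):
        row = {"group": group, "method": method_label}
        if report is None:
            row.update({k: "NA" for k in REPORT_COLUMNS})
            row["n_evaluated"] = "NA"
        else:
            row.update({k: f"{getattr(report, k):.3f}" for k in REPORT_COLUMNS})
            row["n_evaluated"] = str(report.n_evaluated)
        rows.append(row)

    add_row("Reference", "No missing values", result.reference)
    for scenario in sorted(result.config.scenarios):
        for method in METHODS:
            if method not in result.config.methods:
                continue
            add_row(
                SCENARIO_LABELS[scenario],
                METHOD_LABELS[method],
                result.cell(scenario, method),
            )

    frame = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    widths = {
        c: max(len(c), *(len(str(v)) for v in frame[c])) for c in frame.columns
    }
    header = "  ".join(c.ljust(widths[c]) for c in frame.columns)
    lines = [header, "-" * len(header)]
    for _, row in frame.iterrows():
        lines.append("  ".join(str(row[c]).ljust(widths[c]) for c in frame.columns))
    return frame, "\n".join(lines)


def parse_table(csv_text: str) -> Dict[Tuple[str, str], Optional[dict]]:
    """Parse a CSV rendering of the table back into per-cell metric dicts."""
    import io

    frame = pd.read_csv(io.StringIO(csv_text), dtype=str, keep_default_na=False)
    out: Dict[Tuple[str, str], Optional[dict]] = {}
    for _, row in frame.iterrows():
        key = (row["group"], row["method"])
        if row[REPORT_COLUMNS[0]] == "NA":
            out[key] = None
        else:
            out[key] = {k: float(row[k]) for k in REPORT_COLUMNS}
    return out


def export_plot_data(
    result: StudyResult,
    scenario,
    method: str,
    sample_size: int = 500,
    jitter: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """True risk against predicted probability for a random subject sample.

    Samples ``sample_size`` evaluated subjects without replacement from the
    requested cell (``scenario`` may be ``"reference"``) and adds uniform
    ``+/- jitter`` noise to the predicted values only; the raw predictions are
    retained in the ``predicted`` column alongside ``predicted_jittered``.
    """
    key = REFERENCE_KEY if scenario == "reference" else (int(scenario), method)
    if key not in result.predictions:
        raise ValueError(
            f"cell {key} has no predictions (not applicable or not retained)"
        )
    frame = result.predictions[key]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if sample_size >= len(frame):
        if sample_size > len(frame):
            warnings.warn(
                f"sample_size {sample_size} exceeds {len(frame)} evaluated "
                "subjects; exporting all",
                RuntimeWarning,
                stacklevel=2,
            )
        sample = frame.reset_index(drop=True)
    else:
        idx = rng.choice(len(frame), size=sample_size, replace=False)
        sample = frame.iloc[np.sort(idx)].reset_index(drop=True)
    noise = rng.uniform(-jitter, jitter, size=len(sample)) if jitter > 0 else 0.0
    out = sample.copy()
    out["predicted_jittered"] = out["predicted"] + noise
    return out
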