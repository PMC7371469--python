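"""Predictive-performance measures for probability predictions.

Five measures are reported per evaluation: the mean and standard deviation of
the prediction error against the true generating risk, the root mean squared
prediction error (RMSPE), the c-statistic (tie-corrected concordance between
predictions and outcomes), the Brier score, and calibration-in-the-large.

Conventions: prediction error is *predicted minus true*, so a positive mean
error means over-prediction; the error SD uses the sample (n-1) denominator
while RMSPE uses the population denominator; calibration-in-the-large is the
intercept of a logistic recalibration model with the prediction's log-odds as
a fixed offset (0 = mean predictions match mean outcomes, negative =
over-prediction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import rankdata

__all__ = [
    "UndefinedMetricError",
    "PerformanceReport",
    "prediction_errors",
    "rmspe",
    "c_statistic",
    "brier_score",
    "calibration_in_the_large",
    "summarize",
]

REPORT_COLUMNS = (
    "mean_prediction_error",
    "sd_prediction_error",
    "rmspe",
    "c_statistic",
    "brier",
    "calibration_in_the_large",
)

_CLIP = 1e-10


class UndefinedMetricError(ValueError):
    """The metric is undefined for this input (empty, or single-class outcome)."""


@dataclass(frozen=True)
class PerformanceReport:
    """One row of the performance table for a scenario x method cell."""

    mean_prediction_error: float
    sd_prediction_error: float
    rmspe: float
    c_statistic: float
    brier: float
    calibration_in_the_large: float
    n_evaluated: int

    def as_dict(self) -> dict:
        return {
            **{k: float(getattr(self, k)) for k in REPORT_COLUMNS},
            "n_evaluated": int(self.n_evaluated),
        }

    def csv_row(self) -> str:
        """Comma-separated metric values, table column order, 3 decimals."""
        return ",".join(f"{getattr(self, k):.3f}" for k in REPORT_COLUMNS)


def _as_float_array(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


def prediction_errors(predicted, true_risk) -> np.ndarray:
    """Signed per-subject errors, predicted minus true risk."""
    p = _as_float_array(predicted, "predicted")
    t = _as_float_array(true_risk, "true_risk")
    if p.shape != t.shape:
        raise ValueError("predicted and true_risk must have equal length")
    return p - t


def rmspe(errors) -> float:
    """Root mean squared prediction error (population denominator)."""
    e = _as_float_array(errors, "errors")
    if e.size == 0:
        raise UndefinedMetricError("RMSPE is undefined for an empty error vector")
    return float(np.sqrt(np.mean(e**2)))


def c_statistic(predicted, outcomes) -> float:
    """Concordance probability, ties counted one half.

    Over all (case, non-case) pairs, the fraction in which the case received
    the strictly higher prediction, plus half the fraction of ties — the
    Mann-Whitney statistic, computed here from mid-ranks in O(n log n).
    Constant predictions give exactly 0.5.
    """
    p = _as_float_array(predicted, "predicted")
    y = np.asarray(outcomes)
    if p.shape != y.shape:
        raise ValueError("predicted and outcomes must have equal length")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError("c-statistic needs both outcome classes")
    ranks = rankdata(p)  # mid-ranks handle ties
    rank_sum_cases = float(ranks[y == 1].sum())
    return (rank_sum_cases - n1 * (n1 + 1) / 2) / (n1 * n0)


def brier_score(predicted, outcomes) -> float:
    """Mean squared difference between prediction and binary outcome."""
    p = _as_float_array(predicted, "predicted")
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape:
        raise ValueError("predicted and outcomes must have equal length")
    if p.size == 0:
        raise UndefinedMetricError("Brier score is undefined for empty input")
    return float(np.mean((p - y) ** 2))


def calibration_in_the_large(predicted, outcomes) -> float:
    """Intercept of outcomes regressed on an offset of the predictions' logit.

    Solves the one-dimensional score equation
    ``mean(expit(a + logit(predicted))) = mean(outcomes)`` for the intercept
    ``a``. Predictions are clipped away from 0 and 1 before the logit.
    """
    p = _as_float_array(predicted, "predicted")
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape:
        raise ValueError("predicted and outcomes must have equal length")
    if y.size == 0 or y.min() == y.max():
        raise UndefinedMetricError(
            "calibration-in-the-large needs both outcome classes"
        )
    offset = logit(np.clip(p, _CLIP, 1 - _CLIP))
    target = float(y.mean())

    def score(a: float) -> float:
        return float(np.mean(expit(a + offset))) - target

    return float(brentq(score, -40.0, 40.0, xtol=1e-12))


def summarize(predicted, true_risk, outcomes) -> PerformanceReport:
    """All five measures for one set of predictions.

    Only subjects *with* predictions enter; when a handler excludes subjects
    at application time (complete-case), pass the evaluated subset only.
    """
    p = _as_float_array(predicted, "predicted")
    errors = prediction_errors(p, true_risk)
    sd = float(np.std(errors, ddof=1)) if errors.size > 1 else 0.0
    return PerformanceReport(
        mean_prediction_error=float(errors.mean()),
        sd_prediction_error=sd,
        rmspe=rmspe(errors),
        c_statistic=c_statistic(p, outcomes),
        brier=brier_score(p, outcomes),
        calibration_in_the_large=calibration_in_the_large(p, outcomes),
        n_evaluated=int(p.size),
    )
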