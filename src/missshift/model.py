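"""Binary logistic regression by iteratively reweighted least squares.

The prediction model is deliberately small — an intercept, the prepared
predictor, and optionally the missing indicator — so the fitter is a compact
Newton/IRLS routine with step halving, which makes the log-likelihood trace
monotone and lets convergence be declared on successive log-likelihood
differences at a tight tolerance. Complete separation is flagged (fitted
probabilities pinned at 0/1) rather than raised, so that small degenerate
cohorts degrade gracefully.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

from .handlers import PreparedData

__all__ = [
    "DegenerateFitError",
    "FittedModel",
    "fit_logistic",
    "fit_logistic_design",
    "predict_probability",
]

_PROB_EPS = 1e-12


class DegenerateFitError(ValueError):
    """The outcome has a single class; the likelihood has no interior optimum."""


@dataclass
class FittedModel:
    """Coefficients and diagnostics of a fitted logistic model."""

    coefficient_names: tuple
    coefficients: np.ndarray
    converged: bool
    log_likelihood: float
    n_fit: int
    ll_trace: list = field(default_factory=list, repr=False)

    def to_json(self) -> str:
        return json.dumps(
            {
                "coefficient_names": list(self.coefficient_names),
                "coefficients": [float(c) for c in self.coefficients],
                "converged": bool(self.converged),
                "log_likelihood": float(self.log_likelihood),
                "n_fit": int(self.n_fit),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FittedModel":
        d = json.loads(text)
        return cls(
            coefficient_names=tuple(d["coefficient_names"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            converged=d["converged"],
            log_likelihood=d["log_likelihood"],
            n_fit=d["n_fit"],
        )


def _log_likelihood(x: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = x @ beta
    # log expit computed stably via logaddexp
    return float(-(np.logaddexp(0.0, -eta) * y + np.logaddexp(0.0, eta) * (1 - y)).sum())


def fit_logistic_design(
    x: np.ndarray,
    y: np.ndarray,
    names: Sequence[str],
    tolerance: float = 1e-8,
    max_iterations: int = 100,
) -> FittedModel:
    """Maximum-likelihood logistic fit on an explicit design matrix.

    Newton steps with step halving guarantee the log-likelihood never
    decreases; convergence is declared when successive log-likelihoods differ
    by less than ``tolerance``. If any fitted probability is numerically 0 or
    1 at the optimum (complete or quasi-complete separation) the model is
    returned with ``converged = False`` and a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("design and outcome shapes are inconsistent")
    if x.shape[0] == 0:
        raise ValueError("cannot fit on an empty design")
    if x.shape[0] < x.shape[1]:
        raise ValueError("fewer observations than coefficients")
    if y.min() == y.max():
        raise DegenerateFitError("outcome takes a single value; fit is degenerate")

    beta = np.zeros(x.shape[1])
    ll = _log_likelihood(x, y, beta)
    trace = [ll]
    converged = False
    for _ in range(max_iterations):
        p = expit(x @ beta)
        w = np.clip(p * (1.0 - p), _PROB_EPS, None)
        grad = x.T @ (y - p)
        hess = (x * w[:, None]).T @ x
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # step halving: retreat until the likelihood does not decrease
        scale = 1.0
        for _half in range(50):
            ll_new = _log_likelihood(x, y, beta + scale * step)
            if ll_new >= ll:
                break
            scale *= 0.5
        else:
            ll_new = ll
        beta = beta + scale * step
        trace.append(ll_new)
        if abs(ll_new - ll) < tolerance:
            converged = True
            ll = ll_new
            break
        ll = ll_new

    p_final = expit(x @ beta)
    separated = bool((p_final < _PROB_EPS).any() or (p_final > 1 - _PROB_EPS).any())
    if separated:
        warnings.warn(
            "fitted probabilities reached 0/1: possible complete separation",
            RuntimeWarning,
            stacklevel=2,
        )
        converged = False
    if not converged and not separated:
        warnings.warn(
            "logistic fit did not converge within max_iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return FittedModel(
        coefficient_names=tuple(names),
        coefficients=beta,
        converged=converged,
        log_likelihood=ll,
        n_fit=int(x.shape[0]),
        ll_trace=trace,
    )


def fit_logistic(
    data: PreparedData, tolerance: float = 1e-8, max_iterations: int = 100
) -> FittedModel:
    """Fit the prediction model ``Y ~ predictor [+ indicator]``."""
    return fit_logistic_design(
        data.design(), data.outcome, data.column_names, tolerance, max_iterations
    )


def predict_probability(model: FittedModel, data: PreparedData) -> np.ndarray:
    """Per-subject predicted outcome probability for the prepared design.

    The design columns must match the model's coefficient names; subjects the
    handler excluded (complete-case analysis) are simply absent from ``data``
    and receive no prediction.
    """
    if data.column_names != model.coefficient_names:
        raise ValueError(
            f"design columns {data.column_names} do not match model "
            f"coefficients {model.coefficient_names}"
        )
    return expit(data.design() @ model.coefficients)
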