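"""Missing-data handling strategies with a two-phase contract.

Four strategies turn a cohort with a partially observed predictor into a
design ready for logistic regression:

``zero``
    Missing ``P`` imputed with 0, plus a binary missing indicator.
``mean``
    Missing ``P`` imputed with the mean of the observed values *of the cohort
    at hand*, plus a binary missing indicator.
``cca``
    Complete-case analysis: only subjects with ``P`` observed are retained.
``mi``
    Single-dataset imputation by predictive mean matching (PMM), using the
    observed ``P`` values and the outcome ``Y`` as the imputation model.

Each strategy is applied identically at development time (before fitting) and
at application time (before predicting): the mean and the PMM imputation are
recomputed from whichever cohort is being prepared, nothing learned at
development time is carried over. This mirrors handling missing data "the
same way" in both datasets; note it means the outcome is consulted by PMM at
application time, which is only possible in a validation setting where ``Y``
is known.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "METHODS",
    "METHOD_LABELS",
    "HandlerInapplicableError",
    "HandlerState",
    "PreparedData",
    "prepare_zero_indicator",
    "prepare_mean_indicator",
    "prepare_complete_case",
    "pmm_impute",
    "prepare",
]

#: Canonical method keys, in reporting order.
METHODS = ("zero", "mean", "cca", "mi")

METHOD_LABELS = {
    "zero": "Zero imputation",
    "mean": "Mean imputation",
    "cca": "CCA",
    "mi": "Multiple imputation",
}


class HandlerInapplicableError(RuntimeError):
    """A handling strategy cannot be applied to this cohort.

    Raised e.g. for mean imputation or PMM when no values of ``P`` are
    observed, or for complete-case fitting on an empty inclusion set. The
    study pipeline records such cells as not-applicable instead of aborting.
    """


@dataclass
class HandlerState:
    """Audit record of what a handler learned or drew.

    ``learned_mean`` is set only by mean imputation; the PMM fields only by
    chained imputation. ``pmm_draw`` stores the posterior coefficient draw
    used to predict the missing subjects, for reproducibility audits.
    """

    method: str
    learned_mean: Optional[float] = None
    imputation_seed: Optional[int] = None
    pmm_donor_count: Optional[int] = None
    pmm_draw: Optional[np.ndarray] = None


@dataclass
class PreparedData:
    """A regression-ready design: one predictor column, optional indicator.

    ``indicator`` is present (the missingness flag) for the zero and mean
    strategies and ``None`` otherwise. ``ids`` refer back to the cohort's
    ``id`` column; complete-case analysis retains a subset, every other
    strategy retains all subjects.
    """

    ids: np.ndarray
    predictor: np.ndarray
    outcome: np.ndarray
    indicator: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.predictor = np.asarray(self.predictor, dtype=float)
        self.outcome = np.asarray(self.outcome, dtype=np.int64)
        if self.indicator is not None:
            self.indicator = np.asarray(self.indicator, dtype=np.int64)
        lengths = {len(self.ids), len(self.predictor), len(self.outcome)}
        if self.indicator is not None:
            lengths.add(len(self.indicator))
        if len(lengths) > 1:
            raise ValueError("PreparedData columns must have equal length")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def column_names(self) -> tuple:
        """Design column labels, intercept first."""
        if self.indicator is not None:
            return ("intercept", "predictor", "indicator")
        return ("intercept", "predictor")

    def design(self) -> np.ndarray:
        """Design matrix with a leading intercept column."""
        cols = [np.ones(len(self)), self.predictor]
        if self.indicator is not None:
            cols.append(self.indicator.astype(float))
        return np.column_stack(cols)

    def to_frame(self) -> pd.DataFrame:
        data = {"id": self.ids, "predictor": self.predictor}
        if self.indicator is not None:
            data["indicator"] = self.indicator
        data["outcome"] = self.outcome
        return pd.DataFrame(data)


def _check_prepared_cohort(cohort: pd.DataFrame) -> None:
    if cohort["P_observed"].isna().to_numpy().sum() != (cohort["R"] == 1).sum():
        raise ValueError("cohort masking inconsistent: NaN count != count(R=1)")


def prepare_zero_indicator(cohort: pd.DataFrame) -> PreparedData:
    """Impute missing ``P`` with zero and add the missing indicator."""
    _check_prepared_cohort(cohort)
    r = cohort["R"].to_numpy()
    pred = np.where(r == 1, 0.0, cohort["P_observed"].to_numpy())
    return PreparedData(
        ids=cohort["id"].to_numpy(),
        predictor=pred,
        outcome=cohort["Y"].to_numpy(),
        indicator=r,
    )


def prepare_mean_indicator(cohort: pd.DataFrame):
    """Impute missing ``P`` with the observed mean and add the indicator.

    The mean is the arithmetic mean of ``P_observed`` over the subjects with
    ``R = 0`` *in this cohort*; with no observed values the strategy is
    inapplicable (this is why an all-missing scenario admits no mean row).

    Returns ``(HandlerState, PreparedData)``.
    """
    _check_prepared_cohort(cohort)
    r = cohort["R"].to_numpy()
    observed = cohort.loc[cohort["R"] == 0, "P_observed"].to_numpy()
    if observed.size == 0:
        raise HandlerInapplicableError(
            "mean imputation needs at least one observed value of P"
        )
    mean = float(observed.mean())
    pred = np.where(r == 1, mean, cohort["P_observed"].to_numpy())
    state = HandlerState(method="mean", learned_mean=mean)
    return state, PreparedData(
        ids=cohort["id"].to_numpy(),
        predictor=pred,
        outcome=cohort["Y"].to_numpy(),
        indicator=r,
    )


def prepare_complete_case(cohort: pd.DataFrame) -> PreparedData:
    """Retain only subjects with ``P`` observed; no indicator column.

    May return an empty design (e.g. all-missing application data); fitting
    on an empty design is rejected downstream.
    """
    _check_prepared_cohort(cohort)
    sub = cohort[cohort["R"] == 0]
    return PreparedData(
        ids=sub["id"].to_numpy(),
        predictor=sub["P_observed"].to_numpy(),
        outcome=sub["Y"].to_numpy(),
    )


def pmm_impute(cohort: pd.DataFrame, donor_count: int = 5, seed: int = 0):
    """Single-dataset predictive mean matching of ``P`` given ``Y``.

    The imputation model regresses the observed ``P`` on an intercept and the
    outcome by ordinary least squares. A Bayesian draw perturbs the residual
    variance (scaled inverse chi-square) and the coefficients (normal around
    the OLS estimate). Donor candidates are ranked by the distance between the
    donor's predicted value under the OLS point estimate and the target's
    predicted value under the drawn coefficients (type-1 matching); the
    ``donor_count`` closest observed subjects — expanded to include all
    candidates tied at the boundary distance — form the pool, and one donor's
    *observed* ``P`` is drawn uniformly as the imputed value. Because the
    outcome is binary, predicted values within an outcome stratum coincide,
    so the tie-inclusive pool typically spans a whole stratum.

    Returns ``(HandlerState, PreparedData)``; deterministic given ``seed``.
    """
    _check_prepared_cohort(cohort)
    if donor_count < 1:
        raise ValueError("donor_count must be a positive integer")
    r = cohort["R"].to_numpy()
    p_obs = cohort["P_observed"].to_numpy().astype(float)
    y = cohort["Y"].to_numpy().astype(float)
    obs = r == 0
    mis = ~obs
    n_obs = int(obs.sum())
    if n_obs < donor_count or n_obs < 3:
        raise HandlerInapplicableError(
            f"PMM needs at least max(donor_count, 3) = "
            f"{max(donor_count, 3)} observed values, found {n_obs}"
        )

    state = HandlerState(
        method="mi", imputation_seed=int(seed), pmm_donor_count=int(donor_count)
    )
    pred = p_obs.copy()
    if not mis.any():
        return state, PreparedData(
            ids=cohort["id"].to_numpy(), predictor=pred, outcome=cohort["Y"].to_numpy()
        )

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    x_obs = np.column_stack([np.ones(n_obs), y[obs]])
    beta_hat, *_ = np.linalg.lstsq(x_obs, p_obs[obs], rcond=None)
    resid = p_obs[obs] - x_obs @ beta_hat
    dof = max(n_obs - x_obs.shape[1], 1)
    ssr = float(resid @ resid)
    sigma2_draw = ssr / rng.chisquare(dof)
    xtx_inv = np.linalg.inv(x_obs.T @ x_obs)
    chol = np.linalg.cholesky(sigma2_draw * xtx_inv)
    beta_draw = beta_hat + chol @ rng.standard_normal(x_obs.shape[1])
    state.pmm_draw = beta_draw

    yhat_obs = x_obs @ beta_hat
    x_mis = np.column_stack([np.ones(int(mis.sum())), y[mis]])
    yhat_mis = x_mis @ beta_draw

    donors = p_obs[obs]
    mis_idx = np.flatnonzero(mis)
    imputed = np.empty(mis_idx.size)
    # binary Y gives at most two distinct target predictions; the donor pool
    # (k nearest, ties at the boundary included) is shared within each group
    for value in np.unique(yhat_mis):
        sel = yhat_mis == value
        dist = np.abs(yhat_obs - value)
        kth = np.partition(dist, donor_count - 1)[donor_count - 1]
        pool = donors[dist <= kth]
        imputed[sel] = pool[rng.integers(0, pool.size, size=int(sel.sum()))]
    pred[mis_idx] = imputed

    return state, PreparedData(
        ids=cohort["id"].to_numpy(), predictor=pred, outcome=cohort["Y"].to_numpy()
    )


def prepare(method: str, cohort: pd.DataFrame, donor_count: int = 5, seed: int = 0):
    """Dispatch to the handler named ``method``.

    Returns ``(HandlerState or None, PreparedData)``; ``seed`` and
    ``donor_count`` are consulted only by PMM.
    """
    if method == "zero":
        return None, prepare_zero_indicator(cohort)
    if method == "mean":
        return prepare_mean_indicator(cohort)
    if method == "cca":
        return None, prepare_complete_case(cohort)
    if method == "mi":
        return pmm_impute(cohort, donor_count=donor_count, seed=seed)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
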