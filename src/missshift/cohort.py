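"""Synthetic cohorts with a partially observed predictor.

A cohort of ``n`` subjects carries two independent Uniform(0, 1) predictors:
``P``, which may be missing, and ``U``, which is never available to the
prediction model (it drives the outcome and the missingness only). The binary
outcome ``Y`` is drawn from a logistic model in both predictors, and the
missingness flag ``R`` (1 = ``P`` missing) is drawn from one of four
mechanisms. Because missingness can depend on the unobserved ``U``, the
informative mechanism is missing-not-at-random.

Cohorts are plain :class:`pandas.DataFrame` objects with the columns listed in
:data:`COHORT_COLUMNS`; ``true_risk`` always records the generating risk
computed from the *true* ``P``, even after masking, so that prediction error
against the data-generating mechanism stays well defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "COHORT_COLUMNS",
    "GenerationParams",
    "MissingnessMechanism",
    "generate_cohort",
    "missingness_probability",
    "apply_missingness",
    "write_cohort_csv",
    "read_cohort_csv",
]

#: Column order of a serialized cohort.
COHORT_COLUMNS = ["id", "P", "U", "true_risk", "Y", "R", "P_observed"]

_VARIANTS = ("informative", "none", "mcar", "all")


@dataclass(frozen=True)
class GenerationParams:
    """Parameters of the outcome-generating logistic model.

    The default coefficients give ``P(Y=1 | P, U) = expit(-5 + 3 P + 5 U)``,
    an outcome prevalence of about 34%.
    """

    n: int = 20_000
    outcome_intercept: float = -5.0
    outcome_coef_p: float = 3.0
    outcome_coef_u: float = 5.0

    def __post_init__(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ValueError(f"n must be a positive integer, got {self.n!r}")
        for name in ("outcome_intercept", "outcome_coef_p", "outcome_coef_u"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def risk(self, p: np.ndarray, u: np.ndarray) -> np.ndarray:
        """True outcome probability for predictor values ``p`` and ``u``."""
        return expit(
            self.outcome_intercept
            + self.outcome_coef_p * np.asarray(p)
            + self.outcome_coef_u * np.asarray(u)
        )


@dataclass(frozen=True)
class MissingnessMechanism:
    """How the missingness flag ``R`` is generated.

    Variants
    --------
    ``informative``
        ``P(R=1 | P, U) = expit(3 - 2 P - 2 U - 4 P U)`` by default: subjects
        with low values of either predictor (hence low outcome risk) are the
        ones most likely to lack a measurement of ``P``. The marginal
        missingness rate is roughly one half.
    ``none``
        ``P`` observed for everyone.
    ``mcar``
        ``P`` missing completely at random with probability ``mcar_rate``.
    ``all``
        ``P`` missing for everyone.
    """

    variant: str
    mcar_rate: float = 0.5
    intercept: float = 3.0
    coef_p: float = -2.0
    coef_u: float = -2.0
    coef_pu: float = -4.0

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(
                f"variant must be one of {_VARIANTS}, got {self.variant!r}"
            )
        if not 0.0 <= self.mcar_rate <= 1.0:
            raise ValueError(f"mcar_rate must lie in [0, 1], got {self.mcar_rate}")
        for name in ("intercept", "coef_p", "coef_u", "coef_pu"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    # -- convenience constructors ------------------------------------------
    @classmethod
    def informative(cls) -> "MissingnessMechanism":
        return cls(variant="informative")

    @classmethod
    def none(cls) -> "MissingnessMechanism":
        return cls(variant="none")

    @classmethod
    def mcar(cls, rate: float = 0.5) -> "MissingnessMechanism":
        return cls(variant="mcar", mcar_rate=rate)

    @classmethod
    def all_missing(cls) -> "MissingnessMechanism":
        return cls(variant="all")


def missingness_probability(
    p, u, mechanism: MissingnessMechanism
):
    """Per-subject probability that ``P`` is missing.

    Accepts scalars or arrays; broadcasting follows numpy rules.
    """
    p = np.asarray(p, dtype=float)
    u = np.asarray(u, dtype=float)
    if mechanism.variant == "informative":
        lin = (
            mechanism.intercept
            + mechanism.coef_p * p
            + mechanism.coef_u * u
            + mechanism.coef_pu * p * u
        )
        return expit(lin)
    shape = np.broadcast_shapes(p.shape, u.shape)
    if mechanism.variant == "none":
        return np.zeros(shape) if shape else 0.0
    if mechanism.variant == "mcar":
        return np.full(shape, mechanism.mcar_rate) if shape else mechanism.mcar_rate
    # variant == "all"
    return np.ones(shape) if shape else 1.0


def generate_cohort(params: GenerationParams, seed: int) -> pd.DataFrame:
    """Draw a fully observed cohort of ``params.n`` subjects.

    ``P`` and ``U`` are independent Uniform(0, 1); ``Y`` is Bernoulli with the
    true risk. The predictor draws and the outcome draws consume independent
    substreams spawned from ``seed``, so two cohorts that share a seed share
    their subjects exactly even if downstream consumers draw differently.

    The returned frame has ``R = 0`` and ``P_observed = P`` throughout; apply
    a mechanism with :func:`apply_missingness` to mask values.
    """
    pred_ss, outcome_ss = np.random.SeedSequence(seed).spawn(2)
    rng_pred = np.random.default_rng(pred_ss)
    rng_outcome = np.random.default_rng(outcome_ss)

    n = params.n
    p = rng_pred.random(n)
    u = rng_pred.random(n)
    risk = params.risk(p, u)
    y = (rng_outcome.random(n) < risk).astype(np.int64)

    return pd.DataFrame(
        {
            "id": np.arange(n, dtype=np.int64),
            "P": p,
            "U": u,
            "true_risk": risk,
            "Y": y,
            "R": np.zeros(n, dtype=np.int64),
            "P_observed": p.copy(),
        }
    )


def apply_missingness(
    cohort: pd.DataFrame, mechanism: MissingnessMechanism, seed: int
) -> pd.DataFrame:
    """Return a copy of ``cohort`` with ``R`` drawn and ``P_observed`` masked.

    ``R`` is an independent Bernoulli draw per subject with probability given
    by :func:`missingness_probability`; where ``R = 1`` the observed predictor
    becomes missing (NaN). ``P``, ``U``, ``true_risk`` and ``Y`` are
    untouched, so different mechanisms applied to the same cohort differ only
    in the masking.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = cohort.copy()
    prob = missingness_probability(out["P"].to_numpy(), out["U"].to_numpy(), mechanism)
    r = (rng.random(len(out)) < prob).astype(np.int64)
    out["R"] = r
    observed = out["P"].to_numpy().copy()
    observed[r == 1] = np.nan
    out["P_observed"] = observed
    return out


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write a cohort to CSV; missing ``P_observed`` becomes an empty field.

    Floats are written with 17 significant digits so the round trip through
    :func:`read_cohort_csv` is bit-exact.
    """
    cohort.to_csv(path, index=False, columns=COHORT_COLUMNS, float_format="%.17g")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort written by :func:`write_cohort_csv` (lossless round trip)."""
    df = pd.read_csv(
        path,
        float_precision="round_trip",
        dtype={
            "id": np.int64,
            "P": float,
            "U": float,
            "true_risk": float,
            "Y": np.int64,
            "R": np.int64,
            "P_observed": float,
        },
    )
    return df[COHORT_COLUMNS]
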