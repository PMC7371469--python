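import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

from missshift import (
    UndefinedMetricError,
    brier_score,
    c_statistic,
    calibration_in_the_large,
    fit_logistic,
    predict_probability,
    prediction_errors,
    prepare_zero_indicator,
    rmspe,
    summarize,
)


def brute_force_c(predicted, outcomes):
    """O(n^2) concordance over all (case, non-case) pairs; ties count 1/2."""
    predicted = np.asarray(predicted, dtype=float)
    outcomes = np.asarray(outcomes)
    cases = predicted[outcomes == 1]
    controls = predicted[outcomes == 0]
    total = 0.0
    for c in cases:
        total += (c > controls).sum() + 0.5 * (c == controls).sum()
    return total / (len(cases) * len(controls))


# --- prediction errors -----------------------------------------------------

def test_prediction_error_sign_and_examples():
    np.testing.assert_allclose(prediction_errors([0.6, 0.6], [0.6, 0.6]), 0.0)
    np.testing.assert_allclose(prediction_errors([1.0, 1.0], [0.6, 0.6]), 0.4)
    with pytest.raises(ValueError):
        prediction_errors([0.5], [0.5, 0.6])


@pytest.mark.parametrize(
    "errors, expected",
    [
        ([0.0, 0.0, 0.0], 0.0),
        ([0.3, -0.3], 0.3),
        ([0.1, 0.2, 0.2, 0.5], np.sqrt(0.085)),
    ],
)
def test_rmspe_hand_arithmetic(errors, expected):
    assert rmspe(errors) == pytest.approx(expected, abs=1e-12)


def test_rmspe_empty_undefined():
    with pytest.raises(UndefinedMetricError):
        rmspe([])


# --- c-statistic -----------------------------------------------------------

def test_c_statistic_hand_examples():
    # exhaustive pair enumeration: (1 + 1 + 0.5 + 1) / 4
    assert c_statistic([0.2, 0.4, 0.4, 0.9], [0, 0, 1, 1]) == pytest.approx(0.875)
    assert c_statistic([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
    assert c_statistic([0.3] * 6, [0, 1, 0, 1, 0, 1]) == 0.5  # all ties: exactly half


def test_c_statistic_single_class_undefined():
    with pytest.raises(UndefinedMetricError):
        c_statistic([0.2, 0.4], [1, 1])


@settings(max_examples=200, derandomize=True)
@given(
    data=st.lists(
        st.tuples(st.floats(0.001, 0.999), st.integers(0, 1)), min_size=2, max_size=200
    )
)
def test_rank_sum_c_equals_exhaustive_pair_count(data):
    predicted = np.array([d[0] for d in data])
    outcomes = np.array([d[1] for d in data])
    if outcomes.min() == outcomes.max():
        return
    assert c_statistic(predicted, outcomes) == pytest.approx(
        brute_force_c(predicted, outcomes), abs=1e-12
    )


def test_c_statistic_invariant_under_monotone_transforms():
    rng = np.random.default_rng(23)
    predicted = rng.uniform(0.01, 0.99, 150)
    outcomes = rng.integers(0, 2, 150)
    base = c_statistic(predicted, outcomes)
    for transform in (logit, expit, lambda p: 3 * p + 1, lambda p: p**3):
        assert c_statistic(transform(predicted), outcomes) == pytest.approx(
            base, abs=1e-12
        )


# --- Brier score -----------------------------------------------------------

def test_brier_hand_examples():
    assert brier_score([0.0, 1.0], [0, 1]) == 0.0
    assert brier_score([0.5, 0.5, 0.5], [1, 0, 1]) == pytest.approx(0.25)
    assert brier_score([0.8, 0.3], [1, 0]) == pytest.approx(0.065)


def test_brier_constant_prevalence_prediction():
    y = np.array([1] * 3 + [0] * 7)
    prev = y.mean()
    assert brier_score(np.full(10, prev), y) == pytest.approx(prev * (1 - prev))
    with pytest.raises(UndefinedMetricError):
        brier_score([], [])


# --- calibration-in-the-large ----------------------------------------------

def test_citl_constant_prediction_closed_form():
    """With constant predictions the offset-model intercept is
    logit(prevalence) - logit(prediction), exactly."""
    y = np.zeros(10_000)
    y[:2500] = 1
    a = calibration_in_the_large(np.full(10_000, 0.5), y)
    assert a == pytest.approx(logit(0.25) - logit(0.5), abs=1e-9)


def test_citl_prediction_equal_to_prevalence_is_zero():
    y = np.array([1, 0, 0, 0] * 50)
    assert calibration_in_the_large(np.full(200, 0.25), y) == pytest.approx(0, abs=1e-9)


def test_citl_zero_on_self_fitted_predictions(dev_cohort):
    prep = prepare_zero_indicator(dev_cohort)
    fit = fit_logistic(prep)
    probs = predict_probability(fit, prep)
    assert abs(calibration_in_the_large(probs, prep.outcome)) < 1e-6


def test_citl_matches_statsmodels_offset_glm():
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(41)
    predicted = rng.uniform(0.05, 0.95, 3000)
    outcomes = (rng.random(3000) < np.clip(predicted * 1.2, 0, 1)).astype(int)
    ours = calibration_in_the_large(predicted, outcomes)
    glm = sm.GLM(
        outcomes,
        np.ones((3000, 1)),
        family=sm.families.Binomial(),
        offset=logit(predicted),
    ).fit()
    assert ours == pytest.approx(glm.params[0], abs=1e-7)


def test_citl_single_class_undefined():
    with pytest.raises(UndefinedMetricError):
        calibration_in_the_large([0.2, 0.4], [0, 0])


# --- summarize -------------------------------------------------------------

def test_summarize_oracle_predictions(dev_cohort):
    truth = dev_cohort["true_risk"].to_numpy()
    y = dev_cohort["Y"].to_numpy()
    report = summarize(truth, truth, y)
    assert report.mean_prediction_error == 0.0
    assert report.rmspe == 0.0
    assert abs(report.calibration_in_the_large) < 0.1  # Monte Carlo noise only
    assert report.n_evaluated == len(dev_cohort)


def test_summarize_constant_predictions(dev_cohort):
    truth = dev_cohort["true_risk"].to_numpy()
    y = dev_cohort["Y"].to_numpy()
    report = summarize(np.full(len(y), y.mean()), truth, y)
    assert report.c_statistic == 0.5
    assert report.sd_prediction_error == pytest.approx(np.std(truth, ddof=1), abs=1e-12)


def test_summarize_moment_identities(dev_cohort):
    rng = np.random.default_rng(3)
    n = 500
    predicted = rng.uniform(0.05, 0.95, n)
    truth = dev_cohort["true_risk"].to_numpy()[:n]
    y = dev_cohort["Y"].to_numpy()[:n]
    report = summarize(predicted, truth, y)
    # mean-error coherence: mean(pred) = mean(true) + mean error
    assert report.mean_prediction_error + truth.mean() == pytest.approx(
        predicted.mean(), abs=1e-12
    )
    # rmspe^2 = mean^2 + sd^2 (n-1)/n
    assert report.rmspe**2 == pytest.approx(
        report.mean_prediction_error**2
        + report.sd_prediction_error**2 * (n - 1) / n,
        abs=1e-12,
    )
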