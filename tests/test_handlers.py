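import numpy as np
import pytest

from missshift import (
    HandlerInapplicableError,
    fit_logistic,
    pmm_impute,
    predict_probability,
    prepare,
    prepare_complete_case,
    prepare_mean_indicator,
    prepare_zero_indicator,
)

from conftest import make_cohort


def test_zero_indicator_mapping():
    cohort = make_cohort(p=[0.7, 0.2, 0.9], y=[1, 0, 1], r=[0, 1, 0])
    prep = prepare_zero_indicator(cohort)
    np.testing.assert_array_equal(prep.predictor, [0.7, 0.0, 0.9])
    np.testing.assert_array_equal(prep.indicator, [0, 1, 0])
    np.testing.assert_array_equal(prep.outcome, cohort["Y"])
    assert len(prep) == 3


def test_zero_indicator_no_missing_is_raw_design():
    cohort = make_cohort(p=[0.1, 0.5, 0.8], y=[0, 1, 1], r=[0, 0, 0])
    prep = prepare_zero_indicator(cohort)
    np.testing.assert_array_equal(prep.predictor, cohort["P"])
    assert (prep.indicator == 0).all()


def test_mean_indicator_small_example():
    cohort = make_cohort(p=[0.2, 0.4, 0.6], y=[0, 1, 1], r=[0, 0, 1])
    state, prep = prepare_mean_indicator(cohort)
    assert state.learned_mean == pytest.approx(0.3)
    np.testing.assert_allclose(prep.predictor, [0.2, 0.4, 0.3])
    np.testing.assert_array_equal(prep.indicator, [0, 0, 1])


def test_mean_indicator_matches_groupby_recomputation(dev_cohort):
    state, _ = prepare_mean_indicator(dev_cohort)
    oracle = dev_cohort.groupby("R")["P_observed"].mean().loc[0]
    assert state.learned_mean == pytest.approx(oracle, abs=1e-12)


def test_mean_indicator_all_missing_inapplicable():
    cohort = make_cohort(p=[0.2, 0.4], y=[0, 1], r=[1, 1])
    with pytest.raises(HandlerInapplicableError):
        prepare_mean_indicator(cohort)


def test_complete_case_subset_counts():
    cohort = make_cohort(
        p=np.linspace(0.1, 0.9, 10),
        y=[0, 1] * 5,
        r=[1, 0, 0, 1, 0, 1, 0, 0, 1, 0],
    )
    prep = prepare_complete_case(cohort)
    assert len(prep) == 6
    assert prep.indicator is None
    np.testing.assert_array_equal(prep.ids, cohort.loc[cohort["R"] == 0, "id"])


def test_complete_case_none_missing_keeps_everyone():
    cohort = make_cohort(p=[0.1, 0.5], y=[0, 1], r=[0, 0])
    assert len(prepare_complete_case(cohort)) == 2


def test_complete_case_all_missing_empty_and_unfittable():
    cohort = make_cohort(p=[0.1, 0.5, 0.9], y=[0, 1, 1], r=[1, 1, 1])
    prep = prepare_complete_case(cohort)
    assert len(prep) == 0
    with pytest.raises(ValueError):
        fit_logistic(prep)


def test_pmm_imputations_are_observed_donor_values(dev_cohort):
    _, prep = pmm_impute(dev_cohort, donor_count=5, seed=17)
    missing = dev_cohort["R"].to_numpy() == 1
    observed_values = set(dev_cohort.loc[~missing, "P_observed"])
    imputed = prep.predictor[missing]
    assert set(imputed) <= observed_values  # hot-deck property
    assert imputed.min() >= dev_cohort.loc[~missing, "P_observed"].min()
    assert imputed.max() <= dev_cohort.loc[~missing, "P_observed"].max()


def test_pmm_no_missing_leaves_data_untouched():
    cohort = make_cohort(p=np.linspace(0, 1, 20), y=[0, 1] * 10, r=[0] * 20)
    _, prep = pmm_impute(cohort, donor_count=5, seed=3)
    np.testing.assert_array_equal(prep.predictor, cohort["P"])
    assert prep.indicator is None


def test_pmm_imputed_mean_between_outcome_stratum_means(dev_cohort):
    """Imputation borrows from outcome strata, so the imputed mean must lie
    between the observed-P means of the Y=0 and Y=1 observed strata."""
    _, prep = pmm_impute(dev_cohort, donor_count=5, seed=17)
    obs = dev_cohort["R"].to_numpy() == 0
    y = dev_cohort["Y"].to_numpy()
    p_obs = dev_cohort["P_observed"].to_numpy()
    lo = p_obs[obs & (y == 1)].mean()  # cases have higher P on average,
    hi = p_obs[obs & (y == 0)].mean()  # but order is established empirically
    lo, hi = min(lo, hi), max(lo, hi)
    imputed_mean = prep.predictor[~obs].mean()
    assert lo <= imputed_mean <= hi


def test_pmm_too_few_donors_inapplicable():
    cohort = make_cohort(p=[0.2, 0.4, 0.6, 0.8], y=[0, 1, 0, 1], r=[1, 1, 1, 0])
    with pytest.raises(HandlerInapplicableError):
        pmm_impute(cohort, donor_count=5, seed=1)


def test_pmm_deterministic_under_seed(dev_cohort):
    _, a = pmm_impute(dev_cohort, donor_count=5, seed=99)
    _, b = pmm_impute(dev_cohort, donor_count=5, seed=99)
    np.testing.assert_array_equal(a.predictor, b.predictor)
    _, c = pmm_impute(dev_cohort, donor_count=5, seed=100)
    assert not np.array_equal(a.predictor, c.predictor)


@pytest.mark.parametrize("method", ["zero", "mean", "cca", "mi"])
def test_prepare_is_idempotent(method, dev_cohort):
    """Re-applying a handler to the same cohort (same seed) reproduces the
    design exactly: nothing hidden is carried between invocations."""
    _, a = prepare(method, dev_cohort, seed=55)
    _, b = prepare(method, dev_cohort, seed=55)
    np.testing.assert_array_equal(a.ids, b.ids)
    np.testing.assert_array_equal(a.predictor, b.predictor)
    np.testing.assert_array_equal(a.outcome, b.outcome)


def test_prepare_rejects_unknown_method(dev_cohort):
    with pytest.raises(ValueError):
        prepare("oracle", dev_cohort)


def test_zero_and_mean_indicator_fits_are_reparameterizations(dev_cohort):
    """The two indicator designs span the same column space, so per-subject
    fitted probabilities coincide to optimizer tolerance."""
    prep_zero = prepare_zero_indicator(dev_cohort)
    _, prep_mean = prepare_mean_indicator(dev_cohort)
    fit_zero = fit_logistic(prep_zero)
    fit_mean = fit_logistic(prep_mean)
    p_zero = predict_probability(fit_zero, prep_zero)
    p_mean = predict_probability(fit_mean, prep_mean)
    assert np.abs(p_zero - p_mean).max() < 1e-6


def test_zero_indicator_saturates_missing_group(dev_cohort):
    """With predictor pinned to 0 and indicator 1, the missing group is
    saturated: its fitted probability equals its empirical outcome rate."""
    prep = prepare_zero_indicator(dev_cohort)
    fit = fit_logistic(prep)
    probs = predict_probability(fit, prep)
    missing = prep.indicator == 1
    group_rate = prep.outcome[missing].mean()
    assert np.abs(probs[missing] - group_rate).max() < 1e-6
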