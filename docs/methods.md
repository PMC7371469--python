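# Methods

## Data-generating mechanism

Subjects are exchangeable draws: `P, U ~ iid Uniform(0,1)`,
`Y | P,U ~ Bernoulli(expit(-5 + 3P + 5U))`,
`R | P,U ~ Bernoulli(π(P,U))` with mechanism-specific `π`. The informative
(development) mechanism is `π = expit(3 - 2P - 2U - 4PU)`. Exact moments by
2-D quadrature over the unit square: outcome prevalence 0.3433, marginal
missingness 0.5191, outcome rate among missing-P subjects 0.1962. These are
the oracles the generator is tested against; the commonly quoted "34%",
"about half" and "about 0.2" are rounded versions of the same quantities.

`true_risk` is always computed from the *true* `P`, including for subjects
whose `P` is masked, because prediction error is defined against the
generating mechanism, not against what the model could see. Missingness is an
explicit flag `R` plus a maskable `P_observed` (NaN-backed but never
interpreted by value): `P = 0` is a legal value and zero imputation writes 0
on purpose, so "missing" must not be a sentinel.

Random-number policy: one `numpy` `SeedSequence` per cohort, with the
predictor draws and the outcome draws on independent spawned substreams, and
missingness drawn from a separate seed entirely — changing the mechanism (or
only the missingness seed) never changes `P`, `U`, `Y`. The study pipeline
spawns a documented, fixed-order set of streams per replication
(development generation / missingness / imputation, application generation,
then a missingness + imputation pair for each of the four scenarios), so any
cell is reproducible in isolation and independent of which subset of
scenarios is requested.

## Handling strategies

All four strategies obey one two-phase contract: whatever is done before
fitting is re-done, from scratch, on the cohort being predicted. In
particular the imputation mean is recomputed from the application cohort's
observed values, and PMM is re-run on the application cohort using its
outcomes. Recomputation (rather than carrying the development mean) is what
makes the all-missing scenario inapplicable for mean imputation — there is
nothing to average — which is exactly how the performance table behaves. That
PMM consults `Y` at application time is a deliberate peculiarity of the
procedure being studied: it is only possible in a validation setting where
outcomes are known, and would not be available at real deployment.

PMM details (single imputed dataset, m = 1): ordinary least squares of `P` on
an intercept and `Y` among observed subjects; a scaled-inverse-chi-square draw
of the residual variance and a normal draw of the coefficients around the OLS
estimate; type-1 matching (donors predicted under the point estimate, targets
under the drawn coefficients); donor pool of 5, expanded to include all
candidates tied at the boundary distance, with uniform selection. Because `Y`
is binary, predictions within an outcome stratum coincide, so the
tie-inclusive pool typically spans a whole stratum — the imputed value is
then effectively a uniform draw of an observed `P` from the matching outcome
stratum. The donor count, seed and coefficient draw are recorded in
`HandlerState` for audit. PMM requires at least `max(donor_count, 3)`
observed values (3 so the residual variance has a positive degree of
freedom); imputed values are always observed donor values, hence never leave
the observed range.

## Prediction model

Binary logistic regression `Y ~ predictor (+ indicator)` fitted by
Newton/IRLS with step halving. Convergence is declared when successive
log-likelihoods differ by less than 1e-8 (at most 100 iterations); step
halving makes the likelihood trace monotone. Complete or quasi-complete
separation (fitted probabilities numerically 0/1) is flagged
(`converged = False`, warning) rather than raised, so small degenerate
cohorts degrade gracefully; a single-class outcome raises, since the
likelihood has no interior optimum. The fitter is deliberately in-package:
the contract (log-likelihood convergence criterion, monotone trace,
separation flag) is part of the tested surface; statsmodels serves as an
independent oracle in the test suite.

Two structural facts about the indicator designs are load-bearing and
tested: (i) zero- and mean-imputation designs span the same column space, so
their fitted probabilities coincide to optimizer tolerance, and their
complete-data submodel equals the complete-case fit (the likelihood
factorizes over the indicator); (ii) the missing group is saturated — its
fitted probability equals its empirical outcome rate — which is why, under
the development mechanism, every missing-P subject is predicted at the
development outcome rate among missing-P subjects (~0.2).

## Performance measures

Per evaluated subject, prediction error is `predicted − true_risk` (positive
= over-prediction). The error SD uses the sample (n−1) denominator; RMSPE
uses the population denominator (`rmspe² = mean² + sd²·(n−1)/n`). The
c-statistic is the tie-corrected Mann–Whitney concordance computed from
mid-ranks in O(n log n); constant predictions give exactly 0.5, and equality
with the exhaustive O(n²) pair count is property-tested. The Brier score is
the mean squared prediction–outcome difference. Calibration-in-the-large is
the intercept of a logistic recalibration of outcomes on an offset of
`logit(predicted)` (predictions clipped to [1e−10, 1−1e−10]); it is solved as
the one-dimensional score equation by bracketed root finding, which is exact
to 1e−12 and cannot fail to converge, and is cross-checked against an
offset GLM. Negative values mean over-prediction, coherent with the error
sign convention. Complete-case application evaluates only the subjects that
received predictions.

## Study sizes, replication and tolerances

Defaults are development and application cohorts of 20 000 subjects, all four
strategies and scenarios, donor pool 5, single replication — one full study
runs in well under a second. Single-replication output is the faithful
rendition of the original single-run design; since such numbers carry
sampling noise (per-run SD ≈ 0.005 for c-statistics, ≈ 0.02 for
calibration-in-the-large at this n), the pipeline also supports independent
replications with per-cell Monte Carlo means and standard errors, which the
acceptance tests use (20 replications) to compare expectations rather than
individual draws against published single-run values.

## What the generator does and does not emulate

The synthetic cohorts capture the essential structure — one informative,
MNAR-by-construction missingness process tied to an unobserved risk factor,
with a known truth to score against. They do not emulate real EHR data:
there is a single partially observed predictor, no measurement times or
repeated measurements, no case-mix shift, no feedback loop between model
deployment and clinician behaviour (the scenarios are static snapshots of
changed mechanisms), and uniform predictors with a correctly specified
logistic truth. Passing tests therefore demonstrate the mechanism-shift
phenomenon and the correctness of the machinery, not performance guarantees
on real clinical data.

## Degenerate inputs and tie-breaks

Mechanism `none` yields `R = 0` everywhere and all handlers reduce to the raw
design; mechanism `all` leaves only zero imputation applicable (the pipeline
records other cells as not-applicable and continues). MCAR uses an
independent Bernoulli(rate) per subject, not an exact half split, mirroring
the Bernoulli form of the informative mechanism. PMM donor ties are resolved
by pool expansion (all tied candidates included) rather than order-dependent
truncation, so results are independent of sort stability. Plot-data export
samples evaluated subjects without replacement, jitters predicted values only
(uniform ± jitter), and keeps the raw predictions alongside.
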