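"""Generate a synthetic cohort and impose informative missingness.

Each subject has two independent Uniform(0,1) predictors: P (potentially
observed) and U (never observed by the prediction model). The binary outcome
follows P(Y=1|P,U) = expit(-5 + 3P + 5U); the probability that P is missing
follows P(R=1|P,U) = expit(3 - 2P - 2U - 4PU), so absence of a measurement is
itself informative about low risk.
"""

from missshift import (
    GenerationParams,
    MissingnessMechanism,
    apply_missingness,
    generate_cohort,
)

params = GenerationParams(n=20_000)
cohort = generate_cohort(params, seed=1)
masked = apply_missingness(cohort, MissingnessMechanism.informative(), seed=2)

print(masked.head())
print(f"\noutcome prevalence:          {masked['Y'].mean():.3f}   (expected ~0.34)")
print(f"missingness rate:            {masked['R'].mean():.3f}   (expected ~0.52)")
print(
    "outcome rate, P missing:     "
    f"{masked.loc[masked['R'] == 1, 'Y'].mean():.3f}   (expected ~0.20)"
)
print(
    "outcome rate, P observed:    "
    f"{masked.loc[masked['R'] == 0, 'Y'].mean():.3f}"
)
# The gap between the last two lines is the information carried by
# missingness itself: subjects without a measurement are systematically
# lower-risk under this mechanism.
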