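import numpy as np
import pandas as pd
import pytest

from missshift import (
    GenerationParams,
    MissingnessMechanism,
    StudyConfig,
    apply_missingness,
    generate_cohort,
    run_study,
)

# chosen once; all session-level randomness derives from it
MASTER_SEED = 20200702


def make_cohort(p, y, r, u=None):
    """Hand-built cohort frame for unit tests (true_risk from default params)."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    r = np.asarray(r, dtype=np.int64)
    u = np.full(len(p), 0.5) if u is None else np.asarray(u, dtype=float)
    params = GenerationParams(n=len(p))
    observed = p.copy()
    observed[r == 1] = np.nan
    return pd.DataFrame(
        {
            "id": np.arange(len(p), dtype=np.int64),
            "P": p,
            "U": u,
            "true_risk": params.risk(p, u),
            "Y": y,
            "R": r,
            "P_observed": observed,
        }
    )


@pytest.fixture(scope="session")
def paper_params():
    return GenerationParams(n=20_000)


@pytest.fixture(scope="session")
def dev_cohort(paper_params):
    """A development-sized cohort with informative missingness imposed."""
    cohort = generate_cohort(paper_params, seed=MASTER_SEED)
    return apply_missingness(cohort, MissingnessMechanism.informative(), seed=MASTER_SEED + 1)


@pytest.fixture(scope="session")
def study():
    """The paper-faithful single-replication study at n = 20000."""
    return run_study(StudyConfig(seed=MASTER_SEED))


@pytest.fixture(scope="session")
def study_reps():
    """Twenty independent replications for Monte Carlo standard errors."""
    return run_study(StudyConfig(seed=MASTER_SEED, replications=20))
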