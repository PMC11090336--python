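import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort, generated once per session."""
    from exefun import simulate as sim

    return sim.generate_cohort(seed=11)


@pytest.fixture(scope="session")
def scored_cohort():
    """Composites (younger-reference) + participants for one cohort."""
    from exefun.pipeline import cohort_composites

    return cohort_composites(seed=11, scheme="younger_reference")


@pytest.fixture(scope="session")
def scored_cohort_pooled():
    from exefun.pipeline import cohort_composites

    return cohort_composites(seed=11, scheme="pooled")


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_measures(n=10, seed=0, missing=()):
    """Small hand-controllable measures table for composite tests."""
    from exefun.tasks import MEASURE_COLUMNS

    r = np.random.default_rng(seed)
    df = pd.DataFrame(
        r.normal(size=(n, len(MEASURE_COLUMNS))), columns=MEASURE_COLUMNS
    )
    df.insert(0, "participant_id", [f"P{i:03d}" for i in range(1, n + 1)])
    for (row, col) in missing:
        df.loc[row, col] = np.nan
    return df


def make_participants(n=10, n_younger=None):
    if n_younger is None:
        n_younger = n // 2
    geno = ["Val/Val", "Val/Met", "Met/Met"]
    return pd.DataFrame({
        "participant_id": [f"P{i:03d}" for i in range(1, n + 1)],
        "age_group": ["younger"] * n_younger + ["older"] * (n - n_younger),
        "genotype": [geno[i % 3] for i in range(n)],
        "sex": ["M", "F"] * (n // 2) + ["M"] * (n % 2),
    })
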