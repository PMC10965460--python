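import numpy as np
import pandas as pd
import pytest

from halex import GompertzIntensities, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def constant_model():
    """Age-constant illness-death intensities with a known closed form."""
    return GompertzIntensities.constant(0.03, 0.02, 0.05)


@pytest.fixture(scope="session")
def gompertz_model():
    """Age-varying intensities with a sex effect (the generator defaults)."""
    from halex import DEFAULT_INTENSITIES
    return DEFAULT_INTENSITIES


@pytest.fixture(scope="session")
def small_cohort():
    """3,000-subject simulated two-wave cohort under the default process."""
    return simulate_cohort(SimulationConfig(cohort_size=3000, seed=42))


def make_records(rows):
    """Panel-record DataFrame from (id, sex, a0, s0, a1, kind, s1) tuples."""
    df = pd.DataFrame(rows, columns=["subject_id", "sex", "entry_age", "entry_state",
                                     "exit_age", "exit_kind", "exit_state"])
    df["exit_state"] = df["exit_state"].astype("Int64")
    return df


def constant_hazard_counts(m, intervals=None, population=1e5):
    """Age-grouped count table whose every interval has central rate m."""
    from halex import default_age_intervals
    iv = intervals if intervals is not None else default_age_intervals()
    return pd.DataFrame({
        "age_start": [s for s, _ in iv],
        "age_width": [w for _, w in iv],
        "population": population,
        "deaths": [population * m for _ in iv],
    })
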