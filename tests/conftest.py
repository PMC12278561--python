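import numpy as np
import pandas as pd
import pytest

from clabsi_forest.synthetic import CohortConfig, cohort_frames, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-admission default cohort shared by cheap tests."""
    return generate_cohort(CohortConfig(n_admissions=400, seed=11))


@pytest.fixture(scope="session")
def small_tables(small_cohort):
    from clabsi_forest.landmarks import build_landmark_table

    episodes, daily = cohort_frames(small_cohort)
    lm = build_landmark_table(episodes, daily)
    return episodes, daily, lm


def random_survival_node(rng, n=None, max_day=7, p_censor=0.3):
    """Random (time, status) node for split-score oracle checks."""
    n = n or int(rng.integers(4, 25))
    time = rng.integers(1, max_day + 1, size=n)
    status = (rng.random(n) > p_censor).astype(int)
    return time, status


def random_cr_node(rng, n=None, max_day=7, p_censor=0.15):
    """Random (time, cause) node with three causes, 0 = censored."""
    n = n or int(rng.integers(4, 25))
    time = rng.integers(1, max_day + 1, size=n)
    cause = rng.integers(1, 4, size=n)
    cause[rng.random(n) < p_censor] = 0
    return time, cause
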