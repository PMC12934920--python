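"""Shared fixtures: one small synthetic cohort reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from vocalpredict.simulate import CohortConfig, simulate_cohort
from vocalpredict.sequences import fit_interval_models, segment_table


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (8 + 8 mice) without contours, default structure."""
    return simulate_cohort(CohortConfig(n_wt=8, n_dup=8, with_contours=False),
                           seed=0)


@pytest.fixture(scope="session")
def segmented_calls(small_cohort):
    calls = small_cohort["calls"]
    return segment_table(calls, fit_interval_models(calls))


@pytest.fixture(scope="session")
def full_cohort():
    """The default-size cohort (29 WT + 25 Dup, two ages), no contours."""
    return simulate_cohort(CohortConfig(with_contours=False), seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
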