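import numpy as np
import pytest

from infoseek.cohort import ObserverParams, simulate_cohort


@pytest.fixture(scope="session")
def default_observer():
    return ObserverParams(
        subject_id="obs",
        sensitivity=8.0,
        lapse_rate=0.01,
        conf_criteria=(0.6, 1.4),
        betas=np.array([-0.5, -1.0, -0.8]),
        dogmatism=0.0,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-subject simulated study reused by read-only tests."""
    return simulate_cohort(n_subjects=40, seed=101)


@pytest.fixture(scope="session")
def medium_cohort():
    """A 200-subject simulated study reused by fitting tests."""
    return simulate_cohort(n_subjects=200, seed=77)
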