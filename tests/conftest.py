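import numpy as np
import pytest

from neurometab.cohort import CohortConfig, default_ins_cr_truth, simulate_study


@pytest.fixture()
def rng():
    return np.random.default_rng(20200422)


@pytest.fixture(scope="session")
def small_cohort():
    """One simulated study table (66 controls + 33 concussed, 4 sessions)."""
    return simulate_study(CohortConfig(seed=5))


@pytest.fixture(scope="session")
def ins_truth():
    return default_ins_cr_truth()
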