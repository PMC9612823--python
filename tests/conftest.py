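import numpy as np
import pytest

from transinfer.behaviour_synth import CohortConfig, generate_cohort
from transinfer.task_design import generate_scan_trials


@pytest.fixture(scope="session")
def scan_trial_list():
    return generate_scan_trials(seed=42)


@pytest.fixture(scope="session")
def small_cohort():
    """Ten OR-regime participants; shared across read-only tests."""
    data, profiles = generate_cohort(
        CohortConfig(n_participants=10, regime="OR", kappa=0.9), seed=7
    )
    return data, profiles


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
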