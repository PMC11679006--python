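import numpy as np
import pytest

from fogsentry import RunConfig, SimConfig, simulate_cohort, simulate_trial


@pytest.fixture(scope="session")
def run_cfg():
    return RunConfig()


@pytest.fixture(scope="session")
def sim_trial():
    """One simulated trial guaranteed to contain FOG episodes."""
    trial, truth = simulate_trial(SimConfig(), seed=1, min_episodes=2)
    return trial, truth


@pytest.fixture(scope="session")
def small_cohort():
    """3 freezers + 2 non-freezers, 4 trials each: enough for LOFO."""
    ds, truths = simulate_cohort(3, 2, 4, seed=11)
    return ds, truths
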