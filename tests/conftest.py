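import numpy as np
import pytest

from nfasym.paradigm import build_schedule
from nfasym.synth import EEGSimParams, simulate_eeg


@pytest.fixture(scope="session")
def default_schedule():
    return build_schedule()


@pytest.fixture(scope="session")
def one_run_schedule():
    return build_schedule(n_runs=1)


@pytest.fixture(scope="session")
def short_schedule():
    """Two runs, full block structure — cheap but representative."""
    return build_schedule(n_runs=2)


@pytest.fixture(scope="session")
def exp_recording(one_run_schedule):
    return simulate_eeg(
        one_run_schedule, EEGSimParams(seed=42, asym_effect=0.3), "experimental"
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
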