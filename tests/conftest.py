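import numpy as np
import pytest

from statebold.design import SessionDesign, generate_event_schedule


@pytest.fixture(scope="session")
def small_design():
    """Two short runs at reduced EEG rate: fast but structurally complete."""
    return SessionDesign(n_runs=2, run_duration=313 * 2.25, eeg_rate=1000.0)


@pytest.fixture(scope="session")
def small_schedule(small_design):
    return generate_event_schedule(small_design, seed=3)


@pytest.fixture(scope="session")
def paper_scale_design():
    """Session dimensioned like the study: 4 runs, ~30-38 events per run."""
    return SessionDesign(n_runs=4, run_duration=913.5, eeg_rate=1000.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
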