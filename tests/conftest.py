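import numpy as np
import pytest

from scalebp.filters import segment_session
from scalebp.session import Calibration
from scalebp.simulate import SimulationConfig, simulate_session


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def clean_session():
    """Noiseless 75 BPM session with constant BP (true PTT 150 ms)."""
    cfg = SimulationConfig(
        duration_s=20.0, hr_start=75.0, hr_end=75.0, hrv_sd=0.0,
        bp_start=(120.0 + 1e-6, 80.0), bp_end=(120.0, 80.0),
        noise_sd=0.0, drift_amp=0.0, seed=7,
    )
    return simulate_session(cfg)


@pytest.fixture(scope="session")
def clean_segment(clean_session):
    """An interior segment of the clean session (calibration 120/80)."""
    session, _ = clean_session
    return segment_session(session)[2]


@pytest.fixture(scope="session")
def calibration():
    return Calibration(sbp_rest=120.0, dbp_rest=80.0)
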