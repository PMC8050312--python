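import numpy as np
import pytest

import pincontrol as pc


@pytest.fixture(scope="session")
def default_trial() -> pc.SyntheticTrial:
    """One full-length trial with default (noisy, pin-left) settings."""
    return pc.simulate_trial(pc.TrialConfig(seed=42))


@pytest.fixture(scope="session")
def noiseless_trial() -> pc.SyntheticTrial:
    """Deterministic trial: all noise sources off, released from an offset."""
    ctl = pc.ControllerParams(
        noise_sd=0.0, drift_sd=0.0, within_foot_noise_sd=0.0
    )
    cfg = pc.TrialConfig(
        seed=1,
        controller=ctl,
        init_offset_ap=0.02,
        init_offset_ml=0.01,
        marker_noise_sd=0.0,
    )
    return pc.simulate_trial(cfg)


@pytest.fixture(scope="session")
def short_trial() -> pc.SyntheticTrial:
    """A 6-s trial for cheap I/O and pipeline tests."""
    return pc.simulate_trial(pc.TrialConfig(seed=7, duration=6.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
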