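import numpy as np
import pytest

from microlapse import (
    CellConfig,
    DriftConfig,
    NoiseConfig,
    SimConfig,
    simulate_timelapse,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def quiet_config():
    """Small, disturbance-free acquisition: no drift, no noise, no dropouts."""
    return SimConfig(
        shape=(96, 96),
        n_frames=8,
        seed=11,
        drift=DriftConfig(S_inf=(0.0, 0.0), jitter_px=0.0),
        cells=CellConfig(n=5, motion_px_per_frame=0.0, growth_per_hour=0.0),
        noise=NoiseConfig(enabled=False),
        dark_frames=None,
        corrupt_frames=[],
    )


@pytest.fixture(scope="session")
def quiet_stack(quiet_config):
    return simulate_timelapse(quiet_config)


@pytest.fixture(scope="session")
def drifting_stack():
    """Known exponential-settle drift, mild noise, sensor-fixed dirt."""
    cfg = SimConfig(
        shape=(128, 128),
        n_frames=40,
        seed=21,
        drift=DriftConfig(S_inf=(8.0, -6.0), tau_s=600.0, jitter_px=0.0),
        cells=CellConfig(n=8, motion_px_per_frame=0.0, growth_per_hour=0.0),
        dark_frames=None,
        corrupt_frames=[],
    )
    return simulate_timelapse(cfg)
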