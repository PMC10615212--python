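import numpy as np
import pytest

from gaitkit.core import SamplingSpec
from gaitkit.simulate import SimulationConfig, event_schedule, schedule_span, simulate_recording


@pytest.fixture
def clean_cfg() -> SimulationConfig:
    """Noise-free, jitter-free simulation with identity sensor orientation."""
    return SimulationConfig(
        seed=42,
        n_bouts=2,
        strides_per_bout=(6, 8),
        noise_sd_accel=0.0,
        noise_sd_gyro=0.0,
        orientation="identity",
        insole_jitter_sd=0.0,
        insole_dropout_prob=0.0,
    )


@pytest.fixture
def clean_recording(clean_cfg):
    return simulate_recording(clean_cfg)


@pytest.fixture
def schedule(clean_cfg):
    sampling = SamplingSpec(rate=100.0, duration=schedule_span(clean_cfg))
    return event_schedule(clean_cfg, sampling), sampling
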