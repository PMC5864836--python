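import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eggkit import MultichannelRecording, SynthConfig

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_recording(rng):
    """Three channels, 10 minutes at 5 Hz, one carrying a 3 cpm source."""
    fs = 5.0
    n = 3000
    t = np.arange(n) / fs
    source = 100.0 * np.sin(2 * np.pi * 0.05 * t)
    samples = np.vstack(
        [
            source + rng.normal(0, 10, n),
            rng.normal(0, 10, n),
            rng.normal(0, 10, n),
        ]
    )
    return MultichannelRecording(
        samples, fs, ["A", "B", "C"], reference_label="B"
    )


@pytest.fixture
def burst_scenario_cfg():
    """Two-hour validation scenario: 100 uV slow wave, 20 uV noise, 10 bursts."""
    return SynthConfig(
        duration_s=7200.0,
        fs=5.0,
        slow_wave_amp_uv=100.0,
        noise_rms_uv=20.0,
        drift_rms_uv=0.0,
        envelope_sigma=0.0,
        artifact_count=10,
        seed=0,
    )
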