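import numpy as np
import pytest

from gaitkit import FilterParams, PipelineConfig, SimulationSpec, simulate


@pytest.fixture
def nobp_config() -> PipelineConfig:
    """Pipeline config for clean synthetic signals: band-pass stage off.

    The 5-10 Hz band sits above the stride-displacement band, so distance
    tests on simulator output run without it; gravity separation stays on.
    """
    return PipelineConfig(filter=FilterParams(enabled=False))


@pytest.fixture
def clean_walk():
    """A deterministic noiseless 12-stride walk plus its ground truth."""
    spec = SimulationSpec(
        n_strides=12,
        stride_length=16.0 / 12,
        stride_jitter=0.0,
        accel_noise_sd=0.0,
        pressure_glitch_prob=0.0,
        seed=7,
    )
    return simulate(spec)


def make_recording(pressure, accel=None, fs=50.0):
    """Tiny recording helper for hand-built pressure/acceleration patterns."""
    from gaitkit import InsoleRecording

    pressure = np.asarray(pressure)
    n = len(pressure)
    if accel is None:
        accel = np.zeros((n, 3))
    return InsoleRecording(
        t=np.arange(n) / fs, accel=np.asarray(accel, float), pressure=pressure, fs=fs
    )
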