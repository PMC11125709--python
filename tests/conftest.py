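import numpy as np
import pytest

from sitsway import CohortSpec, CoPTrack, PipelineConfig, SwayModelParams


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def fast_config():
    """Reduced-scale config for tests that don't pin the acquisition scale."""
    return PipelineConfig(sampling_rate_hz=100.0, trial_duration_s=20.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sine_track():
    """Circular track: unit-amplitude quadrature sines at 1 Hz, 100 Hz, 20 s."""
    rate, dur = 100.0, 20.0
    t = np.arange(int(rate * dur)) / rate
    return CoPTrack(
        x_ml_cm=np.cos(2 * np.pi * t), y_ap_cm=np.sin(2 * np.pi * t), rate_hz=rate
    )


@pytest.fixture(scope="session")
def small_cohort_spec():
    """Small, fast synthetic cohort used by several integration tests."""
    return CohortSpec(n_per_group=6, duration_s=20.0, rate_hz=100.0, rng_seed=7)


def pure_tone_params(freq_hz: float, amplitude_cm: float, **kw) -> SwayModelParams:
    return SwayModelParams(component_bands=((freq_hz, amplitude_cm, 0.0),), **kw)
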