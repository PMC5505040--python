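import numpy as np
import pytest

from emgimu.features import build_feature_matrix
from emgimu.preprocessing import synchronize
from emgimu.synthetic_data import SynthConfig, generate_recording


def small_config(**kw) -> SynthConfig:
    """Fast 4-class, 3-sensor recording config for unit tests."""
    defaults = dict(
        n_classes=4,
        n_sensors=3,
        n_repetitions=3,
        trial_duration_s=0.8,
        rest_duration_s=0.5,
        seed=1,
    )
    defaults.update(kw)
    return SynthConfig(**defaults)


def separable_config(n_sensors=12, n_classes=6, reps=6, seed=0, **kw) -> SynthConfig:
    """Well-separated multi-class config used for pipeline recovery tests."""
    defaults = dict(
        n_classes=n_classes,
        n_sensors=n_sensors,
        n_repetitions=reps,
        trial_duration_s=1.0,
        rest_duration_s=0.5,
        seed=seed,
    )
    defaults.update(kw)
    return SynthConfig(**defaults)


@pytest.fixture(scope="session")
def small_recording():
    return generate_recording(small_config())


@pytest.fixture(scope="session")
def small_aligned(small_recording):
    return synchronize(small_recording)


@pytest.fixture(scope="session")
def small_features(small_aligned):
    return build_feature_matrix(small_aligned)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
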