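import numpy as np
import pytest

import ovinesense as ov
from ovinesense.features import feature_table
from ovinesense.preprocess import window_recording


def build_feature_table(effect_size, seed, n_lame, n_nonlame, duration):
    """Simulate a flock and return its window-level feature table."""
    cfg = ov.SimulationConfig(
        recording_duration=duration, n_lame=n_lame, n_nonlame=n_nonlame, rng_seed=seed
    )
    profiles = ov.default_profiles(
        cfg, effect_size=effect_size, rng=np.random.default_rng(seed + 100)
    )
    flock = ov.generate_flock(cfg, profiles)
    windows = []
    for rec in flock:
        windows.extend(window_recording(rec))
    return feature_table(windows, cfg.sampling_rate)


@pytest.fixture(scope="session")
def null_table():
    """~2000 windows from a 12-sheep flock with zero lameness effect."""
    return build_feature_table(effect_size=0.0, seed=5, n_lame=6, n_nonlame=6, duration=600)


@pytest.fixture(scope="session")
def effect_table():
    """Same flock layout with a strong (effect_size=2) lameness signal."""
    return build_feature_table(effect_size=2.0, seed=5, n_lame=6, n_nonlame=6, duration=600)


@pytest.fixture(scope="session")
def small_recording():
    cfg = ov.SimulationConfig(recording_duration=300, n_lame=1, n_nonlame=1, rng_seed=3)
    return ov.generate_flock(cfg)[0]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
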