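import numpy as np
import pandas as pd
import pytest

from multierp import (Level, ParadigmConfig, SubjectProfile, generate_level,
                      simulate_recording)
from multierp.preprocess import EpochSet


@pytest.fixture(scope="session")
def default_config():
    return ParadigmConfig()


@pytest.fixture(scope="session")
def small_config():
    # 4 blocks x (20 stim + 3 baseline) = 92 trials; all count constraints
    # (integer frequent count, integer tone-slot mix) still hold
    return ParadigmConfig(blocks_per_level=4, stim_trials_per_block=20)


@pytest.fixture(scope="session")
def learn_schedule(default_config):
    return generate_level(Level.LEARN, default_config, seed=1)


@pytest.fixture(scope="session")
def who_schedule(default_config):
    return generate_level(Level.WHO, default_config, seed=7)


@pytest.fixture(scope="session")
def small_who_schedule(small_config):
    return generate_level(Level.WHO, small_config, seed=11)


@pytest.fixture(scope="session")
def small_who_recording(small_who_schedule):
    return simulate_recording(small_who_schedule, seed=11)


@pytest.fixture(scope="session")
def small_discern_recording(small_config):
    sched = generate_level(Level.DISCERN, small_config, seed=13)
    return simulate_recording(sched, seed=13)


def make_epochs(data, labels=None, srate=250.0, t_start_ms=-200.0,
                channels=None, lock="stimulus"):
    """Handcrafted EpochSet for unit tests."""
    data = np.asarray(data, dtype=float)
    n, n_ch, n_t = data.shape
    if channels is None:
        channels = tuple(f"ch{i}" for i in range(n_ch))
    if labels is None:
        labels = pd.DataFrame(index=range(n))
    times = t_start_ms + np.arange(n_t) / srate * 1000.0
    return EpochSet(data=data, times_ms=times, channels=tuple(channels),
                    labels=labels.reset_index(drop=True), srate_hz=srate,
                    lock=lock)
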