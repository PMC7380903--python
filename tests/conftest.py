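import numpy as np
import pytest

from rehabhar import (
    CNNConfig,
    ExerciseClass,
    SimConfig,
    sample_subject_profile,
    segment_sessions,
    simulate_training_acquisition,
)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=42)


@pytest.fixture(scope="session")
def profile(sim_config):
    return sample_subject_profile(sim_config, "S01")


@pytest.fixture(scope="session")
def tiny_sessions(profile, sim_config):
    """Small acquisition recording: 2 reps x 1 session (8 attempts)."""
    return simulate_training_acquisition(profile, sim_config, reps=2, sessions=1)


@pytest.fixture(scope="session")
def tiny_windows(tiny_sessions):
    return segment_sessions(tiny_sessions)


@pytest.fixture(scope="session")
def fast_cnn_config():
    """Few-epoch training config for structure-level tests."""
    return CNNConfig(epochs=5, seed=0)


def make_toy_windows(n_per_class=30, noise=0.05, seed=0, n_channels=6, length=30):
    """Linearly separable two-class window set: near-constant signals
    (labeled NO_EXERCISE) vs a high-frequency sinusoid (labeled
    BILATERAL_FLEXION).  Separable by construction."""
    from rehabhar.sessions import Window

    rng = np.random.default_rng(seed)
    t = np.arange(length)
    windows = []
    for i in range(n_per_class):
        flat = rng.normal(0.0, noise, size=(length, n_channels))
        windows.append(
            Window(values=flat, label=ExerciseClass.NO_EXERCISE,
                   subject_id="toy", start=i)
        )
        wavy = np.sin(2 * np.pi * 0.4 * t)[:, None] + rng.normal(
            0.0, noise, size=(length, n_channels)
        )
        windows.append(
            Window(values=wavy, label=ExerciseClass.BILATERAL_FLEXION,
                   subject_id="toy", start=i)
        )
    return windows
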