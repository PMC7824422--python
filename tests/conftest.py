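import numpy as np
import pytest

from erspconn import synth
from erspconn.types import EpochSet


@pytest.fixture(scope="session")
def montage():
    return synth.make_montage("study32")


@pytest.fixture(scope="session")
def noise_epochs():
    """100 trials of pure background noise (50 per condition), fs=250."""
    cfg = synth.SimulationConfig(
        fs=250.0, n_subjects=1, n_trials_per_condition=50, seed=101
    )
    datasets, _ = synth.simulate_dataset(cfg)
    return datasets[0]


@pytest.fixture()
def small_epochs():
    """Tiny deterministic EpochSet: 4 trials × 3 channels × 500 samples."""
    rng = np.random.default_rng(7)
    fs = 250.0
    n_samp = 500
    data = rng.standard_normal((4, 3, n_samp))
    time_ms = -1000.0 + np.arange(n_samp) * (1000.0 / fs)
    return EpochSet(
        data,
        time_ms,
        ["a", "b", "c"],
        np.array(["supportive", "supportive", "impeding", "impeding"]),
        fs,
    )


def make_noise_epochs(
    n_trials: int,
    n_channels: int,
    fs: float = 250.0,
    n_samples: int = 1500,
    seed: int = 0,
    t0_ms: float = -4000.0,
    labels=None,
) -> EpochSet:
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_trials, n_channels, n_samples))
    time_ms = t0_ms + np.arange(n_samples) * (1000.0 / fs)
    if labels is None:
        labels = [f"ch{i}" for i in range(n_channels)]
    return EpochSet(
        data, time_ms, labels, np.array(["supportive"] * n_trials), fs
    )
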