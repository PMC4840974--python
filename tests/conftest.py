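import numpy as np
import pytest

from dvmeth import MethylationDataset, SimConfig, simulate_dataset


def make_dataset(values, group=None):
    """Small MethylationDataset from a 2-D array (rows features, cols samples)."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    if group is None:
        half = n_samp // 2
        group = [0] * half + [1] * (n_samp - half)
    return MethylationDataset(
        values=values,
        feature_ids=[f"cg{i:04d}" for i in range(n_feat)],
        sample_ids=[f"s{i:03d}" for i in range(n_samp)],
        group=group,
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulated dataset (6000 x 100, seed 1)."""
    return simulate_dataset(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_sim():
    """A scaled-down simulation for fast per-test use."""
    return simulate_dataset(
        SimConfig(n_features=600, n_true_per_type=20, seed=11)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
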