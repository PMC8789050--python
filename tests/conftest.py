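import numpy as np
import pytest

from guidegp import simulate_dataset, train_model
from guidegp.model import GPHeadConfig, HOMConfig, PreprocessorConfig, TrainConfig

SMALL_LENGTH = 12


def small_configs(kind: str = "conv1d", **train_kwargs):
    """A reduced architecture for fast unit tests."""
    pcfg = PreprocessorConfig(kind=kind, channels=8, hidden_size=8, kernel_width=3)
    hcfg = HOMConfig(n_capsules=3, capsule_dim=4)
    gcfg = GPHeadConfig(n_features=32)
    defaults = dict(epochs=8, batch_size=128, seed=0, n_train_samples=2)
    defaults.update(train_kwargs)
    tcfg = TrainConfig(**defaults)
    return pcfg, hcfg, gcfg, tcfg


@pytest.fixture(scope="session")
def small_dataset():
    data, truth = simulate_dataset(400, SMALL_LENGTH, seed=0)
    return data, truth


@pytest.fixture(scope="session")
def small_model(small_dataset):
    """A quickly trained model reused by tests that only need *a* trained model."""
    data, _ = small_dataset
    pcfg, hcfg, gcfg, tcfg = small_configs(epochs=15)
    return train_model(data, pcfg, hcfg, gcfg, tcfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
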