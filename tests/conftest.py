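import numpy as np
import pytest

from m6acnn import MotifModel, TrainingConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small, strongly separable planted-motif dataset (60 + 60)."""
    return generate_dataset(60, 60, model=MotifModel(insertion_probability=1.0), seed=7)


@pytest.fixture(scope="session")
def tiny_encoded(tiny_dataset):
    X, y = tiny_dataset.encode()
    order = np.random.default_rng(123).permutation(len(y))
    return X[order], y[order]


@pytest.fixture
def fast_config():
    """Training config scaled down for unit tests."""
    return TrainingConfig(epochs=10, early_stop_patience=10, batch_size=16, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
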