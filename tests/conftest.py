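import pytest

from phatg import ModelConfig, SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def fast_config() -> ModelConfig:
    """A small network configuration for fast functional tests."""
    return ModelConfig(
        n_bits=64, hidden_layers=3, width=96, dropout_rate=0.1,
        epochs=150, batch_size=32, initial_lr=1e-3, seed=0,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """160 synthetic PHA-like records with Fox-rule ground truth."""
    ds, gt = generate_dataset(SyntheticConfig(n_samples=160, seed=7))
    return ds, gt


@pytest.fixture(scope="session")
def tiny_dataset():
    """40 records; enough for plumbing tests, too few for accuracy."""
    ds, gt = generate_dataset(SyntheticConfig(n_samples=40, seed=3))
    return ds, gt
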