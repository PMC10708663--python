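import numpy as np
import pytest

from hsicalib.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small end-to-end synthetic dataset shared by fast tests."""
    cfg = SyntheticConfig(n_samples=12, seed=5)
    records, truth = generate_dataset(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def full_dataset():
    """Study-scale dataset (187 samples) shared by the slower checks."""
    cfg = SyntheticConfig(seed=11)
    records, truth = generate_dataset(cfg)
    return cfg, records, truth
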