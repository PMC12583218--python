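import numpy as np
import pytest

from heterodti.model import DTIData
from heterodti.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def small_dataset():
    """A miniature planted dataset for fast structural tests."""
    cfg = SyntheticConfig(m=20, n=15, rank=4, density=0.2, noise=0.0,
                          n_drug_clusters=3, n_target_families=3, nbits=64,
                          seq_length_range=(30, 40))
    return generate(cfg, seed=11)


@pytest.fixture(scope="session")
def small_data(small_dataset):
    return DTIData.from_synthetic(small_dataset)


@pytest.fixture(scope="session")
def standard_dataset():
    """The standard fixture: 60 drugs, 50 targets, rank 8, density 0.15,
    label noise 0.05."""
    return generate(SyntheticConfig(), seed=7)


@pytest.fixture(scope="session")
def standard_data(standard_dataset):
    return DTIData.from_synthetic(standard_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
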