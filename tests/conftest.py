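import numpy as np
import pytest

from alclassify import Dataset, make_synthetic


@pytest.fixture(scope="session")
def easy_two_class():
    """Well-separated 2-class Gaussian data in 10 dimensions."""
    return make_synthetic(k_classes=2, dim=10, n_per_class=60,
                          separation=0.8, noise_sd=0.05, seed=11)


@pytest.fixture(scope="session")
def easy_split(easy_two_class):
    ds = easy_two_class
    n = ds.n_samples
    train = Dataset(ds.samples[: n // 2], ds.labels[: n // 2])
    test = Dataset(ds.samples[n // 2:], ds.labels[n // 2:])
    return train, test


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
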