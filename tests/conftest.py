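import numpy as np
import pytest

from corrsearch import FeatureMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_matrix():
    """Factory for random feature matrices with controllable shape and seed."""

    def make(m=10, n=8, seed=0):
        values = np.random.default_rng(seed).standard_normal((m, n))
        return FeatureMatrix(values)

    return make


def pearson_oracle(x, y):
    """Textbook Pearson correlation, independent of the projection code path."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))
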