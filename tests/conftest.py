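import numpy as np
import pytest

from minml import FeatureDataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def separable_table():
    """Two constant, disjoint classes: C1 all zeros, C2 all tens."""
    patterns = np.vstack([np.zeros((5, 4)), np.full((5, 4), 10.0)])
    labels = np.array(["C1"] * 5 + ["C2"] * 5, dtype=object)
    return FeatureDataset(patterns, labels)


@pytest.fixture
def random_table(rng):
    """Seeded 20x8 two-class table with a mild shift on 3 attributes."""
    X = rng.normal(0, 1, size=(20, 8))
    X[10:, :3] += 2.0
    labels = np.array(["a"] * 10 + ["b"] * 10, dtype=object)
    return FeatureDataset(X, labels)
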