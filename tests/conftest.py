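import numpy as np
import pytest

from chainfs import FeatureTable, SyntheticSpec, make_synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def planted():
    """The standard planted recovery dataset: 200 samples, 60 features
    (5 informative at 3-sigma separation, 5 noisy copies, 50 noise)."""
    spec = SyntheticSpec(n_samples=200, n_informative=5, n_redundant=5,
                         n_noise=50, class_separation=3.0, seed=7)
    table, labels, roles = make_synthetic(spec)
    return table, labels, roles


@pytest.fixture
def tiny_table():
    values = np.array([
        [1.0, 4.0, 0.1],
        [2.0, 3.0, 0.9],
        [3.0, 2.0, 0.2],
        [4.0, 1.0, 0.8],
        [5.0, 0.0, 0.3],
        [6.0, -1.0, 0.7],
    ])
    labels = np.array([0, 0, 0, 1, 1, 1])
    return FeatureTable(values, ["up", "down", "wiggle"]), labels
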