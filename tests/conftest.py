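import numpy as np
import pytest

from hsp90qsar import QSARDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    """30 compounds x 5 descriptors with a known linear signal on the first two."""
    X = rng.standard_normal((30, 5))
    y = 1.5 + 2.0 * X[:, 0] - 1.0 * X[:, 1] + 0.3 * rng.standard_normal(30)
    return QSARDataset([f"c{i}" for i in range(30)], list("abcde"), X, y)


def make_dataset(values, activities=None, ids=None, names=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if activities is None:
        activities = np.zeros(n)
    if ids is None:
        ids = [f"c{i + 1}" for i in range(n)]
    if names is None:
        names = [f"d{j + 1}" for j in range(p)]
    return QSARDataset(ids, names, values, activities)
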