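import numpy as np
import pytest

from plsstab.dataset import ExpressionDataset
from plsstab.simulate import SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    """3 classes, 10 samples/class, 60 genes, strong planted markers."""
    ds, markers = generate(
        SyntheticSpec(K=3, n_per_class=10, m=60, pairwise_markers=2,
                      ovr_markers=2, delta=3.0, sigma=1.0, seed=7)
    )
    return ds, markers


@pytest.fixture
def two_class_dataset(rng):
    """Binary dataset with a handful of shifted genes."""
    X = rng.normal(size=(24, 30))
    X[:12, :4] += 2.5
    labels = np.array([1] * 12 + [2] * 12)
    return ExpressionDataset(X, labels)
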