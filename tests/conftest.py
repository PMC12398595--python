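import numpy as np
import pytest

from melssgan import (
    FeatureDataset,
    MixtureSpec,
    generate_mixture_dataset,
    make_semisupervised_split,
    ring_mixture_spec,
)


@pytest.fixture(scope="session")
def ring_spec() -> MixtureSpec:
    """Default 8-mode ring fixture (4 modes per class, d=16)."""
    return ring_mixture_spec()


@pytest.fixture(scope="session")
def ring_data(ring_spec) -> FeatureDataset:
    return generate_mixture_dataset(ring_spec, 600, seed=101)


@pytest.fixture(scope="session")
def semi_ring_data(ring_data) -> FeatureDataset:
    return make_semisupervised_split(ring_data, 0.3, seed=102)


@pytest.fixture()
def tiny_dataset() -> FeatureDataset:
    """40 rows, d=4, separable two-class blobs, some rows unlabeled."""
    rng = np.random.default_rng(7)
    X0 = rng.normal(-2.0, 0.4, size=(20, 4))
    X1 = rng.normal(2.0, 0.4, size=(20, 4))
    X = np.vstack([X0, X1])
    y = np.array([0] * 20 + [1] * 20)
    y[::4] = -1
    return FeatureDataset(features=X, labels=y)


@pytest.fixture()
def prob_rows() -> np.ndarray:
    rng = np.random.default_rng(13)
    raw = rng.random((5, 3)) + 0.05
    return raw / raw.sum(axis=1, keepdims=True)
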