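import numpy as np
import pytest

from trajselect.containers import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def chain_points():
    """Five collinear cells at positions 0, 1, 2, 4, 8 (one feature)."""
    return np.array([[0.0], [1.0], [2.0], [4.0], [8.0]])


@pytest.fixture
def blob_matrix(rng):
    """Two well-separated Gaussian blobs differing only in feature 0."""
    n_half = 30
    X = rng.normal(0.0, 0.3, size=(2 * n_half, 5))
    X[n_half:, 0] += 8.0
    labels = np.r_[np.zeros(n_half, dtype=int), np.ones(n_half, dtype=int)]
    em = ExpressionMatrix(
        X, [f"c{i}" for i in range(2 * n_half)], [f"f{j}" for j in range(5)], "normalized"
    )
    return em, labels


def make_matrix(values, layer="normalized"):
    values = np.asarray(values, dtype=float)
    n, d = values.shape
    return ExpressionMatrix(
        values, [f"c{i}" for i in range(n)], [f"f{j}" for j in range(d)], layer
    )


@pytest.fixture
def make_em():
    return make_matrix
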