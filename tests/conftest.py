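import numpy as np
import pytest

from exprgat import (
    FeatureMatrix,
    SynthConfig,
    build_adjacency,
    generate_clustered_expression,
    pairwise_correlation,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_adjacency(rng, n):
    """Random binary adjacency with unit diagonal (rows never empty)."""
    A = (rng.random((n, n)) < 0.5).astype(float)
    np.fill_diagonal(A, 1.0)
    return A


@pytest.fixture
def small_clustered():
    """A small, clearly separated 3-group dataset with its graph."""
    cfg = SynthConfig(n_samples=60, n_features=40, k_groups=3, separation=6.0, seed=7)
    expr, labels = generate_clustered_expression(cfg)
    X = FeatureMatrix.from_expression(expr)
    A = build_adjacency(pairwise_correlation(X), density=0.15)
    return X, A, labels
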