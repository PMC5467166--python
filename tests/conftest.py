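import numpy as np
import pandas as pd
import pytest

from comod import generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared by read-only tests."""
    return generate_cohort(seed=42)


@pytest.fixture
def small_expression(rng):
    """A tiny 12-gene x 20-sample matrix with one 6-gene correlated block."""
    factor = rng.standard_normal(20)
    X = rng.normal(0, 1, size=(12, 20))
    X[:6] += 2.0 * factor
    return pd.DataFrame(
        X, index=[f"g{i}" for i in range(12)], columns=[f"s{i}" for i in range(20)]
    )


def random_adjacency(rng, n):
    """Symmetric adjacency in [0,1] with unit diagonal."""
    M = rng.random((n, n))
    A = (M + M.T) / 2.0
    np.fill_diagonal(A, 1.0)
    return A
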