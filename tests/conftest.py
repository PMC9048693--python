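import numpy as np
import pytest

from poibm import CountMatrix


def make_counts(values, gene_prefix="g", sample_prefix="s") -> CountMatrix:
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    return CountMatrix(
        values,
        np.array([f"{gene_prefix}{i}" for i in range(m)], dtype=object),
        np.array([f"{sample_prefix}{j}" for j in range(n)], dtype=object),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture
def toy_pair(rng):
    """Two small batches drawn from the same Poisson model (no batch effect)."""
    m, n = 30, 6
    base = rng.lognormal(3.0, 1.0, size=m)
    X = rng.poisson(base[:, None] * np.ones((m, n))) + 1.0
    Y = rng.poisson(base[:, None] * np.ones((m, n))) + 1.0
    return make_counts(X), make_counts(Y)


@pytest.fixture
def distinct_columns_matrix(rng):
    """A 100-gene, 10-sample matrix whose columns are clearly distinct."""
    m, n = 100, 10
    rates = rng.lognormal(3.0, 1.0, size=(m, n))
    return make_counts(rng.poisson(rates) + 1.0)
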