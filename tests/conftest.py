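import numpy as np
import pytest

from signsum.data import ExpressionMatrix


def make_matrix(p, n1, n0, rng, shift=0.0):
    """Random continuous matrix with the first columns labelled disease."""
    values = rng.standard_normal((p, n1 + n0))
    values[:, :n1] += shift
    return ExpressionMatrix(
        values=values,
        gene_ids=[f"g{j:03d}" for j in range(p)],
        group=[1] * n1 + [0] * n0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20_240)


@pytest.fixture
def small_matrix(rng):
    """6 disease + 6 normal samples, 12 genes; tie-free with high probability."""
    return make_matrix(12, 6, 6, rng, shift=0.8)


@pytest.fixture
def wide_matrix(rng):
    """20 disease + 20 normal samples, 5 genes."""
    return make_matrix(5, 20, 20, rng, shift=0.5)
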