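import numpy as np
import pytest

from coexcis import (
    TernaryExpressionMatrix,
    planted_block_truth,
    synth_expression,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix():
    """5 genes x 6 conditions, hand-constructed ternary values."""
    values = [
        [1, 1, 0, -1, 0, 1],
        [1, 0, 1, -1, 1, 0],
        [-1, -1, 0, 1, 0, -1],
        [0, 1, 1, 0, -1, 1],
        [0, 0, 0, 0, 0, 0],  # zero-variance gene
    ]
    return TernaryExpressionMatrix(
        [f"g{i}" for i in range(1, 6)], [f"c{j}" for j in range(1, 7)], values
    )


@pytest.fixture
def planted_matrix():
    """200 genes, 4 planted modules of 25, 100 conditions, 10% corruption."""
    truth = planted_block_truth(4, 25, 100, 0.1, seed=11)
    return synth_expression(200, 100, truth, seed=12), truth


def random_ternary(n_genes, n_conditions, seed):
    g = np.random.default_rng(seed)
    vals = g.choice([-1, 0, 1], size=(n_genes, n_conditions))
    # guard against zero-variance rows, which have no defined correlation
    for i in range(n_genes):
        if len(np.unique(vals[i])) == 1:
            vals[i, 0] = -1 if vals[i, 0] != -1 else 1
    return TernaryExpressionMatrix(
        [f"g{i:02d}" for i in range(n_genes)],
        [f"c{j:02d}" for j in range(n_conditions)],
        vals,
    )
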