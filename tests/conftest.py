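import numpy as np
import pytest

from scgenegroups.expression import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_raw_matrix():
    """3 genes x 4 cells, raw TPM scale."""
    values = np.array(
        [
            [0.0, 1.0, 3.0, 7.0],
            [2.0, 0.0, 0.0, 1.0],
            [5.0, 5.0, 5.0, 5.0],
        ]
    )
    return ExpressionMatrix(
        values, ["gA", "gB", "gC"], ["c1", "c2", "c3", "c4"], "raw_tpm"
    )


def random_log_matrix(rng, n_genes=50, n_cells=30):
    values = np.abs(rng.normal(2.0, 1.0, size=(n_genes, n_cells)))
    values *= rng.random((n_genes, n_cells)) < 0.7  # dropout-like zeros
    return ExpressionMatrix(
        values,
        [f"g{i}" for i in range(n_genes)],
        [f"c{j}" for j in range(n_cells)],
        "log",
    )
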