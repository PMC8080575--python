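import numpy as np
import pandas as pd
import pytest

from asceco import io_qc


@pytest.fixture
def rng():
    return np.random.default_rng(20201204)


def make_matrix(values, gene_ids=None, cell_ids=None, transform="precomputed"):
    """Build an ExpressionMatrix from a 2-D array with default ids."""
    arr = np.asarray(values, dtype=float)
    genes = gene_ids or [f"g{i}" for i in range(arr.shape[0])]
    cells = cell_ids or [f"c{j}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=genes, columns=cells)
    meta = pd.DataFrame(index=df.columns)
    return io_qc.ExpressionMatrix(df, meta, transform=transform)


@pytest.fixture
def small_expression():
    return make_matrix(
        [[0.0, 2.5, 1.0], [3.0, 0.0, 2.0], [1.5, 1.5, 0.0]],
        gene_ids=["A", "B", "C"],
        cell_ids=["c1", "c2", "c3"],
    )
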