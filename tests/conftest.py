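import numpy as np
import pandas as pd
import pytest

from lsmetacell.data_io import CellExpressionMatrix
from lsmetacell.similarity import CellSimilarityMatrix


@pytest.fixture
def tiny_counts() -> CellExpressionMatrix:
    return CellExpressionMatrix(
        counts=np.array([[1, 2, 0], [3, 4, 1], [0, 0, 5]]),
        cell_ids=["c0", "c1", "c2"],
        gene_ids=["g0", "g1", "g2"],
    )


@pytest.fixture
def block_cells() -> tuple[CellExpressionMatrix, CellSimilarityMatrix]:
    """Four cells in two transcriptional blocks: A,B express gene 1 only,
    C,D express gene 2 only; Pearson similarity is +1 within a block and
    -1 across."""
    X = CellExpressionMatrix(
        counts=np.array([[10, 0], [10, 0], [0, 10], [0, 10]]),
        cell_ids=["A", "B", "C", "D"],
        gene_ids=["g1", "g2"],
    )
    P = CellSimilarityMatrix(
        values=np.array(
            [
                [1.0, 1.0, -1.0, -1.0],
                [1.0, 1.0, -1.0, -1.0],
                [-1.0, -1.0, 1.0, 1.0],
                [-1.0, -1.0, 1.0, 1.0],
            ]
        ),
        cell_ids=["A", "B", "C", "D"],
    )
    return X, P


def random_counts(rng: np.random.Generator, n_cells: int, n_genes: int):
    return CellExpressionMatrix(
        counts=rng.integers(0, 20, size=(n_cells, n_genes)),
        cell_ids=[f"c{i}" for i in range(n_cells)],
        gene_ids=[f"g{j}" for j in range(n_genes)],
    )
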