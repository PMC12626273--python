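"""Cell-cell transcriptional similarity.

The aggregation algorithm consumes a dense symmetric similarity matrix over
cells; by default this is the Pearson correlation between the cells'
log-normalized gene profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .data_io import NormalizedMatrix


@dataclass
class CellSimilarityMatrix:
    """Symmetric cell-cell similarity with the cell ids it covers."""

    values: np.ndarray
    cell_ids: list[str]
    method: str = "pearson"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != self.values.shape[1]:
            raise ValueError("similarity matrix must be square")
        if len(self.cell_ids) != self.values.shape[0]:
            raise ValueError("cell id count does not match matrix size")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.cell_ids)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def cell_similarity(
    N: NormalizedMatrix, method: Literal["pearson"] = "pearson"
) -> CellSimilarityMatrix:
    """Pearson correlation between every pair of cell profiles.

    Cells whose profile is constant across genes have undefined correlation;
    their similarities are set to 0 with a warning and their diagonal entry
    kept at 1.
    """
    if method != "pearson":
        raise ValueError(f"unsupported similarity method {method!r}")
    V = np.asarray(N.values, dtype=float)
    if V.shape[1] < 2:
        raise ValueError("need at least 2 genes for cell-cell correlation")
    sd = V.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(V)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant-profile cells: similarities set to 0"
        )
        R[constant, :] = 0.0
        R[:, constant] = 0.0
    np.fill_diagonal(R, 1.0)
    R = np.clip(R, -1.0, 1.0)
    R = (R + R.T) / 2.0  # exact symmetry
    return CellSimilarityMatrix(values=R, cell_ids=list(N.cell_ids), method="pearson")
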