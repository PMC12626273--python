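"""Reading, writing, filtering and normalizing UMI count matrices.

The package's internal orientation is always cells x genes. Matrix Market
files default to the CellRanger convention (genes x cells) and are
transposed on read; dense TSV/CSV files are assumed cells x genes unless
told otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class ValidationError(ValueError):
    """Raised when an input matrix violates a structural invariant."""


class EmptyResultError(ValueError):
    """Raised when a filtering step removes every gene."""


@dataclass
class CellExpressionMatrix:
    """Integer UMI counts for cells x genes, with ids and optional labels.

    Parameters
    ----------
    counts
        Non-negative integer matrix, one row per cell, one column per gene.
    cell_ids, gene_ids
        Unique string identifiers for the two axes.
    cell_type, group
        Optional per-cell categorical labels (cell type; individual/batch).
    phenotypes
        Optional numeric table keyed by cell id or by group id.
    """

    counts: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    cell_type: Optional[pd.Series] = None
    group: Optional[pd.Series] = None
    phenotypes: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValidationError("counts must be integral")
            self.counts = as_int
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {n_cells} rows"
            )
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {n_genes} columns"
            )
        if len(set(self.cell_ids)) != n_cells:
            raise ValidationError("cell ids must be unique")
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("gene ids must be unique")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, mask_or_idx) -> "CellExpressionMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CellExpressionMatrix(
            counts=self.counts[idx],
            cell_ids=[self.cell_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
            cell_type=None if self.cell_type is None else self.cell_type.iloc[idx].reset_index(drop=True),
            group=None if self.group is None else self.group.iloc[idx].reset_index(drop=True),
            phenotypes=self.phenotypes,
        )

    def subset_genes(self, mask_or_idx) -> "CellExpressionMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CellExpressionMatrix(
            counts=self.counts[:, idx],
            cell_ids=list(self.cell_ids),
            gene_ids=[self.gene_ids[i] for i in idx],
            cell_type=self.cell_type,
            group=self.group,
            phenotypes=self.phenotypes,
        )

    def split_by_group(self) -> dict[str, "CellExpressionMatrix"]:
        """Split into one matrix per group label (sorted group-id order)."""
        if self.group is None:
            raise ValidationError("no group labels attached")
        out = {}
        labels = self.group.astype(str).to_numpy()
        for g in sorted(set(labels)):
            out[g] = self.subset_cells(labels == g)
        return out

    def to_anndata(self):
        """Thin adapter to an :class:`anndata.AnnData` (cells x genes)."""
        import anndata

        obs = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        if self.cell_type is not None:
            obs["cell_type"] = self.cell_type.to_numpy()
        if self.group is not None:
            obs["group"] = self.group.to_numpy()
        var = pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id"))
        return anndata.AnnData(X=self.counts.copy(), obs=obs, var=var)


@dataclass
class NormalizedMatrix:
    """Real-valued normalized expression (cells or metacells x genes)."""

    values: np.ndarray
    mode: Literal["relative", "cpm_like", "log1p_scaled"]
    scale_factor: float
    source_library_sizes: np.ndarray
    cell_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


def library_sizes(X: CellExpressionMatrix) -> np.ndarray:
    """Total UMI count per cell (row sums); zero is legal."""
    return X.counts.sum(axis=1).astype(np.int64)


def read_count_matrix(
    path,
    format: Literal["mtx", "tsv", "csv"] = "mtx",
    orientation: Literal["genes_by_cells", "cells_by_genes"] = "genes_by_cells",
) -> CellExpressionMatrix:
    """Read an MTX triplet (with optional features/barcodes sidecars) or a
    dense TSV/CSV into a :class:`CellExpressionMatrix`.

    For dense files the header row holds gene ids and the first column holds
    cell ids when ``orientation='cells_by_genes'`` (transposed otherwise).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mtx":
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # mmread reports the offending line
            raise ValidationError(f"malformed Matrix Market file {path}: {exc}") from exc
        dense = np.asarray(
            mat.toarray() if scipy.sparse.issparse(mat) else mat
        )
        if orientation == "genes_by_cells":
            dense = dense.T
        n_cells, n_genes = dense.shape
        gene_ids = _read_sidecar(path.parent / "features.tsv", n_genes)
        if gene_ids is None:
            gene_ids = _read_sidecar(path.parent / "genes.tsv", n_genes)
        cell_ids = _read_sidecar(path.parent / "barcodes.tsv", n_cells)
        if gene_ids is None:
            gene_ids = [f"gene_{i}" for i in range(n_genes)]
        if cell_ids is None:
            cell_ids = [f"cell_{i}" for i in range(n_cells)]
        counts = _validate_integral(dense)
        return CellExpressionMatrix(counts, cell_ids, gene_ids)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        if orientation == "genes_by_cells":
            df = df.T
        counts = _validate_integral(df.to_numpy())
        return CellExpressionMatrix(
            counts, [str(i) for i in df.index], [str(c) for c in df.columns]
        )
    raise ValueError(f"unknown format {format!r}")


def _read_sidecar(path: Path, expected: int) -> Optional[list[str]]:
    if not path.exists():
        return None
    df = pd.read_csv(path, sep="\t", header=None)
    ids = df.iloc[:, 0].astype(str).tolist()
    if len(ids) != expected:
        raise ValidationError(
            f"sidecar {path.name} has {len(ids)} ids, expected {expected}"
        )
    return ids


def _validate_integral(dense: np.ndarray) -> np.ndarray:
    if (dense < 0).any():
        bad = np.argwhere(dense < 0)[0]
        raise ValidationError(
            f"negative count at row {bad[0]}, column {bad[1]}"
        )
    as_int = np.rint(dense).astype(np.int64)
    if not np.allclose(as_int, dense, rtol=0, atol=0):
        bad = np.argwhere(as_int != dense)[0]
        raise ValidationError(
            f"non-integer count at row {bad[0]}, column {bad[1]}"
        )
    return as_int


def write_count_matrix(
    X: CellExpressionMatrix,
    path,
    format: Literal["mtx", "tsv", "csv"] = "mtx",
    orientation: Literal["genes_by_cells", "cells_by_genes"] = "genes_by_cells",
) -> None:
    """Write counts; MTX gets features.tsv/barcodes.tsv sidecars."""
    path = Path(path)
    if format == "mtx":
        mat = scipy.sparse.coo_matrix(
            X.counts.T if orientation == "genes_by_cells" else X.counts
        )
        scipy.io.mmwrite(str(path), mat, field="integer")
        pd.Series(X.gene_ids).to_csv(
            path.parent / "features.tsv", sep="\t", header=False, index=False
        )
        pd.Series(X.cell_ids).to_csv(
            path.parent / "barcodes.tsv", sep="\t", header=False, index=False
        )
        return
    sep = "\t" if format == "tsv" else ","
    df = pd.DataFrame(X.counts, index=X.cell_ids, columns=X.gene_ids)
    if orientation == "genes_by_cells":
        df = df.T
    df.to_csv(path, sep=sep)


def read_annotations(path, cell_id_col: str = "cell_id") -> pd.DataFrame:
    """Read a cell annotation TSV (cell_id, cell_type, group, phenotypes...)."""
    df = pd.read_csv(path, sep="\t")
    if cell_id_col not in df.columns:
        raise ValidationError(f"annotation file lacks column {cell_id_col!r}")
    return df.set_index(cell_id_col)


def attach_annotations(
    X: CellExpressionMatrix,
    annot: pd.DataFrame,
    cell_type_col: Optional[str] = "cell_type",
    group_col: Optional[str] = "group",
) -> CellExpressionMatrix:
    """Attach per-cell labels from an annotation table indexed by cell id."""
    missing = [c for c in X.cell_ids if c not in annot.index]
    if missing:
        raise ValidationError(
            f"{len(missing)} cells missing from annotation (first: {missing[0]})"
        )
    aligned = annot.loc[X.cell_ids]
    ct = None
    grp = None
    if cell_type_col is not None:
        if cell_type_col not in aligned.columns:
            raise ValidationError(f"annotation lacks column {cell_type_col!r}")
        ct = aligned[cell_type_col].reset_index(drop=True)
    if group_col is not None:
        if group_col not in aligned.columns:
            raise ValidationError(f"annotation lacks column {group_col!r}")
        grp = aligned[group_col].reset_index(drop=True)
    pheno_cols = [
        c
        for c in aligned.columns
        if c not in (cell_type_col, group_col)
        and pd.api.types.is_numeric_dtype(aligned[c])
    ]
    pheno = aligned[pheno_cols].copy() if pheno_cols else None
    return CellExpressionMatrix(
        X.counts, X.cell_ids, X.gene_ids, cell_type=ct, group=grp, phenotypes=pheno
    )


def filter_genes_by_detection(
    X: CellExpressionMatrix, min_fraction: float = 0.10
) -> CellExpressionMatrix:
    """Keep genes detected (count > 0) in at least ``min_fraction`` of cells.

    The threshold is inclusive: a gene seen in exactly
    ``min_fraction * n_cells`` cells is retained. Idempotent.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in [0, 1]")
    detected = (X.counts > 0).sum(axis=0) / X.n_cells
    keep = detected >= min_fraction
    if not keep.any():
        raise EmptyResultError(
            f"no gene detected in >= {min_fraction:.0%} of cells"
        )
    return X.subset_genes(keep)


def log_normalize(
    X: CellExpressionMatrix, scale_factor: float = 10_000.0
) -> NormalizedMatrix:
    """ln(1 + scale_factor * count / library_size), per cell.

    Every cell must have a positive library size; offending cells are named
    in the error.
    """
    s = library_sizes(X).astype(float)
    zero = s == 0
    if zero.any():
        bad = [X.cell_ids[i] for i in np.flatnonzero(zero)[:5]]
        raise ValidationError(f"zero library size for cells: {bad}")
    values = np.log1p(scale_factor * X.counts / s[:, None])
    return NormalizedMatrix(
        values=values,
        mode="log1p_scaled",
        scale_factor=float(scale_factor),
        source_library_sizes=s,
        cell_ids=list(X.cell_ids),
        gene_ids=list(X.gene_ids),
    )


def relative_normalize(X: CellExpressionMatrix) -> NormalizedMatrix:
    """Counts divided by library size (rows of nonzero cells sum to 1)."""
    s = library_sizes(X).astype(float)
    if (s == 0).any():
        bad = [X.cell_ids[i] for i in np.flatnonzero(s == 0)[:5]]
        raise ValidationError(f"zero library size for cells: {bad}")
    return NormalizedMatrix(
        values=X.counts / s[:, None],
        mode="relative",
        scale_factor=1.0,
        source_library_sizes=s,
        cell_ids=list(X.cell_ids),
        gene_ids=list(X.gene_ids),
    )
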