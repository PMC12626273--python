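"""Correlation-bias and type-I-error diagnostics.

Normalizing counts by a per-cell scaling factor applies the same
multiplicative correction to every gene of that cell; when the scaling
factors vary strongly across cells, this shared factor induces positive
correlation between genes that are truly independent. The functions here
quantify that effect: pairwise gene correlations on normalized data, the
mean absolute deviation from a known truth, the library-size "scale
factor" (variance / mean), and the empirical rejection rate of the exact-t
Pearson independence test on null data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .data_io import CellExpressionMatrix, NormalizedMatrix, library_sizes, log_normalize


@dataclass
class BiasReport:
    variance_size_factor: float
    scale_factor: float
    mean_abs_bias: float
    pair_table: pd.DataFrame
    n_pairs: int


def pairwise_gene_correlation(
    N: NormalizedMatrix, gene_subset=None
) -> np.ndarray:
    """Pearson correlation across observations for every gene pair.

    Constant genes get correlation 0 (flagged with a warning); requires at
    least 3 observations.
    """
    V = np.asarray(N.values, dtype=float)
    if gene_subset is not None:
        idx = np.asarray(gene_subset)
        V = V[:, idx]
    if V.shape[0] < 3:
        raise ValueError("need at least 3 observations for gene correlations")
    sd = V.std(axis=0)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(V, rowvar=False)
    R = np.atleast_2d(R)
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant genes: correlations set to 0")
        R[constant, :] = 0.0
        R[:, constant] = 0.0
    np.fill_diagonal(R, 1.0)
    return np.clip((R + R.T) / 2.0, -1.0, 1.0)


def correlation_bias(estimated: np.ndarray, truth: np.ndarray) -> tuple[float, pd.DataFrame]:
    """Mean |estimated - truth| over unordered off-diagonal gene pairs."""
    est = np.asarray(estimated, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if est.shape != tru.shape:
        raise ValueError(f"shape mismatch: {est.shape} vs {tru.shape}")
    iu = np.triu_indices(est.shape[0], k=1)
    diffs = np.abs(est[iu] - tru[iu])
    table = pd.DataFrame(
        {
            "gene_i": iu[0],
            "gene_j": iu[1],
            "estimated_r": est[iu],
            "true_r": tru[iu],
        }
    )
    return float(diffs.mean()), table


def scale_factor(sizes) -> float:
    """Library-size scale factor: sample variance (n-1) divided by mean."""
    arr = np.asarray(sizes, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("mean must be positive")
    return float(arr.var(ddof=1) / mean)


def _drop_empty_cells(X: CellExpressionMatrix) -> CellExpressionMatrix:
    s = library_sizes(X)
    if (s == 0).any():
        return X.subset_cells(s > 0)
    return X


def evaluate_null_bias(
    null_counts: CellExpressionMatrix,
    truth: np.ndarray | None = None,
    variance_size_factor: float = float("nan"),
    scale: str = "log1p_scaled",
    scale_factor_value: float = 10_000.0,
) -> BiasReport:
    """Full bias report for one simulated dataset.

    Cells left with zero counts by Poisson resampling are dropped before
    normalization. ``truth`` defaults to the zero matrix (null data).
    """
    X = _drop_empty_cells(null_counts)
    if scale == "relative":
        from .data_io import relative_normalize

        N = relative_normalize(X)
    else:
        N = log_normalize(X, scale_factor=scale_factor_value)
    est = pairwise_gene_correlation(N)
    if truth is None:
        truth = np.eye(est.shape[0])
    mean_bias, table = correlation_bias(est, truth)
    return BiasReport(
        variance_size_factor=float(variance_size_factor),
        scale_factor=scale_factor(library_sizes(X)),
        mean_abs_bias=mean_bias,
        pair_table=table,
        n_pairs=len(table),
    )


def empirical_type1_error(
    null_counts: CellExpressionMatrix,
    alpha: float = 0.05,
    n_pairs: int = 1000,
    seed: int = 0,
) -> float:
    """Rejection rate of the Pearson independence test on null data.

    Log-normalizes (scale 10,000; all-zero cells dropped first), samples
    ``n_pairs`` distinct random gene pairs, and tests H0: rho = 0 per pair
    with the exact-t statistic t = r sqrt((m-2)/(1-r^2)) at level ``alpha``.
    Constant genes give r = 0 and never reject.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    X = _drop_empty_cells(null_counts)
    N = log_normalize(X)
    V = N.values
    m, p = V.shape
    if m < 3:
        raise ValueError("need at least 3 cells")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    i = rng.integers(0, p, size=n_pairs)
    j = rng.integers(0, p - 1, size=n_pairs)
    j = np.where(j >= i, j + 1, j)  # distinct pair, uniform over ordered pairs
    Vc = V - V.mean(axis=0)
    sd = Vc.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Vc[:, i] * Vc[:, j]).mean(axis=0) / (sd[i] * sd[j])
    r = np.nan_to_num(r, nan=0.0)
    r = np.clip(r, -0.999999, 0.999999)
    t = r * np.sqrt((m - 2) / (1 - r**2))
    pvals = 2 * scipy.stats.t.sf(np.abs(t), df=m - 2)
    return float((pvals < alpha).mean())
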