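"""Synthetic single-cell count generators.

Two complementary generators drive the diagnostics in this package:

* ``simulate_null`` takes a real (or fixture) count matrix, divides each
  cell by its library size, independently permutes each gene's normalized
  values across cells (destroying all co-expression while preserving each
  gene's marginal expression level), draws new library sizes from a
  truncated normal whose variance is the input variance times a
  "variance size factor" f, and resamples Poisson counts. At f = 0 all
  library sizes are equal; growing f injects progressively more library-size
  variation into data whose genes are, by construction, independent.

* ``simulate_copula`` draws per-cell latent vectors from N(0, R), pushes
  each coordinate through the standard-normal CDF and the inverse CDF of a
  per-gene Gamma(r_i, scale_i), yielding expression levels theta with
  Gamma marginals and the rank-dependence structure of R, then samples
  counts ~ Poisson(t_m * theta_im) with truncated-normal size factors t_m.
  Marginally (at unit t) the counts are negative binomial with
  NB(r_i, p_i), scale_i = (1 - p_i)/p_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats

from ._rng import substream
from .data_io import CellExpressionMatrix, library_sizes


@dataclass
class NullSimulationConfig:
    """Settings for the permutation + Poisson null generator.

    ``variance_size_factor`` (f) scales the empirical variance of the input
    library sizes; f = 0 yields constant library sizes equal to the input
    mean. ``target_mean_size`` overrides the mean of the simulated sizes
    (defaults to the input mean).
    """

    variance_size_factor: float = 0.0
    target_mean_size: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variance_size_factor < 0:
            raise ValueError("variance size factor must be >= 0")


@dataclass
class CopulaModel:
    """Gamma marginals coupled through a latent Gaussian correlation R."""

    gamma_shape: np.ndarray
    gamma_scale: np.ndarray
    latent_correlation: np.ndarray
    size_mean: float
    size_variance: float
    seed: int = 0
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gamma_shape = np.asarray(self.gamma_shape, dtype=float)
        self.gamma_scale = np.asarray(self.gamma_scale, dtype=float)
        self.latent_correlation = np.asarray(self.latent_correlation, dtype=float)
        p = self.gamma_shape.size
        if self.gamma_scale.size != p:
            raise ValueError("shape and scale vectors must have equal length")
        if (self.gamma_shape <= 0).any() or (self.gamma_scale <= 0).any():
            raise ValueError("Gamma shapes and scales must be positive")
        R = self.latent_correlation
        if R.shape != (p, p):
            raise ValueError("latent correlation must be genes x genes")
        if not np.allclose(R, R.T, atol=1e-10):
            raise ValueError("latent correlation must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-10):
            raise ValueError("latent correlation must have unit diagonal")
        if self.size_mean <= 0:
            raise ValueError("size_mean must be positive")
        if self.size_variance < 0:
            raise ValueError("size_variance must be >= 0")
        if not self.gene_ids:
            self.gene_ids = [f"gene_{i}" for i in range(p)]

    @property
    def n_genes(self) -> int:
        return self.gamma_shape.size


def sample_truncated_normal_sizes(
    mean: float, variance: float, m: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draws from Normal(mean, variance) conditioned on being >= 0.

    The parameters are those of the underlying (untruncated) normal;
    sampling is by rejection. ``variance = 0`` returns the constant mean.
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(int(seed) & 0x7FFFFFFF)
    )
    if variance == 0:
        return np.full(m, float(mean))
    sd = np.sqrt(variance)
    out = np.empty(m)
    filled = 0
    while filled < m:
        draw = rng.normal(mean, sd, size=max(m - filled, 16))
        ok = draw[draw >= 0]
        take = min(ok.size, m - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def simulate_null(
    X: CellExpressionMatrix, cfg: NullSimulationConfig
) -> CellExpressionMatrix:
    """Permutation + Poisson resampling with controlled library-size spread.

    Per-gene permutations use independent substreams keyed by gene id, so
    the output is invariant to the storage order of the gene columns.
    """
    s = library_sizes(X).astype(float)
    if (s == 0).any():
        bad = [X.cell_ids[i] for i in np.flatnonzero(s == 0)[:5]]
        raise ValueError(f"cells with zero library size: {bad}")
    y = X.counts / s[:, None]
    mean_size = cfg.target_mean_size if cfg.target_mean_size is not None else s.mean()
    var_size = s.var(ddof=1) * cfg.variance_size_factor
    rng = substream(cfg.seed, "null-sizes")
    s_new = sample_truncated_normal_sizes(mean_size, var_size, X.n_cells, rng)
    counts = np.empty_like(X.counts)
    for j, gid in enumerate(X.gene_ids):
        rng_g = substream(cfg.seed, f"null-gene:{gid}")
        counts[:, j] = rng_g.poisson(s_new * rng_g.permutation(y[:, j]))
    return CellExpressionMatrix(
        counts=counts.astype(np.int64),
        cell_ids=list(X.cell_ids),
        gene_ids=list(X.gene_ids),
        cell_type=X.cell_type,
        group=X.group,
    )


def estimate_gamma_params(X: CellExpressionMatrix) -> pd.DataFrame:
    """Method-of-moments Gamma (negative-binomial mixture) fits per gene.

    Under a Poisson-Gamma compound with unit size factor, a gene with mean
    mu and variance v > mu has p = mu/v, r = mu^2/(v - mu) and scale
    (v - mu)/mu. Genes with v <= mu or mu = 0 are flagged non-estimable.
    Returns a DataFrame indexed by gene id with columns r, p, scale,
    estimable.
    """
    if X.n_cells < 2:
        raise ValueError("need at least 2 cells to estimate moments")
    mu = X.counts.mean(axis=0)
    v = X.counts.var(axis=0, ddof=1)
    estimable = (mu > 0) & (v > mu)
    r = np.full(X.n_genes, np.nan)
    p = np.full(X.n_genes, np.nan)
    scale = np.full(X.n_genes, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        r[estimable] = mu[estimable] ** 2 / (v[estimable] - mu[estimable])
        p[estimable] = mu[estimable] / v[estimable]
        scale[estimable] = (v[estimable] - mu[estimable]) / mu[estimable]
    if not estimable.any():
        raise ValueError("no gene has variance exceeding its mean")
    return pd.DataFrame(
        {"r": r, "p": p, "scale": scale, "estimable": estimable},
        index=pd.Index(X.gene_ids, name="gene_id"),
    )


def simulate_copula(
    model: CopulaModel, m_cells: int, return_latent: bool = False
):
    """Sample counts from the Gamma-Poisson Gaussian-copula model.

    Returns the count matrix and the latent expression-level matrix theta
    (cells x genes), which carries the predefined dependence structure;
    with ``return_latent`` the latent Gaussian draws are appended.
    """
    R = model.latent_correlation
    eigvals = np.linalg.eigvalsh(R)
    if eigvals[0] < -1e-8:
        raise ValueError(
            f"latent correlation is not PSD (smallest eigenvalue {eigvals[0]:.3e})"
        )
    rng = np.random.default_rng(int(model.seed) & 0x7FFFFFFF)
    # Cholesky on a jittered copy tolerates tiny negative eigenvalues
    L = np.linalg.cholesky(R + max(0.0, -eigvals[0] + 1e-12) * np.eye(R.shape[0]))
    z = rng.standard_normal((m_cells, model.n_genes))
    v = z @ L.T
    u = scipy.stats.norm.cdf(v)
    # clip away exact 0/1 so the Gamma quantile stays finite
    u = np.clip(u, 1e-12, 1 - 1e-12)
    theta = scipy.stats.gamma.ppf(u, a=model.gamma_shape, scale=model.gamma_scale)
    t = sample_truncated_normal_sizes(
        model.size_mean, model.size_variance, m_cells, rng
    )
    counts = rng.poisson(t[:, None] * theta)
    X = CellExpressionMatrix(
        counts=counts.astype(np.int64),
        cell_ids=[f"cell_{i}" for i in range(m_cells)],
        gene_ids=list(model.gene_ids),
    )
    if return_latent:
        return X, theta, v
    return X, theta


def block_correlation(
    block_sizes: list[int], rho_within: float, rho_between: float = 0.0
) -> np.ndarray:
    """Block-diagonal exchangeable correlation matrix with unit diagonal."""
    p = int(sum(block_sizes))
    R = np.full((p, p), rho_between, dtype=float)
    start = 0
    for b in block_sizes:
        R[start : start + b, start : start + b] = rho_within
        start += b
    np.fill_diagonal(R, 1.0)
    return R


def make_fixture(
    n_cells: int = 2000,
    n_genes: int = 300,
    mean_library_size: float = 2000.0,
    sigma_log: float = 0.6,
    gene_mean_range: tuple[float, float] = (0.05, 5.0),
    dispersion: float = 1.0,
    seed: int = 0,
    n_cell_types: int = 1,
    block_sizes: Optional[list[int]] = None,
    rho_within: float = 0.0,
) -> CellExpressionMatrix:
    """A reproducible synthetic dataset standing in for real droplet data.

    Per-gene relative expression levels are Gamma distributed (shape =
    ``dispersion``, per-gene mean log-uniform over ``gene_mean_range``);
    library sizes are log-normal with median ``mean_library_size`` and
    log-scale sigma ``sigma_log`` (roughly the ten-fold spread typical of
    droplet data at sigma 0.6-0.8); counts are Poisson. With
    ``block_sizes``/``rho_within`` set, a Gaussian copula couples genes in
    blocks; cells may be tagged with ``n_cell_types`` round-robin labels.
    """
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    lo, hi = gene_mean_range
    gene_means = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
    gene_means /= gene_means.sum()  # relative expression fractions
    shape = np.full(n_genes, float(dispersion))
    scale = gene_means / shape
    sizes = np.exp(rng.normal(np.log(mean_library_size), sigma_log, size=n_cells))
    if block_sizes is not None and rho_within > 0:
        pad = n_genes - sum(block_sizes)
        if pad < 0:
            raise ValueError("block sizes exceed n_genes")
        R = block_correlation(list(block_sizes) + [1] * pad, rho_within)
        eig0 = np.linalg.eigvalsh(R)[0]
        L = np.linalg.cholesky(R + max(0.0, -eig0 + 1e-12) * np.eye(n_genes))
        z = rng.standard_normal((n_cells, n_genes))
        u = np.clip(scipy.stats.norm.cdf(z @ L.T), 1e-12, 1 - 1e-12)
        theta = scipy.stats.gamma.ppf(u, a=shape, scale=scale)
    else:
        theta = rng.gamma(shape, scale, size=(n_cells, n_genes))
    counts = rng.poisson(sizes[:, None] * theta).astype(np.int64)
    cell_type = None
    if n_cell_types > 1:
        cell_type = pd.Series(
            [f"type_{i % n_cell_types}" for i in range(n_cells)], name="cell_type"
        )
    return CellExpressionMatrix(
        counts=counts,
        cell_ids=[f"cell_{i}" for i in range(n_cells)],
        gene_ids=[f"gene_{i}" for i in range(n_genes)],
        cell_type=cell_type,
    )


def make_planted_module_model(
    n_blocks: int = 3,
    block_size: int = 40,
    rho_within: float = 0.6,
    gene_mean: float = 2.0,
    dispersion: float = 2.0,
    size_mean: float = 1.0,
    size_cv: float = 0.5,
    seed: int = 0,
) -> tuple[CopulaModel, np.ndarray]:
    """Copula model with planted co-expression blocks, plus the planted
    block labels (0..n_blocks-1 per gene).

    All genes share a Gamma(dispersion, gene_mean/dispersion) marginal;
    genes within a block share latent correlation ``rho_within``, blocks
    are mutually uncorrelated. Size factors t_m are truncated normal with
    the given mean and coefficient of variation.
    """
    p = n_blocks * block_size
    R = block_correlation([block_size] * n_blocks, rho_within)
    model = CopulaModel(
        gamma_shape=np.full(p, float(dispersion)),
        gamma_scale=np.full(p, gene_mean / dispersion),
        latent_correlation=R,
        size_mean=float(size_mean),
        size_variance=float((size_cv * size_mean) ** 2),
        seed=int(seed),
    )
    labels = np.repeat(np.arange(n_blocks), block_size)
    return model, labels
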