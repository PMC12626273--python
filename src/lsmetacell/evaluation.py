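"""Quantitative evaluation of co-expression quality.

Three ingredients: overlap of the top correlated gene pairs with a
protein-protein interaction (PPI) reference, an exact paired Wilcoxon
signed-rank test for comparing per-cell-type counts between methods, and a
permutation Z-summary statistic for module preservation in an independent
dataset (median of three density-based and three connectivity-based
Z-scores).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .bias_eval import pairwise_gene_correlation
from .coexpression import ModuleSet, module_eigengene, signed_similarity
from .data_io import NormalizedMatrix


# ---------------------------------------------------------------- PPI


@dataclass
class PPIReference:
    """An undirected PPI edge set with optional confidence scores."""

    edges: set[tuple[str, str]]
    scores: dict[tuple[str, str], int] = field(default_factory=dict)
    score_threshold: int = 400

    def __post_init__(self) -> None:
        canon = set()
        for a, b in self.edges:
            if a == b:
                continue
            pair = (a, b) if a <= b else (b, a)
            if pair in self.scores and self.scores[pair] < self.score_threshold:
                continue
            canon.add(pair)
        self.edges = canon

    def __contains__(self, pair) -> bool:
        a, b = pair
        return ((a, b) if a <= b else (b, a)) in self.edges


def read_ppi_edges(path, score_threshold: int = 400) -> PPIReference:
    """Read a STRING-style TSV (protein1, protein2, combined_score) or a
    minimal two-column edge list."""
    df = pd.read_csv(path, sep=r"\s+|\t", engine="python")
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError("PPI file needs at least two columns")
    a_col, b_col = cols[0], cols[1]
    scores = {}
    edges = set()
    score_col = "combined_score" if "combined_score" in cols else None
    for _, row in df.iterrows():
        a, b = str(row[a_col]), str(row[b_col])
        pair = (a, b) if a <= b else (b, a)
        edges.add(pair)
        if score_col is not None:
            scores[pair] = int(row[score_col])
    return PPIReference(edges=edges, scores=scores, score_threshold=score_threshold)


def top_correlated_pairs(
    corr: np.ndarray,
    gene_ids: Sequence[str],
    k: int = 10_000,
    absolute: bool = False,
) -> list[tuple[str, str]]:
    """The ``k`` strongest gene pairs by signed correlation, descending.

    Ties are broken by canonical (sorted) pair id; with ``absolute`` the
    ranking uses |correlation| instead. Returns all pairs if fewer than k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    corr = np.asarray(corr, dtype=float)
    iu = np.triu_indices(corr.shape[0], k=1)
    vals = corr[iu]
    if absolute:
        vals = np.abs(vals)
    pairs = [
        (min(gene_ids[i], gene_ids[j]), max(gene_ids[i], gene_ids[j]))
        for i, j in zip(iu[0], iu[1])
    ]
    order = sorted(range(len(pairs)), key=lambda t: (-vals[t], pairs[t]))
    return [pairs[t] for t in order[:k]]


def ppi_overlap_count(pairs: Sequence[tuple[str, str]], ppi: PPIReference) -> int:
    """Number of gene pairs present in the thresholded PPI edge set."""
    if len(pairs) == 0:
        warnings.warn("empty pair list; overlap is 0")
        return 0
    return sum(1 for p in pairs if p in ppi)


# ------------------------------------------------- exact paired Wilcoxon


def paired_wilcoxon_exact(
    x: Sequence[float],
    y: Sequence[float],
    alternative: Literal["greater", "less", "two_sided"] = "greater",
) -> float:
    """Exact paired Wilcoxon signed-rank p-value with midrank tie handling.

    Zero differences are dropped; |differences| receive midranks; the
    signed-rank statistic W+ sums the ranks of positive differences. For
    n_eff <= 25 the null distribution is computed exactly over all 2^n
    equiprobable sign assignments (via a generating-function convolution,
    which enumerates the same distribution); beyond that a normal
    approximation with tie-corrected variance is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("no nonzero pairs")
    ranks = scipy.stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        # doubled midranks are integers; convolve the sign generating function
        r2 = np.rint(2 * ranks).astype(np.int64)
        total = int(r2.sum())
        counts = np.zeros(total + 1, dtype=np.float64)
        counts[0] = 1.0
        upper = 0
        for r in r2:
            counts[r : upper + r + 1] += counts[0 : upper + 1]
            upper += int(r)
        counts /= 2.0**n
        w2 = int(round(2 * w_plus))
        p_greater = float(counts[w2:].sum())
        p_less = float(counts[: w2 + 1].sum())
    else:
        mean = n * (n + 1) / 4.0
        sd = np.sqrt((ranks**2).sum() / 4.0)
        z = (w_plus - mean) / sd
        p_greater = float(scipy.stats.norm.sf(z))
        p_less = float(scipy.stats.norm.cdf(z))
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    if alternative == "two_sided":
        return float(min(1.0, 2.0 * min(p_greater, p_less)))
    raise ValueError(f"unknown alternative {alternative!r}")


# --------------------------------------------- packaged comparison table


def load_ppi_enrichment_table() -> pd.DataFrame:
    """The packaged per-cell-type PPI enrichment counts (methods as
    columns, cell types as rows) used by the method-comparison test."""
    with resources.files("lsmetacell.data").joinpath(
        "ppi_enrichment_counts.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", index_col=0)


def compare_methods_wilcoxon(
    table: Optional[pd.DataFrame] = None,
    reference: str = "LSMetacell",
    alternative: Literal["greater", "less", "two_sided"] = "greater",
) -> pd.Series:
    """One-sided exact paired Wilcoxon p-value of the reference method
    against every other column of a (cell types x methods) count table."""
    if table is None:
        table = load_ppi_enrichment_table()
    if reference not in table.columns:
        raise ValueError(f"reference column {reference!r} not in table")
    ref = table[reference].to_numpy(dtype=float)
    out = {}
    for col in table.columns:
        if col == reference:
            continue
        out[col] = paired_wilcoxon_exact(
            ref, table[col].to_numpy(dtype=float), alternative=alternative
        )
    return pd.Series(out, name=f"p_{alternative}")


# ----------------------------------------------- module preservation


@dataclass
class PreservationResult:
    table: pd.DataFrame  # per module: Zsummary, Zdensity, Zconnectivity, size
    n_permutations: int
    seed: int


def _module_stats(
    ref_corr: np.ndarray,
    test_corr: np.ndarray,
    test_values: np.ndarray,
    ref_values: np.ndarray,
    idx: np.ndarray,
) -> np.ndarray:
    """Six preservation statistics for one gene set (density triple, then
    connectivity triple)."""
    tc = test_corr[np.ix_(idx, idx)]
    rc = ref_corr[np.ix_(idx, idx)]
    q = idx.size
    iu = np.triu_indices(q, k=1)
    # density: mean |cor|, mean signed adjacency, test eigengene variance
    d1 = float(np.abs(tc[iu]).mean())
    d2 = float(signed_similarity(tc)[iu].mean())
    d3 = _prop_var_explained(test_values[:, idx])
    # connectivity: cor of intramodular connectivities, of kME, of cor vectors
    k_ref = rc.sum(axis=1) - 1.0
    k_test = tc.sum(axis=1) - 1.0
    c1 = _safe_cor(k_ref, k_test)
    kme_ref = _kme_to_pc1(ref_values[:, idx])
    kme_test = _kme_to_pc1(test_values[:, idx])
    c2 = _safe_cor(kme_ref, kme_test)
    c3 = _safe_cor(rc[iu], tc[iu])
    return np.array([d1, d2, d3, c1, c2, c3])


def _prop_var_explained(V: np.ndarray) -> float:
    sd = V.std(axis=0, ddof=1)
    keep = sd > 0
    if keep.sum() < 2:
        return float("nan")
    Z = (V[:, keep] - V[:, keep].mean(axis=0)) / sd[keep]
    s = np.linalg.svd(Z, compute_uv=False)
    return float(s[0] ** 2 / (s**2).sum())


def _kme_to_pc1(V: np.ndarray) -> np.ndarray:
    sd = V.std(axis=0, ddof=1)
    keep = sd > 0
    if keep.sum() < 2:
        return np.full(V.shape[1], np.nan)
    Z = (V[:, keep] - V[:, keep].mean(axis=0)) / sd[keep]
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    e = U[:, 0]
    if np.mean([_safe_cor(e, Z[:, j]) for j in range(Z.shape[1])]) < 0:
        e = -e
    out = np.zeros(V.shape[1])
    out[keep] = [_safe_cor(e, (V[:, k] - V[:, k].mean())) for k in np.flatnonzero(keep)]
    return out


def _safe_cor(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


_STAT_NAMES = [
    "density_mean_abs_cor",
    "density_mean_adjacency",
    "density_var_explained",
    "connectivity_cor_k",
    "connectivity_cor_kme",
    "connectivity_cor_corvec",
]


def module_preservation_zsummary(
    reference: NormalizedMatrix,
    test: NormalizedMatrix,
    modules: ModuleSet,
    n_permutations: int = 100,
    seed: int = 0,
) -> PreservationResult:
    """Permutation Z-summary of module preservation.

    For each non-grey module of size >= 3, six observed statistics (three
    density-based, three connectivity-based) are compared with their null
    distribution over ``n_permutations`` random gene sets of equal size;
    Z = (observed - null mean)/null sd per statistic, Zdensity and
    Zconnectivity are the medians of their triples (statistics with zero
    null spread are excluded with a flag), and Zsummary is the median of
    the two.
    """
    # canonical (sorted) order so results do not depend on storage order
    shared = sorted(set(reference.gene_ids) & set(test.gene_ids))
    if len(shared) < 3:
        raise ValueError("reference and test share fewer than 3 genes")
    ref_pos = {g: i for i, g in enumerate(reference.gene_ids)}
    test_pos = {g: i for i, g in enumerate(test.gene_ids)}
    ref_idx = np.array([ref_pos[g] for g in shared])
    test_idx = np.array([test_pos[g] for g in shared])
    ref_vals = np.asarray(reference.values, dtype=float)[:, ref_idx]
    test_vals = np.asarray(test.values, dtype=float)[:, test_idx]
    ref_corr = _corr_or_zero(ref_vals)
    test_corr = _corr_or_zero(test_vals)
    shared_pos = {g: i for i, g in enumerate(shared)}

    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    rows = []
    excluded_flags = []
    for mod in sorted(modules.module_names):
        genes = [g for g in modules.genes_in(mod) if g in shared_pos]
        q = len(genes)
        if q < 3:
            warnings.warn(f"module {mod!r} has fewer than 3 shared genes; skipped")
            continue
        idx = np.array([shared_pos[g] for g in genes])
        obs = _module_stats(ref_corr, test_corr, test_vals, ref_vals, idx)
        null = np.empty((n_permutations, 6))
        for b in range(n_permutations):
            perm_idx = rng.choice(len(shared), size=q, replace=False)
            null[b] = _module_stats(ref_corr, test_corr, test_vals, ref_vals, perm_idx)
        null_mean = np.nanmean(null, axis=0)
        null_sd = np.nanstd(null, axis=0, ddof=1)
        z = np.full(6, np.nan)
        # a null spread at floating-point noise level is degenerate
        sd_floor = 1e-8 * np.maximum(1.0, np.abs(null_mean))
        ok = (null_sd > sd_floor) & ~np.isnan(obs)
        z[ok] = (obs[ok] - null_mean[ok]) / null_sd[ok]
        flagged = [
            _STAT_NAMES[i]
            for i in range(6)
            if not ok[i]
        ]
        z_density = _nanmedian(z[:3])
        z_connectivity = _nanmedian(z[3:])
        z_summary = _nanmedian(np.array([z_density, z_connectivity]))
        rows.append(
            {
                "module": mod,
                "size": q,
                "Zsummary": z_summary,
                "Zdensity": z_density,
                "Zconnectivity": z_connectivity,
                "excluded_stats": ";".join(flagged),
            }
        )
        excluded_flags.extend(flagged)
    table = pd.DataFrame(rows).set_index("module") if rows else pd.DataFrame()
    return PreservationResult(table=table, n_permutations=n_permutations, seed=seed)


def _nanmedian(a: np.ndarray) -> float:
    if np.all(np.isnan(a)):
        return float("nan")
    return float(np.nanmedian(a))


def _corr_or_zero(V: np.ndarray) -> np.ndarray:
    sd = V.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(V, rowvar=False)
    R = np.atleast_2d(R)
    const = sd == 0
    if const.any():
        R[const, :] = 0.0
        R[:, const] = 0.0
    np.fill_diagonal(R, 1.0)
    return np.clip((R + R.T) / 2.0, -1.0, 1.0)


def random_set_zsummaries(
    reference: NormalizedMatrix,
    test: NormalizedMatrix,
    set_size: int,
    n_sets: int = 30,
    n_permutations: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Zsummary values for random gene sets (null calibration)."""
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    genes = list(reference.gene_ids)
    zs = []
    for b in range(n_sets):
        chosen = list(rng.choice(genes, size=set_size, replace=False))
        labels = pd.Series(
            ["random" if g in set(chosen) else "grey" for g in genes],
            index=pd.Index(genes, name="gene_id"),
        )
        mods = ModuleSet(labels=labels, min_module_size=3)
        res = module_preservation_zsummary(
            reference, test, mods, n_permutations=n_permutations,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        zs.append(float(res.table.loc["random", "Zsummary"]))
    return np.array(zs)
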