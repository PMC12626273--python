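"""Weighted gene co-expression network construction on metacell profiles.

The pipeline mirrors the standard WGCNA construction: signed similarity
a_ij = (1 + cor(x_i, x_j))/2, soft-thresholding power beta chosen by the
scale-free topology fit, adjacency a_ij^beta, topological overlap (TOM),
average-linkage hierarchical clustering on 1 - TOM with a static cut, and
module eigengenes / kME summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance
import scipy.stats

from .bias_eval import pairwise_gene_correlation
from .data_io import NormalizedMatrix

#: WGCNA-style module colour sequence, assigned largest module first.
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]

GREY = "grey"


@dataclass
class CoexpressionNetwork:
    signed_similarity: np.ndarray
    power: float
    adjacency: np.ndarray
    tom: np.ndarray
    gene_ids: list[str]
    power_diagnostics: Optional[pd.DataFrame] = None


@dataclass
class ModuleSet:
    """Gene-to-module labels plus eigengene/kME summaries."""

    labels: pd.Series  # gene_id -> module label; "grey" = unassigned
    min_module_size: int
    eigengenes: Optional[pd.DataFrame] = None  # observations x modules
    kme: Optional[pd.DataFrame] = None  # genes x modules
    var_explained: dict[str, float] = field(default_factory=dict)

    @property
    def module_names(self) -> list[str]:
        return [m for m in self.labels.unique() if m != GREY]

    def genes_in(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


def signed_similarity(corr: np.ndarray) -> np.ndarray:
    """Map a correlation matrix elementwise to [0, 1] via (1 + cor)/2."""
    corr = np.asarray(corr, dtype=float)
    if (corr < -1 - 1e-12).any() or (corr > 1 + 1e-12).any():
        raise ValueError("correlations must lie in [-1, 1]")
    return (1.0 + np.clip(corr, -1.0, 1.0)) / 2.0


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """Scale-free topology fit index: signed R^2 of log10 p(k) on
    log10 mean(k) over equal-width connectivity bins (empty bins dropped).

    Scale-free topology requires p(k) to DECREASE with k, so a positive
    regression slope negates the index (the WGCNA fit-index convention);
    such powers can never be selected."""
    k = np.asarray(k, dtype=float)
    if k.max() == k.min():
        return float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_freq, log_k = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0 or members.mean() <= 0:
            continue
        log_freq.append(np.log10(members.size / k.size))
        log_k.append(np.log10(members.mean()))
    if len(log_k) < 3 or len(set(log_k)) < 2:
        return float("nan")
    slope, intercept, r, *_ = scipy.stats.linregress(log_k, log_freq)
    return float(-np.sign(slope) * r**2)


def _recommended_signed_power(n_observations: int) -> int:
    # sample-size-based defaults for signed networks (WGCNA FAQ convention)
    if n_observations < 20:
        return 18
    if n_observations < 30:
        return 16
    if n_observations < 40:
        return 14
    return 12


def pick_soft_threshold(
    sim: np.ndarray,
    powers: Sequence[int] = tuple(range(1, 21)),
    r2_target: float = 0.8,
    n_observations: Optional[int] = None,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-thresholding power by the scale-free topology fit.

    Returns the smallest power whose fit R^2 reaches ``r2_target``. If no
    power fits, the fallback (with a warning) is the sample-size-based
    recommended power for signed networks when ``n_observations`` is
    given — the convention used in WGCNA practice, since the best of a set
    of poor fits is typically a degenerate low power — and otherwise the
    power with the best fit. The diagnostics table reports R^2 and
    mean/median connectivity per power.
    """
    if len(powers) == 0:
        raise ValueError("powers must be non-empty")
    sim = np.asarray(sim, dtype=float)
    rows = []
    for beta in powers:
        adj = sim**beta
        np.fill_diagonal(adj, 0.0)
        k = adj.sum(axis=1)
        rows.append(
            {
                "power": beta,
                "r2": _scale_free_r2(k),
                "mean_k": float(k.mean()),
                "median_k": float(np.median(k)),
            }
        )
    diag = pd.DataFrame(rows)
    ok = diag[diag["r2"] >= r2_target]
    if len(ok):
        beta = int(ok.iloc[0]["power"])
    elif n_observations is not None:
        rec = _recommended_signed_power(n_observations)
        # stay within the candidate list
        beta = int(min(powers, key=lambda b: abs(b - rec)))
        warnings.warn(
            f"no power reached R^2 >= {r2_target}; using recommended signed "
            f"power beta={beta} for {n_observations} observations"
        )
    else:
        valid = diag.dropna(subset=["r2"])
        if len(valid) == 0:
            warnings.warn("scale-free fit undefined for every power; using smallest")
            beta = int(diag.iloc[0]["power"])
        else:
            beta = int(valid.loc[valid["r2"].idxmax(), "power"])
            warnings.warn(
                f"no power reached R^2 >= {r2_target}; using best fit beta={beta}"
            )
    return beta, diag


def tom(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j (the sum excluding u in {i, j}), with unit diagonal.
    """
    A = np.asarray(adjacency, dtype=float).copy()
    if (A < -1e-12).any() or (A > 1 + 1e-12).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    shared = A @ A  # with zero diagonal, (A^2)_ij = sum_{u != i,j} a_iu a_uj
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - A
    T = (shared + A) / denom
    np.fill_diagonal(T, 1.0)
    return np.clip((T + T.T) / 2.0, 0.0, 1.0)


def detect_modules(
    tom_matrix: np.ndarray,
    gene_ids: Sequence[str],
    min_module_size: int = 30,
    cut_height: float = 0.99,
) -> ModuleSet:
    """Average-linkage clustering on 1 - TOM with a static tree cut.

    ``cut_height`` is the fraction of the joining-height range (5th
    percentile to maximum of the merge heights) at which the tree is cut,
    following the dynamic-tree-cut convention; clusters smaller than
    ``min_module_size`` are set to grey. Module labels are colour names
    assigned largest module first.
    """
    T = np.asarray(tom_matrix, dtype=float)
    p = T.shape[0]
    gene_ids = [str(g) for g in gene_ids]
    if p < min_module_size:
        warnings.warn("fewer genes than min_module_size; all grey")
        return ModuleSet(
            labels=pd.Series(GREY, index=pd.Index(gene_ids, name="gene_id")),
            min_module_size=min_module_size,
        )
    D = 1.0 - T
    np.fill_diagonal(D, 0.0)
    condensed = scipy.spatial.distance.squareform(D, checks=False)
    Z = sch.linkage(condensed, method="average")
    heights = Z[:, 2]
    h_lo = np.percentile(heights, 5)
    h_hi = heights.max()
    if h_hi - h_lo <= 1e-12:
        # flat dendrogram: every pair equally (dis)similar, no structure
        warnings.warn("all merge heights equal; no modules detected")
        return ModuleSet(
            labels=pd.Series(GREY, index=pd.Index(gene_ids, name="gene_id")),
            min_module_size=min_module_size,
        )
    cut = h_lo + cut_height * (h_hi - h_lo)
    raw = sch.fcluster(Z, t=cut, criterion="distance")
    labels = np.full(p, GREY, dtype=object)
    sizes = pd.Series(raw).value_counts()
    kept = [c for c in sizes.index if sizes[c] >= min_module_size]
    # largest first; ties by cluster id for determinism
    kept.sort(key=lambda c: (-sizes[c], c))
    for rank, c in enumerate(kept):
        color = (
            MODULE_COLORS[rank]
            if rank < len(MODULE_COLORS)
            else f"module_{rank}"
        )
        labels[raw == c] = color
    return ModuleSet(
        labels=pd.Series(labels, index=pd.Index(gene_ids, name="gene_id")),
        min_module_size=min_module_size,
    )


def module_eigengene(
    N: NormalizedMatrix, member_genes: Sequence[str]
) -> tuple[np.ndarray, float]:
    """First principal component of the module's standardized expression.

    Genes are z-scored across observations (constant genes dropped with a
    warning); the PC-1 score vector is rescaled to unit sample variance and
    its sign chosen so the mean correlation with the member genes is
    positive. Also returns the proportion of variance explained.
    """
    gene_pos = {g: i for i, g in enumerate(N.gene_ids)}
    idx = [gene_pos[g] for g in member_genes]
    if len(idx) < 2:
        raise ValueError("module needs at least 2 member genes")
    V = np.asarray(N.values, dtype=float)[:, idx]
    if V.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    sd = V.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} constant genes dropped from module")
        V = V[:, keep]
        sd = sd[keep]
        if V.shape[1] < 2:
            raise ValueError("fewer than 2 non-constant member genes")
    Z = (V - V.mean(axis=0)) / sd
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, 0] * S[0]
    var_explained = float(S[0] ** 2 / (S**2).sum())
    scores = scores / scores.std(ddof=1)
    mean_cor = np.mean(
        [np.corrcoef(scores, Z[:, j])[0, 1] for j in range(Z.shape[1])]
    )
    if mean_cor < 0:
        scores = -scores
    return scores, var_explained


def module_eigengenes(N: NormalizedMatrix, modules: ModuleSet) -> ModuleSet:
    """Compute eigengenes, kME and variance explained for every non-grey
    module; returns a completed copy of ``modules``."""
    eig = {}
    var_exp = {}
    for mod in modules.module_names:
        scores, ve = module_eigengene(N, modules.genes_in(mod))
        eig[mod] = scores
        var_exp[mod] = ve
    eig_df = pd.DataFrame(eig, index=pd.Index(N.cell_ids, name="observation"))
    kme_df = kme(N, eig_df)
    return ModuleSet(
        labels=modules.labels,
        min_module_size=modules.min_module_size,
        eigengenes=eig_df,
        kme=kme_df,
        var_explained=var_exp,
    )


def kme(N: NormalizedMatrix, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """Module membership: Pearson correlation of each gene with each
    eigengene (constant genes get 0)."""
    V = np.asarray(N.values, dtype=float)
    E = eigengenes.to_numpy(dtype=float)
    if V.shape[0] != E.shape[0]:
        raise ValueError("observation counts differ between genes and eigengenes")
    Vc = V - V.mean(axis=0)
    Ec = E - E.mean(axis=0)
    v_sd = Vc.std(axis=0)
    e_sd = Ec.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        K = (Vc.T @ Ec) / V.shape[0] / np.outer(v_sd, e_sd)
    K = np.nan_to_num(K, nan=0.0)
    return pd.DataFrame(
        np.clip(K, -1.0, 1.0),
        index=pd.Index(N.gene_ids, name="gene_id"),
        columns=eigengenes.columns,
    )


def module_trait_correlation(
    eigengenes: pd.DataFrame, traits: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r and exact-t two-sided p for every (module, trait) pair.

    Missing trait values are pairwise-deleted; constant traits (or fewer
    than 4 complete observations) yield NaN with ``valid = False``.
    """
    rows = []
    for mod in eigengenes.columns:
        e = eigengenes[mod].to_numpy(dtype=float)
        for trait in traits.columns:
            t_vals = traits[trait].to_numpy(dtype=float)
            ok = ~np.isnan(t_vals) & ~np.isnan(e)
            m = int(ok.sum())
            if m < 4 or np.std(t_vals[ok]) == 0 or np.std(e[ok]) == 0:
                rows.append(
                    {"module": mod, "trait": trait, "r": np.nan, "p": np.nan,
                     "n": m, "valid": False}
                )
                continue
            r = float(np.corrcoef(e[ok], t_vals[ok])[0, 1])
            r_c = min(max(r, -0.999999), 0.999999)
            t_stat = r_c * np.sqrt((m - 2) / (1 - r_c**2))
            p = float(2 * scipy.stats.t.sf(abs(t_stat), df=m - 2))
            rows.append(
                {"module": mod, "trait": trait, "r": r, "p": p, "n": m, "valid": True}
            )
    return pd.DataFrame(rows)


def build_network(
    N: NormalizedMatrix,
    powers: Sequence[int] = tuple(range(1, 21)),
    r2_target: float = 0.8,
    power: Optional[int] = None,
) -> CoexpressionNetwork:
    """Correlation -> signed similarity -> soft threshold -> TOM."""
    corr = pairwise_gene_correlation(N)
    sim = signed_similarity(corr)
    diag = None
    if power is None:
        power, diag = pick_soft_threshold(
            sim, powers=powers, r2_target=r2_target, n_observations=N.n_obs
        )
    adjacency = sim**power
    np.fill_diagonal(adjacency, 1.0)
    T = tom(adjacency)
    return CoexpressionNetwork(
        signed_similarity=sim,
        power=power,
        adjacency=adjacency,
        tom=T,
        gene_ids=list(N.gene_ids),
        power_diagnostics=diag,
    )
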