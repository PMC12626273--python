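"""Library-size-stabilized metacell construction.

Single-cell UMI matrices suffer from large cell-to-cell library-size
variation; when similar cells are pooled into metacells without regard to
that variation, the per-metacell scaling factors applied at normalization
time remain heterogeneous and inflate gene-gene correlations. The
aggregation procedure here grows each metacell from the smallest-library
unassigned cell, adds candidates drawn with probability proportional to
their mean similarity to the current members, and accepts a candidate only
if it moves the metacell's cumulative library size closer to the global
target mean library size mu_L = (total library size) / n.

A "primary" ablation variant keeps the seeding and similarity-weighted
sampling but drops the library-size acceptance rule, stopping each metacell
at a fixed member count instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from ._rng import substream
from .data_io import CellExpressionMatrix, library_sizes
from .similarity import CellSimilarityMatrix


@dataclass
class MetacellResult:
    """A cell-to-metacell partition with the pooled counts."""

    assignment: dict[str, str]
    metacell_ids: list[str]
    metacell_counts: np.ndarray
    metacell_library_sizes: np.ndarray
    gene_ids: list[str]
    target_mu_L: float
    n_requested: int
    seed: int

    @property
    def n_metacells(self) -> int:
        return len(self.metacell_ids)


@dataclass
class GroupAllocation:
    """Per-group metacell targets proportional to library-size share."""

    targets: dict[str, int]
    shares: dict[str, float]


def target_mean_library_size(X: CellExpressionMatrix, n: int) -> float:
    """Global target mean metacell library size: total library size / n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > X.n_cells:
        raise ValueError(f"n={n} exceeds number of cells ({X.n_cells})")
    total = int(library_sizes(X).sum())
    if total <= 0:
        raise ValueError("total library size must be positive")
    return total / n


def _check_alignment(X: CellExpressionMatrix, P: CellSimilarityMatrix) -> np.ndarray:
    """Return P reordered to X's cell order; error on id mismatch."""
    if set(P.cell_ids) != set(X.cell_ids):
        raise ValueError("similarity matrix does not cover exactly the cells of X")
    if P.cell_ids == X.cell_ids:
        return P.values
    pos = {c: i for i, c in enumerate(P.cell_ids)}
    order = np.array([pos[c] for c in X.cell_ids])
    return P.values[np.ix_(order, order)]


def _seed_order(s: np.ndarray, cell_ids: list[str]) -> np.ndarray:
    # smallest library size first, ties by lexicographic cell id
    return np.lexsort((np.array(cell_ids), s))


def build_metacells(
    X: CellExpressionMatrix,
    n: int,
    P: CellSimilarityMatrix,
    seed: int,
    id_prefix: str = "mc",
) -> MetacellResult:
    """Construct library-size-stabilized metacells.

    Each metacell is seeded with the unassigned cell of smallest library
    size and grown by similarity-weighted sampling; a sampled candidate is
    accepted only if adding it does not move the cumulative library size
    away from the target mu_L (ties accepted). A candidate rejected for the
    current metacell is excluded from that metacell's pool but re-eligible
    for later ones. The realized number of metacells is governed by mu_L
    and may differ slightly from ``n``.
    """
    sims = _check_alignment(X, P)
    mu_L = target_mean_library_size(X, n)
    s = library_sizes(X).astype(float)
    m = X.n_cells
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)

    order = _seed_order(s, X.cell_ids)
    unassigned = np.ones(m, dtype=bool)
    labels = np.full(m, -1, dtype=int)
    next_seed_ptr = 0
    k = 0
    while unassigned.any():
        while not unassigned[order[next_seed_ptr]]:
            next_seed_ptr += 1
        seed_cell = order[next_seed_ptr]
        members = [seed_cell]
        unassigned[seed_cell] = False
        labels[seed_cell] = k
        S_curr = s[seed_cell]
        sim_sum = sims[seed_cell].copy()
        rejected = np.zeros(m, dtype=bool)
        while S_curr < mu_L:
            pool = np.flatnonzero(unassigned & ~rejected)
            if pool.size == 0:
                break
            w = np.clip(sim_sum[pool] / len(members), 0.0, None)
            total_w = w.sum()
            if total_w <= 0:
                p = np.full(pool.size, 1.0 / pool.size)
            else:
                p = w / total_w
            cand = int(rng.choice(pool, p=p))
            S_temp = S_curr + s[cand]
            if abs(S_temp - mu_L) <= abs(S_curr - mu_L):
                # acceptance is a contraction toward mu_L by construction
                members.append(cand)
                labels[cand] = k
                unassigned[cand] = False
                S_curr = S_temp
                sim_sum += sims[cand]
            else:
                rejected[cand] = True
        k += 1

    result = _finalize(X, labels, k, mu_L, n, seed, id_prefix)
    small = result.metacell_library_sizes < mu_L / 2
    if small.any():
        warnings.warn(
            f"{int(small.sum())} metacell(s) with library size below mu_L/2 "
            f"({mu_L / 2:.0f}); smallest is {result.metacell_library_sizes.min()}"
        )
    return result


def build_metacells_primary(
    X: CellExpressionMatrix,
    n: int,
    P: CellSimilarityMatrix,
    seed: int,
    id_prefix: str = "mc",
) -> MetacellResult:
    """Ablation variant: identical seeding and similarity-weighted sampling
    but no library-size acceptance rule; every sampled candidate is added
    and each metacell stops at ceil(|X|/n) members (the last takes the
    remainder)."""
    sims = _check_alignment(X, P)
    mu_L = target_mean_library_size(X, n)
    s = library_sizes(X).astype(float)
    m = X.n_cells
    cap = math.ceil(m / n)
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)

    order = _seed_order(s, X.cell_ids)
    unassigned = np.ones(m, dtype=bool)
    labels = np.full(m, -1, dtype=int)
    next_seed_ptr = 0
    k = 0
    while unassigned.any():
        while not unassigned[order[next_seed_ptr]]:
            next_seed_ptr += 1
        seed_cell = order[next_seed_ptr]
        members = [seed_cell]
        unassigned[seed_cell] = False
        labels[seed_cell] = k
        sim_sum = sims[seed_cell].copy()
        while len(members) < cap:
            pool = np.flatnonzero(unassigned)
            if pool.size == 0:
                break
            w = np.clip(sim_sum[pool] / len(members), 0.0, None)
            total_w = w.sum()
            p = w / total_w if total_w > 0 else np.full(pool.size, 1.0 / pool.size)
            cand = int(rng.choice(pool, p=p))
            members.append(cand)
            labels[cand] = k
            unassigned[cand] = False
            sim_sum += sims[cand]
        k += 1
    return _finalize(X, labels, k, mu_L, n, seed, id_prefix)


def _finalize(
    X: CellExpressionMatrix,
    labels: np.ndarray,
    n_metacells: int,
    mu_L: float,
    n_requested: int,
    seed: int,
    id_prefix: str,
) -> MetacellResult:
    metacell_ids = [f"{id_prefix}_{i}" for i in range(n_metacells)]
    assignment = {
        X.cell_ids[i]: metacell_ids[labels[i]] for i in range(X.n_cells)
    }
    counts = aggregate_counts(X, assignment, metacell_ids)
    return MetacellResult(
        assignment=assignment,
        metacell_ids=metacell_ids,
        metacell_counts=counts,
        metacell_library_sizes=counts.sum(axis=1).astype(np.int64),
        gene_ids=list(X.gene_ids),
        target_mu_L=mu_L,
        n_requested=n_requested,
        seed=int(seed),
    )


def aggregate_counts(
    X: CellExpressionMatrix,
    assignment: dict[str, str],
    metacell_ids: list[str] | None = None,
) -> np.ndarray:
    """Pool UMI counts by summing each metacell's member rows.

    ``assignment`` must cover every cell of ``X`` and reference no unknown
    cells; per-gene totals are conserved exactly (integer arithmetic).
    """
    unknown = set(assignment) - set(X.cell_ids)
    if unknown:
        raise ValueError(f"assignment references unknown cells: {sorted(unknown)[:5]}")
    missing = set(X.cell_ids) - set(assignment)
    if missing:
        raise ValueError(f"cells missing from assignment: {sorted(missing)[:5]}")
    if metacell_ids is None:
        metacell_ids = sorted(set(assignment.values()))
    mc_pos = {mc: i for i, mc in enumerate(metacell_ids)}
    out = np.zeros((len(metacell_ids), X.n_genes), dtype=np.int64)
    for row, cell in enumerate(X.cell_ids):
        out[mc_pos[assignment[cell]]] += X.counts[row]
    return out


def allocate_group_targets(
    groups: dict[str, CellExpressionMatrix], n: int
) -> GroupAllocation:
    """Split ``n`` metacells across groups proportionally to each group's
    share of the total library size (largest-remainder rounding, floor of
    one per group, remainder ties broken by group-id order)."""
    gids = sorted(groups)
    if n < len(gids):
        raise ValueError(
            f"n={n} is below the number of groups ({len(gids)}); "
            "every group needs at least one metacell"
        )
    totals = np.array([float(library_sizes(groups[g]).sum()) for g in gids])
    if totals.sum() <= 0:
        raise ValueError("total library size must be positive")
    shares = totals / totals.sum()
    raw = shares * n
    alloc = np.floor(raw).astype(int)
    remainders = raw - alloc
    # award leftover seats to the largest remainders, ties by group order
    leftover = n - int(alloc.sum())
    award_order = sorted(range(len(gids)), key=lambda i: (-remainders[i], gids[i]))
    for i in award_order[:leftover]:
        alloc[i] += 1
    # enforce the floor of one by taking from the best-endowed groups
    while (alloc == 0).any():
        zero_i = int(np.flatnonzero(alloc == 0)[0])
        donor = int(np.argmax(alloc))
        if alloc[donor] <= 1:
            raise ValueError("cannot give every group at least one metacell")
        alloc[donor] -= 1
        alloc[zero_i] += 1
    return GroupAllocation(
        targets={g: int(a) for g, a in zip(gids, alloc)},
        shares={g: float(sh) for g, sh in zip(gids, shares)},
    )


def build_metacells_by_group(
    groups: dict[str, CellExpressionMatrix],
    n: int,
    similarities: dict[str, CellSimilarityMatrix],
    seed: int,
) -> MetacellResult:
    """Group-aware construction: allocate per-group targets proportional to
    library-size share, then run the stabilized aggregation within each
    group with its own mu_L (group total / n_g). Metacell ids are prefixed
    by group and the results concatenated."""
    alloc = allocate_group_targets(groups, n)
    gids = sorted(groups)
    missing = [g for g in gids if g not in similarities]
    if missing:
        raise ValueError(f"no similarity matrix for groups: {missing}")
    all_ids = [c for g in gids for c in groups[g].cell_ids]
    if len(set(all_ids)) != len(all_ids):
        raise ValueError("cell ids must be unique across groups")
    assignment: dict[str, str] = {}
    metacell_ids: list[str] = []
    blocks = []
    gene_ids = None
    mu_weighted = 0.0
    for g in gids:
        Xg = groups[g]
        if gene_ids is None:
            gene_ids = list(Xg.gene_ids)
        elif list(Xg.gene_ids) != gene_ids:
            raise ValueError(f"group {g!r} has a different gene axis")
        sub_seed = int(substream(seed, f"group:{g}").integers(0, 2**31 - 1))
        res = build_metacells(
            Xg, alloc.targets[g], similarities[g], seed=sub_seed, id_prefix=f"{g}:mc"
        )
        assignment.update(res.assignment)
        metacell_ids.extend(res.metacell_ids)
        blocks.append(res.metacell_counts)
        mu_weighted += res.target_mu_L * res.n_metacells
    counts = np.vstack(blocks)
    return MetacellResult(
        assignment=assignment,
        metacell_ids=metacell_ids,
        metacell_counts=counts,
        metacell_library_sizes=counts.sum(axis=1).astype(np.int64),
        gene_ids=gene_ids or [],
        target_mu_L=mu_weighted / max(len(metacell_ids), 1),
        n_requested=n,
        seed=int(seed),
    )


def library_size_cv(sizes) -> float:
    """Coefficient of variation: sample standard deviation (n-1) over mean."""
    arr = np.asarray(sizes, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values for a CV")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("mean must be positive")
    return float(arr.std(ddof=1) / mean)


def metacells_to_expression(result: MetacellResult) -> CellExpressionMatrix:
    """View the pooled metacell counts as an expression matrix."""
    return CellExpressionMatrix(
        counts=result.metacell_counts,
        cell_ids=list(result.metacell_ids),
        gene_ids=list(result.gene_ids),
    )
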