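# lsmetacell

Library-size-stabilized metacell construction and weighted co-expression
network analysis for single-cell RNA-seq.

## The problem

Gene–gene correlation estimates on normalized single-cell counts are
compositionally biased: dividing every gene of a cell by that cell's
library size `s_m` (its total UMI count) applies one shared multiplicative
factor per cell, and when `s_m` varies strongly across cells this shared
factor alone induces positive correlation between genes that are truly
independent. Pooling similar cells into *metacells* reduces sparsity, but
if the pooled library sizes remain heterogeneous the bias survives
aggregation and propagates into WGCNA-style networks as false-positive
edges and inflated type-I error in independence tests.

`lsmetacell` implements a metacell construction that stabilizes library
sizes *during* aggregation. Given a counts matrix `X`, a cell–cell
similarity matrix `P` (Pearson correlation of log-normalized profiles by
default) and a target number of metacells `n`, it:

1. sets the target mean metacell library size `μ_L = (Σ_m s_m) / n`;
2. seeds each metacell with the unassigned cell of smallest library size;
3. repeatedly samples a candidate cell with probability proportional to
   its mean similarity to the current members (negative similarities
   clipped to zero), and
4. accepts the candidate only if `|S + s_cand − μ_L| ≤ |S − μ_L|`, i.e. if
   adding it moves the cumulative library size `S` toward `μ_L`; rejected
   candidates leave the pool for the current metacell but stay available
   for later ones.

A group-aware variant allocates `n_g` metacells to each group
(individual/batch) proportionally to its share of total library size and
runs the construction within groups. A "primary" ablation variant keeps
the seeding and similarity-weighted sampling but replaces the acceptance
rule with a fixed member count `⌈|X|/n⌉` — useful to isolate how much of
the stabilization is due to the acceptance rule itself.

Around the core algorithm the package provides:

- **simulators** — a permutation + Poisson *null* resampler whose
  library-size spread is controlled by a variance size factor `f`
  (`f = 0` gives constant sizes), and a Gamma–Poisson count simulator with
  a Gaussian copula (`θ_im = F_i⁻¹(Φ(v_im))`, `v ~ N(0, R)`,
  counts `~ Poisson(t_m θ_im)`) for planted co-expression structure;
- **diagnostics** — pairwise correlation bias against a known truth, the
  library-size scale factor (variance/mean), empirical type-I error of the
  exact-t Pearson independence test;
- **networks** — signed similarity `a_ij = (1 + cor)/2`, soft threshold by
  scale-free fit, topological overlap (TOM), average-linkage module
  detection, module eigengenes, kME, module–trait correlation;
- **evaluation** — top-k correlated pair overlap with a STRING-style PPI
  edge list, an exact paired Wilcoxon signed-rank test (midrank ties, full
  sign-enumeration null), and a permutation Z-summary module preservation
  statistic (3 density + 3 connectivity components).

## Worked example

```python
from lsmetacell import (build_metacells, build_metacells_primary,
                        cell_similarity, library_size_cv, library_sizes,
                        log_normalize)
from lsmetacell.simulate import make_fixture

X = make_fixture(n_cells=500, n_genes=100, sigma_log=0.8, seed=0)
N = log_normalize(X)                 # ln(1 + 1e4 * count / s_m)
P = cell_similarity(N)               # cell-cell Pearson
result = build_metacells(X, n=25, P=P, seed=0)
print(f"requested n = 25, realized n = {result.n_metacells}")
print(f"target mean library size mu_L = {result.target_mu_L:.0f}")
print(f"CV of single-cell library sizes:  {library_size_cv(library_sizes(X)):.3f}")
print(f"CV of metacell library sizes:     {library_size_cv(result.metacell_library_sizes):.3f}")
prim = build_metacells_primary(X, n=25, P=P, seed=0)
print(f"CV without the acceptance rule:   {library_size_cv(prim.metacell_library_sizes):.3f}")
```

prints

```
requested n = 25, realized n = 25
target mean library size mu_L = 52753
CV of single-cell library sizes:  0.959
CV of metacell library sizes:     0.133
CV without the acceptance rule:   0.207
```

The 500 simulated cells have log-normal library sizes (CV ≈ 0.96, roughly
a ten-fold spread). Plain similarity-weighted pooling into 25 metacells
already shrinks the library-size CV to ≈ 0.21; the acceptance rule cuts it
further to ≈ 0.13, so the per-metacell normalization factors applied
downstream are nearly constant and contribute almost no spurious
correlation.

The same workflow is available from the shell:

```bash
lsmetacell simulate fixture --cells 500 --genes 100 --seed 0 --out counts.mtx
lsmetacell build --counts counts.mtx --n 25 --seed 0 --out-prefix demo
lsmetacell network --counts demo.counts.mtx --out-prefix demo
```

## Layout

- `src/lsmetacell/data_io.py` — readers/writers (MTX + sidecars, TSV/CSV),
  detection filtering, log-normalization
- `src/lsmetacell/similarity.py` — cell–cell Pearson similarity
- `src/lsmetacell/metacell.py` — the stabilized aggregation, group
  allocation, primary variant, CV diagnostic
- `src/lsmetacell/simulate.py` — null resampler, copula simulator, fixtures
- `src/lsmetacell/bias_eval.py` — correlation bias and type-I diagnostics
- `src/lsmetacell/coexpression.py` — signed WGCNA-style network stack
- `src/lsmetacell/evaluation.py` — PPI overlap, exact Wilcoxon, Z-summary
- `src/lsmetacell/pipeline.py`, `cli.py` — orchestration and CLI

See `docs/methods.md` for the model details, parameter defaults and the
design decisions behind the numerical choices.
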