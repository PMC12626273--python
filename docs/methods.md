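# Methods

## Why library-size variance biases co-expression

Normalized expression is `y_im = x_im / s_m` with `s_m` the library size of
cell `m`. Writing `x_im ~ Poisson(s_m θ_im)` for latent expression levels
`θ`, the normalization factor `1/s_m` is shared by every gene of cell `m`;
when `s_m` varies across cells the shared factor induces positive covariance
between genes with independent `θ`. The effect grows with the library-size
*scale factor* `var(s)/mean(s)` and inflates both the mean and the spread of
pairwise Pearson correlation estimates, so independence tests over-reject.
The package demonstrates the effect on data where the truth is known by
construction (the null resampler below) rather than re-deriving it
analytically.

## The stabilized aggregation

Inputs: counts `X` (cells × genes), similarity `P` (cells × cells), target
count `n`, seed. The target mean metacell library size is
`μ_L = (Σ_m s_m)/n` — the global mean over the *requested* number of
metacells, so `n` controls the granularity while `μ_L` controls the stop
rule. (The per-cell mean would make every metacell a single cell and leave
`n` unused.)

Each metacell starts from the unassigned cell with the smallest library
size (ties broken by lexicographic cell id, for determinism). While the
cumulative size `S < μ_L` and candidates remain, a candidate is drawn with
probability `p_x ∝ max(0, mean similarity to current members)`; if every
weight is zero the draw is uniform. The candidate is accepted iff
`|S + s_x − μ_L| ≤ |S − μ_L|`; every accepted step is therefore a
contraction toward `μ_L`. A rejected candidate is excluded from the
*current* metacell's pool only — it returns to the unassigned set for later
metacells. This guarantees termination: each inner iteration removes one
cell from the pool either by assignment or rejection. The realized number
of metacells is governed by `μ_L` and may differ slightly from `n`; a
warning reports metacells whose library size ends below `μ_L/2` (typically
the earliest one when the data contain a cluster of very small cells),
rather than only the last-built one, because seeding starts from the
smallest-library cells.

The *primary* variant removes the acceptance test and stops each metacell
at `⌈|X|/n⌉` members. It isolates the contribution of the acceptance rule:
plain pooling of k cells shrinks the library-size CV roughly by `1/√k`,
while the acceptance rule brings it down further by targeting `μ_L`
directly.

Group-aware construction allocates `n_g` proportional to each group's share
of the total library size (largest-remainder rounding, floor of one per
group, remainder ties broken by group-id order) and applies the algorithm
within each group with the group-local `μ_L = (group total)/n_g`. Cell ids
must be unique across groups; metacell ids are group-prefixed.

Similarity is computed on log-normalized (`ln(1 + 10^4 · x/s)`) profiles of
the detection-filtered genes. The feature space for cell–cell correlation
is a configurable assumption — no HVG selection or PCA is applied by
default; plain Pearson suffices on the data regimes exercised here.

## Simulators

**Null resampler.** `y = x/s` per cell; each gene's `y` column is permuted
independently across cells (destroying all co-expression, preserving the
gene's marginal level distribution); new sizes `s̃ ~ N(mean(s),
f · var(s))` truncated at zero (rejection sampling; the parameters are
those of the underlying normal); counts `~ Poisson(s̃_m y_im)`. The
variance size factor `f` is the single dial: `f = 0` gives constant sizes
and a clean null; `f = 1` reproduces the input's library-size variance.
Per-gene streams are keyed by a hash of the gene id, so output is invariant
to gene storage order.

**Copula simulator.** Per-gene Gamma(r_i, scale_i) marginals (so that
counts at unit size factor are NB(r_i, p_i) with `scale = (1−p_i)/p_i`),
coupled by latent `v ~ N(0, R)` through `θ_im = F_i⁻¹(Φ(v_im))`; counts
`~ Poisson(t_m θ_im)` with truncated-normal `t_m`. `R` must be PSD within
1e-8 on its smallest eigenvalue; the quantile transform is strictly
monotone per gene, so gene-wise ranks of `θ` equal ranks of `v` exactly.
Moment estimation of `(r, p)` from data uses the NB mean–variance
inversion and flags genes with `v ≤ μ` or `μ = 0` as non-estimable.

**Fixtures.** The droplet-like base fixture draws per-gene relative
abundances from a log-uniform range, expression levels from Gamma
(shape 1), library sizes log-normal with log-sd 0.8 (≈ ten-fold spread, CV
≈ 0.95 — the regime of typical droplet data), and Poisson counts. The
planted-module fixture uses 3 blocks of 40 genes with within-block latent
correlation 0.6, Gamma(2) marginals with mean 2, and truncated-normal size
factors with mean 30 and CV 0.5, giving mean metacell library sizes of a
few thousand counts after aggregating 600 cells into 50 metacells. Sizes
were fixed once as realistic desk-scale defaults: the null fixture at
2,000 cells × 300 genes, the planted fixture at 600 cells × 120 genes;
the CV study uses 500 cells pooled into n = 25 metacells (20 cells per
metacell, a typical aggregation depth).

What the generators do *not* emulate: batch effects, dropout beyond the
Poisson–Gamma law, cell-type mixtures with DE genes, doublets, or gene-gene
dependence beyond a Gaussian copula. Passing tests therefore demonstrate
correctness of the algorithms and the direction/order of the library-size
effects, not performance on any particular real tissue.

## Network construction

Gene correlations are computed on log1p-scaled (factor 10,000) profiles of
the *metacells* — normalization after aggregation is the point of the
method, since the post-aggregation scaling factors are nearly constant.
Signed similarity `a = (1 + cor)/2`; adjacency `a^β`; TOM
`(Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij)` (unsigned TOM formula on
the signed-similarity adjacency); modules by average-linkage clustering of
`1 − TOM`.

Numerical choices that were genuinely open:

- **Soft-threshold selection.** For each candidate power the scale-free fit
  index is the *signed* R² (`−sign(slope)·R²`) of `log10 p(k)` against
  `log10 k̄` over 10 equal-width connectivity bins (empty bins dropped).
  The sign matters: on block-structured data an unsigned R² can cross the
  target with an increasing `p(k)`, which is the opposite of scale-free,
  and selects a degenerate low power. The smallest power with fit ≥ 0.8 is
  chosen; when none fits, the fallback is the sample-size-based
  recommended power for signed networks (18/16/14/12 for < 20/30/40/more
  observations) — the best of a set of poor fits is typically β = 1, i.e.
  effectively no thresholding. Equal-width (not equal-count) bins are used
  because equal-count bins make the frequency constant and the regression
  meaningless.
- **Tree cut.** The static cut height is interpreted as a *fraction of the
  joining-height range* (5th percentile to maximum of the merge heights),
  the convention of the dynamic-tree-cut literature; an absolute cut at
  0.99 dissimilarity would merge everything on typical TOM scales, where
  even unrelated genes sit at dissimilarity ≈ 0.95–0.99. A flat dendrogram
  (all merge heights equal, e.g. an identity TOM) yields no modules.
  Clusters below `min_module_size` (default 30) become grey. This replaces
  the hybrid dynamic-cut algorithm with a deterministic, testable
  approximation; fine module splitting near the cut will differ from
  dynamic-cut results.
- **Eigengenes.** First principal component of the z-scored module
  expression, scores rescaled to unit sample variance, sign fixed so the
  mean member-gene correlation is positive (making kME signs
  deterministic). Constant genes are dropped with a warning.

## Evaluation statistics

**Exact paired Wilcoxon.** Zero differences dropped; |d| midranked;
`W⁺ = Σ ranks of positive d`. For `n_eff ≤ 25` the null is computed exactly
over all `2^n` sign assignments via a generating-function convolution on
doubled midranks (integers); beyond that, a normal approximation with
midrank-corrected variance. One-sided "greater" is the default for method
comparison; sidedness of the original comparisons is not documented, and
"greater" is the direction of the claim being tested.

**Top-pair PPI overlap.** Pairs ranked by signed correlation (an absolute
mode is available), ties broken by canonical pair id; overlap counts
membership in the score-thresholded edge set (default combined score
≥ 400).

**Preservation Z-summary.** For each module: density statistics (mean
within-module |cor| in the test data, mean signed adjacency, eigengene
variance explained) and connectivity statistics (correlation of
intramodular connectivities, of kME vectors and of the within-module
correlation entries between reference and test). Each statistic is
standardized against `n_permutations` random gene sets of equal size;
`Z_density` and `Z_connectivity` are the medians of their triples,
`Z_summary` the median of the two. A statistic whose permutation spread is
at floating-point noise level is excluded with a flag — with
test = reference the three connectivity correlations are identically 1, so
self-preservation reduces to the density median by design. Shared genes
are processed in sorted order, making results invariant to gene storage
order and module names.

**Type-I error.** Log-normalize (cells left empty by Poisson resampling
are dropped first, as normalization is undefined for them), sample random
distinct gene pairs, test `ρ = 0` with `t = r√((m−2)/(1−r²))` at level α.
Sample (n−1) variances are used throughout the package (CV, scale factor).

## Known limitations

- O(N²) in cells per group (dense similarity); construction per
  individual and cell type is the intended usage for large data.
- The static tree cut and the six-statistic Z-summary are deliberate
  simplifications of the dynamic-cut and permutation-preservation
  frameworks they approximate; both are exposed via parameters.
- Metacell profiles remain compositional: aggregation shrinks the variance
  of the normalization factors but the unit-sum constraint itself, and the
  mild negative bias it induces, persist (visible as negative between-block
  correlations on fixtures with few genes).
- The acceptance rule assumes annotated, transcriptionally homogeneous
  populations; labels that are uncertain or continuous trajectories
  violate its premise.
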