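import numpy as np
import pandas as pd
import pytest
import scipy.stats

from lsmetacell.coexpression import (
    ModuleSet,
    build_network,
    detect_modules,
    kme,
    module_eigengene,
    module_eigengenes,
    module_trait_correlation,
    pick_soft_threshold,
    signed_similarity,
    tom,
)
from lsmetacell.data_io import NormalizedMatrix


def _norm(values, gene_ids=None):
    values = np.asarray(values, dtype=float)
    return NormalizedMatrix(
        values=values,
        mode="log1p_scaled",
        scale_factor=1.0,
        source_library_sizes=np.ones(values.shape[0]),
        cell_ids=[f"m{i}" for i in range(values.shape[0])],
        gene_ids=gene_ids or [f"g{j}" for j in range(values.shape[1])],
    )


class TestSignedSimilarity:
    @pytest.mark.parametrize("cor,expected", [(1.0, 1.0), (-1.0, 0.0), (0.0, 0.5)])
    def test_endpoint_mapping(self, cor, expected):
        assert signed_similarity(np.array([[cor]]))[0, 0] == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            signed_similarity(np.array([[1.5]]))


class TestSoftThreshold:
    def test_mean_connectivity_closed_form(self):
        p = 11
        sim = np.full((p, p), 0.5)
        np.fill_diagonal(sim, 1.0)
        _, diag = pick_soft_threshold(sim, powers=[2])
        # adjacency 0.25 off-diagonal -> k_i = 0.25 * (p - 1)
        assert diag.loc[0, "mean_k"] == pytest.approx(0.25 * (p - 1))

    def test_mean_connectivity_decreasing_in_power(self):
        rng = np.random.default_rng(0)
        M = rng.uniform(0.1, 0.9, (15, 15))
        sim = (M + M.T) / 2
        np.fill_diagonal(sim, 1.0)
        _, diag = pick_soft_threshold(sim, powers=list(range(1, 10)))
        assert diag["mean_k"].is_monotonic_decreasing

    def test_fit_matches_hand_regression(self):
        # construct a connectivity profile, bin it exactly as the selector
        # does, and reproduce the regression R^2 by hand
        rng = np.random.default_rng(1)
        from lsmetacell.coexpression import _scale_free_r2

        k = rng.pareto(2.0, size=200) + 1
        edges = np.linspace(k.min(), k.max(), 11)
        which = np.clip(np.digitize(k, edges[1:-1]), 0, 9)
        xs, ys = [], []
        for b in range(10):
            members = k[which == b]
            if members.size == 0 or members.mean() <= 0:
                continue
            ys.append(np.log10(members.size / k.size))
            xs.append(np.log10(members.mean()))
        slope, intercept = np.polyfit(xs, ys, 1)
        ss_res = np.sum((np.array(ys) - (slope * np.array(xs) + intercept)) ** 2)
        ss_tot = np.sum((np.array(ys) - np.mean(ys)) ** 2)
        expected = -np.sign(slope) * (1 - ss_res / ss_tot)
        assert _scale_free_r2(k) == pytest.approx(expected, abs=1e-10)
        assert slope < 0  # a Pareto-like degree sequence has decreasing p(k)

    def test_empty_powers_rejected(self):
        with pytest.raises(ValueError):
            pick_soft_threshold(np.eye(3), powers=[])


class TestTOM:
    def test_two_gene_closed_form(self):
        for a in [0.1, 0.5, 0.9]:
            A = np.array([[1.0, a], [a, 1.0]])
            T = tom(A)
            assert T[0, 1] == pytest.approx(a)  # numerator a, denominator a+1-a

    def test_disconnected_stays_disconnected(self):
        T = tom(np.eye(4))
        np.testing.assert_allclose(T, np.eye(4))

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(2)
        M = rng.uniform(0, 1, (10, 10))
        A = (M + M.T) / 2
        np.fill_diagonal(A, 0.0)
        T = tom(A)
        k = A.sum(axis=1)
        for i in range(10):
            for j in range(10):
                if i == j:
                    assert T[i, j] == 1.0
                    continue
                shared = sum(
                    A[i, u] * A[u, j] for u in range(10) if u not in (i, j)
                )
                expected = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
                assert T[i, j] == pytest.approx(expected, abs=1e-12)

    def test_bounded_by_unit_interval(self):
        rng = np.random.default_rng(3)
        M = rng.uniform(0, 1, (20, 20))
        A = (M + M.T) / 2
        T = tom(A)
        assert (T >= 0).all() and (T <= 1).all()
        np.testing.assert_allclose(T, T.T)

    def test_out_of_range_adjacency_rejected(self):
        with pytest.raises(ValueError):
            tom(np.array([[0.0, 1.2], [1.2, 0.0]]))


def _planted_tom(n_blocks=3, block=40, within=0.8, between=0.05):
    p = n_blocks * block
    T = np.full((p, p), between)
    for b in range(n_blocks):
        T[b * block : (b + 1) * block, b * block : (b + 1) * block] = within
    np.fill_diagonal(T, 1.0)
    return T


class TestDetectModules:
    def test_three_planted_blocks_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        T = _planted_tom()
        genes = [f"g{j}" for j in range(T.shape[0])]
        mods = detect_modules(T, genes, min_module_size=30)
        planted = np.repeat([0, 1, 2], 40)
        ari = adjusted_rand_score(planted, mods.labels.to_numpy())
        assert ari == pytest.approx(1.0)
        assert len(mods.module_names) == 3

    def test_identity_tom_all_grey(self):
        genes = [f"g{j}" for j in range(40)]
        mods = detect_modules(np.eye(40), genes, min_module_size=5)
        assert (mods.labels == "grey").all()

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        T = _planted_tom(2, 35, within=0.7, between=0.1)
        genes = [f"g{j}" for j in range(70)]
        base = detect_modules(T, genes, min_module_size=30).labels
        perm = rng.permutation(70)
        permuted = detect_modules(
            T[np.ix_(perm, perm)], [genes[j] for j in perm], min_module_size=30
        ).labels
        for j in perm:
            assert permuted[genes[j]] == base[genes[j]]

    def test_fewer_genes_than_min_size_all_grey(self):
        with pytest.warns(UserWarning):
            mods = detect_modules(np.eye(3), ["a", "b", "c"], min_module_size=10)
        assert (mods.labels == "grey").all()


class TestEigengene:
    def test_identical_genes_reproduce_profile(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        V = np.column_stack([x, x, x])
        N = _norm(V)
        e, ve = module_eigengene(N, N.gene_ids)
        assert ve == pytest.approx(1.0)
        z = (x - x.mean()) / x.std(ddof=1)
        np.testing.assert_allclose(e, z, atol=1e-8)

    def test_two_gene_variance_explained(self):
        # correlation-rho pair: top eigenvalue (1+rho)/2 of the normalized
        # 2x2 correlation spectrum
        rng = np.random.default_rng(6)
        x = rng.normal(size=2000)
        y = 0.6 * x + np.sqrt(1 - 0.36) * rng.normal(size=2000)
        N = _norm(np.column_stack([x, y]))
        _, ve = module_eigengene(N, N.gene_ids)
        rho = np.corrcoef(x, y)[0, 1]
        assert ve == pytest.approx((1 + rho) / 2, abs=1e-9)

    def test_sign_rule_positive_mean_membership(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=30)
        V = np.column_stack(
            [base + 0.3 * rng.normal(size=30) for _ in range(6)]
        )
        N = _norm(V)
        e, _ = module_eigengene(N, N.gene_ids)
        mean_cor = np.mean([np.corrcoef(e, V[:, j])[0, 1] for j in range(6)])
        assert mean_cor > 0

    def test_constant_member_dropped(self):
        rng = np.random.default_rng(8)
        V = np.column_stack([rng.normal(size=10), rng.normal(size=10), np.ones(10)])
        with pytest.warns(UserWarning, match="constant"):
            module_eigengene(_norm(V), ["g0", "g1", "g2"])


class TestKME:
    def test_gene_equal_to_eigengene(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=15)
        N = _norm(np.column_stack([x, rng.normal(size=15)]))
        E = pd.DataFrame({"mod": x})
        K = kme(N, E)
        assert K.loc["g0", "mod"] == pytest.approx(1.0)

    def test_matches_loop_oracle_and_bounds(self):
        rng = np.random.default_rng(10)
        V = rng.normal(size=(25, 6))
        E = pd.DataFrame(rng.normal(size=(25, 2)), columns=["a", "b"])
        N = _norm(V)
        K = kme(N, E)
        assert ((K >= -1) & (K <= 1)).all().all()
        for j, g in enumerate(N.gene_ids):
            for mod in ["a", "b"]:
                expected = np.corrcoef(V[:, j], E[mod])[0, 1]
                assert K.loc[g, mod] == pytest.approx(expected, abs=1e-10)


class TestModuleTraitCorrelation:
    def test_trait_equal_to_eigengene(self):
        rng = np.random.default_rng(11)
        e = rng.normal(size=40)
        E = pd.DataFrame({"mod": e})
        traits = pd.DataFrame({"pheno": e})
        res = module_trait_correlation(E, traits)
        assert res.loc[0, "r"] == pytest.approx(1.0)

    def test_nominal_rejection_rate_under_independence(self):
        rng = np.random.default_rng(12)
        m, reps = 1000, 500
        e = rng.normal(size=(m,))
        E = pd.DataFrame({"mod": e})
        rejections = 0
        for _ in range(reps):
            traits = pd.DataFrame({"t": rng.normal(size=m)})
            res = module_trait_correlation(E, traits)
            rejections += res.loc[0, "p"] < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_missing_values_pairwise_deleted(self):
        e = np.arange(10.0)
        t = e.copy()
        t[:3] = np.nan
        res = module_trait_correlation(
            pd.DataFrame({"m": e}), pd.DataFrame({"t": t})
        )
        assert res.loc[0, "n"] == 7
        assert res.loc[0, "r"] == pytest.approx(1.0)

    def test_constant_trait_flagged(self):
        res = module_trait_correlation(
            pd.DataFrame({"m": np.arange(10.0)}),
            pd.DataFrame({"t": np.ones(10)}),
        )
        assert not res.loc[0, "valid"]


class TestBuildNetwork:
    def test_chain_preserves_symmetry_and_bounds(self):
        rng = np.random.default_rng(13)
        base = rng.normal(size=(30, 1))
        V = base @ np.ones((1, 8)) + 0.8 * rng.normal(size=(30, 8))
        net = build_network(_norm(V), powers=[4])
        assert net.power == 4
        for M in (net.signed_similarity, net.adjacency, net.tom):
            np.testing.assert_allclose(M, M.T, atol=1e-10)
        assert (net.tom >= 0).all() and (net.tom <= 1).all()

    def test_higher_power_never_increases_adjacency(self):
        rng = np.random.default_rng(14)
        V = rng.normal(size=(20, 6))
        n4 = build_network(_norm(V), powers=[4])
        n8 = build_network(_norm(V), powers=[8])
        off = ~np.eye(6, dtype=bool)
        assert (n8.adjacency[off] <= n4.adjacency[off] + 1e-12).all()

    def test_module_eigengenes_complete_moduleset(self):
        rng = np.random.default_rng(15)
        base = rng.normal(size=(40, 1))
        V = np.hstack(
            [
                base + 0.4 * rng.normal(size=(40, 5)),
                -base + 0.4 * rng.normal(size=(40, 5)),
            ]
        )
        N = _norm(V)
        labels = pd.Series(
            ["up"] * 5 + ["down"] * 5, index=pd.Index(N.gene_ids, name="gene_id")
        )
        mods = module_eigengenes(N, ModuleSet(labels=labels, min_module_size=3))
        assert set(mods.eigengenes.columns) == {"up", "down"}
        # sign rule: member genes correlate positively with their eigengene
        for mod in ("up", "down"):
            assert mods.kme.loc[mods.genes_in(mod), mod].mean() > 0
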