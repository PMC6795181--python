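import numpy as np
import pandas as pd
import pytest

from coexcross import coexpr
from coexcross.diffexpr import size_factors


def expr_frame(arr, prefix="g"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])],
                        columns=[f"s{j}" for j in range(arr.shape[1])])


class TestExpressionTransform:
    def test_constant_gene_dropped(self, caplog):
        # the cyclic construction keeps all size factors at exactly 1,
        # so g0 stays constant after normalization
        counts = expr_frame([[5, 5, 5], [1, 9, 4], [4, 1, 9], [9, 4, 1]])
        with caplog.at_level("INFO"):
            out = coexpr.expression_transform(counts)
        assert "g0" not in out.index and "g1" in out.index

    def test_zero_count_maps_to_zero_under_unit_factors(self):
        # the single all-positive balanced gene anchors size factors at 1;
        # log2(0/1 + 1) = 0 for the zero count
        counts = expr_frame([[5, 5, 5], [0, 4, 9]])
        out = coexpr.expression_transform(counts)
        assert out.loc["g1", "s0"] == 0.0

    def test_scaling_one_sample_rescales_normalized_matrix_uniformly(self):
        rng = np.random.default_rng(8)
        counts = expr_frame(rng.poisson(60, size=(30, 6)))
        scaled = counts.copy()
        scaled["s1"] *= 2.0
        norm_a = counts / size_factors(counts)
        norm_b = scaled / size_factors(scaled)
        ratio = (norm_b / norm_a).to_numpy()
        assert np.allclose(ratio, ratio[0, 0], rtol=1e-9)


class TestAdjacency:
    def test_sign_removed_and_power_applied(self):
        # two exactly anti-correlated genes: r = -1 -> |r|^p = 1
        e = expr_frame([[1, 2, 3, 4], [4, 3, 2, 1]])
        a = coexpr.adjacency(e, 2)
        assert a.loc["g0", "g1"] == pytest.approx(1.0)
        # r = -0.5 constructed: corr([1,-1,0],[ -1,0,1 ]) = -0.5
        e2 = expr_frame([[1, -1, 0], [-1, 0, 1]])
        a2 = coexpr.adjacency(e2, 2)
        assert a2.loc["g0", "g1"] == pytest.approx(0.25)

    def test_perfect_correlation_fixed_point(self):
        e = expr_frame([[1, 2, 3, 4], [2, 4, 6, 8]])
        for power in (1, 6, 12):
            assert coexpr.adjacency(e, power).loc["g0", "g1"] == pytest.approx(1.0)

    def test_matches_elementwise_oracle(self, rng):
        e = expr_frame(rng.normal(size=(10, 6)))
        beta = 7
        a = coexpr.adjacency(e, beta).to_numpy()
        x = e.to_numpy()
        for i in range(10):
            for j in range(10):
                if i == j:
                    assert a[i, j] == 0.0
                else:
                    r = np.corrcoef(x[i], x[j])[0, 1]
                    assert a[i, j] == pytest.approx(abs(r) ** beta, abs=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            coexpr.adjacency(expr_frame([[1, 2], [3, 4]]), 6)


class TestScaleFreeFit:
    @staticmethod
    def powerlaw_adjacency():
        # exact discrete power law: n(k) proportional to k^-2 at separated
        # connectivity values; rank-1 outer(k, k)/sum(k) realizes row sums ~ k
        targets = np.arange(1, 9, dtype=float)
        counts = np.maximum(
            (400 * targets**-2.0 / (targets**-2.0).sum()).round().astype(int), 2)
        k = np.repeat(targets, counts)
        a = np.outer(k, k) / k.sum()
        np.fill_diagonal(a, 0)
        genes = [f"g{i}" for i in range(len(k))]
        return pd.DataFrame(a, index=genes, columns=genes)

    def test_powerlaw_fixture_fits_well(self):
        adj = self.powerlaw_adjacency()
        assert coexpr.scale_free_fit(adj) >= 0.95

    def test_equal_connectivity_returns_zero_with_warning(self, caplog):
        n = 25
        a = np.full((n, n), 0.4)
        np.fill_diagonal(a, 0)
        adj = pd.DataFrame(a, index=[f"g{i}" for i in range(n)], columns=[f"g{i}" for i in range(n)])
        with caplog.at_level("WARNING"):
            assert coexpr.scale_free_fit(adj) == 0.0
        assert "equal" in caplog.text

    def test_invariant_to_gene_order(self, rng):
        adj = self.powerlaw_adjacency()
        perm = rng.permutation(len(adj))
        shuffled = adj.iloc[perm, perm]
        assert coexpr.scale_free_fit(shuffled) == pytest.approx(coexpr.scale_free_fit(adj))


class TestTOM:
    def test_triangle_hand_case(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 0)
        genes = ["x", "y", "z"]
        tom = coexpr.tom_similarity(pd.DataFrame(a, index=genes, columns=genes))
        # l = 0.25, k = 1 -> (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5
        assert tom.loc["x", "y"] == pytest.approx(0.5, abs=1e-15)
        assert np.allclose(np.diag(tom), 1.0)

    def test_isolated_pair_zero_overlap(self):
        a = np.zeros((2, 2))
        tom = coexpr.tom_similarity(expr_frame(a) * 0)
        assert tom.iloc[0, 1] == 0.0

    def test_matches_triple_loop_oracle(self, rng):
        n = 20
        a = rng.random((n, n)) * 0.8
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        genes = [f"g{i}" for i in range(n)]
        tom = coexpr.tom_similarity(pd.DataFrame(a, index=genes, columns=genes)).to_numpy()
        k = a.sum(axis=1)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
                expect = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
                assert tom[i, j] == pytest.approx(expect, abs=1e-10)
                assert 0.0 <= tom[i, j] <= 1.0


class TestDendrogramAndCut:
    def test_correlated_pairs_merge_first_and_heights_monotone(self):
        rng = np.random.default_rng(2)
        base1, base2 = rng.normal(size=6), rng.normal(size=6)
        e = expr_frame([base1, base1 * 2 + 1e-6 * rng.normal(size=6),
                        base2, -base2 + 1e-6 * rng.normal(size=6)])
        adj = coexpr.adjacency(e, 2)
        tom = coexpr.tom_similarity(adj)
        z = coexpr.cluster_dendrogram(1 - tom)
        heights = z[:, 2]
        assert (np.diff(heights) >= -1e-12).all()
        first_pairs = {frozenset(z[0, :2].astype(int)), frozenset(z[1, :2].astype(int))}
        assert first_pairs == {frozenset({0, 1}), frozenset({2, 3})}

    def test_zero_dissimilarity_pair_merges_at_zero(self):
        genes = pd.Index(["a", "b", "c"])
        d = pd.DataFrame([[0.0, 0.0, 0.9], [0.0, 0.0, 0.9], [0.9, 0.9, 0.0]],
                         index=genes, columns=genes)
        z = coexpr.cluster_dendrogram(d)
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_single_gene_rejected(self):
        d = pd.DataFrame([[0.0]], index=["g0"], columns=["g0"])
        with pytest.raises(ValueError):
            coexpr.cluster_dendrogram(d)

    def test_all_dissimilar_genes_stay_grey(self, rng):
        n = 10
        d = np.full((n, n), 0.995)
        np.fill_diagonal(d, 0)
        genes = pd.Index([f"g{i}" for i in range(n)])
        z = coexpr.cluster_dendrogram(pd.DataFrame(d, index=genes, columns=genes))
        assign = coexpr.cut_modules(z, genes, min_module_size=3, cut_height=0.5)
        assert (assign == 0).all()

    def test_min_module_size_above_n_gives_all_grey(self, rng):
        e = expr_frame(rng.normal(size=(8, 6)))
        d = 1 - coexpr.tom_similarity(coexpr.adjacency(e, 2))
        z = coexpr.cluster_dendrogram(d)
        assign = coexpr.cut_modules(z, e.index, min_module_size=100, cut_height=0.99)
        assert (assign == 0).all()


class TestEigengenes:
    def test_rank_one_module(self):
        v = np.array([1.0, -1.0, 2.0, -2.0, 0.5, -0.5])
        e = expr_frame(np.vstack([v * c + o for c, o in [(1, 0), (2, 5), (0.5, -3)]]))
        assign = pd.Series(1, index=e.index)
        me = coexpr.module_eigengenes(e, assign)
        vz = (v - v.mean()) / v.std()
        expected = vz / np.linalg.norm(vz)
        got = me.loc[1].to_numpy()
        assert np.allclose(np.abs(got @ expected), 1.0, atol=1e-10)
        kme = coexpr.kme_and_hubs(e, assign, me)
        assert np.allclose(kme["kme"], 1.0)
        assert kme["is_hub"].all()

    def test_sign_canonical_under_global_flip(self):
        rng = np.random.default_rng(9)
        e = expr_frame(rng.normal(size=(12, 8)))
        assign = pd.Series(1, index=e.index)
        me = coexpr.module_eigengenes(e, assign)
        corr = np.corrcoef(np.vstack([e.to_numpy(), me.loc[1].to_numpy()]))[-1, :-1]
        assert corr.mean() >= 0  # orientation convention

    def test_eigengene_explains_most_variance(self, rng):
        e = expr_frame(rng.normal(size=(15, 10)))
        assign = pd.Series(1, index=e.index)
        me = coexpr.module_eigengenes(e, assign).loc[1].to_numpy()
        z = (e.to_numpy() - e.to_numpy().mean(1, keepdims=True))
        z /= z.std(1, keepdims=True)

        def explained(vec):
            vec = (vec - vec.mean()) / np.linalg.norm(vec - vec.mean())
            return np.sum((z @ vec) ** 2)

        best_gene = max(explained(z[i]) for i in range(z.shape[0]))
        assert explained(me) >= best_gene - 1e-8


class TestMerge:
    @staticmethod
    def two_module_expr(target_corr, rng):
        """Two 10-gene modules whose eigengenes correlate ~ target_corr."""
        n_s = 40
        f1 = rng.normal(size=n_s)
        noise = rng.normal(size=n_s)
        noise -= noise @ f1 / (f1 @ f1) * f1
        f2 = target_corr * (f1 - f1.mean()) / f1.std() + np.sqrt(1 - target_corr**2) * (noise - noise.mean()) / noise.std()
        rows = [f1 + 0.05 * rng.normal(size=n_s) for _ in range(10)]
        rows += [f2 + 0.05 * rng.normal(size=n_s) for _ in range(10)]
        e = expr_frame(np.array(rows))
        assign = pd.Series([1] * 10 + [2] * 10, index=e.index)
        return e, assign

    def test_close_eigengenes_merge(self, rng):
        e, assign = self.two_module_expr(0.95, rng)
        merged = coexpr.merge_modules(e, assign, merge_height=0.15)
        assert merged.nunique() == 1

    def test_distant_eigengenes_stay_separate(self, rng):
        e, assign = self.two_module_expr(0.5, rng)
        merged = coexpr.merge_modules(e, assign, merge_height=0.15)
        assert set(merged.unique()) == {1, 2}

    def test_merge_order_independent_of_labeling(self, rng):
        e, assign = self.two_module_expr(0.95, rng)
        swapped = assign.map({1: 2, 2: 1})
        a = coexpr.merge_modules(e, assign, 0.15)
        b = coexpr.merge_modules(e, swapped, 0.15)
        assert (a == b).all()


class TestHubThreshold:
    def test_kme_equal_to_threshold_is_not_hub(self, rng):
        e = expr_frame(rng.normal(size=(10, 12)))
        assign = pd.Series(1, index=e.index)
        me = coexpr.module_eigengenes(e, assign)
        kme = coexpr.kme_and_hubs(e, assign, me)
        pivot = kme["kme"].iloc[3]
        again = coexpr.kme_and_hubs(e, assign, me, hub_threshold=float(pivot))
        assert not again["is_hub"].iloc[3]  # strict inequality
        assert again.loc[kme["kme"] > pivot, "is_hub"].all()

    def test_planted_hub_genes_outrank_weak_members(self):
        rng = np.random.default_rng(17)
        f = rng.normal(size=30)
        strong = [0.95 * f + np.sqrt(1 - 0.95**2) * rng.normal(size=30) for _ in range(8)]
        weak = [0.4 * f + np.sqrt(1 - 0.4**2) * rng.normal(size=30) for _ in range(8)]
        e = expr_frame(np.array(strong + weak))
        assign = pd.Series(1, index=e.index)
        me = coexpr.module_eigengenes(e, assign)
        kme = coexpr.kme_and_hubs(e, assign, me)["kme"]
        assert kme.iloc[:8].mean() > kme.iloc[8:].mean()

    def test_unassigned_genes_get_na(self, rng):
        e = expr_frame(rng.normal(size=(6, 8)))
        assign = pd.Series([1, 1, 1, 1, 0, 0], index=e.index)
        me = coexpr.module_eigengenes(e, assign)
        kme = coexpr.kme_and_hubs(e, assign, me)
        assert kme.loc[assign == 0, "kme"].isna().all()
        assert not kme.loc[assign == 0, "is_hub"].any()


class TestPipelineDeterminismAndInvariance:
    def test_same_input_same_partition(self, rng):
        e = expr_frame(rng.normal(size=(40, 12)))
        a = coexpr.detect_modules(e, power=6, min_module_size=5)
        b = coexpr.detect_modules(e, power=6, min_module_size=5)
        assert (a.assignment == b.assignment).all()

    def test_gene_permutation_preserves_partition(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(23)
        f1, f2 = rng.normal(size=20), rng.normal(size=20)
        rows = [f1 + 0.3 * rng.normal(size=20) for _ in range(12)]
        rows += [f2 + 0.3 * rng.normal(size=20) for _ in range(12)]
        e = expr_frame(np.array(rows))
        perm = rng.permutation(len(e))
        shuffled = e.iloc[perm]
        a = coexpr.detect_modules(e, power=6, min_module_size=5).assignment
        b = coexpr.detect_modules(shuffled, power=6, min_module_size=5).assignment
        assert adjusted_rand_score(a.loc[e.index], b.loc[e.index]) == pytest.approx(1.0)
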