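import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from coexmod import (CutParams, ExpressionMatrix, ModulePartition,
                     cut_dynamic_hybrid, gene_module_stats,
                     hyperparameter_sweep, linkage_tree, merge_close_modules,
                     module_eigengenes, module_trait_correlation,
                     top_hub_genes)
from coexmod.module_detect import default_sweep_grid


def linkage_oracle(d):
    """Naive average-linkage agglomeration: merge heights only."""
    clusters = {i: [i] for i in range(d.shape[0])}
    heights = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai, a in enumerate(keys):
            for b in keys[ai + 1:]:
                avg = np.mean([d[i, j] for i in clusters[a]
                               for j in clusters[b]])
                if best is None or avg < best[0]:
                    best = (avg, a, b)
        h, a, b = best
        heights.append(h)
        clusters[a] = clusters[a] + clusters.pop(b)
    return np.array(heights)


def block_dissimilarity(sizes, within=0.1, between=0.9, jitter=0.0, seed=0):
    n = sum(sizes)
    rng = np.random.default_rng(seed)
    d = np.full((n, n), between)
    start = 0
    labels = np.zeros(n, dtype=int)
    for m, size in enumerate(sizes, start=1):
        d[start:start + size, start:start + size] = within
        labels[start:start + size] = m
        start += size
    if jitter:
        noise = rng.uniform(-jitter, jitter, size=(n, n))
        d = d + (noise + noise.T) / 2
    d = np.clip(d, 0.0, None)
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2, labels


class TestLinkageTree:
    def test_two_leaves_single_merge(self):
        d = np.array([[0.0, 0.4], [0.4, 0.0]])
        tree = linkage_tree(d)
        assert tree.merges.shape == (1, 4)
        assert tree.heights[0] == pytest.approx(0.4)

    def test_equidistant_leaves_are_deterministic(self):
        d = np.full((3, 3), 0.5)
        np.fill_diagonal(d, 0.0)
        t1 = linkage_tree(d)
        t2 = linkage_tree(d)
        np.testing.assert_array_equal(t1.merges, t2.merges)
        np.testing.assert_allclose(t1.heights, 0.5)

    def test_heights_match_naive_agglomeration_oracle(self):
        rng = np.random.default_rng(11)
        d = rng.uniform(0.1, 1.0, size=(8, 8))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        tree = linkage_tree(d)
        np.testing.assert_allclose(np.sort(tree.heights),
                                   np.sort(linkage_oracle(d)), atol=1e-12)

    def test_non_finite_dissimilarity_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.inf
        with pytest.raises(ValueError):
            linkage_tree(d)


class TestCutDynamicHybrid:
    def test_two_perfect_blocks_recovered_exactly(self):
        d, truth = block_dissimilarity([20, 20])
        tree = linkage_tree(d)
        part = cut_dynamic_hybrid(tree, d, CutParams(min_module_size=5))
        assert adjusted_rand_score(truth, part.labels) == 1.0
        assert len(part.module_labels) == 2

    def test_min_size_above_n_unassigns_everything(self):
        d, _ = block_dissimilarity([20, 20])
        tree = linkage_tree(d)
        part = cut_dynamic_hybrid(tree, d, CutParams(min_module_size=50))
        assert (part.labels == 0).all()

    def test_identical_runs_are_identical(self):
        d, _ = block_dissimilarity([15, 15, 10], jitter=0.05, seed=3)
        tree = linkage_tree(d)
        p1 = cut_dynamic_hybrid(tree, d, CutParams(min_module_size=5))
        p2 = cut_dynamic_hybrid(tree, d, CutParams(min_module_size=5))
        np.testing.assert_array_equal(p1.labels, p2.labels)

    def test_deeper_split_never_fewer_stage1_branches(self, default_dataset):
        from coexmod import NetworkConfig, adjacency, correlation_matrix, tom
        cor = correlation_matrix(default_dataset.expr)
        t = tom(adjacency(cor, NetworkConfig()))
        d = t.dissimilarity
        np.fill_diagonal(d, 0.0)
        tree = linkage_tree(d)
        counts = [cut_dynamic_hybrid(tree, d,
                                     CutParams(deep_split=ds)).n_stage1_branches
                  for ds in range(5)]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_modules_respect_min_size(self):
        d, _ = block_dissimilarity([12, 9, 30], jitter=0.05, seed=5)
        tree = linkage_tree(d)
        part = cut_dynamic_hybrid(tree, d, CutParams(min_module_size=10))
        assert all(size >= 10 for size in part.sizes.values())


class TestModuleEigengenes:
    def _expr_with_partition(self, rows, labels):
        ids = [f"g{i}" for i in range(rows.shape[0])]
        expr = ExpressionMatrix(pd.DataFrame(
            rows, index=ids, columns=[f"s{j}" for j in range(rows.shape[1])]))
        return expr, ModulePartition(ids, np.asarray(labels))

    def test_rank_one_module_has_unit_pve_and_unit_member_correlation(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=30)
        rows = np.vstack([2 * base + 1, -3 * base, base])
        expr, part = self._expr_with_partition(rows, [1, 1, 1])
        me = module_eigengenes(expr, part)
        assert me.pve[1] == pytest.approx(1.0, abs=1e-12)
        for row in rows:
            assert abs(np.corrcoef(row, me.vector(1))[0, 1]) == \
                pytest.approx(1.0, abs=1e-10)

    def test_orientation_and_unit_variance_on_random_modules(self):
        rng = np.random.default_rng(1)
        for seed in range(20):
            rows = np.random.default_rng(seed).normal(size=(8, 25))
            expr, part = self._expr_with_partition(rows, [1] * 4 + [2] * 4)
            me = module_eigengenes(expr, part)
            for label in (1, 2):
                v = me.vector(label)
                assert v.std(ddof=1) == pytest.approx(1.0, abs=1e-10)
                members = rows[np.array(part.labels) == label]
                kme = [np.corrcoef(r, v)[0, 1] for r in members]
                assert np.mean(kme) >= 0

    def test_pve_matches_mean_squared_member_correlation(self):
        # population member-eigengene correlation sqrt(rho); pve of the
        # first PC approaches the average squared correlation
        rng = np.random.default_rng(2)
        rho = 0.64
        e = rng.standard_normal(200)
        rows = np.sqrt(rho) * e + np.sqrt(1 - rho) * rng.standard_normal((30, 200))
        expr, part = self._expr_with_partition(rows, [1] * 30)
        me = module_eigengenes(expr, part)
        kme2 = np.mean([np.corrcoef(r, me.vector(1))[0, 1] ** 2 for r in rows])
        assert me.pve[1] == pytest.approx(kme2, abs=0.05)


class TestMergeCloseModules:
    def _three_module_expr(self, cor12=0.9, cor13=0.2, seed=0):
        rng = np.random.default_rng(seed)
        n = 60
        e1 = rng.standard_normal(n)
        e2 = cor12 * e1 + np.sqrt(1 - cor12 ** 2) * rng.standard_normal(n)
        e3 = cor13 * e1 + np.sqrt(1 - cor13 ** 2) * rng.standard_normal(n)
        rows = []
        for e in (e1, e2, e3):
            rows.append(e + 0.01 * rng.standard_normal((6, n)))
        rows = np.vstack(rows)
        ids = [f"g{i}" for i in range(18)]
        expr = ExpressionMatrix(pd.DataFrame(
            rows, index=ids, columns=[f"s{j}" for j in range(n)]))
        part = ModulePartition(ids, np.repeat([1, 2, 3], 6))
        return expr, part

    def test_identical_eigengenes_always_merge(self):
        expr, part = self._three_module_expr(cor12=0.999, cor13=0.0)
        me = module_eigengenes(expr, part)
        merged, _ = merge_close_modules(expr, part, me, h=0.05)
        assert len(merged.module_labels) == 2

    def test_distant_modules_unchanged(self):
        expr, part = self._three_module_expr(cor12=0.2, cor13=0.1)
        me = module_eigengenes(expr, part)
        merged, _ = merge_close_modules(expr, part, me, h=0.15)
        assert len(merged.module_labels) == 3

    def test_closest_first_merge_matches_hand_trace(self):
        # eigengene correlations ~ (0.9, 0.2, 0.2): the hand simulation of
        # the closest-first rule merges exactly the 0.9 pair, then stops
        # because the merged profile stays far from the third eigengene
        expr, part = self._three_module_expr(cor12=0.9, cor13=0.2)
        me = module_eigengenes(expr, part)
        merged, me2 = merge_close_modules(expr, part, me, h=0.15)
        assert len(merged.module_labels) == 2
        # the surviving big module holds the 12 genes of former 1 and 2
        sizes = sorted(merged.sizes.values())
        assert sizes == [6, 12]


class TestGeneModuleStats:
    def test_hub_ranks_follow_intramodular_connectivity(self):
        from coexmod import AdjacencyMatrix
        rng = np.random.default_rng(3)
        rows = rng.normal(size=(3, 20))
        ids = ["a", "b", "c"]
        expr = ExpressionMatrix(pd.DataFrame(
            rows, index=ids, columns=[f"s{j}" for j in range(20)]))
        part = ModulePartition(ids, [1, 1, 1])
        a = np.array([[1.0, 0.9, 0.7], [0.9, 1.0, 0.5], [0.7, 0.5, 1.0]])
        me = module_eigengenes(expr, part)
        stats = gene_module_stats(expr, part, AdjacencyMatrix(ids, a), me)
        assert stats.loc["a", "kIM"] == pytest.approx(1.6)
        assert list(stats["hub_rank"]) == [1, 2, 3]

    def test_gene_equal_to_its_eigengene_has_unit_kme(self):
        from coexmod import AdjacencyMatrix
        rng = np.random.default_rng(4)
        base = rng.normal(size=30)
        rows = np.vstack([base, 2 * base + 3, 0.5 * base - 1.0])
        ids = ["a", "b", "c"]
        expr = ExpressionMatrix(pd.DataFrame(
            rows, index=ids, columns=[f"s{j}" for j in range(30)]))
        part = ModulePartition(ids, [1, 1, 1])
        me = module_eigengenes(expr, part)
        a = np.ones((3, 3))
        stats = gene_module_stats(expr, part, AdjacencyMatrix(ids, a), me)
        assert stats.loc["b", "kME"] == pytest.approx(1.0, abs=1e-9)

    def test_top_k_request_larger_than_module_returns_all(self):
        stats = pd.DataFrame({
            "module": [1] * 5, "kIM": [5, 4, 3, 2, 1],
            "kME": [0.9] * 5, "hub_rank": [1, 2, 3, 4, 5]},
            index=pd.Index([f"g{i}" for i in range(5)], name="gene_id"))
        assert len(top_hub_genes(stats, 1, k=120)) == 5


class TestModuleTraitCorrelation:
    def test_trait_equal_to_eigengene_gives_unit_correlation(self, default_dataset):
        me = module_eigengenes(default_dataset.expr, default_dataset.truth)
        traits = pd.DataFrame({"self": me.values["ME1"]},
                              index=me.values.index)
        res = module_trait_correlation(me, traits)
        assert res.correlation.loc["ME1", "self"] == pytest.approx(1.0)
        assert res.p_values.loc["ME1", "self"] < 1e-20

    def test_permuted_trait_p_values_are_uniform(self):
        rng = np.random.default_rng(5)
        rows = rng.normal(size=(10, 40))
        ids = [f"g{i}" for i in range(10)]
        expr = ExpressionMatrix(pd.DataFrame(
            rows, index=ids, columns=[f"s{j}" for j in range(40)]))
        part = ModulePartition(ids, [1] * 5 + [2] * 5)
        me = module_eigengenes(expr, part)
        ps = []
        for seed in range(200):
            trait = pd.DataFrame(
                {"t": np.random.default_rng(seed).permutation(40)},
                index=me.values.index)
            res = module_trait_correlation(me, trait)
            ps.append(res.p_values.loc["ME1", "t"])
        from scipy.stats import kstest
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_constant_trait_is_missing_with_warning(self, default_dataset):
        me = module_eigengenes(default_dataset.expr, default_dataset.truth)
        traits = pd.DataFrame({"const": np.ones(len(me.values))},
                              index=me.values.index)
        res = module_trait_correlation(me, traits)
        assert res.correlation["const"].isna().all()


def ari_oracle(a, b):
    """Adjusted Rand index from the contingency-table formula, written out
    directly."""
    from math import comb
    a, b = np.asarray(a), np.asarray(b)
    ua, ub = np.unique(a), np.unique(b)
    cont = np.array([[(np.logical_and(a == x, b == y)).sum() for y in ub]
                     for x in ua])
    sum_comb = sum(comb(int(nij), 2) for nij in cont.ravel())
    sum_a = sum(comb(int(ni), 2) for ni in cont.sum(axis=1))
    sum_b = sum(comb(int(nj), 2) for nj in cont.sum(axis=0))
    n = comb(len(a), 2)
    expected = sum_a * sum_b / n
    max_index = (sum_a + sum_b) / 2
    return (sum_comb - expected) / (max_index - expected)


class TestSweep:
    def test_ari_oracle_agreement_and_label_invariance(self):
        a = [1, 1, 1, 2, 2, 2]
        b = [1, 1, 2, 2, 3, 3]
        assert adjusted_rand_score(a, b) == pytest.approx(ari_oracle(a, b),
                                                          abs=1e-12)
        assert adjusted_rand_score([1, 1, 2, 2], [2, 2, 1, 1]) == 1.0

    def test_identical_grid_points_have_unit_ari(self):
        d, truth = block_dissimilarity([20, 20], jitter=0.02, seed=7)
        ids = [f"g{i}" for i in range(40)]
        rng = np.random.default_rng(8)
        expr = ExpressionMatrix(pd.DataFrame(
            rng.normal(size=(40, 20)), index=ids,
            columns=[f"s{j}" for j in range(20)]))
        params = CutParams(min_module_size=5)
        report = hyperparameter_sweep(expr, d, [params, params])
        assert report.ari_matrix[0, 1] == pytest.approx(1.0)

    def test_default_grid_varies_all_four_hyperparameters(self):
        grid = default_sweep_grid()
        assert len({p.deep_split for p in grid}) > 1
        assert len({p.min_module_size for p in grid}) > 1
        assert len({p.merge_threshold for p in grid}) > 1
        assert len({p.pam_stage for p in grid}) > 1

    def test_empty_grid_rejected(self):
        d, _ = block_dissimilarity([10, 10])
        ids = [f"g{i}" for i in range(20)]
        expr = ExpressionMatrix(pd.DataFrame(
            np.random.default_rng(0).normal(size=(20, 10)), index=ids,
            columns=[f"s{j}" for j in range(10)]))
        with pytest.raises(ValueError):
            hyperparameter_sweep(expr, d, [])
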