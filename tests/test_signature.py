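import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from coexmod import (ExpressionMatrix, GeneSetCollection, ModulePartition,
                     make_validation_cohort, ora_hypergeometric,
                     paired_de_test, rank_candidates, signature_score,
                     simulate_dataset, validate_signature)
from coexmod.module_detect import gene_module_stats, module_eigengenes
from conftest import small_spec


def make_expr(vals, prefix="g"):
    ids = [f"{prefix}{i:04d}" for i in range(vals.shape[0])]
    return ExpressionMatrix(pd.DataFrame(
        vals, index=ids, columns=[f"s{j:03d}" for j in range(vals.shape[1])]))


class TestSignatureScore:
    def test_extreme_rank_placement_hits_exact_bounds(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(100, 5))
        expr = make_expr(vals)
        order = expr.data.rank(axis=0)
        top = list(order.index[np.argsort(-order.iloc[:, 0].to_numpy())[:10]])
        # force the same 10 genes to occupy the top ranks in every sample
        vals2 = vals.copy()
        idx = [expr.gene_ids.index(g) for g in top]
        vals2[idx] = 100.0 + np.arange(10)[:, None]
        expr2 = make_expr(vals2)
        assert signature_score(expr2, top).scores.eq(1.0).all()
        vals2[idx] = -100.0 - np.arange(10)[:, None]
        expr3 = make_expr(vals2)
        assert signature_score(expr3, top).scores.eq(0.0).all()

    def test_bitwise_invariance_under_per_sample_monotone_transforms(self):
        rng = np.random.default_rng(1)
        expr = make_expr(rng.normal(size=(200, 8)))
        sig = list(rng.choice(expr.gene_ids, 19, replace=False))
        base = signature_score(expr, sig).scores.round(12)
        transformed = expr.data.copy()
        transformed.iloc[:, 0] = np.exp(transformed.iloc[:, 0])
        transformed.iloc[:, 1] = transformed.iloc[:, 1] ** 3
        transformed.iloc[:, 2] = 5 * transformed.iloc[:, 2] - 7
        warped = signature_score(ExpressionMatrix(transformed), sig)
        assert (warped.scores.round(12) == base).all()

    def test_random_signature_on_null_data_centers_at_half(self):
        means = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            expr = make_expr(rng.normal(size=(2000, 100)))
            sig = list(rng.choice(expr.gene_ids, 19, replace=False))
            means.append(signature_score(expr, sig).scores.mean())
        assert np.mean(means) == pytest.approx(0.5, abs=0.05)

    def test_absent_genes_logged_and_all_absent_is_error(self):
        rng = np.random.default_rng(2)
        expr = make_expr(rng.normal(size=(50, 5)))
        sc = signature_score(expr, [expr.gene_ids[0], "NOT_THERE"])
        assert sc.n_genes_used == 1 and sc.n_genes_missing == 1
        with pytest.raises(ValueError):
            signature_score(expr, ["NOPE1", "NOPE2"])

    def test_signature_covering_all_genes_is_degenerate(self):
        rng = np.random.default_rng(3)
        expr = make_expr(rng.normal(size=(10, 5)))
        with pytest.raises(ValueError):
            signature_score(expr, list(expr.gene_ids))


class TestValidateSignature:
    def test_identical_signature_has_unit_correlation(self):
        rng = np.random.default_rng(4)
        expr = make_expr(rng.normal(size=(300, 30)))
        sig = list(rng.choice(expr.gene_ids, 20, replace=False))
        table = validate_signature(expr, {1: sig}, sig)
        assert table.loc[1, "R"] == pytest.approx(1.0)

    def test_module_sharing_latent_factor_ranks_first(self):
        wins = 0
        n_seeds = 10
        for s in range(n_seeds):
            spec = small_spec(seed=400 + s,
                              module_sizes=(50, 40), rho=(0.64, 0.6),
                              rho_jitter=0.2,
                              driver_plan=((1, 0.5),),
                              candidate_plan=(1, 0.6, 0.3, 0.0))
            base = simulate_dataset(spec)
            val = make_validation_cohort(spec, base, 60, distort=True)
            hubs = {q: [g for g in base.expr.gene_ids
                        if g.startswith(f"M{q}-")][:25] for q in (1, 2)}
            reference = [g for g in base.expr.gene_ids
                         if g.startswith("M1-")][25:44]  # same factor as hubs 1
            table = validate_signature(val.expr, hubs, reference)
            wins += int(table.index[table["rank"] == 1][0] == 1)
        assert wins >= 0.9 * n_seeds


@pytest.fixture(scope="module")
def analyzed():
    ds = simulate_dataset(small_spec(
        seed=21, module_sizes=(60,), rho=(0.7,), rho_jitter=0.3,
        driver_plan=((1, -0.7),), candidate_plan=(1, 0.9, -0.7, 0.3),
        de_targets="candidate_and_module"))
    from coexmod import NetworkConfig, adjacency, correlation_matrix
    cor = correlation_matrix(ds.expr)
    adj = adjacency(cor, NetworkConfig())
    me = module_eigengenes(ds.expr, ds.truth)
    stats = gene_module_stats(ds.expr, ds.truth, adj, me)
    return ds, stats


class TestRankCandidates:

    def test_ineligible_genes_sit_below_eligible_block(self, analyzed):
        ds, stats = analyzed
        table = rank_candidates(ds.expr, ds.truth, stats, 1, ds.driver_gene)
        n_el = int(table["eligible"].sum())
        assert (table["final_rank"].iloc[:n_el] <= n_el).all()
        assert not table["top_n"][~table["eligible"]].any()
        assert sorted(table["final_rank"]) == list(range(1, len(table) + 1))

    def test_driver_excluded_from_its_own_module(self, analyzed):
        ds, stats = analyzed
        table = rank_candidates(ds.expr, ds.truth, stats, 1, ds.driver_gene)
        assert ds.driver_gene not in table.index

    def test_invariant_to_gene_order_and_positive_rescaling(self, analyzed):
        ds, stats = analyzed
        t1 = rank_candidates(ds.expr, ds.truth, stats, 1, ds.driver_gene)
        # shuffle gene order
        rng = np.random.default_rng(0)
        order = list(rng.permutation(ds.expr.gene_ids))
        expr2 = ds.expr.subset_genes(order)
        part2 = ModulePartition(order, [
            dict(zip(ds.truth.gene_ids, ds.truth.labels))[g] for g in order])
        t2 = rank_candidates(expr2, part2, stats, 1, ds.driver_gene)
        assert (t1.sort_index()["final_rank"] ==
                t2.sort_index()["final_rank"]).all()
        # positive per-gene rescaling of expression
        df3 = ds.expr.data * 2.0 + 1.0
        t3 = rank_candidates(ExpressionMatrix(df3), ds.truth, stats, 1,
                             ds.driver_gene)
        assert (t1["final_rank"] == t3["final_rank"]).all()

    def test_n_larger_than_eligible_flags_all_eligible(self, analyzed):
        ds, stats = analyzed
        table = rank_candidates(ds.expr, ds.truth, stats, 1, ds.driver_gene,
                                N=10_000)
        assert int(table["top_n"].sum()) == int(table["eligible"].sum())

    def test_most_members_anticorrelate_in_emulated_scenario(self, analyzed):
        # the planted module anti-correlates with the driver, mirroring a
        # selection where ~85% of top candidates pass the negative screen
        ds, stats = analyzed
        table = rank_candidates(ds.expr, ds.truth, stats, 1, ds.driver_gene,
                                N=47)
        by_hub = table.sort_values("hub_rank").head(47)
        assert by_hub["eligible"].mean() >= 0.8


class TestPairedDeTest:
    def _toy(self, diffs):
        k = len(diffs)
        ctrl = np.linspace(5, 6, k)
        case = ctrl + np.asarray(diffs)
        vals = np.stack([np.concatenate([ctrl, case]),
                         np.concatenate([ctrl, ctrl])])
        ids = ["gDiff", "gSame"]
        samples = [f"c{i}" for i in range(k)] + [f"t{i}" for i in range(k)]
        expr = ExpressionMatrix(pd.DataFrame(vals, index=ids, columns=samples))
        traits = pd.DataFrame({
            "condition": [0] * k + [1] * k,
            "pair": list(range(k)) + list(range(k)),
        }, index=samples)
        from coexmod.data_io import TraitTable
        return expr, TraitTable(traits)

    def test_matches_closed_form_and_scipy(self):
        diffs = [1.0, 1.2, 0.8, 1.1, 0.9]
        expr, traits = self._toy(diffs)
        out = paired_de_test(expr, traits, ["gDiff"])
        d = np.asarray(diffs)
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert out.loc["gDiff", "t"] == pytest.approx(t_expected, abs=1e-12)
        t_sp, p_sp = ss.ttest_rel(d + 1, np.ones(5))
        assert out.loc["gDiff", "t"] == pytest.approx(t_sp, abs=1e-10)
        assert out.loc["gDiff", "p"] == pytest.approx(p_sp, abs=1e-10)

    def test_swapping_conditions_negates_t(self):
        expr, traits = self._toy([0.5, 0.7, 0.6, 0.9])
        out = paired_de_test(expr, traits, ["gDiff"])
        flipped = traits.data.copy()
        flipped["condition"] = 1 - flipped["condition"]
        from coexmod.data_io import TraitTable
        out2 = paired_de_test(expr, TraitTable(flipped), ["gDiff"])
        assert out2.loc["gDiff", "t"] == pytest.approx(-out.loc["gDiff", "t"])
        assert out2.loc["gDiff", "p"] == pytest.approx(out.loc["gDiff", "p"])

    def test_degenerate_cases_flagged(self):
        expr, traits = self._toy([0.0, 0.0, 0.0, 0.0])
        out = paired_de_test(expr, traits)
        assert out.loc["gSame", "p"] == 1.0
        assert out.loc["gSame", "flag"] == "degenerate"
        expr2, traits2 = self._toy([0.4, 0.4, 0.4, 0.4])
        out2 = paired_de_test(expr2, traits2, ["gDiff"])
        assert np.isinf(out2.loc["gDiff", "t"])
        assert out2.loc["gDiff", "flag"] == "infinite_t"


def bh_oracle(p):
    """Step-up Benjamini-Hochberg written out directly."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestOra:
    def test_full_overlap_p_matches_exhaustive_enumeration(self):
        import itertools
        universe = [f"g{i}" for i in range(20)]
        geneset = universe[:5]
        sets = GeneSetCollection({"hit": list(geneset)})
        out = ora_hypergeometric(list(geneset), sets, universe)
        assert out.loc["hit", "p"] == pytest.approx(1.0 / 15504.0, rel=1e-12)
        count = sum(1 for draw in itertools.combinations(universe, 5)
                    if len(set(draw) & set(geneset)) >= 5)
        total = sum(1 for _ in itertools.combinations(universe, 5))
        assert count / total == pytest.approx(1.0 / 15504.0, rel=1e-12)

    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(30)]
        sets = GeneSetCollection({"disjoint": universe[20:25]})
        out = ora_hypergeometric(universe[:5], sets, universe)
        assert out.loc["disjoint", "p"] == pytest.approx(1.0)

    def test_equal_p_values_share_equal_bh_q(self):
        universe = [f"g{i}" for i in range(40)]
        sets = GeneSetCollection({f"s{k}": universe[k * 5:k * 5 + 5]
                                  for k in range(3)})
        out = ora_hypergeometric(universe[:5] + universe[5:7], sets, universe)
        # BH oracle cross-check on the computed p-vector
        np.testing.assert_allclose(out["q"], bh_oracle(out["p"]), atol=1e-12)

    def test_bh_matches_stepup_oracle_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(6)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(3, 40))
            np.testing.assert_allclose(multipletests(p, method="fdr_bh")[1],
                                       bh_oracle(p), atol=1e-12)

    def test_empty_universe_is_an_error(self):
        with pytest.raises(ValueError):
            ora_hypergeometric(["g1"], GeneSetCollection({"s": ["g1"]}), [])
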