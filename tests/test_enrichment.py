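"""Running-sum enrichment score, permutation GSEA and over-representation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncarray import (
    enrichment_score,
    gsea_permutation,
    overrepresentation_test,
    rank_genes,
)


def _ranked(n, seed=0):
    rng = np.random.default_rng(seed)
    metric = np.sort(rng.normal(0, 1, n))[::-1]
    return pd.Series(metric, index=[f"g{i}" for i in range(n)])


class TestRankGenes:
    def _expr(self, rng, n_genes=30, n_per_group=5):
        cols = [f"lo{i}" for i in range(n_per_group)] + [f"hi{i}" for i in range(n_per_group)]
        X = pd.DataFrame(
            rng.normal(0, 1, (n_genes, 2 * n_per_group)),
            index=[f"g{i}" for i in range(n_genes)], columns=cols,
        )
        labels = pd.Series(["low"] * n_per_group + ["high"] * n_per_group, index=cols)
        return X, labels

    def test_equal_means_give_zero_metric(self):
        X = pd.DataFrame(
            [[1.0, 2.0, 3.0, 1.0, 2.0, 3.0], [5.0, 4.0, 3.0, 2.0, 1.0, 0.0]],
            index=["flat", "other"],
            columns=[f"s{i}" for i in range(6)],
        )
        labels = pd.Series(["low"] * 3 + ["high"] * 3, index=X.columns)
        r = rank_genes(X, labels)
        assert r["flat"] == pytest.approx(0.0)

    def test_label_swap_negates_and_reverses(self):
        rng = np.random.default_rng(1)
        X, labels = self._expr(rng)
        r1 = rank_genes(X, labels)
        r2 = rank_genes(X, labels.map({"low": "high", "high": "low"}))
        assert list(r1.index) == list(r2.index[::-1])
        np.testing.assert_allclose(r1.to_numpy(), -r2.to_numpy()[::-1], rtol=1e-12)

    def test_planted_up_gene_ranks_first(self):
        """A gene shifted +2 at sd 0.5 tops 500 null genes in >= 95% of replicates."""
        firsts = 0
        for rep in range(40):
            rng = np.random.default_rng(1000 + rep)
            X, labels = self._expr(rng, n_genes=501, n_per_group=10)
            X.iloc[0] = np.where(labels == "high", 2.0, 0.0) + rng.normal(0, 0.5, 20)
            firsts += rank_genes(X, labels).index[0] == "g0"
        assert firsts >= 38

    def test_degenerate_inputs_error(self):
        X = pd.DataFrame(np.ones((5, 8)), columns=[f"s{i}" for i in range(8)])
        labels = pd.Series(["low"] * 4 + ["high"] * 4, index=X.columns)
        with pytest.raises(ValueError, match="degenerate"):
            rank_genes(X, labels)
        with pytest.raises(ValueError, match="3 samples"):
            rank_genes(X, pd.Series(["low"] * 2 + ["high"] * 6, index=X.columns))


class TestEnrichmentScore:
    def test_hand_example_top_two_of_five(self):
        """N=5, set = top 2 ranks, weight 0: running sum (.5, 1, 2/3, 1/3, 0)."""
        ranked = _ranked(5)
        out = enrichment_score(ranked, {"g0", "g1"}, weight=0.0, min_set_size=1)
        np.testing.assert_allclose(
            out["running_sum"], [0.5, 1.0, 2 / 3, 1 / 3, 0.0], atol=1e-12
        )
        assert out["es"] == pytest.approx(1.0)
        assert out["leading_edge"] == ["g0", "g1"]

    def test_top_k_set_unweighted_closed_form(self):
        """Set = top k of N at weight 0: every hit precedes every miss, so the
        unweighted running sum climbs to exactly 1 at position k (closed form:
        cumulative hit mass i/k with zero miss mass) and decays afterwards."""
        n, k = 200, 12
        ranked = _ranked(n)
        out = enrichment_score(ranked, {f"g{i}" for i in range(k)}, weight=0.0)
        assert out["es"] == pytest.approx(1.0)  # no miss seen before the peak
        assert int(np.argmax(out["running_sum"])) == k - 1

    def test_whole_universe_set_is_null_at_weight_zero(self):
        ranked = _ranked(30)
        out = enrichment_score(ranked, set(ranked.index), weight=0.0)
        assert out["es"] == pytest.approx(0.0, abs=1e-12)

    def test_running_sum_ends_at_zero(self):
        rng = np.random.default_rng(2)
        ranked = _ranked(300, seed=3)
        gene_set = set(rng.choice(ranked.index.to_numpy(), 40, replace=False))
        for w in (0.0, 1.0, 1.5):
            out = enrichment_score(ranked, gene_set, weight=w)
            assert abs(out["running_sum"][-1]) < 1e-9
            assert abs(out["es"]) <= 1.0 + 1e-12

    def test_weight_zero_invariant_to_monotone_metric_transform(self):
        rng = np.random.default_rng(4)
        ranked = _ranked(100, seed=5)
        gene_set = set(rng.choice(ranked.index.to_numpy(), 15, replace=False))
        a = enrichment_score(ranked, gene_set, weight=0.0)
        transformed = pd.Series(np.exp(ranked.to_numpy() / 2), index=ranked.index)
        b = enrichment_score(transformed, gene_set, weight=0.0)
        assert a["es"] == pytest.approx(b["es"], rel=1e-12)

    def test_negative_es_leading_edge_is_tail(self):
        ranked = _ranked(50, seed=6)
        bottom = {f"g{i}" for i in range(44, 50)}
        out = enrichment_score(ranked, bottom, weight=0.0)
        assert out["es"] < 0
        assert set(out["leading_edge"]) <= bottom

    def test_empty_intersection_and_small_sets_error(self):
        ranked = _ranked(20)
        with pytest.raises(ValueError, match="intersection"):
            enrichment_score(ranked, {"absent"}, min_set_size=1)
        with pytest.raises(ValueError, match="min_set_size"):
            enrichment_score(ranked, {"g0", "g1"}, min_set_size=5)


class TestGseaPermutation:
    def _study(self, rng, n_genes=120, n_per_group=8, planted=None):
        cols = [f"lo{i}" for i in range(n_per_group)] + [f"hi{i}" for i in range(n_per_group)]
        X = pd.DataFrame(
            rng.normal(0, 1, (n_genes, 2 * n_per_group)),
            index=[f"g{i}" for i in range(n_genes)], columns=cols,
        )
        labels = pd.Series(["low"] * n_per_group + ["high"] * n_per_group, index=cols)
        if planted:
            X.loc[planted] += np.where(labels == "high", 1.2, 0.0)
        return X, labels

    def test_seeded_runs_are_bit_reproducible(self):
        rng = np.random.default_rng(7)
        X, labels = self._study(rng)
        sets = {f"S{i}": set(np.random.default_rng(i).choice(X.index, 12, replace=False))
                for i in range(4)}
        r1 = gsea_permutation(X, labels, sets, n_perm=100, seed=5)
        r2 = gsea_permutation(X, labels, sets, n_perm=100, seed=5)
        assert [(a.set_name, a.es, a.nes, a.p_perm, a.q_value) for a in r1] == [
            (a.set_name, a.es, a.nes, a.p_perm, a.q_value) for a in r2
        ]

    def test_p_perm_never_zero_and_bounded(self):
        rng = np.random.default_rng(8)
        planted = [f"g{i}" for i in range(15)]
        X, labels = self._study(rng, planted=planted)
        res = gsea_permutation(X, labels, {"planted": set(planted)}, n_perm=100, seed=1)
        assert 0 < res[0].p_perm <= 1
        assert res[0].p_perm >= 1 / 101

    def test_planted_coordinated_set_attains_smallest_q(self):
        rng = np.random.default_rng(9)
        planted = [f"g{i}" for i in range(30)]
        X, labels = self._study(rng, n_genes=300, planted=planted)
        sets = {"planted": set(planted)}
        for i in range(12):
            sets[f"rand{i}"] = set(
                np.random.default_rng(50 + i).choice(X.index[30:], 30, replace=False)
            )
        res = gsea_permutation(X, labels, sets, n_perm=200, seed=2)
        best = min(res, key=lambda r: (r.q_value, r.p_perm))
        assert best.set_name == "planted"
        assert best.es > 0

    def test_permutation_cap_warns(self):
        rng = np.random.default_rng(10)
        X, labels = self._study(rng, n_genes=40, n_per_group=4)  # C(8,4)=70 < 100
        with pytest.warns(UserWarning, match="capping"):
            gsea_permutation(X, labels, {"s": set(X.index[:10])}, n_perm=100, seed=3)

    def test_constant_expression_is_degenerate(self):
        X = pd.DataFrame(np.ones((30, 12)), index=[f"g{i}" for i in range(30)],
                         columns=[f"s{i}" for i in range(12)])
        labels = pd.Series(["low"] * 6 + ["high"] * 6, index=X.columns)
        with pytest.raises(ValueError):
            gsea_permutation(X, labels, {"s": set(X.index[:10])}, n_perm=100, seed=4)


class TestOverrepresentation:
    def test_disjoint_query_has_p_one(self):
        universe = [f"g{i}" for i in range(100)]
        collection = {"s": set(universe[:20])}
        res = overrepresentation_test(universe[50:60], collection, universe)
        assert res.loc[0, "overlap"] == 0
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_fully_contained_query_minimum_tail(self):
        universe = [f"g{i}" for i in range(1000)]
        k = 6
        collection = {"s": set(universe[:k])}
        res = overrepresentation_test(universe[:k], collection, universe)
        assert res.loc[0, "p_value"] == pytest.approx(1.0 / math.comb(1000, k), rel=1e-9)

    def test_matches_exhaustive_enumeration_small_universe(self):
        """Hypergeometric p equals brute-force enumeration over all possible
        overlaps for universes of <= 50 genes."""
        rng = np.random.default_rng(11)
        universe = [f"g{i}" for i in range(50)]
        for rep in range(20):
            set_genes = set(rng.choice(universe, int(rng.integers(5, 25)), replace=False))
            query = list(rng.choice(universe, int(rng.integers(3, 20)), replace=False))
            res = overrepresentation_test(query, {"s": set_genes}, universe)
            observed = len(set_genes & set(query))
            m, n, q = len(universe), len(set_genes), len(query)
            brute = sum(
                math.comb(n, j) * math.comb(m - n, q - j) / math.comb(m, q)
                for j in range(observed, min(n, q) + 1)
            )
            assert res.loc[0, "p_value"] == pytest.approx(brute, rel=1e-9)

    def test_query_outside_universe_or_empty_errors(self):
        universe = ["a", "b", "c", "d", "e"]
        with pytest.raises(ValueError):
            overrepresentation_test([], {"s": {"a"}}, universe)
        with pytest.raises(ValueError):
            overrepresentation_test(["z"], {"s": {"a"}}, universe)

    def test_bh_q_across_sets(self):
        universe = [f"g{i}" for i in range(60)]
        collection = {f"s{i}": set(universe[i : i + 12]) for i in range(0, 36, 12)}
        res = overrepresentation_test(universe[:12], collection, universe)
        assert (res["q_value"] >= res["p_value"] - 1e-12).all()
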