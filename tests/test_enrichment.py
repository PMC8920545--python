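from math import comb

import numpy as np
import pandas as pd
import pytest

from osteoscreen import (
    hypergeometric_ora,
    make_annotation_fixture,
    preranked_gsea,
    simulate_timecourse,
)
from osteoscreen.enrichment import hypergeometric_tail_p
from osteoscreen.io_formats import GeneSetCollection


def brute_force_hypergeom_tail(k, K, n, N):
    """Exact tail enumeration with integer combinatorics."""
    total = comb(N, n)
    return sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)) / total


class TestHypergeometricOra:
    def test_query_equals_universe_gives_p_one(self):
        genes = [f"G{i}" for i in range(6)]
        result = hypergeometric_ora(genes, genes, {"T": genes})
        assert result.iloc[0]["p"] == pytest.approx(1.0)

    def test_closed_form_minimum_p(self):
        """N=20, K=5, n=5, k=5: p = 1/C(20,5)."""
        universe = [f"G{i}" for i in range(20)]
        term = universe[:5]
        result = hypergeometric_ora(term, universe, {"T": term})
        assert result.iloc[0]["p"] == pytest.approx(1 / comb(20, 5), rel=1e-12)

    def test_tail_matches_enumeration_small_universes(self):
        for N in range(2, 12):
            for K in range(1, N + 1):
                for n in range(1, N + 1):
                    for k in range(max(0, n + K - N), min(K, n) + 1):
                        assert hypergeometric_tail_p(k, K, n, N) == pytest.approx(
                            brute_force_hypergeom_tail(k, K, n, N), abs=1e-12
                        )

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="not in universe"):
            hypergeometric_ora(["X"], ["A", "B"], {"T": ["A"]})

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_ora([], ["A"], {"T": ["A"]})

    def test_planted_term_ranks_first_on_synthetic_truth(self, small_config,
                                                         small_dataset):
        truth = small_dataset[4]
        expr = small_dataset[0]
        annotation = make_annotation_fixture(small_config, truth)
        result = hypergeometric_ora(
            truth.true_up_genes, list(expr.index), annotation
        )
        assert result.iloc[0]["term"] == "SYN_OSSIFICATION_LIKE"


def brute_force_gsea_es(genes, stats, members, weight=1.0):
    """Position-by-position running sum; returns the signed max deviation."""
    n = len(genes)
    hits = [g in members for g in genes]
    k = sum(hits)
    denom = sum(abs(s) ** weight for g, s in zip(genes, stats) if g in members)
    running, best = 0.0, 0.0
    for g, s, h in zip(genes, stats, hits):
        if h:
            running += abs(s) ** weight / denom
        else:
            running -= 1.0 / (n - k)
        if abs(running) > abs(best):
            best = running
    return best


def _ranked(genes, stats):
    return pd.DataFrame({"gene": genes, "stat": stats})


class TestPrerankedGsea:
    def test_top_block_matches_brute_force(self):
        genes = [f"G{i}" for i in range(10)]
        stats = [5, 4, 3, 2, 1, -1, -2, -3, -4, -5]
        members = set(genes[:3])
        coll = GeneSetCollection(sets={"TOP": sorted(members)})
        result = preranked_gsea(_ranked(genes, stats), coll, nperm=200, seed=1)
        expected = brute_force_gsea_es(genes, stats, members)
        assert result.iloc[0]["es"] == pytest.approx(expected, abs=1e-12)
        assert expected > 0

    def test_bottom_block_has_negative_es(self):
        genes = [f"G{i}" for i in range(10)]
        stats = [5, 4, 3, 2, 1, -1, -2, -3, -4, -5]
        coll = GeneSetCollection(sets={"BOTTOM": genes[-3:]})
        result = preranked_gsea(_ranked(genes, stats), coll, nperm=200, seed=1)
        assert result.iloc[0]["es"] < 0

    def test_es_bounded_and_p_floor(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(40)]
        stats = sorted(rng.normal(size=40), reverse=True)
        coll = GeneSetCollection(sets={"S": genes[5:15]})
        result = preranked_gsea(_ranked(genes, stats), coll, nperm=200, seed=2)
        assert -1.0 <= result.iloc[0]["es"] <= 1.0
        assert result.iloc[0]["p"] >= 1 / 201

    def test_scaling_stats_leaves_es_unchanged(self):
        rng = np.random.default_rng(1)
        genes = [f"G{i}" for i in range(30)]
        stats = sorted(rng.normal(size=30), reverse=True)
        coll = GeneSetCollection(sets={"S": genes[::4]})
        r1 = preranked_gsea(_ranked(genes, stats), coll, nperm=100, seed=3)
        r2 = preranked_gsea(
            _ranked(genes, [s * 7.5 for s in stats]), coll, nperm=100, seed=3
        )
        assert r1.iloc[0]["es"] == pytest.approx(r2.iloc[0]["es"], abs=1e-12)
        assert r1.iloc[0]["p"] == r2.iloc[0]["p"]

    def test_unweighted_mode_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(2)
        genes = [f"G{i}" for i in range(30)]
        stats = np.sort(rng.normal(size=30))[::-1]
        coll = GeneSetCollection(sets={"S": genes[2:12]})
        r1 = preranked_gsea(_ranked(genes, stats), coll, nperm=100, seed=4,
                            weight=0.0)
        r2 = preranked_gsea(_ranked(genes, np.exp(stats)), coll, nperm=100,
                            seed=4, weight=0.0)
        assert r1.iloc[0]["es"] == pytest.approx(r2.iloc[0]["es"], abs=1e-12)

    def test_bit_reproducible_under_seed(self):
        rng = np.random.default_rng(5)
        genes = [f"G{i}" for i in range(50)]
        stats = sorted(rng.normal(size=50), reverse=True)
        coll = GeneSetCollection(
            sets={"A": genes[:10], "B": genes[20:30], "C": genes[40:]}
        )
        r1 = preranked_gsea(_ranked(genes, stats), coll, nperm=300, seed=42)
        r2 = preranked_gsea(_ranked(genes, stats), coll, nperm=300, seed=42)
        pd.testing.assert_frame_equal(r1, r2)

    def test_small_nperm_warns(self):
        genes = [f"G{i}" for i in range(10)]
        coll = GeneSetCollection(sets={"S": genes[:4]})
        with pytest.warns(UserWarning, match="nperm"):
            preranked_gsea(_ranked(genes, range(10, 0, -1)), coll, nperm=50,
                           seed=0)

    def test_nonfinite_stat_rejected(self):
        genes = ["A", "B", "C", "D"]
        coll = GeneSetCollection(sets={"S": genes[:3]})
        with pytest.raises(ValueError, match="finite"):
            preranked_gsea(_ranked(genes, [1.0, np.nan, 0.5, 0.1]), coll,
                           nperm=100, seed=0)
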