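import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from osteoscreen import ssgsea_scores, stage_median_scores
from osteoscreen.io_formats import GeneSetCollection


def brute_force_ssgsea_es(values, gene_ids, members, alpha):
    """Term-by-term running sum, independent of the implementation:
    walk the expression-sorted list, accumulate weighted in-set CDF minus
    out-of-set ECDF, return the total."""
    n = len(values)
    ranks = rankdata(values)
    order = sorted(range(n), key=lambda i: (-values[i], gene_ids[i]))
    in_set = [gene_ids[i] in members for i in order]
    k = sum(in_set)
    wsum = sum(ranks[i] ** alpha for i in order if gene_ids[i] in members)
    es = 0.0
    p_in = p_out = 0.0
    for pos, i in enumerate(order):
        if in_set[pos]:
            p_in += ranks[i] ** alpha / wsum
        else:
            p_out += 1.0 / (n - k)
        es += p_in - p_out
    return es


def _collection(**sets):
    return GeneSetCollection(sets={k: list(v) for k, v in sets.items()})


class TestSsgseaScores:
    def test_contrasting_samples_have_opposite_signs(self):
        genes = [f"G{i}" for i in range(8)]
        # sample A: set members on top; sample B: members at the bottom
        a = [10, 9, 8, 7, 4, 3, 2, 1]
        b = [1, 2, 3, 4, 7, 8, 9, 10]
        expr = pd.DataFrame({"A": a, "B": b}, index=genes, dtype=float)
        coll = _collection(S=genes[:4])
        scores = ssgsea_scores(expr, coll, normalize=False)
        assert scores.loc["S", "A"] > 0 > scores.loc["S", "B"]

    def test_set_covering_all_genes_dropped(self, toy_expr):
        coll = _collection(ALL=list(toy_expr.index), OK=list(toy_expr.index[:4]))
        with pytest.warns(UserWarning, match="ALL"):
            scores = ssgsea_scores(toy_expr, coll)
        assert list(scores.index) == ["OK"]

    def test_small_overlap_dropped_and_empty_result_is_error(self, toy_expr):
        coll = _collection(TINY=["T00", "T01"])
        with pytest.raises(ValueError, match="no gene set"):
            with pytest.warns(UserWarning, match="TINY"):
                ssgsea_scores(toy_expr, coll, min_overlap=3)

    def test_matches_brute_force_running_sum(self):
        """10-gene single-sample instance agrees with an independent
        term-by-term evaluation to 1e-12."""
        rng = np.random.default_rng(3)
        genes = [f"G{i}" for i in range(10)]
        values = rng.normal(8, 2, size=10)
        members = {"G1", "G4", "G7"}
        expr = pd.DataFrame({"S": values}, index=genes)
        coll = _collection(SET=sorted(members))
        scores = ssgsea_scores(expr, coll, alpha=0.25, normalize=False)
        expected = brute_force_ssgsea_es(values, genes, members, alpha=0.25)
        assert scores.loc["SET", "S"] == pytest.approx(expected, abs=1e-12)

    def test_monotone_transform_invariance(self, toy_expr):
        """Scores depend on ranks only."""
        coll = _collection(S=list(toy_expr.index[2:7]))
        s1 = ssgsea_scores(toy_expr, coll, normalize=False)
        s2 = ssgsea_scores(np.exp(toy_expr / 4.0), coll, normalize=False)
        pd.testing.assert_frame_equal(s1, s2)

    def test_unrelated_gene_does_not_flip_decisive_sign(self):
        """Growing the universe by a gene outside every set leaves the sign
        of a clearly enriched (or depleted) set unchanged."""
        genes = [f"G{i}" for i in range(9)]
        expr = pd.DataFrame(
            {"A": np.arange(9, 0, -1, dtype=float),
             "B": np.arange(1, 10, dtype=float)},
            index=genes,
        )
        coll = _collection(S=genes[:4])
        base = ssgsea_scores(expr, coll, normalize=False)
        extra = expr.copy()
        extra.loc["EXTRA"] = [5.5, 5.5]
        grown = ssgsea_scores(extra, coll, normalize=False)
        assert (np.sign(base) == np.sign(grown)).all().all()

    def test_random_set_scores_center_near_zero_unweighted(self):
        """Unweighted (alpha = 0) scores of random sets over random
        matrices center near zero relative to the score range; with rank
        weighting the integrated statistic is intentionally top-sensitive
        and carries a positive offset, so the symmetry argument applies to
        alpha = 0 only."""
        rng = np.random.default_rng(12)
        means = []
        for _ in range(40):
            genes = [f"G{i}" for i in range(60)]
            expr = pd.DataFrame(
                rng.normal(8, 1, size=(60, 6)), index=genes,
                columns=[f"S{j}" for j in range(6)],
            )
            sets = {
                f"R{k}": list(rng.choice(genes, size=10, replace=False))
                for k in range(5)
            }
            scores = ssgsea_scores(expr, GeneSetCollection(sets=sets),
                                   alpha=0.0, normalize=False)
            span = scores.to_numpy().max() - scores.to_numpy().min()
            if span > 0:
                means.append(scores.to_numpy().mean() / span)
        assert abs(np.mean(means)) < 0.05

    def test_normalization_divides_by_span(self, toy_expr):
        coll = _collection(A=list(toy_expr.index[:4]), B=list(toy_expr.index[4:8]))
        raw = ssgsea_scores(toy_expr, coll, normalize=False)
        norm = ssgsea_scores(toy_expr, coll, normalize=True)
        span = raw.to_numpy().max() - raw.to_numpy().min()
        assert np.allclose(norm.to_numpy(), raw.to_numpy() / span)


class TestStageMedians:
    def _meta(self, samples, days):
        return pd.DataFrame(
            {
                "group": ["control" if d == 0 else "induced" for d in days],
                "day": days,
                "batch": "b1",
            },
            index=samples,
        )

    def test_single_sample_stage_is_identity(self):
        scores = pd.DataFrame([[0.1, 0.5, 0.9]], index=["S"],
                              columns=["a", "b", "c"])
        meta = self._meta(["a", "b", "c"], [0, 1, 3])
        med = stage_median_scores(scores, meta)
        assert list(med.columns) == [0, 1, 3]
        assert med.loc["S", 1] == 0.5

    def test_constant_scores_give_constant_medians(self):
        scores = pd.DataFrame(0.25, index=["S"], columns=list("abcd"))
        meta = self._meta(list("abcd"), [0, 0, 3, 3])
        med = stage_median_scores(scores, meta)
        assert (med.loc["S"] == 0.25).all()

    def test_increasing_module_medians_rise(self, small_merged):
        """The planted increasing module's stage medians are monotone
        non-decreasing up to at most one noise inversion."""
        expr, meta, coll = small_merged[0], small_merged[1], small_merged[2]
        truth = small_merged[4]
        scores = ssgsea_scores(expr, coll)
        med = stage_median_scores(scores, meta).loc[truth.regulator_module]
        inversions = (np.diff(med.to_numpy()) < 0).sum()
        assert inversions <= 1
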