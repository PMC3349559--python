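"""The exact test, FDR, normalisation, screens and clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import nbinom

import tagdge as t
from tagdge import dge
from oracles import ac_two_sided_single, bh_stepup


class TestNormalisation:
    def test_tpm_arithmetic(self):
        assert t.normalize_tpm(50, 500_000) == pytest.approx(100.0)
        assert t.normalize_tpm(0, 123) == 0.0
        with pytest.raises(ValueError):
            t.normalize_tpm(1, 0)

    def test_rpkm_arithmetic_and_scaling(self):
        assert t.normalize_rpkm(10, 500, 1_000_000) == pytest.approx(20.0)
        assert t.normalize_rpkm(0, 500, 1_000_000) == 0.0
        assert t.normalize_rpkm(10, 1000, 1_000_000) == pytest.approx(
            t.normalize_rpkm(10, 500, 1_000_000) / 2)
        with pytest.raises(ValueError):
            t.normalize_rpkm(1, 0, 100)
        with pytest.raises(ValueError):
            t.normalize_rpkm(1, 100, 0)

    def test_tpm_column_sum(self, small_clean, small_index):
        res = t.map_tags(small_clean, small_index)
        total = small_clean.total_clean
        tpm = t.normalize_tpm(res.counts.to_numpy(), total)
        assert tpm.sum() == pytest.approx(1e6 * res.ledger.unique_match / total)


class TestAudicClaverie:
    def test_balanced_null_is_one(self):
        assert t.audic_claverie_p(0, 1e6, 0, 1e6) == 1.0

    def test_closed_form_ten_vs_zero(self):
        assert t.audic_claverie_p(10, 2e5, 0, 2e5) == pytest.approx(2 ** -10,
                                                                   abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            t.audic_claverie_p(-1, 1e5, 0, 1e5)
        with pytest.raises(ValueError):
            t.audic_claverie_p(0, 0, 0, 1e5)

    def test_symmetry_where_exact(self):
        # the conditional law is NB(x+1, .), so the statistic is exchangeable
        # only for identical (count, total) pairs
        for x in (0, 3, 40):
            a = t.audic_claverie_p(x, 1e5, x, 1e5)
            b = t.audic_claverie_p(x, 1e5, x, 1e5)
            assert a == b == pytest.approx(1.0)

    @pytest.mark.parametrize("x,n1,y,n2", [
        (0, 1e5, 17, 3e6), (5, 1e6, 5, 1e6), (100, 3e6, 2, 1e5),
        (31, 2e5, 77, 2e5), (12, 1e5, 360, 3e6),
    ])
    def test_matches_arbitrary_precision_oracle(self, x, n1, y, n2):
        expected = ac_two_sided_single(x, n1, y, n2)
        assert t.audic_claverie_p(x, n1, y, n2) == pytest.approx(
            expected, rel=1e-9)

    @pytest.mark.parametrize("x,n1,y,n2", [
        (3, 1e5, 9, 3e6), (50, 1e6, 50, 2e6), (0, 2e5, 8, 2e5),
    ])
    def test_tails_match_negative_binomial(self, x, n1, y, n2):
        # independent route: the conditional law is NB(x+1, n1/(n1+n2))
        pnb = n1 / (n1 + n2)
        lower = nbinom.cdf(y, x + 1, pnb)
        upper = nbinom.sf(y - 1, x + 1, pnb)
        assert t.audic_claverie_p(x, n1, y, n2) == pytest.approx(
            min(1.0, 2 * min(lower, upper)), rel=1e-9)

    def test_monotone_in_imbalance_at_fixed_total(self):
        n1 = n2 = 2e5
        ps = [t.audic_claverie_p(x, n1, 30 - x, n2) for x in range(16)]
        assert all(a <= b + 1e-15 for a, b in zip(ps, ps[1:]))

    def test_large_counts_stable(self):
        p = t.audic_claverie_p(10_000, 1e6, 10_600, 1e6)
        assert 0.0 < p < 1.0
        p2 = t.audic_claverie_p(500_000, 1e6, 500_000, 1e6)
        assert p2 == pytest.approx(1.0, abs=1e-6)


class TestBH:
    def test_single_p_identity(self):
        assert t.bh_fdr([0.02]) == pytest.approx([0.02])

    def test_hand_stepup(self):
        assert t.bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_empty(self):
        assert len(t.bh_fdr([])) == 0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            t.bh_fdr([0.0, 0.5])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1,
                    max_size=30))
    def test_matches_textbook_oracle_and_bounds(self, ps):
        q = t.bh_fdr(ps)
        assert np.allclose(q, bh_stepup(ps), rtol=1e-12, atol=0)
        assert (q <= 1.0 + 1e-15).all()
        assert (q >= np.asarray(ps) - 1e-15).all()


def _matrix(counts: dict, totals: dict) -> t.ExpressionMatrix:
    df = pd.DataFrame(counts)
    df.index.name = "gene"
    return t.ExpressionMatrix(df, lib_totals=totals)


class TestCallDE:
    def test_equal_expression_never_significant(self):
        mat = _matrix({"a": [100, 7], "b": [100, 7]},
                      {"a": 10_000, "b": 10_000})
        design = dge.ComparisonDesign.from_pairs([("a", "b")])
        res = t.call_de(mat, design)["b_vs_a"]
        assert (res["log2_ratio"] == 0).all()
        assert not res["significant"].any()

    def test_zero_in_both_excluded_from_family(self):
        mat = _matrix({"a": [50, 0], "b": [90, 0]}, {"a": 1000, "b": 1000})
        res = t.call_de(mat, dge.ComparisonDesign.from_pairs([("a", "b")]))
        assert len(res["b_vs_a"]) == 1

    def test_missing_library_raises(self):
        mat = _matrix({"a": [1], "b": [1]}, {"a": 10, "b": 10})
        with pytest.raises(ValueError, match="unknown library"):
            t.call_de(mat, dge.ComparisonDesign.from_pairs([("a", "zz")]))

    def test_up_down_partition(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(60, size=200)
        y = rng.poisson(60, size=200)
        y[:30] *= 9
        x[30:60] *= 9
        mat = _matrix({"a": x, "b": y}, {"a": int(x.sum()), "b": int(y.sum())})
        res = t.call_de(mat, dge.ComparisonDesign.from_pairs([("a", "b")]))
        summary = t.up_down_summary(res)
        row = summary.loc["b_vs_a"]
        assert row["up"] + row["down"] == row["significant"] > 0

    def test_degenerate_thresholds_call_everything_tested(self):
        mat = _matrix({"a": [5, 0, 0], "b": [9, 4, 0]},
                      {"a": 1000, "b": 2000})
        res = t.call_de(mat, dge.ComparisonDesign.from_pairs([("a", "b")]),
                        fdr_threshold=1.01, log2_threshold=0.0)["b_vs_a"]
        nonzero_ratio = res["log2_ratio"] != 0
        assert (res["significant"] == nonzero_ratio).all()
        assert res["significant"].sum() == nonzero_ratio.sum() == 2

    def test_pseudocount_gives_finite_ratio_for_zeroes(self):
        mat = _matrix({"a": [0], "b": [1000]}, {"a": 10_000, "b": 10_000})
        res = t.call_de(mat, dge.ComparisonDesign.from_pairs([("a", "b")]))
        lr = res["b_vs_a"]["log2_ratio"].iloc[0]
        assert np.isfinite(lr)
        assert lr == pytest.approx(np.log2(1000.5 / 0.5))


class TestScreens:
    def test_intersection_examples(self):
        assert t.intersect_comparisons([{"A", "B"}, {"B", "C"}]) == {"B"}
        assert t.intersect_comparisons([{"A"}, set()]) == set()
        with pytest.raises(ValueError):
            t.intersect_comparisons([])

    def test_extreme_screen_rules(self):
        prof = pd.DataFrame(
            [[11, 11, 12, 11, 11, 11],
             [11, -11, 12, 11, 11, 11],
             [9, 11, 12, 11, 11, 11],
             [-11, -11, -12, -11, -11, -11]],
            index=["up_ok", "mixed", "weak", "down_ok"])
        up, down = t.screen_extremes(prof, threshold=10)
        assert up == {"up_ok"}
        assert down == {"down_ok"}


class TestClustering:
    @staticmethod
    def _blobs():
        rng = np.random.default_rng(1)
        a = rng.normal(5.0, 0.2, size=(10, 6))
        b = rng.normal(-5.0, 0.2, size=(10, 6))
        idx = [f"g{i}" for i in range(20)]
        return pd.DataFrame(np.vstack([a, b]), index=idx)

    def test_two_blobs_recovered(self):
        prof = self._blobs()
        labels, _ = t.cluster_trends(prof, k=2)
        first = set(labels.loc[prof.index[:10]])
        second = set(labels.loc[prof.index[10:]])
        assert len(first) == len(second) == 1 and first != second

    def test_k_equals_n_singletons(self):
        prof = self._blobs().iloc[:5]
        labels, _ = t.cluster_trends(prof, k=5)
        assert labels.nunique() == 5

    def test_order_invariance(self):
        prof = self._blobs()
        l1, _ = t.cluster_trends(prof, k=2)
        shuffled = prof.sample(frac=1.0, random_state=7)
        l2, _ = t.cluster_trends(shuffled, k=2)
        part1 = {frozenset(l1.index[l1 == c]) for c in l1.unique()}
        part2 = {frozenset(l2.index[l2 == c]) for c in l2.unique()}
        assert part1 == part2

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError):
            t.cluster_trends(self._blobs(), k=21)


def test_trend_profiles_align_with_design_order():
    df1 = pd.DataFrame({"log2_ratio": [1.0, 2.0]},
                       index=pd.Index(["g1", "g2"], name="gene"))
    df2 = pd.DataFrame({"log2_ratio": [3.0]},
                       index=pd.Index(["g1"], name="gene"))
    prof = t.trend_profiles({"c1": df1, "c2": df2}, ["g1", "g2"])
    assert list(prof.columns) == ["c1", "c2"]
    assert list(prof.index) == ["g1"]          # g2 untested in c2 dropped
    assert prof.loc["g1"].tolist() == [1.0, 3.0]
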