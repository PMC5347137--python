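from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import exact_hypergeom_tail, permutation_ranksum_p
from nmdpipe import expression_analysis as ea


def make_expr(n, rng=None, contrast="daf2_vs_wt"):
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame(
        {
            "transcript_id": [f"t{i}" for i in range(n)],
            "gene_id": [f"g{i}" for i in range(n)],
            "status": "OK",
            "fpkm_wt": rng.uniform(1, 100, n),
            "fpkm_daf2": rng.uniform(1, 100, n),
            f"log2fc_{contrast}": rng.normal(0, 1, n),
            f"p_{contrast}": rng.uniform(0, 1, n),
        }
    )


class TestComputeFpkm:
    def test_unit_definition(self):
        assert ea.compute_fpkm(100, 1000, 1_000_000) == pytest.approx(100.0)

    def test_zero_count(self):
        assert ea.compute_fpkm(0, 500, 1_000_000) == 0.0

    def test_scale_invariance(self):
        a = ea.compute_fpkm(100, 1000, 1_000_000)
        b = ea.compute_fpkm(200, 1000, 2_000_000)
        assert a == pytest.approx(b)

    @pytest.mark.parametrize("length,total", [(0, 1e6), (1000, 0)])
    def test_zero_denominators_error(self, length, total):
        with pytest.raises(ValueError):
            ea.compute_fpkm(10, length, total)


class TestFilterExpression:
    def test_bad_status_removed(self):
        df = make_expr(4)
        df.loc[1, "status"] = "NOTEST"
        df.loc[2, "status"] = "HIDATA"
        out = ea.filter_expression(df)
        assert set(out["transcript_id"]) == {"t0", "t3"}

    def test_zero_fpkm_removed(self):
        df = make_expr(3)
        df.loc[0, "fpkm_daf2"] = 0.0
        out = ea.filter_expression(df)
        assert "t0" not in set(out["transcript_id"])

    def test_clean_table_identity(self):
        df = make_expr(5)
        assert len(ea.filter_expression(df)) == 5

    def test_missing_status_errors(self):
        with pytest.raises(ValueError):
            ea.filter_expression(make_expr(2).drop(columns=["status"]))


class TestClassifyDe:
    def test_boundaries_inclusive(self):
        df = make_expr(1)
        df["log2fc_daf2_vs_wt"] = [-1.0]
        df["p_daf2_vs_wt"] = [0.10]
        out = ea.classify_de(df, "daf2_vs_wt")
        assert out["de_class"].tolist() == ["down"]

    def test_moderate_fc_unchanged_at_default(self):
        df = make_expr(1)
        df["log2fc_daf2_vs_wt"] = [-0.5]
        df["p_daf2_vs_wt"] = [0.01]
        assert ea.classify_de(df, "daf2_vs_wt")["de_class"].tolist() == ["unchanged"]

    def test_relaxed_threshold_calls_down(self):
        df = make_expr(1)
        df["log2fc_daf2_vs_wt"] = [-0.5]
        df["p_daf2_vs_wt"] = [0.01]
        out = ea.classify_de(df, "daf2_vs_wt", fc_threshold=ea.GO_INPUT_FC_THRESHOLD)
        assert out["de_class"].tolist() == ["down"]

    def test_up_symmetric(self):
        df = make_expr(1)
        df["log2fc_daf2_vs_wt"] = [1.0]
        df["p_daf2_vs_wt"] = [0.10]
        assert ea.classify_de(df, "daf2_vs_wt")["de_class"].tolist() == ["up"]

    def test_missing_contrast_errors(self):
        with pytest.raises(KeyError):
            ea.classify_de(make_expr(2), "nope")

    def test_threshold_monotonicity(self):
        # relaxing the fold-change cut never shrinks the down set
        df = make_expr(500, np.random.default_rng(7))
        strict = ea.classify_de(df, "daf2_vs_wt", fc_threshold=1.0)
        relaxed = ea.classify_de(df, "daf2_vs_wt", fc_threshold=0.4)
        strict_down = set(strict.loc[strict["de_class"] == "down", "transcript_id"])
        relaxed_down = set(relaxed.loc[relaxed["de_class"] == "down", "transcript_id"])
        assert strict_down <= relaxed_down


class TestChi2FractionTest:
    def test_frozen_value(self):
        # Pearson chi-square, no continuity correction, computed independently
        # with scipy.stats.chi2_contingency during development
        chi2, p = ea.chi2_fraction_test([[30, 70], [10, 190]])
        assert chi2 == pytest.approx(36.06, abs=0.01)
        assert p < 1e-8

    def test_equal_fractions_null(self):
        chi2, p = ea.chi2_fraction_test([[30, 70], [60, 140]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_margin_untestable(self):
        chi2, p = ea.chi2_fraction_test([[0, 70], [0, 190]])
        assert chi2 is None and p is None

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            ea.chi2_fraction_test([[-1, 2], [3, 4]])


def make_feature_tables(n, feat_flags, down_flags):
    de = pd.DataFrame(
        {
            "transcript_id": [f"t{i}" for i in range(n)],
            "contrast": "c",
            "de_class": np.where(down_flags, "down", "unchanged"),
        }
    )
    features = pd.DataFrame(
        {"transcript_id": [f"t{i}" for i in range(n)], "has_ptc": feat_flags}
    )
    return de, features


class TestFeatureFractionTest:
    def test_margins_conserved(self):
        rng = np.random.default_rng(2)
        n = 500
        de, features = make_feature_tables(
            n, rng.random(n) < 0.3, rng.random(n) < 0.2
        )
        res = ea.feature_fraction_test(de, features, "PTC")
        assert sum(sum(row) for row in res.table) == n

    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(3)
        n = 2000
        down = rng.random(n) < 0.2
        feat = np.where(down, rng.random(n) < 0.3, rng.random(n) < 0.1)
        de, features = make_feature_tables(n, feat, down)
        res = ea.feature_fraction_test(de, features, "PTC")
        assert res.p < 0.01
        assert res.fraction_down > res.fraction_other

    def test_unknown_feature_errors(self):
        de, features = make_feature_tables(4, [True] * 4, [False] * 4)
        with pytest.raises(KeyError):
            ea.feature_fraction_test(de, features, "bogus")


class TestRankSum:
    def test_identical_distributions_p_near_one(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 400)
        assert ea.rank_sum_test(x, x.copy()) == pytest.approx(1.0, abs=0.05)

    def test_small_sample_matches_permutation_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.normal(0, 1, 4)
            y = rng.normal(0.5, 1, 4)
            assert ea.rank_sum_test(x, y) == pytest.approx(
                permutation_ranksum_p(x, y), abs=0.05
            )

    def test_shift_detected(self):
        rng = np.random.default_rng(6)
        x = rng.normal(-0.5, 0.5, 300)
        y = rng.normal(0.0, 0.5, 300)
        assert ea.rank_sum_test(x, y) < 0.01


class TestUtr3FoldchangeTest:
    @staticmethod
    def _tables(shift_long=0.0, n=300, seed=0):
        rng = np.random.default_rng(seed)
        cats = np.repeat(["short", "medium", "long"], n)
        fc = rng.normal(0, 0.5, 3 * n)
        fc[cats == "long"] += shift_long
        df = pd.DataFrame(
            {
                "transcript_id": [f"t{i}" for i in range(3 * n)],
                "log2fc_daf2_vs_wt": fc,
                "p_daf2_vs_wt": 0.5,
            }
        )
        features = pd.DataFrame(
            {"transcript_id": df["transcript_id"], "utr3_category": cats}
        )
        return df, features

    def test_identical_distributions(self):
        df, features = self._tables()
        res = ea.utr3_foldchange_test(df, features, "daf2_vs_wt")
        assert res["p_values"]["long_vs_short"] > 0.05

    def test_shifted_long_detected(self):
        df, features = self._tables(shift_long=-0.5)
        res = ea.utr3_foldchange_test(df, features, "daf2_vs_wt")
        assert res["p_values"]["long_vs_short"] < 0.01
        assert res["median_log2fc"]["long"] < res["median_log2fc"]["short"]

    def test_small_category_skipped(self):
        df, features = self._tables(n=2)
        features.loc[features["utr3_category"] == "long", "utr3_category"] = "medium"
        features.iloc[-1, features.columns.get_loc("utr3_category")] = "long"
        res = ea.utr3_foldchange_test(df, features, "daf2_vs_wt")
        assert res["p_values"]["long_vs_short"] is None


class TestRestoration:
    @staticmethod
    def _df(log2fc_down, p_down, log2fc_restore):
        n = len(log2fc_down)
        return pd.DataFrame(
            {
                "transcript_id": [f"t{i}" for i in range(n)],
                "log2fc_daf2_vs_wt": log2fc_down,
                "p_daf2_vs_wt": p_down,
                "log2fc_double_vs_daf2": log2fc_restore,
                "p_double_vs_daf2": 0.5,
            }
        )

    def test_positive_restore_called(self):
        df = self._df([-2.0], [0.01], [0.8])
        out = ea.restoration_analysis(df, "daf2_vs_wt", "double_vs_daf2")
        assert bool(out["restored"].iloc[0]) is True

    def test_negative_restore_not_called(self):
        df = self._df([-2.0], [0.01], [-0.2])
        out = ea.restoration_analysis(df, "daf2_vs_wt", "double_vs_daf2")
        assert bool(out["restored"].iloc[0]) is False

    def test_not_down_not_evaluated(self):
        df = self._df([0.5], [0.01], [0.8])
        out = ea.restoration_analysis(df, "daf2_vs_wt", "double_vs_daf2")
        assert pd.isna(out["restored"].iloc[0])

    def test_threshold_configurable(self):
        df = self._df([-2.0], [0.01], [0.3])
        out = ea.restoration_analysis(
            df, "daf2_vs_wt", "double_vs_daf2", restore_threshold=0.4
        )
        assert bool(out["restored"].iloc[0]) is False

    def test_summary_counts(self):
        df = self._df([-2.0, -2.0, 0.0], [0.01, 0.01, 0.5], [0.5, -0.5, 1.0])
        calls = ea.restoration_analysis(df, "daf2_vs_wt", "double_vs_daf2")
        summary = ea.summarize_restoration(calls)
        assert summary.n_down == 2
        assert summary.n_restored == 1
        assert summary.fraction_restored == pytest.approx(0.5)


class TestOverrepresentation:
    def test_frozen_hypergeometric_value(self):
        # exact tail sum computed independently: P(X>=5) for
        # Hypergeom(N=100, K=10, n=10) = 6.716e-4
        universe = [f"g{i}" for i in range(100)]
        term = {"T": universe[:10]}
        target = universe[5:10] + universe[50:55]  # overlap 5
        res = ea.overrepresentation_test(target, term, universe)
        assert res["p_fisher"].iloc[0] == pytest.approx(
            exact_hypergeom_tail(5, 100, 10, 10), rel=1e-9
        )
        assert res["p_fisher"].iloc[0] == pytest.approx(6.716e-4, rel=1e-3)

    def test_ease_with_overlap_one_is_one(self):
        universe = [f"g{i}" for i in range(50)]
        res = ea.overrepresentation_test(
            universe[:1] + universe[30:34], {"T": universe[:10]}, universe
        )
        assert res["overlap"].iloc[0] == 1
        assert res["p_ease"].iloc[0] == pytest.approx(1.0)

    def test_disjoint_term_skipped(self):
        universe = [f"g{i}" for i in range(50)]
        res = ea.overrepresentation_test(
            universe[:5], {"T": universe[40:45]}, universe
        )
        assert len(res) == 0

    def test_ease_ge_fisher_property(self):
        rng = np.random.default_rng(8)
        universe = [f"g{i}" for i in range(300)]
        target = list(rng.choice(universe, size=40, replace=False))
        term_map = {
            f"T{j}": list(rng.choice(universe, size=rng.integers(5, 60), replace=False))
            for j in range(25)
        }
        res = ea.overrepresentation_test(target, term_map, universe)
        assert (res["p_ease"] >= res["p_fisher"] - 1e-12).all()

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            ea.overrepresentation_test(["a"], {"T": ["a"]}, [])

    def test_sorted_by_ease(self):
        rng = np.random.default_rng(9)
        universe = [f"g{i}" for i in range(200)]
        target = universe[:30]
        term_map = {f"T{j}": list(rng.choice(universe, size=20, replace=False))
                    for j in range(10)}
        res = ea.overrepresentation_test(target, term_map, universe)
        assert res["p_ease"].is_monotonic_increasing


class TestSetOverlap:
    def test_identical_sets(self):
        universe = [f"g{i}" for i in range(1000)]
        a = universe[:20]
        k, fold, p = ea.set_overlap_test(a, a, universe)
        assert k == 20
        assert p < 1e-30
        assert p == pytest.approx(exact_hypergeom_tail(20, 1000, 20, 20), rel=1e-6)

    def test_disjoint_sets(self):
        universe = [f"g{i}" for i in range(100)]
        k, fold, p = ea.set_overlap_test(universe[:10], universe[50:60], universe)
        assert k == 0
        assert p == pytest.approx(1.0)

    def test_empty_set(self):
        universe = [f"g{i}" for i in range(100)]
        k, fold, p = ea.set_overlap_test([], universe[:10], universe)
        assert (k, fold, p) == (0, None, 1.0)

    def test_independent_sets_fold_near_one(self):
        rng = np.random.default_rng(10)
        universe = [f"g{i}" for i in range(500)]
        folds = []
        for _ in range(500):
            a = rng.choice(universe, size=60, replace=False)
            b = rng.choice(universe, size=60, replace=False)
            _, fold, _ = ea.set_overlap_test(a, b, universe)
            folds.append(fold)
        assert np.mean(folds) == pytest.approx(1.0, abs=0.1)


@given(st.integers(1, 30), st.integers(1, 30), st.integers(0, 30))
@settings(max_examples=100, deadline=None)
def test_hypergeom_tail_matches_exact_summation(term_size, target_size, overlap):
    N = 60
    k = min(overlap, term_size, target_size)
    assert ea.hypergeom_tail(k, N, term_size, target_size) == pytest.approx(
        exact_hypergeom_tail(k, N, term_size, target_size), rel=1e-9
    )
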