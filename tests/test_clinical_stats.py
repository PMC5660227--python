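"""ROC machinery, marker combination, group tests and survival analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import serumpeaks as sp
from serumpeaks.exceptions import ParameterError


def pair_counting_auc(neg, pos):
    """Oracle: concordant pairs / all pairs, ties counted one half."""
    wins = ties = 0
    for a in neg:
        for b in pos:
            if b > a:
                wins += 1
            elif b == a:
                ties += 1
    return (wins + 0.5 * ties) / (len(neg) * len(pos))


def _roc(neg, pos, **kw):
    scores = np.concatenate([neg, pos])
    labels = np.r_[np.zeros(len(neg), int), np.ones(len(pos), int)]
    return sp.roc_analysis(scores, labels, **kw)


class TestRocAnalysis:
    def test_perfect_separation_cutoff_at_midpoint(self):
        res = _roc([1.0, 2.0], [3.0, 4.0])
        assert res.auc == 1.0
        assert res.youden_cutoff == pytest.approx(2.5)
        assert res.youden == pytest.approx(1.0)

    def test_interleaved_scores(self):
        res = _roc([1.0, 3.0], [2.0, 4.0])
        assert res.auc == pytest.approx(0.75)

    def test_tied_score_counts_half(self):
        res = _roc([1.0, 2.0], [2.0, 3.0])
        assert res.auc == pytest.approx(0.875)

    @pytest.mark.parametrize("seed", range(10))
    def test_auc_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        neg = rng.integers(0, 12, rng.integers(3, 12)).astype(float)
        pos = rng.integers(2, 14, rng.integers(3, 12)).astype(float)
        if np.ptp(np.concatenate([neg, pos])) == 0:
            pos = pos + 1
        res = _roc(neg, pos)
        assert res.auc == pytest.approx(pair_counting_auc(neg, pos), abs=1e-12)

    def test_negated_scores_with_flipped_orientation_identical_auc(self):
        rng = np.random.default_rng(3)
        neg, pos = rng.normal(0, 1, 30), rng.normal(1, 1, 40)
        a = _roc(neg, pos, positive_high=True)
        b = _roc(-neg, -pos, positive_high=False)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)

    def test_curve_monotone_and_ci_contains_auc(self):
        rng = np.random.default_rng(4)
        res = _roc(rng.normal(0, 1, 50), rng.normal(1, 1, 50))
        assert np.all(np.diff(res.tpr) >= 0)
        assert np.all(np.diff(res.fpr) >= 0)
        lo, hi = res.auc_ci_95
        assert lo <= res.auc <= hi

    def test_binormal_limit(self):
        # scores N(0,1) vs N(2,1): AUC -> Phi(2/sqrt(2)) = 0.9214
        rng = np.random.default_rng(11)
        res = _roc(rng.normal(0, 1, 2000), rng.normal(2, 1, 2000))
        assert abs(res.auc - norm.cdf(2 / np.sqrt(2))) < 0.02

    def test_equal_variance_cutoff_converges_to_mean_midpoint(self):
        rng = np.random.default_rng(12)
        res = _roc(rng.normal(0, 1, 2000), rng.normal(2, 1, 2000))
        assert res.youden_cutoff == pytest.approx(1.0, abs=0.15)

    def test_one_class_only_rejected(self):
        with pytest.raises(ParameterError):
            sp.roc_analysis(np.arange(5.0), np.ones(5, int))

    def test_constant_scores_rejected(self):
        with pytest.raises(ParameterError):
            sp.roc_analysis(np.ones(6), np.r_[np.zeros(3, int), np.ones(3, int)])


class TestCombineMarkers:
    def test_single_feature_combination_equals_feature_roc(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 1, 40), rng.normal(1.5, 1, 40)])
        y = np.r_[np.zeros(40, int), np.ones(40, int)]
        _, combined = sp.combine_markers(pd.DataFrame({"x": x}), y)
        single = sp.roc_analysis(x, y)
        assert combined.auc == pytest.approx(single.auc, abs=1e-12)

    def test_two_informative_features_combine_at_least_as_well(self):
        rng = np.random.default_rng(1)
        n = 250
        y = np.r_[np.zeros(n, int), np.ones(n, int)]
        a = np.concatenate([rng.normal(0, 1, n), rng.normal(1, 1, n)])
        b = np.concatenate([rng.normal(0, 1, n), rng.normal(1, 1, n)])
        _, combined = sp.combine_markers(pd.DataFrame({"a": a, "b": b}), y)
        best_single = max(sp.roc_analysis(a, y).auc, sp.roc_analysis(b, y).auc)
        assert combined.auc >= best_single - 0.02

    def test_constant_feature_dropped_with_remaining_used(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 1, 30), rng.normal(2, 1, 30)])
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        df = pd.DataFrame({"x": x, "c": np.ones(60)})
        _, combined = sp.combine_markers(df, y)
        assert combined.auc == pytest.approx(sp.roc_analysis(x, y).auc, abs=1e-12)

    def test_perfect_separation_falls_back_to_ridge(self):
        x = np.concatenate([np.zeros(20), np.ones(20) * 10.0])
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        scores, combined = sp.combine_markers(pd.DataFrame({"x": x}), y)
        assert combined.auc == 1.0
        assert np.all(np.isfinite(scores))

    def test_missing_rows_dropped(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 1, 25), rng.normal(2, 1, 25)])
        x[3] = np.nan
        y = np.r_[np.zeros(25, int), np.ones(25, int)]
        scores, _ = sp.combine_markers(pd.DataFrame({"x": x}), y)
        assert len(scores) == 49


class TestGroupCompare:
    def test_null_permutations_rarely_significant(self):
        # ~5% of permuted-label runs cross p<0.05 (two-sided t test)
        rng = np.random.default_rng(0)
        values = rng.normal(10, 2, 40)
        hits = 0
        for _ in range(200):
            labels = rng.permutation(["a"] * 20 + ["b"] * 20)
            _, p = sp.group_compare(values, labels, "t_test")
            hits += p < 0.05
        assert hits <= 25  # binomial(200, 0.05) upper tail

    def test_equal_constant_groups_give_p_one(self):
        stat, p = sp.group_compare(
            np.full(8, 3.0), ["a"] * 4 + ["b"] * 4, "t_test"
        )
        assert (stat, p) == (0.0, 1.0)

    def test_constant_unequal_groups_rejected(self):
        with pytest.raises(ParameterError):
            sp.group_compare(
                np.r_[np.ones(4), np.full(4, 2.0)], ["a"] * 4 + ["b"] * 4, "t_test"
            )

    def test_anova_matches_hand_computed_fixture(self):
        # groups (1,2,3), (2,3,4), (6,7,8): grand mean 4; SSB = 3*(2-4)^2 +
        # 3*(3-4)^2 + 3*(7-4)^2 = 42; SSW = 6; F = (42/2)/(6/6) = 21
        values = np.array([1.0, 2, 3, 2, 3, 4, 6, 7, 8])
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        f, p = sp.group_compare(values, labels, "anova")
        assert f == pytest.approx(21.0)
        assert 0 < p < 0.01

    def test_welch_differs_from_student_under_unequal_variance(self):
        rng = np.random.default_rng(5)
        v = np.concatenate([rng.normal(0, 0.1, 10), rng.normal(1, 3.0, 30)])
        labels = ["a"] * 10 + ["b"] * 30
        t1, _ = sp.group_compare(v, labels, "t_test")
        t2, _ = sp.group_compare(v, labels, "welch")
        assert t1 != t2


class TestDichotomize:
    def test_perfectly_ordered_expression_reproduces_outcome_partition(self):
        expression = np.arange(1.0, 11.0)
        outcome = (expression <= 5).astype(int)  # low expression -> death
        cutoff, groups = sp.dichotomize_by_outcome_roc(expression, outcome)
        assert cutoff == pytest.approx(5.5)
        assert list(groups) == ["low"] * 5 + ["high"] * 5

    def test_planted_cutoff_recovered_within_one_gap(self):
        df = sp.generate_survival(n=46, cutoff_truth=500.0, hazard_ratio=8.0,
                                  censor_rate=0.0, seed=42)
        dead5y = ((df["time"] < 60) & (df["event"] == 1)).astype(int)
        cutoff, _ = sp.dichotomize_by_outcome_roc(df["expression"], dead5y)
        expr = np.sort(df["expression"].to_numpy())
        below = expr[expr < 500.0]
        above = expr[expr >= 500.0]
        lo = below[-2] if len(below) >= 2 else expr[0]
        hi = above[1] if len(above) >= 2 else expr[-1]
        assert lo <= cutoff <= hi

    def test_constant_expression_rejected(self):
        with pytest.raises(ParameterError):
            sp.dichotomize_by_outcome_roc(np.ones(10), np.r_[np.zeros(5), np.ones(5)])


def hand_logrank(records):
    """Oracle: textbook log-rank table over distinct event times."""
    times = sorted(records.loc[records["event"] == 1, "time"].unique())
    O = E = V = 0.0
    for t in times:
        at_risk = records["time"] >= t
        n = at_risk.sum()
        n1 = (at_risk & (records["group"] == "A")).sum()
        d = ((records["time"] == t) & (records["event"] == 1)).sum()
        d1 = (
            (records["time"] == t) & (records["event"] == 1) & (records["group"] == "A")
        ).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestKmLogrank:
    def test_identical_groups_give_null_statistic(self):
        df = pd.DataFrame(
            {
                "time": [3.0, 5.0, 8.0, 3.0, 5.0, 8.0],
                "event": [1, 0, 1, 1, 0, 1],
                "group": ["A"] * 3 + ["B"] * 3,
            }
        )
        _, chi2, p = sp.km_logrank(df)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_record_worked_example_matches_hand_table(self):
        df = pd.DataFrame(
            {
                "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "event": [1, 1, 1, 1, 1, 1],
                "group": ["A", "A", "A", "B", "B", "B"],
            }
        )
        curves, chi2, p = sp.km_logrank(df)
        assert chi2 == pytest.approx(hand_logrank(df), abs=1e-9)
        assert 0 < p < 1

    def test_km_without_censoring_equals_empirical_survival(self):
        times = np.array([2.0, 4.0, 4.0, 7.0, 9.0])
        df = pd.DataFrame(
            {
                "time": np.concatenate([times, [1.0, 2.0]]),
                "event": 1,
                "group": ["A"] * 5 + ["B"] * 2,
            }
        )
        curves, _, _ = sp.km_logrank(df)
        km = curves["A"]
        for t in times:
            expected = (times > t).mean()
            got = float(km.loc[km.index == t].iloc[-1, 0])
            assert got == pytest.approx(expected)

    def test_all_censored_rejected(self):
        df = pd.DataFrame(
            {"time": [1.0, 2.0, 3.0, 4.0], "event": 0, "group": ["A", "A", "B", "B"]}
        )
        with pytest.raises(ParameterError):
            sp.km_logrank(df)
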