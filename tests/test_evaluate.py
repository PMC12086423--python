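import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cgmstaging import (
    confusion_stats,
    group_compare,
    km_estimate,
    logrank,
    offset_correlations,
    repeatability_report,
    roc,
)
from cgmstaging.classify import ThresholdSet


def brute_force_auc(scores, labels):
    """Concordant pairs + half ties, over all case/control pairs."""
    cases = [s for s, l in zip(scores, labels) if l]
    ctrls = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for c in cases:
        for d in ctrls:
            total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(ctrls))


class TestConfusionStats:
    def test_progression_worked_example(self):
        # 11 progressors of whom 9 flagged; 18 flagged in total (9 fp)
        outcomes = [True] * 11 + [False] * 53
        flags = [True] * 9 + [False] * 2 + [True] * 9 + [False] * 44
        cs = confusion_stats(flags, outcomes)
        assert (cs.tp, cs.fp, cs.fn) == (9, 9, 2)
        assert cs.rounded()["sensitivity"] == 82
        assert cs.rounded()["ppv"] == 50

    def test_all_flagged_all_positive(self):
        cs = confusion_stats([True] * 5, [True] * 5)
        assert cs.rounded()["sensitivity"] == 100
        assert cs.rounded()["ppv"] == 100
        assert cs.specificity is None  # no negatives: undefined, not zero

    def test_random_vectors_match_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            f = rng.random(30) < 0.4
            o = rng.random(30) < 0.3
            cs = confusion_stats(f, o)
            tp = sum(1 for a, b in zip(f, o) if a and b)
            fp = sum(1 for a, b in zip(f, o) if a and not b)
            fn = sum(1 for a, b in zip(f, o) if not a and b)
            tn = sum(1 for a, b in zip(f, o) if not a and not b)
            assert (cs.tp, cs.fp, cs.fn, cs.tn) == (tp, fp, fn, tn)

    def test_ratios_recompute_from_counts(self):
        cs = confusion_stats([True, True, False, False], [True, False, True, False])
        assert cs.sensitivity == 100.0 * cs.tp / (cs.tp + cs.fn)
        assert cs.ppv == 100.0 * cs.tp / (cs.tp + cs.fp)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_stats([True], [True, False])


class TestROC:
    def test_perfect_separation(self):
        r = roc([1, 2, 3, 10, 11, 12], [False] * 3 + [True] * 3)
        assert r.auc == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(1)
        s = rng.random(2000)
        y = rng.random(2000) < 0.5
        assert abs(roc(s, y).auc - 0.5) < 0.05

    def test_toy_set_with_tie_matches_pair_counting(self):
        scores = [1.0, 2.0, 2.0, 3.0, 4.0, 4.0]
        labels = [False, False, True, False, True, True]
        r = roc(scores, labels)
        assert r.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_curve_is_monotone(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=100) + np.where(rng.random(100) < 0.5, 1.0, 0.0)
        y = rng.random(100) < 0.5
        r = roc(s, y)
        assert (np.diff(r.sensitivity) >= 0).all()
        assert (np.diff(r.one_minus_specificity) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc([1.0, 2.0], [True, True])


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_cdf(self):
        rng = np.random.default_rng(7)
        times = rng.exponential(2.0, 40)
        km = km_estimate(times, [True] * 40, horizon=1.0)
        assert km.risk_pct == pytest.approx(100.0 * np.mean(times <= 1.0))

    def test_ten_subjects_two_events_before_horizon(self):
        times = [0.2, 0.7] + [1.2] * 8
        events = [True, True] + [False] * 8
        km = km_estimate(times, events, horizon=1.0)
        assert km.risk_pct == pytest.approx(20.0)

    def test_all_censored_risk_zero(self):
        km = km_estimate([1.0] * 6, [False] * 6, horizon=1.0)
        assert km.risk_pct == 0.0
        assert km.risk_ci == (0.0, 0.0)

    def test_interleaved_censoring_matches_hand_product_limit(self):
        # events at 1 (n=6), 3 (n=4); censored at 2 and 4; late exits at 5
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 5.0]
        events = [True, False, True, False, False, False]
        km = km_estimate(times, events, horizon=4.5)
        s_hand = (1 - 1 / 6) * (1 - 1 / 4)
        assert km.risk_pct == pytest.approx(100 * (1 - s_hand), abs=1e-12)
        # Greenwood variance by hand
        var_hand = s_hand**2 * (1 / (6 * 5) + 1 / (4 * 3))
        half = 1.959963984540054 * 100 * np.sqrt(var_hand)
        assert km.risk_ci == pytest.approx(
            (max(100 * (1 - s_hand) - half, 0.0), 100 * (1 - s_hand) + half)
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [], horizon=1.0)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        g = ([1.0, 2.0, 3.0], [True, False, True])
        stat, p = logrank([g, g])
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_extreme_difference(self):
        g1 = ([0.1] * 10, [True] * 10)
        g2 = ([5.0] * 10, [False] * 10)
        stat, p = logrank([g1, g2])
        assert p < 0.001

    def test_eight_subject_example_matches_hand_computation(self):
        # group A: events at 1, 2; censored 3.  group B: events at 2, 4; more.
        a = ([1.0, 2.0, 3.0, 4.0], [True, True, False, False])
        b = ([2.0, 3.0, 4.0, 5.0], [True, False, True, False])
        stat, p = logrank([a, b])
        # hand computation with scipy for the chi-square tail only
        # event time 1: n=8 (4,4), d=1, E_a = 4/8
        # event time 2: n=7 (3,4), d=2, E_a = 2*3/7, var per standard formula
        o_a = 2.0
        e_a = 4 / 8 + 2 * 3 / 7 + 0 * 2 / 5 + 1 * 1 / 3
        v = (
            1 * (4 / 8) * (1 - 4 / 8) * (8 - 1) / (8 - 1)
            + 2 * (3 / 7) * (1 - 3 / 7) * (7 - 2) / (7 - 1)
            + 1 * (1 / 3) * (1 - 1 / 3) * (3 - 1) / (3 - 1)
        )
        expect = (o_a - e_a) ** 2 / v
        assert stat == pytest.approx(expect, rel=1e-9)
        assert p == pytest.approx(1 - stats.chi2.cdf(expect, 1), rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank([([1.0], [True]), ([], [])])


class TestGroupCompare:
    def test_identical_groups_give_p_one(self):
        df = pd.DataFrame({"m": np.tile([1.0, 2.0, 3.0, 4.0], 5)})
        out = group_compare({"a": df, "b": df.copy()}, numeric_cols=["m"])
        assert out.loc[0, "p_a_vs_b"] > 0.95

    def test_strongly_shifted_groups_significant(self):
        rng = np.random.default_rng(3)
        a = pd.DataFrame({"m": rng.normal(0, 1, 50)})
        b = pd.DataFrame({"m": rng.normal(3, 1, 50)})
        out = group_compare({"a": a, "b": b}, numeric_cols=["m"])
        assert out.loc[0, "p_a_vs_b"] < 0.001
        assert out.loc[0, "kruskal_p"] < 0.001

    def test_small_case_matches_exact_rank_sum_enumeration(self):
        x = [1.0, 3.0, 5.0]
        y = [2.0, 4.0, 6.0, 7.0]
        out = group_compare(
            {"a": pd.DataFrame({"m": x}), "b": pd.DataFrame({"m": y})},
            numeric_cols=["m"],
        )
        # exhaustive permutation distribution of the rank-sum statistic
        pooled = x + y
        obs = sum(stats.rankdata(pooled)[: len(x)])
        count = 0
        total = 0
        for combo in itertools.combinations(range(7), 3):
            r = stats.rankdata(pooled)
            s = sum(r[list(combo)])
            total += 1
            if abs(s - 12.0) >= abs(obs - 12.0) - 1e-12:  # 12 = mean rank sum
                count += 1
        exact_p = count / total
        assert out.loc[0, "p_a_vs_b"] == pytest.approx(exact_p, abs=0.02)

    def test_p_values_invariant_to_group_order(self):
        rng = np.random.default_rng(4)
        a = pd.DataFrame({"m": rng.normal(0, 1, 20)})
        b = pd.DataFrame({"m": rng.normal(1, 1, 20)})
        p1 = group_compare({"a": a, "b": b}, ["m"]).loc[0, "p_a_vs_b"]
        p2 = group_compare({"b": b, "a": a}, ["m"]).loc[0, "p_b_vs_a"]
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_categorical_counts_and_test(self):
        a = pd.DataFrame({"sex": ["male"] * 8 + ["female"] * 12})
        b = pd.DataFrame({"sex": ["male"] * 14 + ["female"] * 6})
        out = group_compare({"a": a, "b": b}, numeric_cols=[], categorical_cols=["sex"])
        assert out.loc[0, "kind"] == "categorical"
        assert 0 < out.loc[0, "p_a_vs_b"] < 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare({"a": pd.DataFrame({"m": [1.0]}), "b": pd.DataFrame()})


class TestOffsetCorrelations:
    def test_exactly_linear_pairs(self):
        df = pd.DataFrame(
            {
                "nocturnal_mean": [100.0, 105.0, 110.0, 120.0],
                "ta140": [1.0, 2.0, 3.0, 5.0],
                "sd_glucose": [16.0, 17.0, 18.0, 20.0],
                "cv": [14.0, 15.0, 16.0, 18.0],
            }
        )
        out = offset_correlations(df).set_index("metric")
        assert out.loc["ta140", "r"] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {
                "nocturnal_mean": rng.normal(106, 8, 2000),
                "ta140": rng.uniform(0, 30, 2000),
                "sd_glucose": rng.normal(16, 2, 2000),
                "cv": rng.normal(14, 2, 2000),
            }
        )
        out = offset_correlations(df)
        assert (out["r"].abs() < 0.08).all()

    def test_ten_row_table_matches_closed_form_pearson(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            {
                "nocturnal_mean": rng.normal(106, 8, 10),
                "ta140": rng.uniform(0, 30, 10),
                "sd_glucose": rng.normal(16, 2, 10),
                "cv": rng.normal(14, 2, 10),
            }
        )
        out = offset_correlations(df).set_index("metric")
        x = df["nocturnal_mean"].to_numpy()
        for m in ("ta140", "sd_glucose", "cv"):
            y = df[m].to_numpy()
            r_hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
                np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
            )
            assert out.loc[m, "r"] == pytest.approx(r_hand, rel=1e-12)

    def test_too_few_rows_and_constant_column_rejected(self):
        df = pd.DataFrame({"nocturnal_mean": [1.0, 2.0], "ta140": [1.0, 2.0],
                           "sd_glucose": [1.0, 2.0], "cv": [1.0, 2.0]})
        with pytest.raises(ValueError):
            offset_correlations(df)


THRESHOLDS = ThresholdSet(
    cutoffs={"sd_glucose": 20.0, "ta140": 10.0, "ta160": 5.0, "ta180": 2.0},
    n_controls=10,
)


def paired_rows(deltas):
    """Two sessions per participant, second shifted additively by `deltas`."""
    rows = []
    for i, d in enumerate(deltas):
        base = {
            "participant_id": f"P{i}",
            "mean_glucose": 115.0,
            "nocturnal_mean": 106.0,
            "sd_glucose": 16.0,
            "ta140": 6.0,
            "ta160": 1.0,
            "ta180": 0.2,
        }
        rows.append({**base, "session_id": "1"})
        shifted = dict(base)
        shifted["mean_glucose"] += d
        shifted["nocturnal_mean"] += d
        rows.append({**shifted, "session_id": "2"})
    return pd.DataFrame(rows)


class TestRepeatability:
    def test_identical_pairs_fully_concordant(self):
        table, summary = repeatability_report(paired_rows([0.0, 0.0]), THRESHOLDS)
        assert (table["delta_mean_glucose"] == 0).all()
        assert summary["n_abs_delta_mean_gt_limit"] == 0
        assert summary["any_k_concordance_fraction"] == 1.0

    def test_additive_shift_moves_mean_not_sd(self):
        table, summary = repeatability_report(paired_rows([15.0]), THRESHOLDS)
        assert table.loc[0, "delta_mean_glucose"] == pytest.approx(15.0)
        assert table.loc[0, "delta_sd_glucose"] == 0.0
        assert summary["n_abs_delta_mean_gt_limit"] == 1

    def test_unpaired_input_rejected(self):
        df = paired_rows([0.0]).iloc[:1]
        with pytest.raises(ValueError, match="exactly 2"):
            repeatability_report(df, THRESHOLDS)
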