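import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from seedvigor.stats_eval import (
    DetectionSet,
    EvalInstance,
    ImageEval,
    anova,
    check_assumptions,
    compact_letter_display,
    evaluate_map,
    tukey_hsd,
    validation_regression,
)


class TestAssumptionChecks:
    def test_constant_group_flagged_not_crashed(self):
        groups = {"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = check_assumptions(groups)
        row = report["normality"].set_index("group").loc["a"]
        assert row["constant"]
        assert np.isnan(row["shapiro_p"])

    def test_levene_rejection_rate_near_alpha_under_null(self):
        """Splitting one normal sample into 3 groups: Levene rejects ~5%."""
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 400
        for _ in range(reps):
            x = rng.normal(size=30)
            groups = {"a": x[:10], "b": x[10:20], "c": x[20:]}
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                report = check_assumptions(groups)
            rejections += report["levene_p"] < 0.05
        rate = rejections / reps
        assert 0.015 < rate < 0.09  # ~alpha within 3 binomial SE

    def test_shapiro_power_against_skew(self):
        """Exponential groups of n=30 are rejected far more often than alpha."""
        rng = np.random.default_rng(8)
        rejections = 0
        reps = 200
        for _ in range(reps):
            groups = {"a": rng.exponential(size=30)}
            report = check_assumptions(groups)
            rejections += report["normality"]["shapiro_p"].iloc[0] < 0.05
        assert rejections / reps > 0.5

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            check_assumptions({"a": [1.0, 2.0]})


class TestAnova:
    def test_hand_computed_balanced_two_way(self):
        """2x2 with 2 replicates per cell, worked by hand:
        SS_A=32, SS_B=8, SS_AB=0, SS_E=2, F_A=64, F_B=16, F_AB=0."""
        rows = []
        data = {("a1", "b1"): [1, 2], ("a1", "b2"): [3, 4],
                ("a2", "b1"): [5, 6], ("a2", "b2"): [7, 8]}
        for (a, b), values in data.items():
            for v in values:
                rows.append({"A": a, "B": b, "y": float(v)})
        table = anova(pd.DataFrame(rows), "y", ["A", "B"])
        assert table.loc["A", "sum_sq"] == pytest.approx(32.0)
        assert table.loc["B", "sum_sq"] == pytest.approx(8.0)
        assert table.loc["A:B", "sum_sq"] == pytest.approx(0.0, abs=1e-10)
        assert table.loc["Residual", "sum_sq"] == pytest.approx(2.0)
        assert table.loc["A", "F"] == pytest.approx(64.0)
        assert table.loc["B", "F"] == pytest.approx(16.0)

    def test_one_way_matches_scipy(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {"g": np.repeat(list("abc"), 8), "y": rng.normal(size=24)}
        )
        table = anova(df, "y", ["g"])
        f, p = sps.f_oneway(*[df[df.g == g].y for g in "abc"])
        assert table.loc["g", "F"] == pytest.approx(f)
        assert table.loc["g", "PR(>F)"] == pytest.approx(p)

    def test_identical_constant_groups_degenerate(self):
        df = pd.DataFrame({"g": list("aabbcc"), "y": [5.0] * 6})
        table = anova(df, "y", ["g"])
        assert table.loc["g", "F"] == 0.0
        assert table.loc["g", "PR(>F)"] == 1.0

    def test_empty_cell_rejected(self):
        df = pd.DataFrame(
            {"A": ["a1", "a1", "a2"], "B": ["b1", "b2", "b1"], "y": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValueError, match="empty"):
            anova(df, "y", ["A", "B"])

    def test_type_I_error_rate_under_null(self):
        """3 groups, n=3, no effects: one-way rejection rate ~ alpha."""
        rng = np.random.default_rng(12)
        reps = 300
        rejections = 0
        for _ in range(reps):
            df = pd.DataFrame(
                {"g": np.repeat(list("abc"), 3), "y": rng.normal(size=9)}
            )
            p = anova(df, "y", ["g"]).loc["g", "PR(>F)"]
            rejections += p < 0.05
        assert 0.015 < rejections / reps < 0.09


class TestTukey:
    def test_two_groups_match_studentized_range_closed_form(self):
        rng = np.random.default_rng(5)
        groups = {"a": rng.normal(0, 1, 10), "b": rng.normal(1, 1, 10)}
        res = tukey_hsd(groups)
        a, b = groups["a"], groups["b"]
        mse = (np.var(a, ddof=1) + np.var(b, ddof=1)) / 2
        q = abs(a.mean() - b.mean()) / np.sqrt(mse / 10)
        p = sps.studentized_range.sf(q, 2, 18)
        assert res.table["p_adj"].iloc[0] == pytest.approx(p, abs=1e-4)

    def test_identical_groups_nothing_significant(self):
        groups = {k: [1.0, 2.0, 3.0, 4.0] for k in "abc"}
        res = tukey_hsd(groups)
        assert not res.table["reject"].any()
        assert not res.significance.values.any()

    def test_single_shifted_group_detected(self):
        rng = np.random.default_rng(6)
        groups = {
            "a": rng.normal(0, 1, 12),
            "b": rng.normal(0, 1, 12),
            "c": rng.normal(8, 1, 12),
        }
        res = tukey_hsd(groups)
        sig = res.significance
        assert sig.loc["a", "c"] and sig.loc["b", "c"]
        assert not sig.loc["a", "b"]

    def test_tukey_p_at_least_unadjusted_t(self):
        rng = np.random.default_rng(9)
        groups = {k: rng.normal(i * 0.5, 1, 8) for i, k in enumerate("abcd")}
        res = tukey_hsd(groups)
        for _, row in res.table.iterrows():
            t_p = sps.ttest_ind(groups[row["group1"]], groups[row["group2"]]).pvalue
            assert row["p_adj"] >= t_p - 1e-10

    def test_single_group_empty_result(self):
        res = tukey_hsd({"a": [1.0, 2.0]})
        assert res.table.empty


class TestCompactLetterDisplay:
    @staticmethod
    def _sig(names, pairs):
        sig = pd.DataFrame(False, index=names, columns=names)
        for i, j in pairs:
            sig.loc[i, j] = sig.loc[j, i] = True
        return sig

    def test_all_nonsignificant_share_one_letter(self):
        letters = compact_letter_display(self._sig(list("abc"), []))
        assert set(letters.values()) == {"a"}

    def test_all_significant_get_distinct_letters(self):
        names = list("xyz")
        letters = compact_letter_display(
            self._sig(names, itertools.combinations(names, 2))
        )
        assert sorted(letters.values()) == ["a", "b", "c"]

    def test_chain_case(self):
        letters = compact_letter_display(self._sig(list("ABC"), [("A", "C")]))
        assert letters == {"A": "a", "B": "ab", "C": "b"}

    def test_uppercase_option(self):
        letters = compact_letter_display(self._sig(list("ab"), [("a", "b")]),
                                         uppercase=True)
        assert letters == {"a": "A", "b": "B"}

    def test_validity_on_random_matrices(self, rng):
        """Exhaustive consistency: groups share a letter iff the pair is
        non-significant, on random matrices up to 6 groups."""
        for _ in range(200):
            n = int(rng.integers(2, 7))
            names = [f"g{i}" for i in range(n)]
            pairs = [
                p for p in itertools.combinations(names, 2) if rng.random() < 0.4
            ]
            sig = self._sig(names, pairs)
            letters = compact_letter_display(sig)
            for i, j in itertools.combinations(names, 2):
                shared = set(letters[i]) & set(letters[j])
                if sig.loc[i, j]:
                    assert not shared, (letters, pairs)
                else:
                    assert shared, (letters, pairs)


class TestValidationRegression:
    def test_perfect_agreement(self):
        ref = np.linspace(5, 50, 20)
        fit = validation_regression(ref, ref)
        assert fit.slope == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_scaled_estimates_keep_r2(self):
        ref = np.linspace(5, 50, 20)
        fit = validation_regression(2 * ref, ref)
        assert fit.slope == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_zero_variance_reference_rejected(self):
        with pytest.raises(ValueError):
            validation_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


# ---- mAP evaluator -----------------------------------------------------------


def _box(x0, y0, x1, y1, cls=0, conf=None):
    poly = np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], float)
    return EvalInstance(cls=cls, polygon=poly, confidence=conf)


class TestEvaluateMap:
    def test_perfect_predictions_score_one(self):
        truths = [_box(10, 10, 40, 30), _box(60, 60, 90, 95, cls=1)]
        preds = [_box(10, 10, 40, 30, conf=0.9), _box(60, 60, 90, 95, cls=1, conf=0.8)]
        dets = DetectionSet(images=[ImageEval((100, 100), preds, truths)])
        result = evaluate_map(dets)
        for key in ("map_box50", "map_box50_95", "map_mask50", "map_mask50_95"):
            assert result[key] == pytest.approx(1.0)

    def test_no_predictions_scores_zero(self):
        dets = DetectionSet(images=[ImageEval((50, 50), [], [_box(5, 5, 20, 20)])])
        result = evaluate_map(dets)
        assert result["map_box50"] == 0.0
        assert result["map_mask50_95"] == 0.0

    def test_hand_computed_pr_curve(self):
        """1 class, 2 GT; predictions = one TP (conf .9) then one FP (conf .8):
        all-point AP50 = 0.5 (precision 1 up to recall 0.5, then no recall gain)."""
        truths = [_box(10, 10, 30, 30), _box(60, 60, 80, 80)]
        preds = [_box(10, 10, 30, 30, conf=0.9), _box(5, 60, 25, 80, conf=0.8)]
        dets = DetectionSet(images=[ImageEval((100, 100), preds, truths)],
                            iou_thresholds=[0.5])
        assert evaluate_map(dets)["map_box50"] == pytest.approx(0.5)

    def test_high_confidence_false_positive_never_raises_ap(self):
        truths = [_box(10, 10, 30, 30)]
        base = [_box(11, 10, 30, 30, conf=0.8)]
        with_fp = base + [_box(50, 50, 70, 70, conf=0.95)]
        ap_base = evaluate_map(
            DetectionSet([ImageEval((100, 100), base, truths)], [0.5])
        )["map_box50"]
        ap_fp = evaluate_map(
            DetectionSet([ImageEval((100, 100), with_fp, truths)], [0.5])
        )["map_box50"]
        assert ap_fp <= ap_base

    def test_map5095_never_exceeds_map50(self, rng):
        truths = [_box(10, 10, 35, 30), _box(50, 55, 80, 85, cls=1)]
        preds = [
            _box(12, 11, 36, 32, conf=0.9),
            _box(49, 53, 78, 88, cls=1, conf=0.7),
            _box(5, 70, 20, 90, conf=0.6),
        ]
        result = evaluate_map(DetectionSet([ImageEval((100, 100), preds, truths)]))
        assert result["map_box50_95"] <= result["map_box50"] + 1e-12
        assert result["map_mask50_95"] <= result["map_mask50"] + 1e-12

    def test_class_without_ground_truth_contributes_zero(self):
        truths = [_box(10, 10, 30, 30)]
        preds = [_box(10, 10, 30, 30, conf=0.9), _box(40, 40, 60, 60, cls=5, conf=0.8)]
        result = evaluate_map(DetectionSet([ImageEval((100, 100), preds, truths)], [0.5]))
        assert result["per_class_ap50"]["box"][5] == 0.0
        assert result["map_box50"] == pytest.approx(0.5)  # mean over 2 classes

    def test_invalid_iou_threshold_rejected(self):
        with pytest.raises(ValueError):
            DetectionSet(images=[], iou_thresholds=[0.42])
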