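"""Evaluation statistics: confusion matrix, Wilson intervals, F1, ROC/AUC.

The golden table freezes every per-class precision/recall interval and F1
of the three study result tables as (k, n) integer inputs with their
printed 3-decimal outputs, and checks that the package reproduces each row
exactly. Independent oracles: numeric score-test inversion for Wilson
bounds, Mann-Whitney pair counting for AUC, plus statsmodels/scikit-learn
cross-checks.
"""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import norm

from cytoattn.evaluation import (
    ConfusionMatrix,
    confusion_matrix,
    evaluate_predictions,
    precision_recall_f1,
    roc_ovr,
    round_half_up,
    wilson_interval,
)

# Frozen study rows: (model, class, metric, k, n, point, ci_low, ci_high).
GOLDEN_INTERVALS = [
    ("spatial_attention", "NPM1-RARA", "precision", 25, 27, 0.926, 0.766, 0.979),
    ("spatial_attention", "NPM1-RARA", "recall", 25, 26, 0.962, 0.811, 0.993),
    ("spatial_attention", "PML-RARA", "precision", 262, 264, 0.992, 0.973, 0.998),
    ("spatial_attention", "PML-RARA", "recall", 262, 266, 0.985, 0.962, 0.994),
    ("spatial_attention", "NUP98-RARG", "precision", 5, 6, 0.833, 0.436, 0.970),
    ("spatial_attention", "NUP98-RARG", "recall", 5, 5, 1.000, 0.566, 1.000),
    ("spatial_attention", "STAT5B-RARA", "precision", 16, 16, 1.000, 0.806, 1.000),
    ("spatial_attention", "STAT5B-RARA", "recall", 16, 16, 1.000, 0.806, 1.000),
    ("spatial_attention", "TTMV-RARA", "precision", 41, 43, 0.953, 0.845, 0.987),
    ("spatial_attention", "TTMV-RARA", "recall", 41, 43, 0.953, 0.845, 0.987),
    ("spatial_attention", "overall", "accuracy", 350, 357, 0.980, 0.960, 0.990),
    ("self_attention_resnet", "NPM1-RARA", "precision", 23, 24, 0.958, 0.798, 0.993),
    ("self_attention_resnet", "NPM1-RARA", "recall", 23, 26, 0.885, 0.710, 0.960),
    ("self_attention_resnet", "PML-RARA", "precision", 261, 268, 0.974, 0.947, 0.987),
    ("self_attention_resnet", "PML-RARA", "recall", 261, 266, 0.981, 0.957, 0.992),
    ("self_attention_resnet", "NUP98-RARG", "precision", 4, 4, 1.000, 0.510, 1.000),
    ("self_attention_resnet", "NUP98-RARG", "recall", 4, 5, 0.800, 0.376, 0.964),
    ("self_attention_resnet", "STAT5B-RARA", "precision", 16, 16, 1.000, 0.806, 1.000),
    ("self_attention_resnet", "STAT5B-RARA", "recall", 16, 16, 1.000, 0.806, 1.000),
    ("self_attention_resnet", "TTMV-RARA", "precision", 37, 44, 0.841, 0.706, 0.921),
    ("self_attention_resnet", "TTMV-RARA", "recall", 37, 43, 0.860, 0.727, 0.934),
    ("self_attention_resnet", "overall", "accuracy", 342, 357, 0.958, 0.932, 0.974),
    ("multilayer_cnn", "NPM1-RARA", "precision", 29, 34, 0.853, 0.699, 0.936),
    ("multilayer_cnn", "NPM1-RARA", "recall", 29, 30, 0.967, 0.833, 0.994),
    ("multilayer_cnn", "PML-RARA", "precision", 254, 260, 0.977, 0.951, 0.989),
    ("multilayer_cnn", "PML-RARA", "recall", 254, 265, 0.958, 0.927, 0.977),
    ("multilayer_cnn", "NUP98-RARG", "precision", 0, 3, 0.000, 0.000, 0.561),
    ("multilayer_cnn", "NUP98-RARG", "recall", 0, 4, 0.000, 0.000, 0.490),
    ("multilayer_cnn", "STAT5B-RARA", "precision", 6, 13, 0.462, 0.232, 0.709),
    ("multilayer_cnn", "STAT5B-RARA", "recall", 6, 18, 0.333, 0.163, 0.563),
    ("multilayer_cnn", "TTMV-RARA", "precision", 37, 54, 0.685, 0.553, 0.793),
    ("multilayer_cnn", "TTMV-RARA", "recall", 37, 47, 0.787, 0.651, 0.880),
    ("multilayer_cnn", "overall", "accuracy", 318, 355, 0.896, 0.860, 0.923),
]

# (model, class, precision (k, n), recall (k, n), printed F1)
GOLDEN_F1 = [
    ("spatial_attention", "NPM1-RARA", (25, 27), (25, 26), 0.943),
    ("spatial_attention", "PML-RARA", (262, 264), (262, 266), 0.989),
    ("spatial_attention", "NUP98-RARG", (5, 6), (5, 5), 0.909),
    ("spatial_attention", "STAT5B-RARA", (16, 16), (16, 16), 1.000),
    ("spatial_attention", "TTMV-RARA", (41, 43), (41, 43), 0.953),
    ("self_attention_resnet", "NPM1-RARA", (23, 24), (23, 26), 0.920),
    ("self_attention_resnet", "PML-RARA", (261, 268), (261, 266), 0.978),
    ("self_attention_resnet", "NUP98-RARG", (4, 4), (4, 5), 0.889),
    ("self_attention_resnet", "STAT5B-RARA", (16, 16), (16, 16), 1.000),
    ("self_attention_resnet", "TTMV-RARA", (37, 44), (37, 43), 0.851),
    ("multilayer_cnn", "NPM1-RARA", (29, 34), (29, 30), 0.906),
    ("multilayer_cnn", "PML-RARA", (254, 260), (254, 265), 0.968),
    ("multilayer_cnn", "NUP98-RARG", (0, 3), (0, 4), 0.000),
    ("multilayer_cnn", "STAT5B-RARA", (6, 13), (6, 18), 0.387),
    ("multilayer_cnn", "TTMV-RARA", (37, 54), (37, 47), 0.733),
]


def two_class_cm(kp: int, np_: int, kr: int, nr: int) -> ConfusionMatrix:
    """Minimal confusion matrix realizing precision kp/np_ and recall kr/nr
    for the first class (tp = kp = kr is required)."""
    assert kp == kr
    tp, fp, fn = kp, np_ - kp, nr - kr
    return ConfusionMatrix(counts=np.array([[tp, fn], [fp, 0]]), class_names=("pos", "rest"))


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        cm = confusion_matrix(list("AABBB"), list("AABBB"), ("A", "B"))
        np.testing.assert_array_equal(cm.counts, [[2, 0], [0, 3]])
        assert cm.accuracy() == 1.0

    def test_empty_input_gives_zero_matrix(self):
        cm = confusion_matrix([], [], ("A", "B"))
        assert cm.counts.sum() == 0

    def test_small_enumeration(self):
        cm = confusion_matrix(["A", "A", "B"], ["A", "B", "B"], ("A", "B"))
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 1]])

    def test_unknown_label_is_named_in_error(self):
        with pytest.raises(ValueError, match="'C'"):
            confusion_matrix(["A", "C"], ["A", "A"], ("A", "B"))

    def test_row_sums_are_true_class_counts(self):
        rng = np.random.default_rng(0)
        names = ("A", "B", "C")
        true = rng.choice(names, size=60)
        pred = rng.choice(names, size=60)
        cm = confusion_matrix(true, pred, names)
        for i, name in enumerate(names):
            assert cm.counts[i].sum() == (true == name).sum()


class TestWilsonInterval:
    @pytest.mark.parametrize("_, cls, metric, k, n, point, lo, hi", GOLDEN_INTERVALS)
    def test_reproduces_every_printed_interval(self, _, cls, metric, k, n, point, lo, hi):
        low, high = wilson_interval(k, n)
        assert round_half_up(k / n) == pytest.approx(point, abs=5e-4)
        assert round_half_up(low) == pytest.approx(lo, abs=5e-4)
        assert round_half_up(high) == pytest.approx(hi, abs=5e-4)

    def test_all_successes_lower_bound_closed_form(self):
        z = norm.ppf(0.975)
        for n in (5, 16, 100):
            low, high = wilson_interval(n, n)
            assert high == 1.0
            assert low == pytest.approx(1.0 / (1.0 + z * z / n), abs=1e-12)

    def test_zero_trials_raise(self):
        with pytest.raises(ValueError):
            wilson_interval(0, 0)
        with pytest.raises(ValueError):
            wilson_interval(3, 2)

    def test_matches_numeric_score_test_inversion(self):
        """Bounds solve (phat - p)^2 = z^2 p(1-p)/n, found by root-finding."""
        z = norm.ppf(0.975)
        rng = np.random.default_rng(2024)

        def g(p, phat, n):
            return (phat - p) ** 2 - z * z * p * (1 - p) / n

        for _ in range(1000):
            n = int(rng.integers(1, 500))
            k = int(rng.integers(0, n + 1))
            phat = k / n
            low, high = wilson_interval(k, n)
            # shrink brackets slightly so the trivial root at p = phat for
            # phat in {0, 1} does not shadow the score-test bound
            if k == 0:
                oracle_low = 0.0
            else:
                upper_bracket = phat if k < n else 1.0 - 1e-12
                oracle_low = brentq(g, 0.0, upper_bracket, args=(phat, n), xtol=1e-13)
            if k == n:
                oracle_high = 1.0
            else:
                lower_bracket = phat if k > 0 else 1e-12
                oracle_high = brentq(g, lower_bracket, 1.0, args=(phat, n), xtol=1e-13)
            assert low == pytest.approx(oracle_low, abs=1e-9)
            assert high == pytest.approx(oracle_high, abs=1e-9)

    def test_matches_statsmodels_wilson(self):
        from statsmodels.stats.proportion import proportion_confint

        for k, n in [(25, 27), (5, 5), (0, 4), (350, 357), (7, 19)]:
            low, high = wilson_interval(k, n)
            sm_low, sm_high = proportion_confint(k, n, alpha=0.05, method="wilson")
            assert low == pytest.approx(sm_low, abs=1e-12)
            assert high == pytest.approx(sm_high, abs=1e-12)


class TestPrecisionRecallF1:
    @pytest.mark.parametrize("_, cls, pkn, rkn, f1_printed", GOLDEN_F1)
    def test_reproduces_every_printed_f1(self, _, cls, pkn, rkn, f1_printed):
        cm = two_class_cm(pkn[0], pkn[1], rkn[0], rkn[1])
        precision, recall, f1 = precision_recall_f1(cm)
        assert precision["pos"].point == pytest.approx(pkn[0] / pkn[1])
        assert recall["pos"].point == pytest.approx(rkn[0] / rkn[1])
        assert round_half_up(f1["pos"]) == pytest.approx(f1_printed, abs=5e-4)

    def test_symmetric_precision_recall_give_equal_f1(self):
        cm = two_class_cm(41, 43, 41, 43)
        _, _, f1 = precision_recall_f1(cm)
        assert round_half_up(f1["pos"]) == 0.953

    def test_diagonal_matrix_gives_perfect_metrics(self):
        cm = ConfusionMatrix(counts=np.diag([4, 6, 2]), class_names=("A", "B", "C"))
        precision, recall, f1 = precision_recall_f1(cm)
        for c in ("A", "B", "C"):
            assert precision[c].point == recall[c].point == f1[c] == 1.0

    def test_zero_denominator_is_flagged_not_crashed(self):
        # class B never predicted and never true
        cm = ConfusionMatrix(counts=np.array([[5, 0], [0, 0]]), class_names=("A", "B"))
        precision, recall, f1 = precision_recall_f1(cm)
        assert precision["B"].undefined and recall["B"].undefined
        assert precision["B"].point == 0.0 and f1["B"] == 0.0


def _mann_whitney_auc(pos_scores, neg_scores) -> float:
    """Pair-counting oracle with half credit for ties."""
    wins = sum((p > n) + 0.5 * (p == n) for p in pos_scores for n in neg_scores)
    return wins / (len(pos_scores) * len(neg_scores))


class TestRocAuc:
    def _probs(self, scores):
        scores = np.asarray(scores, dtype=float)
        return np.stack([scores, 1 - scores], axis=1)

    def test_perfect_separation_gives_auc_one(self):
        y = [0, 0, 1, 1]
        probs = self._probs([0.9, 0.8, 0.2, 0.1])
        _, _, auc = roc_ovr(y, probs, 0)
        assert auc == 1.0

    def test_constant_scores_give_auc_half(self):
        y = [0, 1, 0, 1]
        probs = self._probs([0.4, 0.4, 0.4, 0.4])
        _, _, auc = roc_ovr(y, probs, 0)
        assert auc == 0.5

    def test_known_small_instance(self):
        # positives {0.9, 0.4}, negatives {0.8, 0.2}: 3 of 4 pairs won
        y = [0, 0, 1, 1]
        probs = self._probs([0.9, 0.4, 0.8, 0.2])
        _, _, auc = roc_ovr(y, probs, 0)
        assert auc == 0.75
        assert _mann_whitney_auc([0.9, 0.4], [0.8, 0.2]) == 0.75

    def test_absent_class_yields_undefined_auc(self):
        y = [1, 1]
        probs = self._probs([0.2, 0.6])
        _, _, auc = roc_ovr(y, probs, 0)
        assert auc is None

    def test_trapezoid_auc_equals_mann_whitney_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(4, 21))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            # discrete scores force ties
            scores = rng.integers(0, 5, size=n) / 4.0
            probs = np.stack([1 - scores, scores], axis=1)
            _, _, auc = roc_ovr(y, probs, 1)
            oracle = _mann_whitney_auc(scores[y == 1], scores[y == 0])
            assert auc == pytest.approx(oracle, abs=1e-12)

    def test_matches_sklearn_on_a_random_instance(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, size=50)
        scores = rng.random(50)
        probs = np.stack([1 - scores, scores], axis=1)
        _, _, auc = roc_ovr(y, probs, 1)
        assert auc == pytest.approx(roc_auc_score(y, scores), abs=1e-12)


class TestEvaluatePredictions:
    def test_all_correct_with_closed_form_ci(self):
        z = norm.ppf(0.975)
        names = ("A", "B")
        report = evaluate_predictions(["A"] * 6 + ["B"] * 4, ["A"] * 6 + ["B"] * 4, names)
        acc = report.overall_accuracy
        assert acc.point == 1.0
        assert acc.ci_low == pytest.approx(1.0 / (1.0 + z * z / 10), abs=1e-12)

    def test_study_scale_accuracy_percentage(self):
        # 350 of 357 correct reproduces the headline 98.04%
        true = ["A"] * 357
        pred = ["A"] * 350 + ["B"] * 7
        report = evaluate_predictions(true, pred, ("A", "B"))
        assert round(100 * report.overall_accuracy.point, 2) == 98.04

    def test_micro_average_recall_equals_overall_accuracy(self):
        rng = np.random.default_rng(3)
        names = ("A", "B", "C")
        true = rng.choice(names, size=90)
        pred = rng.choice(names, size=90)
        report = evaluate_predictions(true, pred, names)
        micro = sum(report.recall[c].k for c in names) / sum(report.recall[c].n for c in names)
        assert micro == pytest.approx(report.overall_accuracy.point)
        assert report.overall_accuracy.point == pytest.approx(
            np.trace(report.confusion.counts) / report.confusion.total
        )

    def test_report_is_deterministic_and_serializable(self, tmp_path):
        rng = np.random.default_rng(5)
        names = ("A", "B")
        true = rng.choice(names, size=30)
        probs = rng.dirichlet((1, 1), size=30)
        pred = [names[i] for i in probs.argmax(axis=1)]
        r1 = evaluate_predictions(true, pred, names, probs)
        r2 = evaluate_predictions(true, pred, names, probs)
        assert r1.to_dict() == r2.to_dict()
        r1.to_json(tmp_path / "report.json")
        import json

        assert json.loads((tmp_path / "report.json").read_text())["overall_accuracy"]["n"] == 30
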