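"""Confusion matrices, metric suite, ROC/AUC."""

import numpy as np
import pytest

from gaborderm.classify import SVMSpec, train_classifier
from gaborderm.data import CLASSES
from gaborderm.metrics import (
    ConfusionMatrix,
    compute_metrics,
    confusion_matrix,
    roc_curves,
)


def naive_per_cell_metrics(counts):
    """Oracle: per-class TP/TN/FP/FN by direct cell-by-cell summation."""
    k = counts.shape[0]
    out = []
    for c in range(k):
        tp = tn = fp = fn = 0
        for i in range(k):
            for j in range(k):
                v = counts[i, j]
                if i == c and j == c:
                    tp += v
                elif i == c:
                    fn += v
                elif j == c:
                    fp += v
                else:
                    tn += v
        out.append((tp, tn, fp, fn))
    return out


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = list(CLASSES) * 3
        cm = confusion_matrix(y, y)
        assert np.all(cm.counts == np.diag(np.diag(cm.counts)))
        assert np.trace(cm.counts) == 21

    def test_all_wrong_binary_flip_is_antidiagonal(self):
        y_true = ["mel"] * 4 + ["nv"] * 6
        y_pred = ["nv"] * 4 + ["mel"] * 6
        cm = confusion_matrix(y_true, y_pred, classes=("mel", "nv"))
        np.testing.assert_array_equal(cm.counts, [[0, 4], [6, 0]])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_matrix(["nv"], ["nv", "mel"])

    def test_one_vs_rest_collapse(self):
        counts = np.arange(9).reshape(3, 3)
        cm = ConfusionMatrix(counts, classes=("a", "b", "c"))
        for i, expected in enumerate(naive_per_cell_metrics(counts)):
            assert cm.one_vs_rest(i) == expected


class TestComputeMetrics:
    def test_hand_worked_binary_matrix(self):
        # TP=8, FN=2, FP=1, TN=9 for the positive class
        cm = ConfusionMatrix(np.array([[8, 2], [1, 9]]),
                             classes=("pos", "neg"))
        report = compute_metrics(cm)
        pos = report.per_class.loc["pos"]
        assert pos["sensitivity"] == pytest.approx(0.800, abs=1e-3)
        assert pos["specificity"] == pytest.approx(0.900, abs=1e-3)
        assert pos["precision"] == pytest.approx(8 / 9, abs=1e-3)
        assert pos["f1"] == pytest.approx(16 / 19, abs=1e-3)
        assert pos["mcc"] == pytest.approx(0.704, abs=1e-3)
        assert report.accuracy == pytest.approx(0.850, abs=1e-3)

    def test_micro_identity_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            counts = rng.integers(0, 50, size=(7, 7))
            if counts.sum() == 0:
                continue
            report = compute_metrics(ConfusionMatrix(counts))
            assert report.precision == pytest.approx(report.accuracy, abs=1e-12)
            assert report.sensitivity == pytest.approx(report.accuracy, abs=1e-12)
            assert report.f1 == pytest.approx(report.accuracy, abs=1e-12)

    def test_agrees_with_per_cell_oracle(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 30, size=(7, 7))
        report = compute_metrics(ConfusionMatrix(counts))
        for i, c in enumerate(CLASSES):
            tp, tn, fp, fn = naive_per_cell_metrics(counts)[i]
            row = report.per_class.loc[c]
            assert row["sensitivity"] == pytest.approx(
                tp / (tp + fn), abs=1e-12
            )
            assert row["specificity"] == pytest.approx(
                tn / (tn + fp), abs=1e-12
            )

    def test_diagonal_matrix_all_ones(self):
        report = compute_metrics(ConfusionMatrix(np.diag([3, 1, 4, 1, 5, 9, 2])))
        assert report.accuracy == 1.0
        assert report.mcc == 1.0
        assert np.all(report.per_class[["sensitivity", "specificity",
                                        "precision", "f1"]] == 1.0)

    def test_macro_average_available(self):
        counts = np.array([[5, 1], [2, 8]])
        cm = ConfusionMatrix(counts, classes=("a", "b"))
        macro = compute_metrics(cm, average="macro")
        per = macro.per_class
        assert macro.sensitivity == pytest.approx(per["sensitivity"].mean())

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_metrics(ConfusionMatrix(np.zeros((7, 7), dtype=int)))


class TestRocCurves:
    def test_perfectly_ordered_scores_auc_one(self):
        y = np.array(["mel"] * 5 + ["nv"] * 5)
        scores = np.zeros((10, 7))
        mel_col = CLASSES.index("mel")
        scores[:5, mel_col] = 1.0  # positives strictly above negatives
        roc = roc_curves(scores, y)
        assert roc.auc["mel"] == pytest.approx(1.0)
        fpr, tpr = roc.curves["mel"]
        assert fpr[0] == 0.0 and tpr[0] == 0.0
        assert fpr[-1] == 1.0 and tpr[-1] == 1.0
        assert np.all(np.diff(fpr) >= 0)

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(2)
        n = 2000
        y = rng.choice(["mel", "nv"], size=n)
        scores = rng.normal(size=(n, 7))
        roc = roc_curves(scores, y)
        assert roc.auc["mel"] == pytest.approx(0.5, abs=0.05)

    def test_constant_scores_auc_exactly_half(self):
        y = np.array(["mel"] * 4 + ["nv"] * 6)
        scores = np.ones((10, 7))
        roc = roc_curves(scores, y)
        assert roc.auc["mel"] == 0.5

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        y = rng.choice(["mel", "nv", "bkl"], size=200)
        scores = rng.normal(size=(200, 7))
        a = roc_curves(scores, y)
        b = roc_curves(np.exp(3 * scores) + 7, y)
        for c in a.auc:
            assert a.auc[c] == pytest.approx(b.auc[c], abs=1e-12)


class TestTrainClassifier:
    def test_separable_two_class_linear(self):
        rng = np.random.default_rng(4)
        x = np.vstack([rng.normal(0, 0.2, (20, 2)),
                       rng.normal(5, 0.2, (20, 2))])
        y = np.array(["a"] * 20 + ["b"] * 20)
        model = train_classifier(x, y, SVMSpec("linear"))
        assert np.mean(model.predict(x) == y) == 1.0

    def test_xor_needs_gaussian_kernel(self):
        rng = np.random.default_rng(5)
        centers = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
        labels = ["a", "a", "b", "b"]
        x = np.vstack([c + rng.normal(0, 0.05, (25, 2)) for c in centers])
        y = np.array([l for l in labels for _ in range(25)])
        gauss = train_classifier(x, y, SVMSpec("gaussian"))
        linear = train_classifier(x, y, SVMSpec("linear"))
        assert np.mean(gauss.predict(x) == y) == 1.0
        assert np.mean(linear.predict(x) == y) < 1.0

    def test_decision_scores_shape_matches_classes(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(30, 3))
        y = rng.choice(["a", "b", "c"], size=30)
        model = train_classifier(x, y, SVMSpec("quadratic"))
        assert model.decision_scores(x).shape == (30, 3)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            train_classifier(np.zeros((5, 2)), ["a"] * 5)

    def test_unknown_kernel_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            SVMSpec("cubic")
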