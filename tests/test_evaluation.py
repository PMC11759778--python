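import numpy as np
import pytest
from sklearn.metrics import confusion_matrix as sk_confusion
from sklearn.metrics import precision_recall_fscore_support

from tremorclust import (
    binary_metrics,
    confusion_matrix,
    load_fixture,
    map_labels_by_permutation,
    multiclass_metrics,
)


def _task_arrays(name, truth_col):
    df = load_fixture(name)
    truth = df[truth_col].to_numpy()
    clusters = df["predominant_cluster"].to_numpy()
    mapped = map_labels_by_permutation(clusters, truth).apply(clusters)
    return truth, mapped


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self):
        truth = [1, 2, 3] * 4 + [1, 2]
        cm = confusion_matrix(truth, truth, [1, 2, 3])
        assert np.trace(cm) == 14
        assert cm.sum() == 14
        assert (cm[~np.eye(3, dtype=bool)] == 0).all()

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 1], [0, 2], [0, 1])

    def test_binary_tremor_table_counts(self):
        truth, mapped = _task_arrays("table2", "updrs_score")
        cm = confusion_matrix(truth, mapped, [0, 1])
        # positive = tremor (1): TP=8, FN=6, FP=0, TN=11
        assert cm[1, 1] == 8 and cm[1, 0] == 6 and cm[0, 1] == 0 and cm[0, 0] == 11

    def test_binarised_severity_table_counts(self):
        truth, mapped = _task_arrays("table4", "binary_score")
        cm = confusion_matrix(truth, mapped, [1, 2])
        # positive = moderate (2): TP=2, FN=1, FP=3, TN=8
        assert cm[1, 1] == 2 and cm[1, 0] == 1 and cm[0, 1] == 3 and cm[0, 0] == 8

    def test_matches_sklearn(self, rng):
        truth = rng.integers(0, 3, size=60)
        pred = rng.integers(0, 3, size=60)
        np.testing.assert_array_equal(
            confusion_matrix(truth, pred, [0, 1, 2]),
            sk_confusion(truth, pred, labels=[0, 1, 2]),
        )


class TestBinaryMetrics:
    def test_tremor_vs_non_tremor(self):
        truth, mapped = _task_arrays("table2", "updrs_score")
        m = binary_metrics(confusion_matrix(truth, mapped, [0, 1]), [0, 1], positive=1)
        assert m.accuracy == pytest.approx(0.76)
        assert m.precision == pytest.approx(1.00)
        assert m.recall == pytest.approx(8 / 14)
        assert m.f1 == pytest.approx(0.727, abs=5e-4)

    def test_moderate_vs_milder(self):
        truth, mapped = _task_arrays("table4", "binary_score")
        m = binary_metrics(confusion_matrix(truth, mapped, [1, 2]), [1, 2], positive=2)
        assert m.accuracy == pytest.approx(10 / 14)
        assert m.precision == pytest.approx(0.40)
        assert m.recall == pytest.approx(2 / 3)
        assert m.f1 == pytest.approx(0.50)

    def test_all_correct_gives_ones(self):
        cm = np.array([[7, 0], [0, 5]])
        m = binary_metrics(cm, [0, 1], positive=1)
        assert (m.accuracy, m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_undefined_precision_flagged_as_zero(self):
        cm = np.array([[5, 0], [3, 0]])  # nothing predicted positive
        m = binary_metrics(cm, [0, 1], positive=1)
        assert m.precision == 0.0 and not m.precision_defined


class TestMulticlassMetrics:
    def test_severity_table_per_class(self):
        truth, mapped = _task_arrays("table3", "updrs_score")
        report = multiclass_metrics(confusion_matrix(truth, mapped, [1, 2, 3]), [1, 2, 3])
        assert report.accuracy == pytest.approx(8 / 14)
        c1, c2, c3 = report.per_class[1], report.per_class[2], report.per_class[3]
        assert (c1.precision, c1.recall) == (pytest.approx(2 / 3), pytest.approx(2 / 3))
        assert (c2.precision, c2.recall) == (pytest.approx(0.50), pytest.approx(0.60))
        assert c2.f1 == pytest.approx(0.545, abs=5e-4)
        assert (c3.precision, c3.recall) == (pytest.approx(0.50), pytest.approx(1 / 3))
        assert c3.f1 == pytest.approx(0.40)

    def test_severity_table_macro_averages(self):
        truth, mapped = _task_arrays("table3", "updrs_score")
        report = multiclass_metrics(confusion_matrix(truth, mapped, [1, 2, 3]), [1, 2, 3])
        assert report.macro_precision == pytest.approx(0.556, abs=5e-4)
        assert report.macro_recall == pytest.approx(0.533, abs=5e-4)
        assert report.macro_f1 == pytest.approx(0.537, abs=5e-4)

    def test_binary_consistency_with_multiclass(self):
        truth, mapped = _task_arrays("table2", "updrs_score")
        cm = confusion_matrix(truth, mapped, [0, 1])
        b = binary_metrics(cm, [0, 1], positive=1)
        r = multiclass_metrics(cm, [0, 1])
        pos = r.per_class[1]
        assert (b.precision, b.recall, b.f1) == (pos.precision, pos.recall, pos.f1)
        assert b.accuracy == r.accuracy

    def test_accuracy_equals_direct_fraction(self, rng):
        truth = rng.integers(0, 4, size=50)
        pred = rng.integers(0, 4, size=50)
        report = multiclass_metrics(confusion_matrix(truth, pred, [0, 1, 2, 3]), [0, 1, 2, 3])
        assert report.accuracy == pytest.approx(np.mean(truth == pred))

    def test_matches_sklearn_macro(self, rng):
        truth = rng.integers(0, 3, size=80)
        pred = rng.integers(0, 3, size=80)
        report = multiclass_metrics(confusion_matrix(truth, pred, [0, 1, 2]), [0, 1, 2])
        p, r, f, _ = precision_recall_fscore_support(
            truth, pred, labels=[0, 1, 2], average="macro", zero_division=0
        )
        assert report.macro_precision == pytest.approx(p)
        assert report.macro_recall == pytest.approx(r)
        assert report.macro_f1 == pytest.approx(f)

    def test_class_order_permutation_symmetry(self):
        truth, mapped = _task_arrays("table3", "updrs_score")
        a = multiclass_metrics(confusion_matrix(truth, mapped, [1, 2, 3]), [1, 2, 3])
        b = multiclass_metrics(confusion_matrix(truth, mapped, [3, 1, 2]), [3, 1, 2])
        assert a.accuracy == b.accuracy
        for c in (1, 2, 3):
            assert a.per_class[c] == b.per_class[c]
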