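"""Metric arithmetic: confusion counts, rounding, macro averages, run summaries."""

import numpy as np
import pytest

from wingclassify import (
    confusion_matrix,
    evaluate_run,
    macro_metrics,
    per_class_accuracy,
    repeat_and_summarize,
    summarize_reports,
)
from wingclassify.evaluation import ConfusionMatrix, EvaluationReport


def _report(i, p, r, f):
    cm = ConfusionMatrix(classes=["a", "b"], counts=np.eye(2, dtype=int))
    return EvaluationReport(run_index=i, confusion=cm, per_class_accuracy={},
                            macro_precision=p, macro_recall=r, macro_f1=f)


class TestConfusionMatrix:
    def test_hand_enumerated_counts(self):
        cm = confusion_matrix(["A", "A", "A"], ["A", "A", "B"], classes=["A", "B"])
        assert cm.counts.tolist() == [[2, 0], [1, 0]]

    def test_perfect_predictions_are_diagonal(self):
        cm = confusion_matrix(["x"] * 17, ["x"] * 17, classes=["x", "y"])
        assert cm.counts[0, 0] == 17
        assert cm.counts.sum() == 17

    def test_empty_inputs_give_zero_matrix(self):
        cm = confusion_matrix([], [], classes=["a", "b"])
        assert not cm.counts.any()

    def test_column_sums_are_true_class_counts(self):
        truth = ["a"] * 5 + ["b"] * 3
        pred = ["a", "b", "a", "a", "b", "b", "a", "b"]
        cm = confusion_matrix(truth, pred, classes=["a", "b"])
        assert cm.column_sums.tolist() == [5, 3]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(["a"], ["z"], classes=["a", "b"])
        with pytest.raises(ValueError):
            confusion_matrix(["a", "b"], ["a"], classes=["a", "b"])


class TestPerClassAccuracy:
    @pytest.mark.parametrize("correct,total,expected", [(13, 17, 76), (12, 17, 71),
                                                        (17, 17, 100), (15, 17, 88)])
    def test_rounded_integer_percentages(self, correct, total, expected):
        counts = np.array([[correct, 0], [total - correct, 1]])
        cm = ConfusionMatrix(classes=["a", "b"], counts=counts)
        assert per_class_accuracy(cm)["a"] == expected

    def test_empty_column_is_undefined(self):
        cm = ConfusionMatrix(classes=["a", "b"], counts=np.array([[3, 0], [0, 0]]))
        with pytest.raises(ZeroDivisionError, match="b"):
            per_class_accuracy(cm)


class TestMacroMetrics:
    def test_identity_matrix_is_perfect(self):
        cm = ConfusionMatrix(classes=list("abc"), counts=np.eye(3, dtype=int) * 4)
        assert macro_metrics(cm) == (100.0, 100.0, 100.0)

    def test_symmetric_two_class_case(self):
        cm = ConfusionMatrix(classes=["a", "b"], counts=np.array([[8, 2], [2, 8]]))
        prec, rec, f1 = macro_metrics(cm)
        assert prec == pytest.approx(80.0)
        assert rec == pytest.approx(80.0)
        assert f1 == pytest.approx(80.0)

    def test_all_wrong_class_contributes_zero(self):
        # every true 'b' predicted 'a': recall(b) = 0, f1(b) = 0
        cm = ConfusionMatrix(classes=["a", "b"], counts=np.array([[5, 5], [0, 0]]))
        prec, rec, f1 = macro_metrics(cm)
        assert rec == pytest.approx(50.0)
        assert f1 == pytest.approx(100.0 / 3.0)

    def test_macro_recall_equals_mean_unrounded_accuracy(self, rng):
        counts = rng.integers(0, 20, size=(4, 4))
        counts += np.eye(4, dtype=counts.dtype)  # no empty columns
        cm = ConfusionMatrix(classes=list("abcd"), counts=counts)
        _, rec, _ = macro_metrics(cm)
        per_class = 100.0 * cm.diagonal / cm.column_sums
        assert rec == pytest.approx(per_class.mean(), abs=1e-9)

    def test_oracle_equivalence_with_sklearn(self, rng):
        """Macro P/R/F1 match the independent reference implementation to 1e-9
        on 100 random small label vectors."""
        from sklearn.metrics import precision_recall_fscore_support

        classes = list("abcd")
        for _ in range(100):
            n = int(rng.integers(5, 40))
            truth = rng.choice(classes, size=n).tolist()
            pred = rng.choice(classes, size=n).tolist()
            cm = confusion_matrix(truth, pred, classes)
            prec, rec, f1 = macro_metrics(cm)
            sp, sr, sf, _ = precision_recall_fscore_support(
                truth, pred, labels=classes, average="macro", zero_division=0
            )
            assert prec == pytest.approx(sp * 100, abs=1e-9)
            assert rec == pytest.approx(sr * 100, abs=1e-9)
            assert f1 == pytest.approx(sf * 100, abs=1e-9)

    def test_random_guess_recall_near_chance(self, rng):
        """Random predictions on a balanced 7-class set: macro recall ~ 1/7."""
        classes = [f"c{i}" for i in range(7)]
        truth = np.repeat(classes, 200).tolist()
        pred = rng.choice(classes, size=len(truth)).tolist()
        _, rec, _ = macro_metrics(confusion_matrix(truth, pred, classes))
        assert rec == pytest.approx(100.0 / 7.0, abs=5.0)


class TestEvaluateRun:
    def test_internal_consistency(self, trained_tiny_net, tiny_dataset):
        report = evaluate_run(trained_tiny_net, tiny_dataset.subset("test"))
        prec, rec, f1 = macro_metrics(report.confusion)
        assert report.macro_precision == prec
        assert report.macro_recall == rec
        assert report.macro_f1 == f1
        assert report.per_class_accuracy == per_class_accuracy(report.confusion)
        # conservation: column sums equal per-class test counts
        test_counts = tiny_dataset.subset("test").class_counts()
        assert report.confusion.column_sums.tolist() == [
            test_counts[c] for c in report.confusion.classes
        ]

    def test_empty_test_set_rejected(self, trained_tiny_net, tiny_dataset):
        from wingclassify.preprocessing import LabeledImageSet

        empty = LabeledImageSet(records=[], classes=list(tiny_dataset.classes))
        with pytest.raises(ValueError):
            evaluate_run(trained_tiny_net, empty)


class TestRepeatSummary:
    def test_summary_over_mocked_runs(self):
        summary, reports = repeat_and_summarize(
            lambda seed, i: _report(i, 90 + seed, 80 + seed, 85 + seed),
            n_runs=4,
            seeds=[0, 1, 2, 3],
        )
        assert summary.n_runs == 4 and len(reports) == 4
        f1 = summary.metrics["macro_f1"]
        assert f1["mean"] == pytest.approx(86.5)
        assert f1["min"] == 85.0 and f1["max"] == 88.0

    def test_single_run_min_equals_mean_equals_max(self):
        summary, _ = repeat_and_summarize(lambda s, i: _report(i, 91, 92, 93), n_runs=1)
        m = summary.metrics["macro_f1"]
        assert m["min"] == m["mean"] == m["max"] == 93.0

    def test_duplicate_seeds_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            repeat_and_summarize(lambda s, i: _report(i, 1, 1, 1), n_runs=2, seeds=[5, 5])

    def test_summarize_requires_reports(self):
        with pytest.raises(ValueError):
            summarize_reports([])


class TestExports:
    def test_confusion_csv_table_layout(self, tmp_path):
        from wingclassify.evaluation import export_confusion_csv

        reports = []
        for i in range(2):
            cm = ConfusionMatrix(classes=["a", "b"], counts=np.array([[3 + i, 1], [0, 2]]))
            prec, rec, f1 = (0.0, 0.0, 0.0)
            reports.append(
                EvaluationReport(run_index=i, confusion=cm,
                                 per_class_accuracy={"a": 100, "b": 67},
                                 macro_precision=prec, macro_recall=rec, macro_f1=f1)
            )
        path = tmp_path / "cms.csv"
        export_confusion_csv(reports, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "predicted,a_R1,a_R2,b_R1,b_R2"
        assert lines[1] == "a,3,4,1,1"
        assert lines[2] == "b,0,0,2,2"
        assert lines[3] == "accuracy_pct,100,100,67,67"

    def test_summary_plot_written(self, tmp_path):
        from wingclassify.evaluation import plot_summary

        summary, _ = repeat_and_summarize(
            lambda s, i: _report(i, 90 + s, 91 + s, 92 + s), n_runs=2, seeds=[0, 2]
        )
        path = tmp_path / "summary.png"
        plot_summary({"grayscale": summary}, path)
        assert path.exists() and path.stat().st_size > 0
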