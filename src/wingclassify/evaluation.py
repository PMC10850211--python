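"""Test-set evaluation: confusion matrices, per-class accuracy, macro metrics.

Conventions match the reference tables: the confusion matrix stores one
COLUMN per true class (entry (i, j) counts test images of true class j
predicted as class i), per-class accuracy is the diagonal over the column sum
expressed as a round-half-up integer percentage, and macro precision /
recall / F1 are unweighted means over classes on the 0-100 scale.  Summaries
over repeated training runs report mean, min and max per metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .model import Network, predict
from .preprocessing import LabeledImageSet

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "RepeatSummary",
    "confusion_matrix",
    "per_class_accuracy",
    "macro_metrics",
    "evaluate_run",
    "summarize_reports",
    "repeat_and_summarize",
    "export_confusion_csv",
    "plot_summary",
]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class ConfusionMatrix:
    """K x K counts, one column per true class, one row per predicted class."""

    classes: list[str]
    counts: np.ndarray  # (K, K) int64, counts[pred, true]

    def __post_init__(self) -> None:
        k = len(self.classes)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def column_sums(self) -> np.ndarray:
        """Per-class test counts (true-class totals)."""
        return self.counts.sum(axis=0)

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.counts)


@dataclass
class EvaluationReport:
    """Metrics for one trained run, all derived from one confusion matrix."""

    run_index: int
    confusion: ConfusionMatrix
    per_class_accuracy: dict[str, int]
    macro_precision: float  # percentages, 0-100
    macro_recall: float
    macro_f1: float


@dataclass
class RepeatSummary:
    """Mean / min / max of each macro metric over repeated runs."""

    n_runs: int
    metrics: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, stats in self.metrics.items():
            if not stats["min"] - 1e-9 <= stats["mean"] <= stats["max"] + 1e-9:
                raise ValueError(f"summary for {name} violates min <= mean <= max")


def confusion_matrix(
    truth: Sequence[str], pred: Sequence[str], classes: Sequence[str]
) -> ConfusionMatrix:
    """Exact counts of (predicted, true) label pairs.

    The diagonal holds correct classifications; empty inputs give an
    all-zero matrix.
    """
    if len(truth) != len(pred):
        raise ValueError(f"truth and pred lengths differ: {len(truth)} vs {len(pred)}")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(truth, pred):
        if t not in index:
            raise ValueError(f"unknown true label {t!r}")
        if p not in index:
            raise ValueError(f"unknown predicted label {p!r}")
        counts[index[p], index[t]] += 1
    return ConfusionMatrix(classes=list(classes), counts=counts)


def per_class_accuracy(cm: ConfusionMatrix) -> dict[str, int]:
    """Per-class accuracy as round-half-up integer percentages.

    accuracy(class) = 100 * correct / column total; a class with no test
    images has an undefined accuracy and raises.
    """
    totals = cm.column_sums
    out = {}
    for j, cls in enumerate(cm.classes):
        if totals[j] == 0:
            raise ZeroDivisionError(f"class {cls!r} has no test images; accuracy undefined")
        out[cls] = _round_half_up(100.0 * cm.counts[j, j] / totals[j])
    return out


def macro_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """Macro-averaged precision, recall and F1, as percentages.

    Per class: precision = TP/(TP+FP) over the prediction row, recall =
    TP/(TP+FN) over the truth column, F1 their harmonic mean; the macro
    value is the unweighted mean over classes.  A class with a zero
    denominator contributes 0 to the average.
    """
    tp = cm.diagonal.astype(np.float64)
    row_sums = cm.counts.sum(axis=1).astype(np.float64)  # predicted-as-class totals
    col_sums = cm.column_sums.astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(row_sums > 0, tp / row_sums, 0.0)
        recall = np.where(col_sums > 0, tp / col_sums, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2.0 * precision * recall / denom, 0.0)
    return (
        float(precision.mean() * 100.0),
        float(recall.mean() * 100.0),
        float(f1.mean() * 100.0),
    )


def evaluate_run(net: Network, test_set: LabeledImageSet, run_index: int = 0) -> EvaluationReport:
    """Predict the test split once and derive every metric from one matrix."""
    if len(test_set) == 0:
        raise ValueError("empty test set")
    probs = predict(net, [r.pixels for r in test_set.records])
    pred = [test_set.classes[i] for i in probs.argmax(axis=1)]
    truth = [r.class_label for r in test_set.records]
    cm = confusion_matrix(truth, pred, test_set.classes)
    prec, rec, f1 = macro_metrics(cm)
    return EvaluationReport(
        run_index=run_index,
        confusion=cm,
        per_class_accuracy=per_class_accuracy(cm),
        macro_precision=prec,
        macro_recall=rec,
        macro_f1=f1,
    )


def summarize_reports(reports: Sequence[EvaluationReport]) -> RepeatSummary:
    """Mean/min/max of each macro metric over a set of per-run reports."""
    if not reports:
        raise ValueError("need at least one report to summarize")
    metrics = {}
    for name in ("macro_precision", "macro_recall", "macro_f1"):
        vals = np.array([getattr(r, name) for r in reports], dtype=np.float64)
        metrics[name] = {
            "mean": float(vals.mean()),
            "min": float(vals.min()),
            "max": float(vals.max()),
        }
    return RepeatSummary(n_runs=len(reports), metrics=metrics)


def repeat_and_summarize(
    run_once: Callable[[int, int], EvaluationReport],
    n_runs: int = 4,
    seeds: Sequence[int] | None = None,
) -> tuple[RepeatSummary, list[EvaluationReport]]:
    """Execute ``n_runs`` full train+evaluate cycles and aggregate the metrics.

    ``run_once(seed, run_index)`` performs one complete cycle (the cli module
    provides the standard pipeline runner); seeds must be distinct so the
    repeats actually differ.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if seeds is None:
        seeds = list(range(n_runs))
    if len(seeds) != n_runs:
        raise ValueError(f"need {n_runs} seeds, got {len(seeds)}")
    if len(set(seeds)) != len(seeds):
        raise ValueError(f"seeds must be distinct, got {list(seeds)}")
    reports = [run_once(int(s), i) for i, s in enumerate(seeds)]
    return summarize_reports(reports), reports


def export_confusion_csv(reports: Sequence[EvaluationReport], path) -> None:
    """Write per-run confusion matrices in the reference table layout.

    One column per (true class, run) pair, side by side; one row per
    predicted class, plus a final integer accuracy row.
    """
    import csv

    if not reports:
        raise ValueError("need at least one report")
    classes = reports[0].confusion.classes
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["predicted"] + [f"{c}_R{r.run_index + 1}" for c in classes for r in reports])
        for i, pred_class in enumerate(classes):
            writer.writerow(
                [pred_class]
                + [int(r.confusion.counts[i, j]) for j, _ in enumerate(classes) for r in reports]
            )
        writer.writerow(
            ["accuracy_pct"]
            + [r.per_class_accuracy[c] for c in classes for r in reports]
        )


def plot_summary(summaries: dict[str, RepeatSummary], path) -> None:
    """Bar chart of mean macro metrics with min-max whiskers per setup.

    ``summaries`` maps a setup label (e.g. "grayscale", "rgb") to its
    repeated-run summary; metrics are grouped on the x axis.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metric_names = ("macro_f1", "macro_precision", "macro_recall")
    labels = list(summaries)
    x = np.arange(len(metric_names), dtype=float)
    width = 0.8 / max(len(labels), 1)
    fig, ax = plt.subplots(figsize=(7, 4))
    for k, label in enumerate(labels):
        stats = [summaries[label].metrics[m] for m in metric_names]
        means = [s["mean"] for s in stats]
        err = np.array(
            [[s["mean"] - s["min"] for s in stats], [s["max"] - s["mean"] for s in stats]]
        )
        ax.bar(x + k * width, means, width, yerr=err, capsize=4, label=label)
    ax.set_xticks(x + width * (len(labels) - 1) / 2)
    ax.set_xticklabels(["F1", "precision", "recall"])
    ax.set_ylabel("macro metric (%)")
    ax.set_ylim(0, 105)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
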