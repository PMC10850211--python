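"""Dataset splitting and the CNN training loop.

Defaults follow the reference experimental protocol: a stratified random
70/15/15 train/validation/test split, Adam with learning rate 0.00015 and L2
weight-decay coefficient 0.0005, batch size 100, 20 epochs, no learning-rate
schedule and no early stopping.  Per-epoch train and validation accuracy and
cross-entropy loss are recorded so learning curves can be exported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .model import Network, batch_from_images, softmax
from .preprocessing import LabeledImageSet

__all__ = [
    "SplitSpec",
    "TrainConfig",
    "EpochRecord",
    "TrainingHistory",
    "split_dataset",
    "train",
    "export_history",
]


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions (must sum to 1) and split policy."""

    train_frac: float = 0.70
    val_frac: float = 0.15
    test_frac: float = 0.15
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.train_frac, self.val_frac, self.test_frac)
        if any(f <= 0 for f in fracs):
            raise ValueError(f"all split fractions must be positive, got {fracs}")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(
                f"split fractions must sum to 1 (got {sum(fracs):.4f}); "
                "renormalize explicitly rather than relying on implicit scaling"
            )


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and loop hyperparameters (defaults: the reference protocol)."""

    epochs: int = 20
    batch_size: int = 100
    learning_rate: float = 0.00015
    weight_decay: float = 0.0005
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be positive, got {self.learning_rate}")
        if self.weight_decay < 0:
            raise ValueError(f"weight_decay must be >= 0, got {self.weight_decay}")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is implemented")


@dataclass(frozen=True)
class EpochRecord:
    epoch: int
    train_loss: float
    train_acc: float
    val_loss: float
    val_acc: float


@dataclass
class TrainingHistory:
    """One record per completed epoch plus an optional checkpoint reference."""

    records: list[EpochRecord] = field(default_factory=list)
    checkpoint: str | None = None

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "epoch": r.epoch,
                    "train_loss": r.train_loss,
                    "train_acc": r.train_acc,
                    "val_loss": r.val_loss,
                    "val_acc": r.val_acc,
                }
                for r in self.records
            ]
        )


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


def _largest_remainder(n: int, fracs: tuple[float, float, float]) -> tuple[int, int, int]:
    """Integer allocation of n items to three fractions; ties favor earlier splits."""
    quotas = [f * n for f in fracs]
    base = [int(np.floor(q)) for q in quotas]
    short = n - sum(base)
    order = sorted(range(3), key=lambda i: (-(quotas[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    return tuple(base)


def split_dataset(dataset: LabeledImageSet, spec: SplitSpec | None = None) -> LabeledImageSet:
    """Assign every record to train/val/test, disjointly and exhaustively.

    Stratified mode (the default) applies the fractions within each class
    using largest-remainder rounding, so per-class proportions match the
    requested fractions as closely as integers allow.  Deterministic per seed.
    """
    spec = spec or SplitSpec()
    for r in dataset.records:
        if r.split != "unassigned":
            raise ValueError(f"record {r.id!r} is already assigned to {r.split!r}")
    rng = np.random.default_rng(spec.seed)
    fracs = (spec.train_frac, spec.val_frac, spec.test_frac)
    assignment: dict[str, str] = {}

    if spec.stratified:
        groups = [[r for r in dataset.records if r.class_label == c] for c in dataset.classes]
    else:
        groups = [list(dataset.records)]
    for group in groups:
        if spec.stratified and len(group) < 3:
            cls = group[0].class_label if group else "<empty>"
            raise ValueError(
                f"class {cls!r} has only {len(group)} images; stratified splitting "
                "needs at least 3 per class"
            )
        n_train, n_val, n_test = _largest_remainder(len(group), fracs)
        perm = rng.permutation(len(group))
        for rank, gi in enumerate(perm):
            if rank < n_train:
                tag = "train"
            elif rank < n_train + n_val:
                tag = "val"
            else:
                tag = "test"
            assignment[group[gi].id] = tag

    return LabeledImageSet(
        records=[replace(r, split=assignment[r.id]) for r in dataset.records],
        classes=list(dataset.classes),
    )


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------


def _to_arrays(images: LabeledImageSet) -> tuple[np.ndarray, np.ndarray]:
    x = batch_from_images([r.pixels for r in images.records])
    class_index = {c: i for i, c in enumerate(images.classes)}
    y = np.array([class_index[r.class_label] for r in images.records], dtype=np.int64)
    return x, y


def _cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    return float(-np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, 1.0)).mean())


class _Adam:
    """Adam with L2 weight decay added to the gradient (coupled, framework-style)."""

    def __init__(self, net: Network, lr: float, weight_decay: float):
        self.lr = lr
        self.wd = weight_decay
        self.t = 0
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.state = {}
        for li, layer in enumerate(net.layers):
            for name, p in layer.params():
                self.state[(li, name)] = (np.zeros_like(p), np.zeros_like(p))

    def step(self, net: Network) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for li, layer in enumerate(net.layers):
            for name, p in layer.params():
                g = getattr(layer, "d" + name) + self.wd * p
                m, v = self.state[(li, name)]
                m[...] = b1 * m + (1 - b1) * g
                v[...] = b2 * v + (1 - b2) * g * g
                mhat = m / (1 - b1**self.t)
                vhat = v / (1 - b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _evaluate_loss_acc(net: Network, x: np.ndarray, y: np.ndarray, batch: int) -> tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, len(x), batch):
        probs = softmax(net.forward(x[i : i + batch], train=False))
        losses.append(_cross_entropy(probs, y[i : i + batch]) * len(y[i : i + batch]))
        correct += int((probs.argmax(axis=1) == y[i : i + batch]).sum())
    return sum(losses) / len(y), correct / len(y)


def train(
    net: Network,
    train_set: LabeledImageSet,
    val_set: LabeledImageSet,
    config: TrainConfig | None = None,
) -> tuple[Network, TrainingHistory]:
    """Run the full training loop; returns the trained net and its history.

    Exactly ``config.epochs`` passes over the (already augmented) training
    records, shuffled each epoch, with one Adam update per batch; the last
    short batch is kept.  Validation metrics are computed after each epoch;
    no early stopping.  Records tagged "test" are rejected outright so test
    data can never leak into training.
    """
    config = config or TrainConfig()
    if len(train_set) == 0:
        raise ValueError("empty training set")
    for s, name in ((train_set, "train"), (val_set, "validation")):
        for r in s.records:
            if r.split == "test":
                raise ValueError(f"test-tagged record {r.id!r} passed to the {name} set")
    if list(train_set.classes) != list(val_set.classes):
        raise ValueError("train and validation sets disagree on the class vocabulary")

    x_tr, y_tr = _to_arrays(train_set)
    x_val, y_val = _to_arrays(val_set)
    rng = np.random.default_rng(config.seed)
    opt = _Adam(net, config.learning_rate, config.weight_decay)
    history = TrainingHistory()

    for epoch in range(1, config.epochs + 1):
        perm = rng.permutation(len(x_tr))
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, len(perm), config.batch_size):
            idx = perm[i : i + config.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            logits = net.forward(xb, train=True)
            probs = softmax(logits)
            ep_loss += _cross_entropy(probs, yb) * len(yb)
            ep_correct += int((probs.argmax(axis=1) == yb).sum())
            grad = probs.copy()
            grad[np.arange(len(yb)), yb] -= 1.0
            net.backward((grad / len(yb)).astype(np.float32))
            opt.step(net)
        val_loss, val_acc = _evaluate_loss_acc(net, x_val, y_val, config.batch_size)
        history.records.append(
            EpochRecord(
                epoch=epoch,
                train_loss=ep_loss / len(x_tr),
                train_acc=ep_correct / len(x_tr),
                val_loss=val_loss,
                val_acc=val_acc,
            )
        )
    return net, history


def export_history(history: TrainingHistory, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the history as ``history.csv`` and a two-panel ``curves.png``.

    The plot mirrors the usual learning-curve figure: accuracy and loss over
    epochs, train and validation series in each panel.
    """
    if len(history) == 0:
        raise ValueError("cannot export an empty training history")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        csv_path = out_dir / "history.csv"
        frame = history.to_frame()
        frame.to_csv(csv_path, index=False)
    except OSError as exc:
        raise OSError(f"cannot write history to {out_dir}: {exc}") from exc

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_acc, ax_loss) = plt.subplots(1, 2, figsize=(10, 4))
    ax_acc.plot(frame["epoch"], frame["train_acc"], label="training", color="tab:blue")
    ax_acc.plot(frame["epoch"], frame["val_acc"], label="validation", color="tab:orange")
    ax_acc.set_xlabel("epoch")
    ax_acc.set_ylabel("accuracy")
    ax_acc.set_ylim(0, 1.02)
    ax_acc.legend()
    ax_loss.plot(frame["epoch"], frame["train_loss"], label="training", color="tab:blue")
    ax_loss.plot(frame["epoch"], frame["val_loss"], label="validation", color="tab:orange")
    ax_loss.set_xlabel("epoch")
    ax_loss.set_ylabel("cross-entropy loss")
    ax_loss.legend()
    fig.tight_layout()
    png_path = out_dir / "curves.png"
    fig.savefig(png_path, dpi=110)
    plt.close(fig)
    return csv_path, png_path
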