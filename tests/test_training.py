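"""Splitting arithmetic, leak protection, loop contracts, history export."""

import numpy as np
import pandas as pd
import pytest

from wingclassify import (
    ArchitectureConfig,
    AugmentConfig,
    SplitSpec,
    TrainConfig,
    augment_set,
    build_network,
    export_history,
    split_dataset,
    train,
)
from wingclassify.preprocessing import ImageRecord, LabeledImageSet


def _toy_set(n_per_class, classes=("a", "b"), size=8):
    rng = np.random.default_rng(0)
    records = [
        ImageRecord(id=f"{c}{i}", pixels=rng.random((size, size, 1)).astype(np.float32),
                    class_label=c)
        for c in classes
        for i in range(n_per_class)
    ]
    return LabeledImageSet(records=records, classes=list(classes))


class TestSplitDataset:
    def test_largest_remainder_per_class(self):
        ds = _toy_set(20, classes=tuple("abcdefg"))
        out = split_dataset(ds, SplitSpec(seed=1))
        for c in ds.classes:
            by_split = {s: 0 for s in ("train", "val", "test")}
            for r in out.records:
                if r.class_label == c:
                    by_split[r.split] += 1
            assert (by_split["train"], by_split["val"], by_split["test"]) == (14, 3, 3)

    def test_exact_fractions_single_class(self):
        ds = _toy_set(100, classes=("only",))
        out = split_dataset(ds, SplitSpec(seed=2, stratified=False))
        counts = {s: sum(r.split == s for r in out.records) for s in ("train", "val", "test")}
        assert counts == {"train": 70, "val": 15, "test": 15}

    def test_disjoint_and_exhaustive(self, tiny_dataset):
        tags = [r.split for r in tiny_dataset.records]
        assert all(t in ("train", "val", "test") for t in tags)
        ids = [r.id for r in tiny_dataset.records]
        assert len(set(ids)) == len(ids)

    def test_seeded_determinism(self):
        ds = _toy_set(10)
        a = split_dataset(ds, SplitSpec(seed=5))
        b = split_dataset(ds, SplitSpec(seed=5))
        assert [(r.id, r.split) for r in a.records] == [(r.id, r.split) for r in b.records]

    def test_tiny_class_rejected(self):
        ds = _toy_set(2)
        with pytest.raises(ValueError, match="a"):
            split_dataset(ds, SplitSpec(seed=1))

    def test_already_assigned_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            split_dataset(tiny_dataset, SplitSpec(seed=1))

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SplitSpec(0.75, 0.15, 0.15)
        with pytest.raises(ValueError):
            SplitSpec(-0.1, 0.55, 0.55)


class TestTrainLoop:
    def test_history_has_one_record_per_epoch(self, tiny_dataset):
        aug = augment_set(tiny_dataset.subset("train"), AugmentConfig(factor=2, seed=1))
        net = build_network(
            ArchitectureConfig(input_channels=1, n_classes=3, input_size=64), seed=1
        )
        _, hist = train(net, aug, tiny_dataset.subset("val"),
                        TrainConfig(epochs=2, batch_size=8, seed=1))
        assert len(hist) == 2
        for r in hist.records:
            assert 0.0 <= r.train_acc <= 1.0
            assert 0.0 <= r.val_acc <= 1.0

    def test_zero_epochs_forbidden(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)

    def test_empty_train_set_rejected(self, tiny_dataset):
        empty = LabeledImageSet(records=[], classes=list(tiny_dataset.classes))
        net = build_network(
            ArchitectureConfig(input_channels=1, n_classes=3, input_size=64)
        )
        with pytest.raises(ValueError):
            train(net, empty, tiny_dataset.subset("val"), TrainConfig(epochs=1))

    def test_test_tagged_records_rejected(self, tiny_dataset):
        net = build_network(
            ArchitectureConfig(input_channels=1, n_classes=3, input_size=64)
        )
        with pytest.raises(ValueError, match="test"):
            train(net, tiny_dataset.subset("test"), tiny_dataset.subset("val"),
                  TrainConfig(epochs=1))

    def test_learns_separable_synthetic_data(self, benchmark_result):
        """On the separable synthetic benchmark the loss trend must be downward:
        mean train loss over the last 3 epochs below the first 3, and final
        train accuracy above the first epoch's."""
        records = benchmark_result.history.records
        first3 = np.mean([r.train_loss for r in records[:3]])
        last3 = np.mean([r.train_loss for r in records[-3:]])
        assert last3 < first3
        assert records[-1].train_acc > records[0].train_acc

    def test_identical_seeds_identical_history(self, tiny_dataset):
        aug = augment_set(tiny_dataset.subset("train"), AugmentConfig(factor=2, seed=3))
        hists = []
        for _ in range(2):
            net = build_network(
                ArchitectureConfig(input_channels=1, n_classes=3, input_size=64), seed=7
            )
            _, h = train(net, aug, tiny_dataset.subset("val"),
                         TrainConfig(epochs=2, batch_size=8, seed=7))
            hists.append(h.records)
        assert hists[0] == hists[1]


class TestExportHistory:
    def test_csv_round_trip(self, tiny_dataset, tmp_path):
        aug = augment_set(tiny_dataset.subset("train"), AugmentConfig(factor=1, seed=1))
        net = build_network(
            ArchitectureConfig(input_channels=1, n_classes=3, input_size=64), seed=1
        )
        _, hist = train(net, aug, tiny_dataset.subset("val"),
                        TrainConfig(epochs=2, batch_size=8, seed=1))
        csv_path, png_path = export_history(hist, tmp_path)
        frame = pd.read_csv(csv_path)
        assert list(frame.columns) == ["epoch", "train_loss", "train_acc", "val_loss", "val_acc"]
        assert len(frame) == 2
        assert np.allclose(frame["train_loss"], [r.train_loss for r in hist.records])
        assert png_path.exists()

    def test_empty_history_rejected(self, tmp_path):
        from wingclassify.training import TrainingHistory

        with pytest.raises(ValueError):
            export_history(TrainingHistory(), tmp_path)
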