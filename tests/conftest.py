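import numpy as np
import pytest

from wingclassify import (
    ArchitectureConfig,
    AugmentConfig,
    SplitSpec,
    TrainConfig,
    augment_set,
    build_network,
    generate_dataset,
    make_species_specs,
    split_dataset,
    train,
)


@pytest.fixture(scope="session")
def specs3():
    return make_species_specs(3, seed=11)


@pytest.fixture(scope="session")
def tiny_dataset(specs3):
    """3 classes x 8 grayscale wings at 64 px, split 70/15/15."""
    ds = generate_dataset(specs3, n_per_class=8, seed=21, channels=1, size=64)
    return split_dataset(ds, SplitSpec(seed=31))


@pytest.fixture(scope="session")
def trained_tiny_net(tiny_dataset):
    """A briefly trained 3-class grayscale net at 64 px (for saliency tests)."""
    aug = augment_set(tiny_dataset.subset("train"), AugmentConfig(factor=4, seed=41))
    net = build_network(
        ArchitectureConfig(input_channels=1, n_classes=3, input_size=64), seed=51
    )
    net, _ = train(
        net,
        aug,
        tiny_dataset.subset("val"),
        TrainConfig(epochs=3, batch_size=16, learning_rate=0.002, seed=61),
    )
    return net


@pytest.fixture(scope="session")
def benchmark_result():
    """The full desk-scale synthetic-recovery study (shared across tests)."""
    from wingclassify.benchmark import run_synthetic_recovery

    return run_synthetic_recovery(seed=0)


@pytest.fixture
def zero_net():
    net = build_network(
        ArchitectureConfig(input_channels=1, n_classes=3, input_size=64), seed=0
    )
    for layer in net.layers:
        for _, p in layer.params():
            p[...] = 0.0
    return net


@pytest.fixture
def rng():
    return np.random.default_rng(123)
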