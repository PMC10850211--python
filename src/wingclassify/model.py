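"""The shallow wing-classification CNN.

Architecture: four blocks of (3x3 same-padding convolution -> ReLU -> 2x2
max-pool) followed by a single fully-connected layer mapping the flattened
feature volume straight to the class logits — there are no hidden dense
layers.  The binary (2-way) and species-level (7-way) variants differ only in
the width of that last layer; the grayscale and RGB variants differ only in
the first convolution's input channels.

The network, including all backward passes and the Adam optimizer, is
implemented directly on NumPy arrays.  Writing the backward pass by hand is
what makes Guided Grad-CAM straightforward: the ReLU layers accept a "guided"
backward mode (gradients pass only where both the forward activation and the
incoming gradient are positive) and the last pooled feature map exposes its
activations and gradients for class-activation mapping.

Layout convention: batches are NCHW float32; single images enter and leave
the public API as HWC (matching the rest of the package).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ArchitectureConfig",
    "Network",
    "build_network",
    "count_layers",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ArchitectureConfig:
    """Topology knobs for the shallow CNN.

    input_channels : 1 (grayscale) or 3 (RGB).
    n_classes      : width of the final fully-connected layer (2 or 7 in the
                     reference experiments; any >= 2 accepted).
    conv_channels  : widths of the four convolution blocks.
    kernel_size    : square kernel side, odd (same padding).
    input_size     : square input side; must be divisible by 2**4 for the
                     four pooling stages.
    """

    input_channels: int = 3
    n_classes: int = 7
    conv_channels: tuple[int, int, int, int] = (16, 32, 64, 128)
    kernel_size: int = 3
    pool: str = "max2"
    activation: str = "relu"
    input_size: int = 256

    def __post_init__(self) -> None:
        if self.input_channels not in (1, 3):
            raise ValueError(f"input_channels must be 1 or 3, got {self.input_channels}")
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        if len(self.conv_channels) != 4:
            raise ValueError("conv_channels must have exactly 4 entries")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd (same padding)")
        if self.pool != "max2" or self.activation != "relu":
            raise ValueError("only pool='max2' and activation='relu' are implemented")
        if self.input_size % 16 != 0:
            raise ValueError(
                f"input_size must be divisible by 16 (four 2x2 pooling stages), "
                f"got {self.input_size}"
            )


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class Conv2D:
    """3x3 (k x k) same-padding convolution, stride 1, via im2col GEMM."""

    kind = "conv"

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        fan_in = in_ch * k * k
        scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU networks
        self.W = (rng.standard_normal((out_ch, in_ch, k, k)) * scale).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.k = k
        self._cols = None
        self._in_shape = None

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        # (N, C, H, W, k, k) -> (N*H*W, C*k*k)
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * self.k * self.k
        )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        cols = self._im2col(x)
        out = cols @ self.W.reshape(self.W.shape[0], -1).T + self.b
        if train:
            self._cols = cols
            self._in_shape = x.shape
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c_in, h, w = self._in_shape
        g = grad.transpose(0, 2, 3, 1).reshape(n * h * w, -1)  # (NHW, out)
        self.dW = (g.T @ self._cols).reshape(self.W.shape).astype(np.float32)
        self.db = g.sum(axis=0).astype(np.float32)
        dcols = g @ self.W.reshape(self.W.shape[0], -1)  # (NHW, C*k*k)
        # col2im: scatter-add each kernel tap back into the padded input grid.
        p = self.k // 2
        dxp = np.zeros((n, c_in, h + 2 * p, w + 2 * p), dtype=np.float32)
        dcols = dcols.reshape(n, h, w, c_in, self.k, self.k)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + h, p : p + w]


class ReLU:
    kind = "relu"

    def __init__(self):
        self._pos = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        pos = x > 0
        if train:
            self._pos = pos
        return np.where(pos, x, 0.0).astype(np.float32)

    def backward(self, grad: np.ndarray, guided: bool = False) -> np.ndarray:
        g = np.where(self._pos, grad, 0.0)
        if guided:
            g = np.where(g > 0, g, 0.0)  # deconv-style: drop negative gradients too
        return g.astype(np.float32)


class MaxPool2:
    """2x2, stride-2 max pooling."""

    kind = "pool"

    def __init__(self):
        self._argmax = None
        self._in_shape = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4
        )
        arg = r.argmax(axis=-1)
        if train:
            self._argmax = arg
            self._in_shape = x.shape
        return np.take_along_axis(r, arg[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(out, self._argmax[..., None], grad[..., None], axis=-1)
        return out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h, w
        )


class Flatten:
    kind = "flatten"

    def __init__(self):
        self._in_shape = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._in_shape)


class Linear:
    kind = "fc"

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_dim)
        self.W = (rng.standard_normal((out_dim, in_dim)) * scale).astype(np.float32)
        self.b = np.zeros(out_dim, dtype=np.float32)
        self._x = None

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW = (grad.T @ self._x).astype(np.float32)
        self.db = grad.sum(axis=0).astype(np.float32)
        return (grad @ self.W).astype(np.float32)


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


@dataclass
class Network:
    """The assembled CNN: ordered layers plus its architecture config."""

    config: ArchitectureConfig
    layers: list = field(default_factory=list)
    seed: int = 0

    #: index (into ``layers``) of the last conv block's pooled output — the
    #: feature map Grad-CAM hooks into.
    @property
    def last_feature_index(self) -> int:
        pools = [i for i, l in enumerate(self.layers) if l.kind == "pool"]
        return pools[-1]

    def parameter_count(self) -> int:
        return sum(int(np.prod(p.shape)) for l in self.layers for _, p in l.params())

    def layer_census(self) -> dict[str, int]:
        census: dict[str, int] = {}
        for l in self.layers:
            census[l.kind] = census.get(l.kind, 0) + 1
        return census

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Logits for an NCHW batch."""
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray, guided: bool = False) -> np.ndarray:
        """Propagate a logit-space gradient back to the input; returns dX."""
        for l in reversed(self.layers):
            if l.kind == "relu":
                grad = l.backward(grad, guided=guided)
            else:
                grad = l.backward(grad)
        return grad

    def forward_with_features(self, x: np.ndarray):
        """Logits plus the last pooled conv feature map (train-mode caches on)."""
        feats = None
        for i, l in enumerate(self.layers):
            x = l.forward(x, train=True)
            if i == self.last_feature_index:
                feats = x
        return x, feats

    def backward_to_features(self, grad: np.ndarray) -> np.ndarray:
        """Gradient of a logit-space seed w.r.t. the last pooled feature map."""
        for l in reversed(self.layers[self.last_feature_index + 1 :]):
            grad = l.backward(grad)
        return grad


def build_network(config: ArchitectureConfig, seed: int = 0) -> Network:
    """Assemble the four conv blocks and the single fully-connected head."""
    rng = np.random.default_rng(seed)
    layers: list = []
    in_ch = config.input_channels
    for out_ch in config.conv_channels:
        layers.append(Conv2D(in_ch, out_ch, config.kernel_size, rng))
        layers.append(ReLU())
        layers.append(MaxPool2())
        in_ch = out_ch
    layers.append(Flatten())
    side = config.input_size // 16
    layers.append(Linear(in_ch * side * side, config.n_classes, rng))
    return Network(config=config, layers=layers, seed=seed)


def count_layers(net: Network) -> tuple[int, int]:
    """(number of convolutional layers, number of fully-connected layers)."""
    census = net.layer_census()
    return census.get("conv", 0), census.get("fc", 0)


def batch_from_images(images: np.ndarray | list[np.ndarray]) -> np.ndarray:
    """Stack HWC images (or one image) into an NCHW float32 batch."""
    if isinstance(images, np.ndarray) and images.ndim == 3:
        images = [images]
    arrs = []
    for im in images:
        im = np.asarray(im, dtype=np.float32)
        if im.ndim == 2:
            im = im[:, :, None]
        arrs.append(im.transpose(2, 0, 1))
    return np.stack(arrs)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def predict(net: Network, images, batch_size: int = 64) -> np.ndarray:
    """Class-probability vectors for a batch of HWC images.

    Each row is non-negative and sums to 1; the argmax is the predicted
    class index in the order of the training class vocabulary.
    """
    x = batch_from_images(images)
    expected = (net.config.input_channels, net.config.input_size, net.config.input_size)
    if x.shape[1:] != expected:
        raise ValueError(f"expected images of CHW shape {expected}, got {x.shape[1:]}")
    out = []
    for i in range(0, x.shape[0], batch_size):
        logits = net.forward(x[i : i + batch_size], train=False)
        out.append(softmax(logits))
    return np.concatenate(out, axis=0)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------


def save_checkpoint(net: Network, path: str | Path) -> None:
    """Persist weights + architecture + seed as a JSON file (text format)."""
    payload = {
        "config": {
            "input_channels": net.config.input_channels,
            "n_classes": net.config.n_classes,
            "conv_channels": list(net.config.conv_channels),
            "kernel_size": net.config.kernel_size,
            "pool": net.config.pool,
            "activation": net.config.activation,
            "input_size": net.config.input_size,
        },
        "seed": net.seed,
        "weights": [
            {name: p.astype(np.float64).ravel().tolist() for name, p in l.params()}
            for l in net.layers
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path: str | Path) -> Network:
    with open(path) as fh:
        payload = json.load(fh)
    cfg = payload["config"]
    config = ArchitectureConfig(
        input_channels=cfg["input_channels"],
        n_classes=cfg["n_classes"],
        conv_channels=tuple(cfg["conv_channels"]),
        kernel_size=cfg["kernel_size"],
        pool=cfg["pool"],
        activation=cfg["activation"],
        input_size=cfg["input_size"],
    )
    net = build_network(config, seed=payload["seed"])
    for layer, saved in zip(net.layers, payload["weights"]):
        for name, p in layer.params():
            p[...] = np.asarray(saved[name], dtype=np.float32).reshape(p.shape)
    return net
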