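"""Guided Grad-CAM interpretability for the wing CNN.

Two complementary gradient views are combined:

* Grad-CAM — gradients of the target-class score with respect to the last
  convolutional block's (pooled) feature maps are spatially averaged into
  per-channel weights; the rectified weighted sum of the activation maps is a
  coarse, class-discriminative localization grid.
* Guided backpropagation — a backward pass to the input image in which every
  ReLU passes a gradient only where both its forward activation and the
  incoming gradient are positive, yielding a sharp pixel-resolution map.

Their elementwise product (after bilinear upsampling of the coarse map to
input resolution) is class-discriminative AND high-resolution; on wing
images it concentrates on the vein network.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .model import Network, batch_from_images

__all__ = [
    "SaliencyMap",
    "grad_cam",
    "guided_backprop",
    "guided_grad_cam",
    "overlay",
    "export_overlays",
]


@dataclass
class SaliencyMap:
    """Coarse CAM, pixel-level guided gradients, and their fused product."""

    cam: np.ndarray  # (h, w) non-negative, max-normalized to 1 when nonzero
    guided_grad: np.ndarray  # (H, W) channel-collapsed gradient magnitudes
    fused: np.ndarray  # (H, W) non-negative, upsampled cam * guided_grad
    target_class: str
    image_id: str

    def __post_init__(self) -> None:
        if (self.cam < 0).any() or (self.fused < 0).any():
            raise ValueError("cam and fused maps must be non-negative")
        if self.fused.shape != self.guided_grad.shape:
            raise ValueError("fused and guided_grad must share H x W")


def _check_input(net: Network, image: np.ndarray) -> np.ndarray:
    x = batch_from_images(image)
    expected = (net.config.input_channels, net.config.input_size, net.config.input_size)
    if x.shape[1:] != expected:
        raise ValueError(f"expected CHW {expected}, got {x.shape[1:]}")
    return x


def _class_index(net: Network, target_class: int) -> int:
    idx = int(target_class)
    if not 0 <= idx < net.config.n_classes:
        raise ValueError(
            f"target class index {idx} outside [0, {net.config.n_classes})"
        )
    return idx


def grad_cam(net: Network, image: np.ndarray, target_class: int) -> np.ndarray:
    """Coarse class-activation map on the last conv block's feature grid.

    Channel weights are the spatial means of the target-logit gradient with
    respect to the feature maps; the cam is the ReLU of the weighted sum of
    activations, normalized to max 1 when any activation survives.  Spatial
    side = input_size / 2**4 (four pooling stages).
    """
    x = _check_input(net, image)
    idx = _class_index(net, target_class)
    logits, feats = net.forward_with_features(x)
    seed = np.zeros_like(logits)
    seed[0, idx] = 1.0
    dfeats = net.backward_to_features(seed)  # (1, C, h, w)
    weights = dfeats[0].mean(axis=(1, 2))  # (C,)
    cam = np.maximum((weights[:, None, None] * feats[0]).sum(axis=0), 0.0)
    m = cam.max()
    if m > 0:
        cam = cam / m
    return cam.astype(np.float32)


def guided_backprop(net: Network, image: np.ndarray, target_class: int) -> np.ndarray:
    """Pixel-resolution gradient of the target logit under the guided rule.

    Channels are collapsed by the maximum absolute value, giving an (H, W)
    magnitude map.
    """
    x = _check_input(net, image)
    idx = _class_index(net, target_class)
    logits = net.forward(x, train=True)
    seed = np.zeros_like(logits)
    seed[0, idx] = 1.0
    dx = net.backward(seed, guided=True)  # (1, C, H, W)
    return np.abs(dx[0]).max(axis=0).astype(np.float32)


def guided_grad_cam(
    net: Network, image: np.ndarray, target_class: int, image_id: str = "", class_name: str | None = None
) -> SaliencyMap:
    """Fuse the upsampled Grad-CAM with the guided-backprop map.

    The coarse cam is bilinearly upsampled to input resolution and multiplied
    elementwise with the guided gradient magnitudes; the product inherits
    non-negativity and the cam's class discrimination.
    """
    cam = grad_cam(net, image, target_class)
    guided = guided_backprop(net, image, target_class)
    factor = guided.shape[0] // cam.shape[0]
    cam_up = ndimage.zoom(cam, factor, order=1, mode="nearest", grid_mode=True)
    fused = np.maximum(cam_up * guided, 0.0)
    return SaliencyMap(
        cam=cam,
        guided_grad=guided,
        fused=fused.astype(np.float32),
        target_class=class_name if class_name is not None else str(target_class),
        image_id=image_id,
    )


def overlay(
    smap: SaliencyMap,
    image: np.ndarray,
    alpha: float = 0.5,
    colormap: str = "inferno",
) -> np.ndarray:
    """Alpha-blend the fused heat map over the grayscale-rendered original.

    The fused map is max-normalized for display, mapped through a perceptual
    colormap and blended with weight ``alpha``; output is H x W x 3 in [0,1].
    """
    import matplotlib

    matplotlib.use("Agg")

    if image.ndim == 2:
        image = image[:, :, None]
    if image.shape[:2] != smap.fused.shape:
        raise ValueError(
            f"saliency map {smap.fused.shape} does not match image {image.shape[:2]}"
        )
    gray = image.mean(axis=2) if image.shape[2] > 1 else image[:, :, 0]
    heat = smap.fused
    m = heat.max()
    heat = heat / m if m > 0 else heat
    rgb_heat = matplotlib.colormaps[colormap](heat)[:, :, :3]
    base = np.repeat(gray[:, :, None], 3, axis=2)
    return np.clip((1.0 - alpha) * base + alpha * rgb_heat, 0.0, 1.0).astype(np.float32)


def export_overlays(
    net: Network,
    images: list[tuple[str, np.ndarray, int]],
    out_dir: str | Path,
    classes: list[str] | None = None,
    alpha: float = 0.5,
    colormap: str = "inferno",
) -> list[Path]:
    """Write one overlay PNG and one raw fused-map PNG per (id, image, class).

    Returns the overlay paths; file count equals the number of input images.
    """
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for image_id, image, target in images:
        name = classes[target] if classes else str(target)
        smap = guided_grad_cam(net, image, target, image_id=image_id, class_name=name)
        comp = overlay(smap, image, alpha=alpha, colormap=colormap)
        path = out_dir / f"{image_id}_overlay.png"
        Image.fromarray(np.round(comp * 255.0).astype(np.uint8), "RGB").save(path)
        fused = smap.fused
        m = fused.max()
        fused8 = np.round((fused / m if m > 0 else fused) * 255.0).astype(np.uint8)
        Image.fromarray(fused8, "L").save(out_dir / f"{image_id}_fused.png")
        paths.append(path)
    return paths
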