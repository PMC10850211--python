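"""Stochastic training-set expansion.

Each training image is replaced by ``factor`` (default 32) random variants
drawn from a bounded transform envelope: rotation in +/- 15 degrees, horizontal
and vertical shift in +/- 20% of the side, zoom-in up to 1.5x, and a random
crop removing up to 40% of the side length.  Validation and test images are
never augmented.

The four operations compose in a fixed, documented order —
crop -> zoom -> rotate -> shift — realized as a single bilinear warp so that
repeated resampling does not compound interpolation blur.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .preprocessing import LabeledImageSet

__all__ = ["AugmentConfig", "TransformParams", "sample_transform", "apply_transform", "augment_set"]


@dataclass(frozen=True)
class AugmentConfig:
    """Bounds of the stochastic transform envelope.

    rotation_deg  : symmetric rotation bound in degrees (default 15).
    shift_frac    : symmetric shift bound as a fraction of the side (default 0.20).
    zoom_max      : maximum zoom-in factor, >= 1 (default 1.5; no zoom-out).
    crop_max_frac : maximum fraction of side length removed by the crop (default 0.40).
    factor        : number of variants generated per source image (default 32).
    fill_mode     : how out-of-frame pixels are filled ("reflect" or "constant").
    seed          : RNG seed for the whole expansion.
    """

    rotation_deg: float = 15.0
    shift_frac: float = 0.20
    zoom_max: float = 1.5
    crop_max_frac: float = 0.40
    factor: int = 32
    fill_mode: str = "reflect"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rotation_deg < 0:
            raise ValueError("rotation_deg must be >= 0")
        if not 0.0 <= self.shift_frac <= 1.0:
            raise ValueError("shift_frac must be in [0, 1]")
        if self.zoom_max < 1.0:
            raise ValueError("zoom_max must be >= 1")
        if not 0.0 <= self.crop_max_frac < 1.0:
            raise ValueError("crop_max_frac must be in [0, 1)")
        if self.factor < 1:
            raise ValueError("factor must be >= 1")
        if self.fill_mode not in ("reflect", "constant"):
            raise ValueError(f"fill_mode must be 'reflect' or 'constant', got {self.fill_mode!r}")


@dataclass(frozen=True)
class TransformParams:
    """One sampled realization of the transform envelope."""

    angle: float  # degrees
    dx: float  # fraction of width
    dy: float  # fraction of height
    zoom: float
    crop_frac: float
    crop_cx: float = 0.5  # crop-window center, fraction of side
    crop_cy: float = 0.5

    @property
    def is_identity(self) -> bool:
        return (
            self.angle == 0.0
            and self.dx == 0.0
            and self.dy == 0.0
            and self.zoom == 1.0
            and self.crop_frac == 0.0
        )


def sample_transform(rng: np.random.Generator, config: AugmentConfig) -> TransformParams:
    """Draw each transform field independently and uniformly from its bound."""
    crop_frac = float(rng.uniform(0.0, config.crop_max_frac))
    # The crop window's center is uniform over positions keeping it in frame.
    half = (1.0 - crop_frac) / 2.0
    return TransformParams(
        angle=float(rng.uniform(-config.rotation_deg, config.rotation_deg)),
        dx=float(rng.uniform(-config.shift_frac, config.shift_frac)),
        dy=float(rng.uniform(-config.shift_frac, config.shift_frac)),
        zoom=float(rng.uniform(1.0, config.zoom_max)),
        crop_frac=crop_frac,
        crop_cx=float(rng.uniform(half, 1.0 - half)),
        crop_cy=float(rng.uniform(half, 1.0 - half)),
    )


def apply_transform(
    image: np.ndarray, params: TransformParams, fill_mode: str = "reflect"
) -> np.ndarray:
    """Apply crop -> zoom -> rotate -> shift to a square image.

    The crop extracts a random-centered window of side (1 - crop_frac) * size
    and rescales it back to full size; zoom and rotation act about the image
    center; the shift translates by round(dx * W) columns and round(dy * H)
    rows.  Output shape equals input shape; the composition is executed as one
    bilinear ``affine_transform`` (output->input coordinate map).
    """
    if image.ndim == 2:
        image = image[:, :, None]
    h, w = image.shape[:2]
    if h != w:
        raise ValueError(f"apply_transform requires a square image, got {h}x{w}")
    if params.is_identity:
        return image.astype(np.float32).copy()

    size = float(h)
    c = (size - 1) / 2.0  # rotation/zoom pivot in pixel coordinates (rows, cols)

    # Build the forward maps stage by stage (row, col homogeneous 3x3), then
    # invert the composite for scipy's output->input convention.
    def translation(ty, tx):
        m = np.eye(3)
        m[0, 2], m[1, 2] = ty, tx
        return m

    def scaling(s):
        m = np.eye(3)
        m[0, 0] = m[1, 1] = s
        return m

    # Crop: window of side s_w centered at (crop_cy, crop_cx) * size, resized back.
    s_w = (1.0 - params.crop_frac) * size
    crop = (
        scaling(size / s_w)
        @ translation(-(params.crop_cy * size - s_w / 2.0), -(params.crop_cx * size - s_w / 2.0))
    )
    zoom = translation(c, c) @ scaling(params.zoom) @ translation(-c, -c)
    th = np.deg2rad(params.angle)
    rot = np.eye(3)
    rot[0, 0], rot[0, 1] = np.cos(th), -np.sin(th)
    rot[1, 0], rot[1, 1] = np.sin(th), np.cos(th)
    rot = translation(c, c) @ rot @ translation(-c, -c)
    shift = translation(round(params.dy * h), round(params.dx * w))

    forward = shift @ rot @ zoom @ crop
    inverse = np.linalg.inv(forward)

    out = np.empty_like(image, dtype=np.float32)
    mode = "reflect" if fill_mode == "reflect" else "constant"
    for ch in range(image.shape[2]):
        out[:, :, ch] = ndimage.affine_transform(
            image[:, :, ch].astype(np.float32),
            inverse[:2, :2],
            offset=inverse[:2, 2],
            order=1,
            mode=mode,
            cval=0.0,
        )
    return np.clip(out, 0.0, 1.0)


def augment_set(images: LabeledImageSet, config: AugmentConfig) -> LabeledImageSet:
    """Expand a training subset ``factor``-fold with sampled transforms.

    Every record must carry the "train" tag; each output record keeps its
    source's class label and is named ``<source id>#<variant index>``.
    Deterministic for a given ``config.seed``.
    """
    for r in images.records:
        if r.split != "train":
            raise ValueError(
                f"augment_set expects only train records; {r.id!r} is tagged {r.split!r}"
            )
    rng = np.random.default_rng(config.seed)
    out = []
    for r in images.records:
        for v in range(config.factor):
            params = sample_transform(rng, config)
            out.append(
                replace(
                    r,
                    id=f"{r.id}#{v}",
                    pixels=apply_transform(r.pixels, params, config.fill_mode),
                )
            )
    return LabeledImageSet(records=out, classes=list(images.classes))
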