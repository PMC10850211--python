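"""Image loading and the fixed preprocessing applied to every wing photograph.

The pipeline's deterministic front end: decode an image file, crop the largest
centered square, resize to the network input size (256 x 256 by default) and
optionally collapse to grayscale.  All pixel values live in [0, 1] as float32
H x W x C arrays (C = 1 for grayscale, 3 for RGB) throughout the package.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "PreprocessConfig",
    "ImageRecord",
    "LabeledImageSet",
    "load_image",
    "center_crop",
    "to_grayscale",
    "resize",
    "preprocess",
    "load_image_set",
]

#: ITU-R BT.601 luminosity weights used for RGB -> grayscale conversion.
GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114], dtype=np.float64)

SPLITS = ("train", "val", "test", "unassigned")


@dataclass(frozen=True)
class PreprocessConfig:
    """Fixed preprocessing parameters.

    target_size : side length of the square network input, pixels (>= 32).
    color_mode  : "rgb" (3 channels) or "grayscale" (1 channel).
    crop_mode   : only "center" is defined — crop the largest centered square.
    """

    target_size: int = 256
    color_mode: str = "rgb"
    crop_mode: str = "center"

    def __post_init__(self) -> None:
        if self.target_size < 32:
            raise ValueError(f"target_size must be >= 32, got {self.target_size}")
        if self.color_mode not in ("rgb", "grayscale"):
            raise ValueError(f"color_mode must be 'rgb' or 'grayscale', got {self.color_mode!r}")
        if self.crop_mode != "center":
            raise ValueError(f"only crop_mode='center' is supported, got {self.crop_mode!r}")

    @property
    def channels(self) -> int:
        return 3 if self.color_mode == "rgb" else 1


@dataclass
class ImageRecord:
    """One labeled image: id, float pixel grid in [0,1], class label, split tag."""

    id: str
    pixels: np.ndarray  # H x W x C, float32, values in [0, 1]
    class_label: str
    split: str = "unassigned"

    def __post_init__(self) -> None:
        if self.split not in SPLITS:
            raise ValueError(f"split must be one of {SPLITS}, got {self.split!r}")


@dataclass
class LabeledImageSet:
    """A collection of labeled images with an ordered class vocabulary."""

    records: list[ImageRecord] = field(default_factory=list)
    classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in LabeledImageSet")
        known = set(self.classes)
        for r in self.records:
            if r.class_label not in known:
                raise ValueError(f"record {r.id!r} has label {r.class_label!r} not in classes")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, split: str) -> "LabeledImageSet":
        """Records carrying the given split tag, sharing the class vocabulary."""
        if split not in SPLITS:
            raise ValueError(f"unknown split {split!r}")
        return LabeledImageSet(
            records=[r for r in self.records if r.split == split],
            classes=list(self.classes),
        )

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.classes}
        for r in self.records:
            counts[r.class_label] += 1
        return counts

    def map_images(self, fn) -> "LabeledImageSet":
        """Apply ``fn`` to every record's pixels, keeping ids/labels/splits."""
        return LabeledImageSet(
            records=[replace(r, pixels=fn(r.pixels)) for r in self.records],
            classes=list(self.classes),
        )


def load_image(path: str | Path, color_mode: str = "rgb") -> np.ndarray:
    """Decode a PNG/TIFF/JPEG file into an H x W x C float grid in [0, 1].

    C is 3 for ``color_mode="rgb"`` and 1 for ``"grayscale"`` (luminosity
    conversion applied at load time for color sources).
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.float32) / 255.0
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot decode image file {path}: {exc}") from exc
    if color_mode == "grayscale":
        return to_grayscale(arr)
    if color_mode == "rgb":
        return arr
    raise ValueError(f"color_mode must be 'rgb' or 'grayscale', got {color_mode!r}")


def _as_hwc(image: np.ndarray) -> np.ndarray:
    if image.ndim == 2:
        return image[:, :, None]
    if image.ndim == 3 and image.shape[2] in (1, 3):
        return image
    raise ValueError(f"expected H x W or H x W x C (C in 1,3) image, got shape {image.shape}")


def center_crop(image: np.ndarray, size: int) -> np.ndarray:
    """Extract a ``size x size`` window centered on the image.

    Odd remainders are split with the smaller offset toward the top-left:
    offset = floor((dim - size) / 2).
    """
    image = _as_hwc(image)
    h, w = image.shape[:2]
    if size > min(h, w):
        raise ValueError(f"crop size {size} exceeds image min dimension {min(h, w)}")
    top = (h - size) // 2
    left = (w - size) // 2
    return image[top : top + size, left : left + size, :]


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse a 3-channel image to 1 channel with BT.601 luminosity weights."""
    image = _as_hwc(image)
    if image.shape[2] != 3:
        raise ValueError(f"to_grayscale expects 3 channels, got {image.shape[2]}")
    gray = image.astype(np.float64) @ GRAY_WEIGHTS
    return np.clip(gray, 0.0, 1.0).astype(np.float32)[:, :, None]


def resize(image: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize of a square or rectangular image to ``size x size``."""
    image = _as_hwc(image)
    if image.shape[0] == size and image.shape[1] == size:
        return image.astype(np.float32)
    channels = image.shape[2]
    arr = np.clip(image, 0.0, 1.0).astype(np.float32)
    if channels == 1:
        pil = Image.fromarray((arr[:, :, 0] * 255.0).round().astype(np.uint8), mode="L")
    else:
        pil = Image.fromarray((arr * 255.0).round().astype(np.uint8), mode="RGB")
    out = np.asarray(pil.resize((size, size), Image.BILINEAR), dtype=np.float32) / 255.0
    return _as_hwc(out)


def preprocess(image: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Apply the fixed pipeline: center-crop to the largest square, resize, recolor.

    Output is always (target_size, target_size, C) with values in [0, 1];
    grayscale inputs under an rgb config are rejected (no channel invention).
    """
    config = config or PreprocessConfig()
    image = _as_hwc(image)
    h, w, c = image.shape
    if config.color_mode == "rgb" and c != 3:
        raise ValueError("rgb preprocessing requires a 3-channel input image")
    image = center_crop(image, min(h, w))
    image = resize(image, config.target_size)
    if config.color_mode == "grayscale" and image.shape[2] == 3:
        image = to_grayscale(image)
    return np.clip(image, 0.0, 1.0).astype(np.float32)


def load_image_set(
    manifest: str | Path,
    config: PreprocessConfig | None = None,
    root: str | Path | None = None,
) -> LabeledImageSet:
    """Load a dataset from a CSV manifest with header ``id,filepath,class,seed``.

    Relative file paths resolve against ``root`` (default: the manifest's
    directory).  Every image is run through :func:`preprocess`.
    """
    manifest = Path(manifest)
    root = Path(root) if root is not None else manifest.parent
    config = config or PreprocessConfig()
    records: list[ImageRecord] = []
    classes: list[str] = []
    with open(manifest, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "filepath", "class"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"manifest {manifest} must have columns {sorted(required)}")
        for row in reader:
            path = Path(row["filepath"])
            if not path.is_absolute():
                path = root / path
            pixels = preprocess(load_image(path, config.color_mode), config)
            if row["class"] not in classes:
                classes.append(row["class"])
            records.append(ImageRecord(id=row["id"], pixels=pixels, class_label=row["class"]))
    return LabeledImageSet(records=records, classes=classes)
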