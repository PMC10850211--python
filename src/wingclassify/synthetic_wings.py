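"""Procedural generation of labeled wing-like images.

Real mosquito wings are nearly two-dimensional: a pale membrane covered in
scales, crossed by a species-specific tree of dark longitudinal veins and
crossveins, photographed against a uniform dome-lit background.  This module
emulates exactly those ingredients — an elliptical silhouette on a bright
near-uniform background, a dark vein fan whose count and spread differ by
class, crossveins, and speckle texture — so that every downstream stage
(preprocessing, augmentation, CNN training, evaluation, saliency) can be
exercised on data with a known ground truth, including per-pixel vein masks.

The generator is deliberately not photorealistic.  It guarantees two things:
seeded bit-level determinism and class separability by construction (distinct
vein count / fan spread per class).
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .preprocessing import ImageRecord, LabeledImageSet

__all__ = [
    "SpeciesSpec",
    "RenderedWing",
    "make_species_specs",
    "render_wing",
    "generate_wings",
    "generate_dataset",
]

#: Mean background gray level (dome illumination) and its per-pixel noise.
BACKGROUND_LEVEL = 0.9
BACKGROUND_NOISE = 0.02
#: Membrane (wing interior) base intensity and vein darkness.
MEMBRANE_LEVEL = 0.78
VEIN_LEVEL = 0.22


@dataclass(frozen=True)
class SpeciesSpec:
    """Class-specific wing geometry.

    vein_count          : number of primary longitudinal veins (2-8 supported).
    branch_angle_mean   : mean angular spacing between adjacent veins, degrees.
    branch_angle_sd     : per-image Gaussian jitter on each vein angle, degrees.
    vein_thickness      : vein stroke thickness, pixels (>= 1) at a 256 canvas.
    crossvein_positions : fractions along the wing length where crossveins sit.
    speckle_density     : fraction of membrane pixels darkened as scales.
    base_tint           : RGB multiplier in [0,1]^3 applied to membrane/scales.
    """

    class_name: str
    vein_count: int
    branch_angle_mean: float
    branch_angle_sd: float
    vein_thickness: float
    crossvein_positions: tuple[float, ...]
    speckle_density: float
    base_tint: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.vein_count < 2:
            raise ValueError(f"vein_count must be >= 2, got {self.vein_count}")
        if self.vein_thickness < 1:
            raise ValueError(f"vein_thickness must be >= 1 px, got {self.vein_thickness}")
        for f in self.crossvein_positions:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"crossvein position {f} outside [0,1]")
        if not 0.0 <= self.speckle_density <= 1.0:
            raise ValueError(f"speckle_density {self.speckle_density} outside [0,1]")
        if not all(0.0 <= t <= 1.0 for t in self.base_tint):
            raise ValueError(f"base_tint {self.base_tint} outside [0,1]^3")


@dataclass
class RenderedWing:
    """One rendered wing: pixels in [0,1], exact vein-pixel mask, provenance."""

    pixels: np.ndarray  # H x W x C float32, C in {1, 3}
    vein_mask: np.ndarray  # H x W bool, True where vein ink was laid down
    class_name: str
    seed_used: int

    def __post_init__(self) -> None:
        if self.pixels.shape[:2] != self.vein_mask.shape:
            raise ValueError("pixels and vein_mask disagree on H x W")
        if not self.vein_mask.any():
            raise ValueError("vein_mask has no true pixel")


def make_species_specs(k: int, seed: int) -> list[SpeciesSpec]:
    """Create ``k`` species specs with pairwise-distinct vein geometry.

    Vein counts cycle 4..8 and fan spacings form a strictly increasing
    sequence, so every (vein_count, branch_angle_mean) pair is distinct and
    classes are separable by construction.  Deterministic per seed.
    """
    if k < 2:
        raise ValueError(f"need at least 2 classes, got k={k}")
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(k):
        n_cross = int(rng.integers(2, 4))
        specs.append(
            SpeciesSpec(
                class_name=f"species_{i:02d}",
                vein_count=4 + i % 5,
                branch_angle_mean=10.0 + 4.0 * i + float(rng.uniform(0.0, 2.0)),
                branch_angle_sd=float(rng.uniform(1.0, 2.5)),
                vein_thickness=float(rng.uniform(2.0, 3.5)),
                crossvein_positions=tuple(
                    float(x) for x in np.sort(rng.uniform(0.25, 0.85, size=n_cross))
                ),
                speckle_density=float(rng.uniform(0.02, 0.06)),
                base_tint=tuple(float(x) for x in rng.uniform(0.78, 1.0, size=3)),
            )
        )
    return specs


def _draw_segment(ink: np.ndarray, p0, p1, thickness: float) -> None:
    """Deposit an anti-aliased thick line segment onto the ink map (max-blend).

    Coverage is 1 inside the stroke and falls off linearly over one pixel at
    the edge, computed from the exact point-to-segment distance inside the
    segment's bounding box.
    """
    h, w = ink.shape
    x0, y0 = p0
    x1, y1 = p1
    r = thickness / 2.0 + 0.5
    lo_x = max(int(np.floor(min(x0, x1) - r - 1)), 0)
    hi_x = min(int(np.ceil(max(x0, x1) + r + 1)), w - 1)
    lo_y = max(int(np.floor(min(y0, y1) - r - 1)), 0)
    hi_y = min(int(np.ceil(max(y0, y1) + r + 1)), h - 1)
    if lo_x > hi_x or lo_y > hi_y:
        return
    ys, xs = np.mgrid[lo_y : hi_y + 1, lo_x : hi_x + 1]
    dx, dy = x1 - x0, y1 - y0
    seg_len2 = dx * dx + dy * dy
    if seg_len2 == 0:
        dist = np.hypot(xs - x0, ys - y0)
    else:
        t = np.clip(((xs - x0) * dx + (ys - y0) * dy) / seg_len2, 0.0, 1.0)
        dist = np.hypot(xs - (x0 + t * dx), ys - (y0 + t * dy))
    cov = np.clip(thickness / 2.0 + 0.5 - dist, 0.0, 1.0)
    region = ink[lo_y : hi_y + 1, lo_x : hi_x + 1]
    np.maximum(region, cov, out=region)


def _vein_paths(spec: SpeciesSpec, rng: np.random.Generator, size: int):
    """Polyline control points for each primary vein, fanning from the wing base."""
    cx = cy = size / 2.0
    a, b = 0.42 * size, 0.24 * size  # ellipse semi-axes
    root = np.array([cx - 0.92 * a, cy])
    n = spec.vein_count
    spread = spec.branch_angle_mean * (n - 1)
    base_angles = np.linspace(-spread / 2.0, spread / 2.0, n)
    base_angles = base_angles + rng.normal(0.0, spec.branch_angle_sd, size=n)
    paths = []
    for ang in np.deg2rad(base_angles):
        # March from the root toward the margin, bending gently, and stop at
        # the silhouette boundary so veins never cross the background.
        pts = [root.copy()]
        p = root.copy()
        step = 0.06 * size
        theta = ang
        for _ in range(40):
            p = p + step * np.array([np.cos(theta), np.sin(theta)])
            if ((p[0] - cx) / a) ** 2 + ((p[1] - cy) / b) ** 2 >= 0.96:
                break
            pts.append(p.copy())
            theta *= 0.93  # curvature: veins straighten toward the tip
        paths.append(np.array(pts))
    return paths, (cx, cy, a, b), root


def render_wing(
    spec: SpeciesSpec, seed: int, channels: int = 3, size: int = 256
) -> RenderedWing:
    """Render one wing image: silhouette, vein tree, crossveins, speckles.

    Bit-identical for identical (spec, seed, channels, size).  The returned
    ``vein_mask`` marks exactly the pixels touched by vein ink.
    """
    if channels not in (1, 3):
        raise ValueError(f"channels must be 1 or 3, got {channels}")
    if size < 64:
        raise ValueError(f"size must be >= 64, got {size}")
    rng = np.random.default_rng(seed)

    paths, (cx, cy, a, b), _root = _vein_paths(spec, rng, size)
    ys, xs = np.mgrid[0:size, 0:size]
    silhouette = ((xs - cx) / a) ** 2 + ((ys - cy) / b) ** 2 <= 1.0

    # Dome-lit background: bright, near-uniform, class-independent.
    gray = BACKGROUND_LEVEL + rng.uniform(-BACKGROUND_NOISE, BACKGROUND_NOISE, (size, size))
    # Membrane with mild texture.
    membrane = MEMBRANE_LEVEL + rng.normal(0.0, 0.01, (size, size))
    gray = np.where(silhouette, membrane, gray)

    # Scales: sparse darker speckles on the membrane.
    speckle = (rng.random((size, size)) < spec.speckle_density) & silhouette
    gray = np.where(speckle, gray - rng.uniform(0.08, 0.22, (size, size)), gray)

    # Vein ink: primary veins plus crossveins bridging adjacent veins.
    thickness = spec.vein_thickness * size / 256.0
    ink = np.zeros((size, size))
    for pts in paths:
        for p0, p1 in zip(pts[:-1], pts[1:]):
            _draw_segment(ink, p0, p1, max(thickness, 1.0))
    for frac in spec.crossvein_positions:
        for va, vb in zip(paths[:-1], paths[1:]):
            ia = min(int(round(frac * (len(va) - 1))), len(va) - 1)
            ib = min(int(round(frac * (len(vb) - 1))), len(vb) - 1)
            _draw_segment(ink, va[ia], vb[ib], max(0.7 * thickness, 1.0))

    gray = gray * (1.0 - ink) + VEIN_LEVEL * ink
    gray = np.clip(gray, 0.0, 1.0)
    vein_mask = ink > 0.05

    if channels == 3:
        tint = np.array(spec.base_tint)
        pix = gray[:, :, None] * np.ones(3)
        # Tint applies to membrane and scales only; background and veins stay neutral.
        pix = np.where(
            (silhouette & ~vein_mask)[:, :, None], gray[:, :, None] * tint[None, None, :], pix
        )
    else:
        pix = gray[:, :, None]
    return RenderedWing(
        pixels=np.clip(pix, 0.0, 1.0).astype(np.float32),
        vein_mask=vein_mask,
        class_name=spec.class_name,
        seed_used=int(seed),
    )


def wing_silhouette(size: int) -> np.ndarray:
    """Boolean mask of the elliptical wing silhouette at a given canvas size.

    The silhouette geometry is shared by every rendered wing (only the vein
    tree and texture vary), so downstream analyses — e.g. comparing saliency
    on vein pixels vs the rest of the wing membrane — can reuse it.
    """
    cx = cy = size / 2.0
    a, b = 0.42 * size, 0.24 * size
    ys, xs = np.mgrid[0:size, 0:size]
    return ((xs - cx) / a) ** 2 + ((ys - cy) / b) ** 2 <= 1.0


def _image_seed(seed: int, class_index: int, image_index: int) -> int:
    ss = np.random.SeedSequence([int(seed), class_index, image_index])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_wings(
    specs: list[SpeciesSpec],
    n_per_class: int,
    seed: int,
    channels: int = 3,
    size: int = 256,
) -> list[tuple[str, RenderedWing]]:
    """Render a balanced in-memory dataset: ``n_per_class`` wings per spec.

    Returns (record id, RenderedWing) pairs; ids are ``<class>_<index>``.
    Pixel values are quantized to the 8-bit grid so that in-memory data and
    PNG round-trips are bit-identical.
    """
    if n_per_class < 1:
        raise ValueError(f"n_per_class must be >= 1, got {n_per_class}")
    out = []
    for ci, spec in enumerate(specs):
        for j in range(n_per_class):
            s = _image_seed(seed, ci, j)
            wing = render_wing(spec, s, channels=channels, size=size)
            q = np.round(wing.pixels * 255.0).astype(np.uint8)
            wing.pixels = (q.astype(np.float32) / 255.0)
            out.append((f"{spec.class_name}_{j:04d}", wing))
    return out


def generate_dataset(
    specs: list[SpeciesSpec],
    n_per_class: int,
    seed: int,
    channels: int = 3,
    out_dir: str | Path | None = None,
    size: int = 256,
) -> LabeledImageSet:
    """Generate a balanced labeled dataset; optionally write PNGs + manifest.

    With ``out_dir`` set, writes one 8-bit PNG per wing, a CSV manifest with
    header ``id,filepath,class,seed`` and a JSON dump of the specs.  Returns
    the in-memory :class:`LabeledImageSet` either way.
    """
    wings = generate_wings(specs, n_per_class, seed, channels=channels, size=size)
    records = [
        ImageRecord(id=wid, pixels=w.pixels, class_label=w.class_name) for wid, w in wings
    ]
    classes = [s.class_name for s in specs]
    dataset = LabeledImageSet(records=records, classes=classes)

    if out_dir is not None:
        out_dir = Path(out_dir)
        try:
            (out_dir / "images").mkdir(parents=True, exist_ok=True)
            rows = []
            for wid, w in wings:
                arr = np.round(w.pixels * 255.0).astype(np.uint8)
                img = Image.fromarray(arr[:, :, 0], "L") if channels == 1 else Image.fromarray(arr, "RGB")
                rel = f"images/{wid}.png"
                img.save(out_dir / rel)
                rows.append((wid, rel, w.class_name, w.seed_used))
            with open(out_dir / "manifest.csv", "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["id", "filepath", "class", "seed"])
                writer.writerows(rows)
            with open(out_dir / "species_specs.json", "w") as fh:
                json.dump([asdict(s) for s in specs], fh, indent=2)
        except OSError as exc:
            raise OSError(f"cannot write dataset to {out_dir}: {exc}") from exc
    return dataset
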