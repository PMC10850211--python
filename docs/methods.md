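# Methods

## Problem and model

The package classifies single mosquito-wing images. The classifier is a
shallow CNN chosen to match small sample sizes and CPU-scale hardware: four
convolution blocks (3 × 3 kernels, same padding, widths 16/32/64/128, ReLU,
2 × 2 max-pool) and one fully-connected output layer mapping the flattened
4th-block features to K class logits, trained with softmax cross-entropy.
The binary (K = 2, *Aedes* vs non-*Aedes*) and species (K = 7) variants share
every layer except the head; the grayscale and RGB variants differ only in
the first convolution's input channels. Kernel size, widths, pooling and
activation are this package's defaults — the experimental protocol we follow
fixes only the depth (4 conv + 1 FC), the 256-px input, and the training
hyperparameters — and all are exposed in `ArchitectureConfig`.

The forward and backward passes and the Adam optimizer are implemented
directly on NumPy (im2col convolutions, argmax-routed pooling). The backward
pass is verified against central finite differences in the test suite; this
hand-rolled autodiff is what makes guided backpropagation a one-flag variant
of the standard backward pass rather than a framework surgery exercise.

## Fixed preprocessing

Images are decoded to float32 in [0, 1], cropped to the largest centered
square (offsets `floor((dim − size)/2)`, preserving the wing's aspect ratio),
bilinearly resized to `target_size` (default 256), and optionally collapsed
to one channel with ITU-R BT.601 weights (0.299 R + 0.587 G + 0.114 B). No
channel mean/std normalization is applied. Grayscale inputs under an RGB
config are rejected rather than channel-replicated.

## Augmentation envelope

Each training image is replaced by `factor` (default 32) variants. Per
variant, independent uniform draws give: rotation angle in ±15°, shift in
±20 % of the side (applied as a whole-pixel translation `round(frac·side)`),
zoom-in factor in [1, 1.5] (zoom-out is excluded), and a crop removing up to
40 % of the side length, window position uniform over in-frame placements.
The composition order crop → zoom → rotate → shift is fixed and documented;
it is executed as a single composed bilinear affine warp so repeated
resampling does not compound interpolation blur. Out-of-frame pixels are
filled by reflection (default) to avoid constant borders becoming a class
cue. Only the training split is augmented; validation and test images pass
through preprocessing unchanged.

## Splitting and training

Records are split 70/15/15 into train/validation/test, stratified per class
with largest-remainder rounding (ties favor train > val > test), seeded. The
loop runs exactly `epochs` (default 20) shuffled passes, batch size 100, one
Adam step per batch (lr 1.5 × 10⁻⁴, β = 0.9/0.999, ε = 10⁻⁸), with L2 weight
decay 5 × 10⁻⁴ added to the gradient (the coupled, framework-style
convention). There is no learning-rate schedule and no early stopping; the
final-epoch model is the product. Test-tagged records are rejected by
`train()` at the interface, so leakage is structurally impossible.

Reproducibility: one global seed fans out into named substreams (spec
generation, rendering, splitting, augmentation, weight init, batch
shuffling) via independent `SeedSequence`s, so changing one stage's
randomness never shifts another's. Identical configs give bit-identical
histories on one machine.

## Evaluation

The confusion matrix stores one column per true class. Per-class accuracy is
`100 · diagonal / column sum`, reported as round-half-up integers (13/17 →
76). Macro precision/recall/F1 are unweighted class means on the 0–100
scale; a class with a zero denominator contributes 0. Macro recall equals
the mean of the unrounded per-class accuracies — asserted as a cross-check,
and all three metrics are verified to 10⁻⁹ against scikit-learn on random
label vectors. Repeated runs (default 4, distinct seeds) are summarized as
mean/min/max per metric.

## Guided Grad-CAM

Grad-CAM hooks the last conv block's *pooled* feature map (16 × 16 for
256-px inputs, 4 × 4 for 64-px): channel weights are the spatial means of the
target-logit gradient, the map is the rectified weighted activation sum,
max-normalized when nonzero. Guided backpropagation repeats the backward
pass with every ReLU passing gradient only where both its forward activation
and the incoming gradient are positive; channels are collapsed by maximum
absolute value (sum is the exposed alternative). The fused map is the
bilinearly upsampled CAM multiplied elementwise with the guided map; the
seed of both passes is the raw class logit. Overlays alpha-blend (α = 0.5)
the max-normalized fused map through a perceptual colormap ("inferno") over
the grayscale-rendered original. Because the first convolution's transposed
backward pass spreads gradient support, neither map is exactly zero
anywhere; "guided is sharper" is therefore quantified on the effective
support (pixels above 1 % of each map's maximum).

## Synthetic wing generator

The generator emulates what matters for this pipeline: a bright near-uniform
dome-lit background (0.90 ± 0.02, deliberately class-independent so the
classifier cannot exploit illumination shortcuts), an elliptical membrane
(intensity ≈ 0.78, semi-axes 0.42/0.24 of the canvas), a vein fan rooted at
the wing base whose vein count (4–8) and angular spacing are distinct per
class by construction, crossveins bridging adjacent veins at spec-fixed
fractional positions, per-image Gaussian jitter on vein angles, and sparse
dark speckles standing in for scales. Veins are drawn as anti-aliased thick
polylines (exact point-to-segment distance coverage); every ink-touched
pixel is recorded in a per-image boolean vein mask, which is what allows the
saliency claim ("attention sits on the veins") to be tested quantitatively.
RGB renders tint membrane and scales with a per-class base tint; veins and
background stay neutral.

What it does *not* emulate: mounting-medium artifacts, damaged or folded
wings, microscope optics, perspective, inter-specimen allometry. Passing
tests on synthetic wings therefore demonstrate that the pipeline's machinery
is correct and that it recovers planted, vein-borne class structure — not
that any particular accuracy will transfer to photographs. Intra-class
variability magnitudes (angle jitter SD, speckle density ranges) are free
parameters of the generator with defaults chosen to make classes separable
but not trivially so (a nearest-centroid baseline on 16 × 16 thumbnails
clears chance by > 20 points, which the suite asserts).

## Desk-scale synthetic-recovery study

The end-to-end benchmark trains the real architecture on generated wings at
sizes a single CPU handles in about a minute: 3 classes × 50 grayscale
images at 64 px, 70/15/15 split, 8× augmentation, 10 epochs. Because this
yields roughly 60× fewer Adam updates than the full-scale protocol (~42
updates/epoch for 10 epochs vs ~288 for 20), the update budget is rescaled
once: batch size 20 and learning rate 1.5 × 10⁻³ (10× the full-scale rate).
These are fixed study conditions. Success criteria: macro F1 ≥ 90 % on the
held-out test split at the benchmark's fixed seed, and mean fused saliency
on vein-mask pixels exceeding the mean over the rest of the membrane.

Small-data training with Adam and no early stopping is visibly stochastic:
across seeds most runs end at 95–100 % macro F1, while an occasional run
takes a late destabilizing step and lands far lower. The acceptance script
handles this the way the full-scale protocol does — four repeated runs
reported as mean/min/max — rather than by selecting seeds or adding
stabilizers the protocol does not have.

## Numerical and degenerate-input choices

* float32 throughout the network; losses accumulated in float64.
* Round-half-up (`floor(x + 0.5)`) for table percentages.
* Largest-remainder split rounding; ties toward the earlier split.
* Zero-denominator metric classes contribute 0; a class with an empty test
  column raises rather than silently reporting.
* Identity transforms short-circuit to an exact pixel copy.
* 8-bit PNG quantization is applied to in-memory generated pixels too, so
  in-memory datasets and disk round-trips are bit-identical.

## Known limitations

* The checkpoint format is JSON text — portable and diff-able, but large for
  big nets; a binary format would be preferable for production fleets.
* The photograph-loading path (CSV manifest + directory) is exercised against
  generated PNGs, not real microscope output.
* No cascade mode (binary filter feeding the 7-class net) is wired into the
  CLI; the two heads are trained and evaluated independently.
* Training is single-threaded NumPy; the full-scale 256-px, 32×, 20-epoch
  configuration is hours of CPU, not the minutes the desk-scale study takes.
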