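# wingclassify

Species identification of mosquitoes from single-wing photographs with a
shallow convolutional neural network.

Mosquito wings are nearly two-dimensional, easy to mount and photograph under
standardized dome illumination, and carry species-specific vein geometry
(wing-beat mechanics puts veins under strong selection). That makes a wing
image a compact, robust identification target even when the rest of a
field-sampled specimen is damaged. `wingclassify` implements the full
pipeline for this problem, aimed at medical entomologists and vector
surveillance labs who need *Aedes* species calls without deep-learning
infrastructure:

* **Preprocessing** — center crop to the largest square, bilinear resize to
  256 × 256, optional grayscale (BT.601 luminosity) conversion, pixels in [0, 1].
* **Augmentation** — each training image is replaced by 32 random variants
  inside a bounded envelope: rotation in ±15°, horizontal/vertical shift in
  ±20 %, zoom-in up to 1.5×, and a random crop removing up to 40 % of the side.
* **Model** — a deliberately shallow CNN: four blocks of 3 × 3 convolution →
  ReLU → 2 × 2 max-pool (widths 16/32/64/128), flattened into a *single*
  fully-connected layer of K class logits. K = 2 separates *Aedes* from
  non-*Aedes*; K = 7 separates seven *Aedes* species. The grayscale and RGB
  variants differ only in the first convolution's input channels. The
  network, its backward pass, and the Adam optimizer (lr 1.5 × 10⁻⁴, weight
  decay 5 × 10⁻⁴, batch 100, 20 epochs) are implemented directly on NumPy.
* **Evaluation** — stratified 70/15/15 split, confusion matrices (one column
  per true class), per-class accuracy as integer percentages, macro-averaged
  precision / recall / F1, and mean/min/max aggregation over repeated runs.
* **Interpretability** — Guided Grad-CAM: the class-activation map of the
  last conv block (gradient-weighted, rectified) upsampled and multiplied
  with the guided-backpropagation input gradient; overlays show the network
  attending to the wing veins.
* **Synthetic wings** — a procedural generator that renders wing-like images
  (elliptical silhouette on a dome-lit background, class-specific vein fans,
  crossveins, scale speckles, per-pixel vein masks) so the whole pipeline is
  testable end-to-end on one CPU with no photograph download. Real datasets
  plug in through a CSV manifest (`id,filepath,class,seed`) over
  PNG/TIFF/JPEG directories.

## Worked example

Train on a generated 3-class dataset (30 wings per class, 64-px grayscale,
8× augmentation, 10 epochs):

```bash
cat > quickstart.yaml <<'YAML'
generate: {n_classes: 3, n_per_class: 30, channels: 1}
architecture: {input_channels: 1, n_classes: 3, input_size: 64}
augment: {factor: 8}
train: {epochs: 10, batch_size: 20, learning_rate: 0.0015}
YAML
wingclassify run --config quickstart.yaml --seed 7 --out qs_run
```

prints

```
run complete: macro F1 100.0% (min 100.0, max 100.0) over 1 run(s); artifacts in qs_run
```

meaning the trained CNN classified every one of the 12 held-out test wings
(4 per class) correctly — the confusion matrix in `qs_run/report.json` is
diagonal (`[[4,0,0],[0,4,0],[0,0,4]]`, per-class accuracy 100 %). The run
directory also holds the config snapshot, the generated images and manifest,
`history.csv` (the last epochs show training accuracy climbing to 0.93 with
validation at 0.93–1.00), the learning-curve plot, a JSON checkpoint, and
Guided Grad-CAM overlays for the first test wings. Running with an empty
config reproduces the full-scale protocol shape (256-px inputs, 32×
augmentation, 20 epochs, batch 100).

The library is usable without the CLI:

```python
from wingclassify import (make_species_specs, generate_dataset, split_dataset,
                          augment_set, build_network, train, evaluate_run,
                          guided_grad_cam, AugmentConfig, ArchitectureConfig,
                          TrainConfig, SplitSpec)
```

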