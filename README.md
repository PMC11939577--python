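# lusseg — lung-ultrasound A-line/B-line segmentation and counting

A complete, CPU-only implementation of a transformer-encoder segmentation
pipeline for lung-ultrasound reverberation artifacts:

- **Pre-processing:** non-local-means denoising → CLAHE → unsharp masking.
- **Model:** ViT-Small/16 encoder (12 pre-norm transformer blocks, embed 384,
  6 heads) feeding a skip-free four-stage convolutional decoder
  (upsample → 3×3 conv → batch norm → ReLU, then a 1×1 head) — 22,938,945
  trainable parameters (≈23 M) at the default 224×224 configuration.
- **Loss:** Dice + λ · binary cross-entropy restricted to the target's inner
  boundary (one-pixel morphological rim), λ = 1 by default.
- **Metrics:** Dice, sensitivity, specificity, precision, F1, IoU, and the
  symmetric Hausdorff distance between mask boundaries.
- **Counting:** threshold → dilation → Canny → contour bounding boxes;
  a box is an A-line if width > 1.5 × height, a B-line if height > 1.5 ×
  width, with a no-contour fallback reporting (0, 0).
- **Synthetic phantoms:** a seeded generator reproducing pleura/A-line/B-line
  geometry with log-normal speckle, so the whole pipeline trains and
  evaluates without clinical data.
- **Training:** Adam (lr 1e-4), batch 16, k-fold cross-validation, best
  checkpoint by validation Dice.

Everything — including the network and its training — runs on a small NumPy
reverse-mode autodiff engine shipped inside the package (`lusseg.autograd`),
so the only dependencies are numpy, scipy, scikit-image, pillow, pandas,
pyyaml and click. No GPU, no downloads. See `docs/methods.md` for the
scientific details and conventions.

## A worked example

Generate a phantom, enhance it, and count its artifacts
(`examples/01_phantom_to_counts.py`):

```python
from lusseg import PhantomSpec, count_lines, generate_phantom, preprocess

spec = PhantomSpec(n_a_lines=3, n_b_lines=2, seed=7)
image, mask, truth = generate_phantom(spec)
enhanced = preprocess(image)
report, overlay = count_lines(mask)
```

Output of the script:

```text
phantom: 224x224, truth: 3 A-lines, 2 B-lines
foreground fraction: 0.093
image std before/after enhancement: 0.198 -> 0.240
counted: 3 A-lines, 2 B-lines (fallback_used=False)
  B_LINE       bbox=(113, 33)  14x191
  B_LINE       bbox=(145, 33)  14x191
  A_LINE       bbox=(  0, 58)  94x 12
  A_LINE       bbox=(  0, 90)  94x 12
  A_LINE       bbox=(  0,122)  94x 12
counts match the generator ground truth
```

Train the desk-scale network on 100 phantoms and evaluate one fold
(`examples/02_train_and_evaluate.py`, a few minutes on one CPU):

```text
model: 96px input, 22,144,097 trainable parameters
training on 80 phantoms, validating on 20
trained 5 epochs in 113s
epoch losses: [1.098, 0.681, 0.595, 0.558, 0.536]
validation Dice 0.679, IoU 0.545, Hausdorff 17.92px
```

At the acceptance scale (200 phantoms, same protocol) the same fold reaches
validation Dice 0.806 and Hausdorff 6.67 px in about five minutes.

## Command line

The same pipeline is exposed as a thin CLI:

```bash
lus synth --n 200 --out data/phantoms --seed 42          # seeded dataset
lus preprocess input.png --out enhanced.png              # enhancement chain
lus train --data data/phantoms --out runs/cv             # k-fold CV training
lus segment scan.png --checkpoint runs/cv/fold0_best.npz --out preds/
lus count preds/scan_mask.png --overlay overlay.png      # A/B-line counts
lus evaluate preds/scan_mask.png truth.png               # metric report
lus model-summary                                        # parameter counts
```

`lus model-summary` prints, among other fields:

```json
{
  "encoder_parameters": 21665664,
  "decoder_parameters": 1273281,
  "total_trainable_parameters": 22938945,
  "total_millions_rounded": 23
}
```

Every command accepts `--config cfg.yaml` (see `configs/study.yaml` for the
full 224×224 study protocol and `configs/desk.yaml` for the CPU-friendly
96×96 profile).

## Repository layout

```
src/lusseg/          the package (autograd engine, model, losses, metrics,
                     preprocess, postprocess, synthetic, pipeline, CLI)
tests/               unit suites per module + tests/test_acceptance.py
scripts/acceptance.py   standalone recomputation of the printed target
configs/             study.yaml (full protocol), desk.yaml (CPU profile)
examples/            narrative scripts (phantom→counts, training, ablation)
docs/methods.md      methods note
```
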