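# Methods

This note records what the package computes and why, in enough detail to
re-derive every number the test suite checks.

## Problem

Lung ultrasound diagnosis leans on two reverberation artifacts. **A-lines**
are horizontal echoes of the pleural line repeated at integer multiples of
the skin–pleura distance; they indicate aerated lung. **B-lines** are
vertical, laser-like streaks running from the pleural line to the bottom of
the image; their count correlates with interstitial fluid. The package
segments both artifact families as a single foreground class and then counts
them geometrically.

## Pre-processing

Three classical enhancement steps run in a fixed order on `[0, 1]` grayscale
images:

1. **Non-local-means denoising** (patch 7, search window 21, strength 0.08)
   suppresses multiplicative speckle while preserving edges.
2. **CLAHE** (8×8 tiles, clip limit 2.0 on the conventional 8-bit scale)
   normalizes contrast across depth.
3. **Unsharp masking** (`img + amount · (img − Gaussian(img, σ=1))`,
   amount 1.0) sharpens the artifact boundaries the loss and the counter
   both depend on.

Parameter conventions follow the common OpenCV-style scales and are converted
internally to scikit-image's conventions: the CLAHE clip limit is divided by
256, and Canny thresholds (below) are divided by 4·255, the full range of the
unnormalized Sobel response to a binary step.

## Architecture

The network is an encoder–decoder without skip connections:

- **Encoder:** ViT-Small/16 — 16×16 patch embedding into 384 dimensions, a
  class token, learned position embeddings, 12 pre-norm transformer blocks
  (6 heads, MLP ratio 4), and a final layer norm. The class token is dropped
  and the patch tokens are reshaped into a `384 × (H/16) × (W/16)` feature
  map.
- **Decoder:** four stages of `2× nearest-neighbour upsampling → 3×3
  convolution → batch norm → ReLU` with channel widths `[256, 128, 64, 32]`
  at 224 px, followed by a 1×1 convolution to a single logit map at input
  resolution. The head bias is initialized to −2 so early predictions respect
  the background-dominated class prior.

With the default 224×224 configuration this totals **22,938,945 trainable
parameters** (21,665,664 encoder + 1,273,281 decoder), i.e. 23 M to the
nearest million. The count is a closed-form function of the configuration
and is reproduced independently by the test suite and by
`scripts/acceptance.py`.

All tensor operations run on a small reverse-mode automatic-differentiation
engine written for this package (`lusseg.autograd`): float32, tape-based,
with analytic backward rules for matmul, convolution (implemented as k²
shifted GEMMs), layer/batch norm, softmax and the usual elementwise ops.
Every backward rule is verified against central finite differences in
`tests/test_autograd.py`. Nearest-neighbour upsampling is used instead of
bilinear: it is exact, has a trivially correct adjoint (2×2 sum pooling), and
leaves the parameter count unchanged.

## Loss

The training loss is a boundary-aware Dice loss:

```
L = 1 − (2·|P∩T| + ε) / (|P| + |T| + ε)          (Dice term, ε = 1e-6)
  + λ · BCE(P, T) averaged over the target's inner boundary pixels
```

The inner boundary is the target minus its 3×3 binary erosion (one-pixel rim
by default). λ defaults to 1 and is exposed in the config; the ablation in
`examples/03_boundary_loss_ablation.py` sweeps λ ∈ {0, 1}. With an empty
boundary the second term is zero, and λ = 0 reduces the loss exactly to
plain Dice. A single boundary pixel predicted at probability 0.5 contributes
−ln(0.5) = ln 2 ≈ 0.6931, a closed-form anchor used by the tests.

**A property worth knowing:** because the boundary mask is a subset of the
target, the target equals 1 on every pixel the BCE sees, so the boundary term
reduces to −ln(p) on the rim — a one-sided push toward foreground with no
counter-force just outside the target. For thick targets whose rim is a small
fraction of their area this acts as boundary sharpening; for thin structures
(the desk-scale phantoms' artifacts are 4–5 px wide, so a one-pixel rim is
roughly half the foreground) it systematically over-segments. In a matched
three-seed ablation on 96 px phantoms the λ = 1 models reached lower Dice
(0.73–0.83 vs 0.89–0.97) and *higher* mean Hausdorff distance (7.14 vs
3.26 px) than plain Dice at every seed and every training budget tried. The
package reports this honestly rather than altering the loss or the phantoms;
see the acceptance-test notes in the README.

## Metrics

Seven per-image metrics: Dice, sensitivity, specificity, precision, F1, IoU,
and the symmetric Hausdorff distance between mask boundaries (computed with a
KD-tree and tested for exact agreement with a brute-force double loop).
Conventions: 0/0 ratios score 1.0 when both masks are empty (flagged
`degenerate`); the Hausdorff distance is undefined (NaN, skipped in
aggregation) when either mask is empty. Dice ≡ F1 and Dice = 2·IoU/(1+IoU)
hold identically on binary masks and are asserted on random inputs. Note
that specificity is *not* invariant to padding both masks (padding adds true
negatives); the foreground-referenced metrics are.

## Counting (post-processing)

From a probability map: threshold at 0.5 → 3×3 binary dilation → Canny edge
detection (σ = 1, thresholds 50/150 on the 8-bit scale) → 3×3 edge dilation →
hole filling → connected components → per-component bounding box. A box is an
**A-line if width > 1.5 × height**, a **B-line if height > 1.5 × width**, and
unclassified otherwise (reported but not counted). If no contour survives,
the original segmentation is kept, both counts are zero and a fallback flag
is set. The mask is zero-padded before edge detection so that regions
touching the image border still produce closed contours (a border-touching
region has no edge at the border, and an unclosed contour cannot be filled —
it would split into its top and bottom edges and be counted twice).

## Synthetic phantoms

Clinical data is request-only, so the package ships a seeded phantom
generator that reproduces the artifact geometry: a bright pleural band at
depth `d` (image only — anatomy is not counted); A-lines at depths `k·d`,
`k = 2 … n+1`, with geometric intensity decay 0.8 per step; B-lines as
vertical streaks from below the pleura to the bottom edge, placed on a
separated column grid; Gaussian blur; multiplicative log-normal speckle
(mean-corrected). Real B-lines erase the A-lines they cross, so when both
families are present the A-bands span the widest B-free column interval —
this keeps every mask component separable, which the geometric counter
requires. Identical specs (including the seed) produce bit-identical
phantoms.

## Training protocol

Adam (lr 1e-4, β = (0.9, 0.999)), batch 16, boundary-aware Dice loss on
sigmoid probabilities, k-fold cross-validation (default 5), best checkpoint
per fold selected by validation Dice. The study-scale profile
(`configs/study.yaml`) trains 40 epochs at 224×224; the desk profile
(`configs/desk.yaml`) keeps the full-depth encoder and every optimizer
setting but shrinks the input to 96×96 (6×6 token grid, decoder
`[128, 64, 32, 16]`, ≈22.1 M parameters) and trains 5 epochs, so a complete
train/evaluate cycle fits in minutes on one CPU. Training is deterministic
given the config seed on a fixed device class.

## Evaluation conventions

Per-image metrics are averaged within folds and fold means are averaged
(documented choice; the aggregation level does not otherwise matter to the
tests). Line-count accuracy compares `count_lines` on thresholded
predictions against the generator's manifest counts.
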