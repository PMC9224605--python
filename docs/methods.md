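# Methods

## Problem setting

LSCI devices export, per patient, a grayscale intensity image and a
blood-perfusion map rendered as a blue→red heatmap. Three questions are
answered in sequence: where is the keloid (segmentation), how perfused is
it (perfusion recovery in PU, mL/100 g/min), and is it regressing, stable,
or progressing (three-class growth state). The three stages form a cascade:
the segmentation mask gates the perfusion analysis, and the segmentation
encoder's intensity features are reused by the growth-state classifier.

## Synthetic cohort generator

Clinical LSCI exports are private, so the generator emulates the image
*products* the pipeline consumes — not speckle optics.

- **Lesion shape.** A Gaussian-smoothed uniform random field thresholded at
  the quantile matching a target area fraction (drawn from 0.05–0.25 of the
  frame by default) gives irregular, smooth-bordered blobs; if the connected
  component count or areas come out wrong after 10 retries, perturbed
  star-shaped ellipses (radius modulated by 4 random low-order harmonics)
  are placed instead, which control count and area directly.
- **Perfusion field.** Inside the lesion: `target × (1 + cv·g)` where `g` is
  Gaussian-smoothed standardized noise with correlation length
  `heterogeneity_scale` (12 px default) — standardizing `g` over the lesion
  makes the inside mean equal the target exactly, before clipping at 0.
  Outside: N(background, 10% CV) around a 35 PU skin baseline.
- **Growth state.** The stage scales the body-site mean perfusion
  (regressive ×0.8, stable ×1.0, progressive ×1.25) and sets the
  within-lesion heterogeneity (CV 0.10 / 0.15 / 0.25): level plus
  unevenness is the learnable signal. Site profiles default to the seven
  cohort means (103.0–182.8 PU, overall 129.9) with cohort weights; each
  lesion additionally draws an 8%-CV lognormal jitter, since two lesions of
  the same site and stage do not share one exact perfusion level. The
  default stage mix is 49/37/64 over 150 (largest-remainder rounding for
  other n).
- **Intensity image.** The lesion is brighter (≈150 vs ≈90 gray levels)
  with finer texture; the requested number of darker pigmentation-like
  distractor patches are placed strictly outside the lesion; Gaussian
  sensor noise (SD 3) on top.
- **Heatmap.** Rendered through the packaged 256-entry
  blue→cyan→green→yellow→red ramp over 0–300 PU (nearest-PU anchor,
  clipping at the ends). 0–300 covers resting skin through the most
  perfused lesions plus heterogeneity.

Everything is a pure function of `(spec, seed)`; repeat calls are
byte-identical.

What the generator does **not** emulate: speckle statistics, optical blur,
site anatomy, camera vignetting, annotation noise in the stage labels, or
any correlation between lesion shape and stage. A green test on this cohort
establishes that the pipeline's mechanics work and that its learnable
signal (perfusion level + heterogeneity) is recoverable — not that the
clinical headline numbers are reproduced.

## Perfusion recovery

The vendor's colormap is unpublished, so the LUT is an explicit input: an
anchor table (validated: ≥2 anchors, strictly increasing PU, duplicate
colors with conflicting PU rejected) or a colorbar strip with endpoint PUs
(one anchor per pixel, colors averaged across the strip, consecutive
duplicates collapsed). Inversion is nearest-neighbor in RGB (exact integer
arithmetic; ties to the lower PU), with a per-pixel distance map to flag
off-palette pixels such as annotation overlays — flagged, never fatal.
Nearest-neighbor rather than interpolation because rendered heatmaps are
quantized and RGB ramps are not monotone channel-wise. Round-trip error is
bounded by half the LUT's PU quantization step per pixel (≈0.59 PU for the
default ramp); the measured end-to-end relative error of the mean with
ground-truth masks is ~0.1%, far below what predicted-mask disagreement
contributes. The degenerate relative error at A = B = 0 is defined as 0%.
Coordinates are 0-based, row-major, half-open boxes.

## Neural stack

A reverse-mode autodiff core over numpy float64 arrays implements exactly
the ops the models need (broadcast arithmetic, batched matmul, layer norm,
softmax, GELU, token gather/concat, fused CE/MSE losses). Everything is
seeded through `numpy.random.Generator`; training is deterministic given
the config.

- **Segmentation.** ViT encoder over patch tokens; the decoder taps several
  encoder depths (4 evenly spaced at full scale, 2 in the tiny profile),
  projects and sums them, and maps each token to its patch's per-pixel
  2-class logits. The head also receives the raw patch pixels (a U-Net
  style skip) so boundary precision is not limited by the token width.
  Loss: per-pixel cross-entropy (DICE is the metric, not the loss).
  Augmentation: random flips and rigid rotation ≤15°, identical transform
  on image and mask, nearest-neighbor for the mask so it stays binary.
  Masks are resampled nearest-neighbor everywhere; images bilinearly.
- **MAE pretraining.** 75% of patches masked uniformly at random; the
  encoder sees visible patches only; a light decoder (shared mask token +
  positional embeddings) reconstructs pixels; MSE on masked patches only.
  Held-out reconstruction error before/after is reported.
- **Evaluator.** The masked perfusion image (PU / 200 so inputs are O(1))
  is patchified; patches with any pixel above τ (default 0 PU) are kept —
  on default lesions this discards most of the grid, the token-economy
  property. A perfusion ViT encodes the kept tokens *without the final
  layer norm*: per-token normalization would suppress the absolute
  perfusion level, which is the class signal; the pre-norm residual stream
  preserves it. Each token is concatenated channel-wise with the frozen
  segmentation encoder's token at the same grid position; a global token
  (mean perfusion token ⊕ mean intensity token) leads the sequence, a
  4-layer (tiny: 2) transformer decoder attends over it, and the head reads
  the global slot. Ties in the argmax resolve to the lowest class index.

## Training schedules and the tiny profile

Full-scale defaults mirror the reference recipe: segmentation SGD from lr
0.02 with per-epoch exponential decay (γ = 0.95 — the decay rate is not
specified anywhere, this is our documented default), 100 epochs, 1600 MAE
epochs; evaluator lr 0.001 halved at epochs 50/100/200, 400 epochs, random
erasing of 25% of pixels. These need GPU-scale budgets and are not run in
tests.

The `tiny()` profiles (64 px, patch 8, 2-layer/32-dim encoders) exist so the
complete cross-validated pipeline runs on one CPU in minutes. Three
adaptations were measured to be necessary at this scale, all documented
here because they deviate from the full recipe:

- Segmentation lr 0.05, γ = 0.98: the full-scale schedule under-trains the
  tiny model (5-fold DICE 0.876 vs 0.927; overfit ceiling 0.85 vs 0.98).
- Evaluator lr 0.01 with weight decay 1e-3, LR milestones at the same
  fractions of the run (epochs ×50/400, ×100/400, ×200/400), and a
  translation augmentation that moves the whole lesion to a random
  in-frame position each step. Without translation the transformer
  memorizes lesion position/shape through its positional embeddings
  instead of reading the perfusion level (validation accuracy ≈ chance
  while training accuracy reaches 1.0).
- Random erasing is disabled in the tiny profile: at 64 px it removes the
  level signal faster than it regularizes (pooled accuracy 0.58 with
  erasing vs 0.89 without, all else equal). The full profile keeps 25%.

The MAE-vs-random paired comparison runs both arms under the reference
schedule (lr 0.02, γ 0.95, short 14-epoch regime, 60 cases): that is the
regime where pretraining is expected to matter — with the hot tiny schedule
random initialization already converges and the difference washes out,
mirroring the published observation that pretraining pays off exactly when
data and budget are limited.

## Numerical and procedural choices

- DICE of two empty masks is 1.0 (both agree there is no lesion); the
  Youden identity J = Se + Sp − 1 holds exactly by construction on our
  unrounded values.
- Per-class accuracy is one-vs-rest (TP+TN)/N; the overall figure is
  multiclass trace/N. Classification metrics are reported both pooled over
  validation folds (headline) and as per-fold means.
- Stratified k-fold via scikit-learn (per-fold class counts within ±1 of
  proportional); `k = 1` is accepted as the trivial train = validate split.
- Gradient clipping at global norm 1.0 everywhere; SGD momentum 0.9.
- Class imbalance (49/37/64) is handled by unweighted cross-entropy,
  matching the reference recipe's silence on the point.
- The evaluator's intensity encoder is the fold's own segmentation encoder
  (frozen, never fine-tuned through the cascade), so no validation case
  meets an encoder trained on it.

## Known limitations

- The within-keloid perfusion texture model is a stand-in, not a biological
  claim; real stage/texture relationships may be weaker or different.
- Perfusion values above the LUT range clip at rendering and bias recovered
  means low for the hottest lesions (measured: ≤4% relative on the worst
  synthetic case, <0.1% on average).
- Tiny-profile results quantify desk-scale learnability of the synthetic
  signal; they are not comparable to the published clinical metrics, which
  require the private dataset and full-scale training.
- The device-reported mean ("A" in the error formulas) is emulated by the
  generator's ground-truth mean; with real exports the module reports the
  recovered mean against whatever reference the device provides.
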