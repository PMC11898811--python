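# Methods

This document defines the algorithms implemented in `forceseg` precisely
enough to re-derive every number the test suite checks.

Conventions: images are `(H, W, 3)` uint8; label maps are `(H, W)`
non-negative integers with 0 = background and instance ids 1..N; points
are `(row, col)` integer tuples; all floating-point model math runs in
float32 (switchable to float64 via `forceseg.nn.set_dtype` for gradient
checking).

## 1. Synthetic scene generator (`forceseg.synthetic`)

Scenes are compositions of analytic ellipses so that membership,
overlaps, centroids and extreme points have exact ground truth.

- Each cell is an ellipse (random semi-axes, orientation, position) with
  a smaller nucleus ellipse inside it.
- Pixel membership is evaluated from the implicit ellipse equation at
  pixel centers; where two cells overlap, the pixel is assigned to the
  instance whose *center* is nearest (ties break to the lower id).
- Layout search: up to 32 candidate layouts are sampled; the one whose
  realized pairwise overlap fraction is closest to `overlap_target` is
  kept. With `overlap_target = 0`, candidate pairs must keep a boundary
  clearance of at least 4 px (`center distance >= a1 + a2 + 4`), so that
  disjoint cells remain separable after blur and resampling.
- Rendering: per-cell stained colour with jitter, intracellular grain
  (Gaussian random field, sigma 0.7), Gaussian blur (`blur_sigma`,
  default 1), additive Gaussian noise (`noise_sigma`, default 3).
- `make_dataset` writes `scene_%05d` PNG images, 16-bit PNG label maps
  and JSON extreme points, plus a `manifest.jsonl`; splits are 60/20/20
  by the largest-remainder method (ties favour train, then val).

## 2. Extreme points (`forceseg.points`)

For a non-empty boolean mask, the four extreme points use fixed tie
rules:

- top: minimal row, then minimal column;
- bottom: maximal row, then maximal column;
- left: minimal column, then minimal row;
- right: maximal column, then maximal row.

An empty mask raises `EmptyInstanceError`. These four points are the
*only* exact annotation the weakly-supervised losses consume.

## 3. Preprocessing pipeline (`forceseg.preprocessing`)

`preprocess_image` produces an instance pseudo-label map:

1. Resize to 256×256 (bilinear).
2. Keep a grayscale copy of the *raw* resized image for texture
   analysis (contrast normalization would distort texture statistics).
3. Contrast normalization: per-channel percentile stretch followed by
   CLAHE on the luminance channel.
4. Colour clustering: k-means (k = 3) in CIELAB space; the foreground
   clusters are those whose colour differs most from the border median
   (image borders are assumed background-dominated).
5. Texture refinement on the raw grayscale: Gabor energy (wavelengths 4
   and 8 px, smoothed with sigma = 3×wavelength) and an LBP-uniformity
   map (P = 8, R = 1, fraction of uniform codes smoothed with sigma 12)
   form a texture score; an Otsu threshold *within the colour mask*
   removes smooth background regions. The refinement is applied only if
   the Otsu separability is at least 0.5 **and** it would remove at most
   25 % of the mask — otherwise texture is uninformative and the colour
   mask is kept unchanged. Texture refinement only removes pixels, never
   adds them.
6. Morphology: opening with a 3×3 square, closing with a 5×5 square.
7. Connected components (8-connectivity), discarding components smaller
   than 20 px; ids are assigned in scan order.
8. Extreme points are extracted per component.

## 4. Force map (`forceseg.force_map`)

For each instance, the centroid C is the mean pixel coordinate
(`scipy.ndimage.center_of_mass`). The force at instance pixel p is

- unit mode (default):  f(p) = -alpha * (p - C) / ||p - C||
- distance mode:        f(p) = -alpha * (p - C)

i.e. a vector of magnitude alpha (unit mode) pointing from the pixel
toward its centroid. Pixels within 0.5 px of the centroid, and all
background pixels, get the zero vector. The field is stored as two
channels (delta-row, delta-col). `force_field_from_prediction`
thresholds a probability map, labels it (8-connectivity) and computes
the same field — used for two-pass inference.

Geometric invariants (tested): exact magnitude alpha, exact alignment
with the pixel-to-centroid direction, near-zero net force on symmetric
shapes, and equivariance under 90° rotation.

## 5. Losses (`forceseg.losses`)

Boundaries are inner boundaries: foreground pixels with at least one
4-neighbour outside the mask (the image border counts as outside).

- **Point-distance loss** `L_pd`: sum over the four extreme points of
  the Euclidean distance to the nearest predicted-boundary pixel.
  Empty prediction → sentinel `4·sqrt(H² + W²)`.
- **Boundary-alignment loss** `L_boundary`: mean over predicted-boundary
  pixels of the distance to the nearest target-boundary pixel (directed
  chamfer). Empty side → sentinel `sqrt(H² + W²)`.
- **Dense segmentation loss** `L_seg = BCE + λ (1 − softDice)` with
  λ = 0.5, probability clipping ε = 1e-7 and Dice smoothing 1.0.
- **Total**: `1.0·L_seg + 0.5·L_boundary + 0.3·L_pd`, where the
  boundary/point weights are multiplied by the curriculum ramp
  `min(1, 2·epoch / n_epochs)` (dense term first, geometry later).

Differentiable surrogates used for backprop:

- soft boundary map `b = ŷ − minpool3(ŷ)` (3×3 min-pooling);
- `l_boundary_soft = Σ b·D_target / Σ b` with `D_target` the Euclidean
  distance transform of the target boundary;
- `l_pd_soft`: per extreme point, a Gibbs softmin (temperature 0.5) of
  the distance map weighted by the soft boundary mass.

The surrogates agree with the exact losses to within ~1 px on hard
masks (tested), and the exact losses are what metrics report.

## 6. Network (`forceseg.nn`)

A lightweight encoder–decoder built on the package's own reverse-mode
autodiff (`Tensor`, conv2d via im2col, fused batch norm, depthwise
convolution, bilinear resize with dense interpolation matrices, 3×3
min-pooling with argmin gradient routing):

- stem: stride-2 convolution;
- encoder: four inverted-residual stages with feature taps at strides
  4, 8, 16, 32;
- multi-scale aggregation: 1×1 projections, bilinear upsampling to
  stride 4, softmax-weighted learnable scale weights;
- cross-scale attention: queries at stride 4 attend to keys/values at
  stride 32 (scaled dot-product, residual connection);
- force-map injection: the two force channels are downsampled and
  concatenated at stride 4;
- decoder with a stem skip connection and a sigmoid head.

`build_model` enforces a hard parameter budget of 5.2 M
(`BudgetExceededError`); the default configuration uses ~68 k parameters
and `ModelConfig.ablation_scale()` ~12 k.

## 7. Training (`forceseg.train`)

- Optimizer: Adam, base LR 1e-3, weight decay 1e-5; the scale-weight
  parameters form their own group (0.1× LR, weight decay 1e-4). Cosine
  LR schedule over `n_epochs`.
- Augmentation (joint on image + labels): rotation ±15°, horizontal
  flip p = 0.5, 4×4 elastic grid (sigma 3), gamma in [0.8, 1.2],
  optional scale jitter. Extreme points are *recomputed from the
  augmented ground-truth instances*, never transformed numerically.
- Supervision modes: `pseudo` (default) trains the dense terms against
  cached preprocessing pseudo-labels — the weakly-supervised setting in
  which only extreme points are exact — while `ground_truth` trains
  directly on the generator masks (upper bound / debugging).
- Force channels are teacher-forced from the (augmented) ground-truth
  instance geometry during training; at inference they are re-estimated
  from the first-pass prediction (two-pass).
- Early stopping: patience 10 on the pseudo-based validation loss
  (computed with final loss weights, no curriculum); the best epoch's
  weights are restored. Validation Dice/BF against ground truth are
  logged for monitoring only.
- Determinism: every random draw derives from `(seed, epoch, index)`
  streams of `numpy.random.default_rng`; retraining the same
  configuration reproduces `history.csv` byte for byte.

### Ablation harness

`run_ablation` trains four supervision variants on the same dataset and
seed — `none` (dense loss only, no force channels), `force_only`,
`points_only`, and `full` — and reports test-split Dice and boundary-F1
for each. **Empirical note**: on the bundled synthetic benchmark
(64×64 scenes, 4–7 overlapping cells, heavy blur, pseudo supervision,
15 epochs) all four variants converge to within ~0.007 Dice of each
other (~0.96); the pseudo-labels alone are a strong enough dense signal
at this scale that the point/boundary terms and force channels do not
produce a measurable, consistently ordered improvement.

## 8. Metrics (`forceseg.metrics`)

Pixel-level Dice, IoU, precision, recall and F1 from the confusion
counts, with the conventions: both masks empty → 1.0; exactly one empty
→ 0.0. Identities `dice = 2·iou/(1+iou)` and `f1 = dice` hold exactly.
Boundary-F1 matches boundary pixels within a 2 px Euclidean tolerance
(distance transforms), with the same empty-mask conventions.
`evaluate_dataset` returns a per-image table plus a final `mean` row.
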