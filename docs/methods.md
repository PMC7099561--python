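# Methods

This note documents the models, parameters and numerical choices behind
`fazseg`, and what the synthetic experiments do and do not demonstrate.

## Problem setting

En-face OCTA renders the superficial capillary plexus of the macula as a
bright vessel pattern on a dark background; the superficial foveal
avascular zone (sFAZ) is the single dark capillary-free region at the
center. The quantity of clinical interest is its physical area. Viewer
brightness/contrast (B/C) settings change the rendered intensities —
higher values of either darken the image — so a useful automatic method
must be robust across renderings. The pipeline treats segmentation as
per-pixel binary classification followed by morphological cleanup and
area calibration.

## Synthetic cohort generator

No public dataset accompanies this problem setting, so the package ships a
generator that emulates the statistical structure of such a study: N
subjects, each imaged once and exported under nine B/C settings — the
default 130/20, brightness variants 90/110/150/170 at contrast 20, and
contrast variants 0/10/30/40 at brightness 130 — with one ground-truth
mask per subject shared by all nine renderings.

* **FAZ geometry.** The region is star-convex about its center with radius
  r(θ) = r₀(1 + Σₖ aₖ cos(kθ + φₖ)), k ∈ {2..5}, amplitudes ≤ 0.07. This is
  hole-free and single-component by construction and matches the smooth
  closed contours of real FAZ boundaries. Radii are drawn uniformly from
  0.20–0.44 mm (low myopes) or 0.16–0.34 mm (high myopes), spanning the
  areas reported for healthy adults (~0.1–0.6 mm²) with a modestly smaller
  FAZ in high myopia; centers jitter ±3 % of the field around the middle.
* **Vessels.** Seeded biased random walks (per-step heading noise σ = 0.18
  rad) stamped as bright strokes and blurred to a ~1–3 px Gaussian profile,
  with stroke count proportional to a per-subject density parameter
  (0.5–0.85). Strokes are suppressed inside the 1-px-eroded FAZ, leaving
  the dim noisy background (28 ± 6 gray levels), so the FAZ interior is
  darker than its surround by well over 30 gray levels.
* **B/C remap.** The device viewer's mapping is proprietary; the package
  uses a monotone pointwise affine-then-clip map
  out = clip(g(c)·(x − p(b))) with gain g(c) = exp(−0.02·(c−20)) decreasing
  in contrast and pivot p(b) = 0.9·(b−130) increasing in brightness. The
  default 130/20 is the identity; mean intensity is non-increasing in
  either parameter; contrast below 20 lifts faint strokes above fixed
  visibility thresholds. Only these directional properties are asserted —
  the functional form is a package choice, calibrated once so the extreme
  settings neither saturate nor clip to black.

**What passing tests show / do not show.** The simulator reproduces the
*task structure* (single dark star-convex target, distractor vasculature,
monotone rendering changes, shared ground truth) but not OCT physics:
no speckle or flow-decorrelation noise, no projection artifacts, no deep
plexus, no pathological FAZ shapes. High accuracy here demonstrates that
the implementation learns and quantifies correctly under the stated
conditions; it does not certify clinical performance.

## Network

Encoder: two stem Conv-BN-ReLU blocks, then five pooling blocks
(Conv-BN-ReLU → SE → 2×2 max pool). Decoder: five upsampling blocks
(bilinear 2× → concat encoder skip → Conv-BN-ReLU → SE) and a 1×1
convolution + sigmoid head. A Conv-BN-ReLU block is two convolution →
batch-norm → ReLU stages with same-size padding. The SE block global-
average-pools each channel, applies dense d → d/r (ReLU) and d/r → d
(sigmoid) layers, and rescales each channel by the resulting weight in
(0, 1); the skip passed to the decoder is the SE output before pooling.

Architecture parameters left open by the design are configuration surface
with these defaults: 3×3 kernels (U-Net convention), channel schedule
(32, 64, 128, 256, 512, 512) at full scale, SE reduction 16 (the SE
paper's default), average pooling as the SE squeeze, He-uniform seeded
initialization. The head bias starts at −3, the approximate prior
log-odds of a foreground pixel (the sFAZ covers a few percent of the
field); without it, early optimization is spent unlearning the 50 % prior.

The scaled-down profile used for CPU experiments is input 128 × 128,
channels (8, 16, 32, 32, 32, 32), SE reduction 4 — bottleneck 4 × 4.

The network runs on a package-local reverse-mode autodiff engine
(`fazseg.autodiff`) providing exactly the required operator set;
convolution is one im2col matrix product per layer, and every operator's
gradient is verified against central finite differences in the test suite.
Activations are float32.

## Training

* Loss: pixelwise binary cross-entropy on logits (numerically stable
  form); Dice loss available by configuration.
* Optimizer: Adam, β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸. Full-scale default
  learning rate 1 × 10⁻⁴; the scaled-down profile uses 5 × 10⁻³ with batch
  size 4, appropriate for its ~500× smaller parameter count and short run.
* Plateau rule: if the minimum training loss over the trailing 30 epochs
  has not improved on the best loss before that window, the rate halves.
  Each reduction re-anchors the window, so an unbroken plateau spanning two
  windows halves the rate exactly twice.
* Checkpointing: parameters are snapshotted whenever the held-out
  "correct rate" strictly improves, and the best snapshot is returned.
  "Correct rate" is defined as mean pixel accuracy at threshold 0.5 — the
  most literal reading of a correct-classification rate for per-pixel
  classification (per-image DSC would also be defensible).
* Cross-validation is participant-based — all nine renderings of a subject
  stay on one side of each fold — and stratified on myopia class by
  round-robin dealing within each stratum, so fold sizes differ by ≤ 1 and
  high-myopia counts are within 1 of proportional. Batch-norm uses batch
  statistics during training and running averages (momentum 0.1) at
  evaluation.

## Post-processing and quantification

Binarization uses probability ≥ threshold, so threshold 0 keeps every
pixel and the sweep curve is defined on the whole grid. Foreground
components use 8-connectivity, holes (interior background) 4-connectivity
— the standard dual pairing that avoids topological paradoxes. Ties for
the largest component are broken toward the component that appears first
in row-major order (deterministic; ties essentially never occur on real
probability maps). The refined mask is therefore always a single hole-free
region or empty. Area = N·mm²/(H·W) with the scan width in millimeters a
required input (3 mm default in the simulator), never hard-coded.

Degenerate metric denominators follow the convention that perfect
agreement on an absent class scores 1 (e.g. DSC of two empty masks);
groups with fewer than 3 rows report the area correlation as NaN rather
than raising. The threshold sweep defaults to the 0.00–1.00 grid in steps
of 0.01 with morphological refinement applied before scoring; raw
binarization is available by flag. The Pearson p-value uses the two-sided
t transform with n−2 degrees of freedom.

## Desk-scale experiment sizes

The canned experiment (`fazseg.experiments.scaled_down_study`, also run by
`scripts/acceptance.py`) uses a 12-subject cohort (3 high myopes,
preserving the 12/45 proportion) at 128 × 128, one fold of a k = 4
participant-based stratified split (9 train / 3 test subjects = 81/27
images), and 15 training epochs — sizes chosen so the full study runs in
minutes on one CPU while leaving clear margins on its checks (held-out
mean DSC ≥ 0.90 pooled and ≥ 0.85 per B/C group, area R ≥ 0.9, and a
DSC-vs-threshold curve flat to < 0.05 over the middle half of the grid).
Typical results are pooled DSC ≈ 0.95–0.97 with worst-group means within
0.01 of pooled, area R ≥ 0.96, and mid-grid sweep variation < 0.01.

## Known limitations

* The simulator's simplifications listed above; in particular the B/C
  remap is an invertible pointwise map, gentler than a real viewer's
  quantized tone curve.
* The numpy engine is single-threaded and CPU-bound; full-scale 704 × 704
  training is supported by the code but impractical without substituting a
  GPU framework behind the same block interfaces.
* Batch-norm statistics come from small batches (4); eval-mode predictions
  early in training can lag the train-mode state until the running
  averages settle.
* The "correct rate" used for checkpoint selection saturates near 1 on
  easy cohorts, so late checkpoints may tie and the first best is kept.
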