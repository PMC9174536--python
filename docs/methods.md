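# Methods

This note records the models, numerical choices and design decisions behind
`angioseg`, in the spirit of a package methods appendix. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Problem setting

An X-ray coronary angiogram is a single grayscale frame in which
contrast-filled arteries appear as a dark, connected, branching curvilinear
tree occupying a few percent of the pixels, over a background with smooth
nonuniform illumination, low contrast and noise. Segmentation is binary
per-pixel classification (vessel vs background) under severe class
imbalance. The package targets the *lightweight* regime: sub-million
parameter networks that train and run on ordinary CPUs.

## Network

The architecture is an encoder–decoder (U-Net) whose convolutional stages
are bottleneck residual blocks: a 1×1 pointwise convolution expands k
channels to t·k, a 3×3 depthwise convolution filters spatially (stride 1
or 2), and a 1×1 linear projection maps to k′ channels. The first two
stages carry batch normalization and ReLU6 (`min(max(0,x),6)`); the
projection carries batch normalization only (a *linear* bottleneck). The
input is added to the output iff stride = 1 and k = k′. Convolutions
followed by batch normalization carry no bias; the final 1×1 sigmoid head
carries one. ReLU6 is used throughout the blocks; the head is a plain
sigmoid, and masks are binarized at probability 0.5.

**Squeeze-and-excitation (SE).** When enabled, a channel gate acts on the
expanded (t·k-channel) representation after the depthwise stage: global
average pooling to a channel vector z, then FC → ReLU → FC → sigmoid with
hidden width `max(C // r, floor)`, and per-channel rescaling. Defaults
r = 48, floor = 4. r was calibrated once against the whole-network SE
budget (+0.02 M at t = 2): the common default r = 16 would add ~0.07 M here
because the gate sits on the expanded representation of every block, three
and a half times the intended increment.

**Patch attention module (PAM).** Self-attention over non-overlapping n×n
patches of the deepest encoder map. Each patch is reduced to one position
by per-channel average pooling (parameter-free, consistent with the later
upsampling step); three bias-free 1×1 convolutions at full channel width
produce q, k, v; the affinity matrix is the row-stochastic softmax
`s_mn = exp(q_m·k_n)/Σ_n' exp(q_m·k_n')`, stabilized by per-row max
subtraction; position m of the attended output receives `Σ_n s_mn·v_n`
(row-stochastic attention applied to the values, matching the softmax
normalization axis). The attended map is scaled by a learnable α
(initialized to 0, so the module starts as a pooled-identity path — the
standard stabilization for learnable-scale attention), added to the pooled
map, upsampled back with nearest neighbour, and added pixel-wise to the
input. The attention matrix holds ((H·W)/n²)² entries — 1/n⁴ of pixel-wise
position attention. Default patch size n = 2.

### Frozen reference layout and its calibration

The layout was fixed once by calibrating the trainable-parameter count
against the budgets quoted for this family of models (0.65/1.13/1.61/2.09 M
for the plain backbone at t = 2/4/6/8; +0.02 M for SE; +0.08 M for PAM;
0.75 M for the full model) and is never re-tuned per experiment:

- stage widths (32, 40, 64, 128, 160); five resolution levels, so inputs
  must be divisible by 16 (and by 16·n when PAM is on);
- encoder: one bottleneck block per stage plus a stride-2 transition block
  between stages; two bridge blocks at the deepest level (the only blocks
  with active residuals);
- decoder: 4×4 stride-2 transposed convolutions (with batch norm and ReLU6)
  to the narrow widths (32, 32, 16, 8), skip concatenation with the
  matching encoder stage, then one bottleneck block per stage;
- head: 1×1 convolution with bias, sigmoid.

The parameter count is affine in t (every t-dependent term is linear in t),
which the calibration exploits: the slope is ~0.24 M per unit t and the
intercept ~0.17 M. A narrow decoder with 4×4 up-convolutions is what makes
both ends meet — 2×2 kernels leave the t-independent budget unreachably
small at any width assignment, and 4×4 stride-2 is a standard
checkerboard-free decoder choice in segmentation. PAM's +0.08 M pins the
deepest width near 160 (3·160² + 1 = 76 801 extra scalars).

Exact per-block counts are available in closed form
(`model.block_param_count`) and are cross-checked against the built modules
in the tests.

## Objective

Per image with mask y and predicted probabilities p:

- background weight `w = 1 − Σy/(H·W)`, computed **per image** (the weight
  formula is written over one mask; batch loss is the mean of per-image
  losses);
- weighted cross-entropy
  `−mean(α·w·y·log p + (1−w)·(1−y)·log(1−p))` with α = 0.2; α multiplies
  the positive term only, exactly as the formula is printed;
- Dice loss `1 − (2Σ(y·p)+ε)/(Σy+Σp+ε)` with smoothing ε = 1 pixel-unit
  to avoid 0/0 on empty masks;
- total `L = L_WCE + β·L_Dice`, β = 0.01.

Probabilities are clipped to [1e-7, 1−1e-7] before logs, with a
straight-through gradient inside the bounds.

## Optimization

Adam with first-moment coefficient β₁ = 0.9 (the conventional reading of
"momentum 0.9" for Adam), β₂ = 0.999, additive (coupled) L2 weight decay
1e-4, batch size 16, poly learning-rate schedule
`base_lr·(1 − iter/max_iter)^0.9` from base_lr 4e-3. Mini-batches cycle a
seeded shuffled order, reshuffled each epoch. `max_iter` is config-driven
(epochs × batches per epoch for real datasets; 300 raw iterations for the
desk-scale fixture experiment). Weights are initialized Kaiming-uniform
(fan-in), batch-norm scale 1 / shift 0, all from one seeded generator in
construction order, so builds and runs are bit-reproducible on one device.

## Preprocessing

Exactly one of {none, top-hat, CLAHE} is applied per run — the strategies
are ablation alternatives, not a chain.

- **Top-hat enhancement**: `clip(F + whitetophat(F) − blacktophat(F), 0, 1)`
  with a flat disk structuring element, radius 9 at a 300-pixel image side
  and scaled proportionally for other sizes (the kernel must exceed the
  maximum vessel width; vessels here are ≲ 8 px wide at that scale).
  Clipping, not renormalization, preserves identity on already
  well-contrasted regions.
- **CLAHE**: clip limit 2.0 (in multiples of the mean bin height) on an
  8×8 tile grid, operating on an internal 8-bit quantization of [0, 1] —
  standard histogram machinery, exactly reproducible — with bilinear
  interpolation between tile mappings. Implemented in-package so the
  per-tile clipped histograms are inspectable; scikit-image's
  `equalize_adapthist` serves as an independent qualitative cross-check in
  the tests.
- Geometry: center-crop (e.g. 300→288, 768→576) or bilinear resize for
  images / nearest for masks; both are provided and config-driven since
  either convention appears in practice (288 = 16·18 fits the five-level
  network).
- Augmentation: random rotation (±15°), random crop (90–100 % of the side,
  resized back), random horizontal/vertical flips — magnitudes are
  config-exposed since only the transform families are canonical. One
  seeded draw is applied identically to image (bilinear) and mask
  (nearest), keeping masks strictly binary.

## Evaluation

Confusion counts at threshold 0.5; SE = TP/(TP+FN), SP = TN/(TN+FP),
ACC = (TP+TN)/total, with NaN flags instead of crashes on zero
denominators. The ROC is built over all unique thresholds on pixels pooled
across the whole test set (matching a single-curve presentation; the
alternative — per-image AUC averaging — is not used), and AUC is the
trapezoidal area, which equals the pairwise rank statistic
P(p_vessel > p_background) + ½·P(tie); the tests assert this equivalence to
1e-9 and agreement with scikit-learn to 1e-12.

## Synthetic phantoms

The generator emulates what makes angiograms hard — thin dark connected
curvilinear trees (random-walk centerlines with tapering widths and
bifurcations, vessel fraction enforced in (0.03, 0.10) by bounded
regeneration), smooth nonuniform illumination (a coarse 4×4 random grid
spline-upsampled, amplitude 0.12), vessel darkening graded by
distance-to-edge (dark cores, soft rims, contrast 0.35), and Gaussian noise
(σ 0.03) — and nothing else: no catheters, ribs, diaphragm shadows, motion
blur or contrast-agent physics. Passing tests therefore demonstrate that
the architecture, objective, optimizer and metrics are wired correctly and
can fit vessel-like structure; they say nothing about accuracy on clinical
data, which would require training on a real angiogram corpus. The default
fixture is 4 images at 96×96 (divisible by 16·n) so the full model overfits
it in 300 iterations within minutes on one CPU; 288×288 phantoms are
available for realism.

## Numerical engine

The network runs on a small reverse-mode autodiff engine over float32 numpy
arrays (`angioseg._autograd`): grouped/depthwise and 1×1 convolutions,
strided transposed convolution, fused batch normalization, pooling,
nearest-neighbour upsampling, batched matmul, stabilized softmax and the
pointwise algebra, each with a hand-written backward pass verified against
central differences (or, for batch norm, against a composition of verified
primitives, since normalization makes finite differences ill-conditioned in
float32). Depthwise convolution is evaluated as k² shifted multiply-adds
and 1×1 convolution as a BLAS matmul, which keeps a full training iteration
on the 4×96×96 fixture batch at roughly two-thirds of a second on one CPU
core. Determinism: given the same seed, thread count and BLAS, forward,
backward and the Adam update are bit-reproducible; the test suite asserts
bit-identical loss histories for identically seeded runs.

## Known limitations

- No GPU path and no mixed precision; throughput is adequate for phantom
  experiments, not for training on full clinical datasets.
- Batch-norm statistics are per-batch only (no synchronized or frozen
  variants); very small batches give noisy normalization.
- The phantom generator's realism gap (above) bounds what desk-scale
  results can claim.
- Single-frame, single-class segmentation only: no DICOM cine-loops, no
  vesselness filters, no multi-class heads, no topology-aware metrics.
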