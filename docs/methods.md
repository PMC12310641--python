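# Methods

## Problem and pipeline

The package quantifies eyelid-margin shape from a single anterior-segment
photograph. Two binary regions are needed: the palpebral fissure (the
opening between the lids) and the cornea. The fissure boundary supplies
the upper and lower lid-margin curves; the cornea supplies both the
lateral measurement window and the metric calibration, since its
horizontal diameter is anatomically near-constant (11.5 mm is used
throughout). The pipeline has three stages — segmentation, geometric
measurement, evaluation — and each stage is usable on its own.

## Segmentation model

AtDU-Net is a U-shaped encoder/decoder network with one shared encoder
and one independent decoder per region, so the two tasks share features
without competing for output channels. The regions are nested (cornea ⊂
fissure), so the heads are two independent sigmoid/binary tasks, not a
softmax partition.

Encoder: a stem of two 3×3 convolution blocks at `base_channels`,
followed by `depth` stages. Each stage halves the spatial size and
doubles the channels via a Hierarchical Attention Sampling Module
(HASM), then refines it with a shape-preserving Split Axial Detail
Module (SADM).

The block internals are a design choice of this package (only the block
names and the pooling/large-kernel ingredients are fixed by the
architecture we follow):

- **HASM** — (i) compression: 3×3 stride-2 convolution block; (ii)
  hierarchical attention: global-average descriptor → bottleneck MLP
  (reduction 4) → sigmoid gates, applied multiplicatively per channel;
  (iii) context aggregation: global max- and average-pool descriptors
  broadcast and concatenated with the gated map, fused by a 7×7
  convolution, added residually.
- **SADM** — 3×3 feature-generation block, then single-head scaled
  dot-product self-attention run independently along each row (over
  columns) and along each column (over rows), with q/k/v as 1×1
  convolutions and embedding dimension equal to the channel count;
  `x + row + col` residual combination. Attention weights are softmax
  rows summing to 1.
- **Decoders** — per stage: nearest-neighbour 2× upsampling, skip
  concatenation, two 3×3 convolution blocks. Nearest upsampling was
  chosen over bilinear because its adjoint is exact and trivial in the
  autodiff core and the two following 3×3 convolutions can realise any
  interpolation kernel the optimisation needs; 1×1 convolution + sigmoid
  head.
- Every convolution block is conv → instance norm → ReLU. Instance
  normalisation (per sample, per channel) was chosen over batch norm
  because training uses batch size 2; without normalisation the
  attention stack's activations grow multiplicatively and training
  destabilises.

Ablation flags reproduce the baseline variants: `use_has=False` replaces
HASM by the bare strided convolution block, `use_sad=False` removes
SADM, `dual_decoder=False` keeps a single head. Parameter counts are
monotone across BaseNet ≤ +HAS ≤ +HAS+SAD, which the tests assert.

The forward/backward passes run on a purpose-built reverse-mode autodiff
core over NumPy (im2col convolutions dispatched to BLAS via tensordot).
Every operator's gradient is verified against central differences in the
test suite.

### Training

- Loss: per head, binary cross-entropy plus soft-Dice (1 − 2Σpt/(Σp+Σt)),
  summed over heads. BCE drives per-pixel calibration; the Dice term
  counteracts the foreground/background imbalance of the small cornea.
- Optimiser Adam, lr 1e-3, batch 2, no scheduler. Model selection keeps
  the epoch with the best held-out mean Dice; the held-out split is
  monitored every epoch.
- Augmentation: random crop (fraction 0.85, resized back) and random
  horizontal/vertical flips, applied identically to image and masks;
  masks are resampled nearest-neighbour so they stay binary and the
  cornea ⊆ fissure law is preserved (property-tested).
- Inference: threshold 0.5, keep the largest 4-connected component, fill
  interior holes — the measurement stage requires one simply connected
  region per class. An all-background prediction is surfaced as an empty
  mask plus warning, and measurement refuses it.
- Working resolution: the toy-scale default is 96×144 (images resized
  bilinearly, masks nearest). The geometry of the task survives
  downsampling, and the curvature stage is resolution-independent
  because its calibration is re-derived from the fitted corneal radius
  at whatever resolution the masks have.

## Geometric measurement

Coordinates use the image's bottom-left corner as origin with y up
(x = column, y = H − 1 − row), so "upper lid" literally has larger y.

1. **Boundary**: the fissure mask's inner boundary (mask pixels with a
   4-neighbour background pixel). On clean binary masks this is
   equivalent to intensity edge detection but deterministic and
   parameter-free.
2. **Chains**: per integer column, the maximum boundary y joins the
   upper chain and the minimum the lower chain; columns where the two
   differ by < 2 px (the canthus tips, where the margins merge) are
   dropped. This resolves the one-y-per-x requirement of the quadratic
   fit.
3. **Corneal circle**: Welzl's move-to-front smallest-enclosing-circle
   algorithm on the corneal mask's boundary, with a fixed-seed working
   shuffle for determinism. Exhaustive pair/triple enumeration and an
   independent computational-geometry library serve as test oracles.
4. **Span**: [round(m − r), round(m + r)], clamped to the chains' shared
   x-domain; a span narrower than 10 px is refused as degenerate.
5. **Fit**: ordinary least-squares quadratic per lid over the clipped
   chain (≥ 10 points required).
6. **Curvature**: K(x) = |2a| / (1 + (2ax + b)²)^{3/2}. The mean is the
   arithmetic mean of K over all integer x in the span — computed from
   the fitted curve, not from raw pixel second differences, which are
   meaningless at 1-px quantisation. Point curvatures are evaluated on
   the fit at x = m − r, m, m + r even when the rounded endpoint lost a
   raw boundary pixel.
7. **Units**: K_px (pixel⁻¹) divides by the scale (mm/px) to give mm⁻¹.
   Default scale mode `cornea` uses 11.5 mm / (2 r̂) with r̂ the fitted
   radius, so the conversion self-corrects for any resize;
   `fixed:<mm_per_px>` supports externally calibrated rigs.

Numerical behaviour worth knowing: a quadratic fitted to a circular arc
of radius R over ±0.5 R has mean curvature ≈ 6.4% below 1/R — intrinsic
parabola-vs-arc model mismatch, not noise; the tests freeze this value
from a continuous least-squares oracle. On synthetic eyes, whose lid
margins *are* quadratics, recovery from exact masks is ~0.01–0.05%
relative error.

## Synthetic data generator

Each eye is sampled as: corneal radius r uniform in 14–17% of the image
width; both lids' vertex curvatures (2|a|, converted to mm⁻¹ by the
corneal scale) uniform in [0.19, 0.26] mm⁻¹, bracketing clinically
reported lid-curvature magnitudes near 0.2–0.25 mm⁻¹; fissure width set
so the corneal diameter is 62–78% of it; both arcs forced through the
same two canthus points (guaranteeing a closed almond and exact
intersections), with a small random tilt and centre jitter; the cornea
centred in the local opening and required to fit inside fissure and
canvas. Unsatisfiable combinations (e.g. extreme curvature on a tiny
canvas) fail with a seeded error after bounded resampling. Rendering
layers four flat colours (skin, sclera, iris, pupil at 0.35 r) plus
seeded Gaussian noise (σ = 6 intensity levels by default). The default
canvas is 496×744.

What it does not emulate: eyelashes, specular highlights, skin texture,
inter-rater annotation noise, non-quadratic lid shapes, partial lid
coverage of the cornea. Passing tests therefore demonstrate the
correctness of the machinery and its noise robustness at the stated
conditions, not clinical-grade performance on photographs.

## Problem sizes used in the test suite

Chosen as the package's own desk-scale defaults: curvature recovery uses
20 eyes at 992×1488 (corneal diameter ≥ 400 px, median relative error
bound 3% per lid); the learning check trains on 20 images (15/5 split
emulating a 100:30 ratio) for 30 epochs at 96×144 with base 8 channels,
reaching held-out mean Dice ≥ 0.95; the smallest-enclosing-circle oracle
covers 200 random sets up to 60 points; the curvature-formula oracle
covers 1000 random quadratics at 1e−6 agreement.

## Known limitations

- The measurement is restricted to the corneal span by design;
  whole-margin (canthus-to-canthus) profiling is out of scope.
- Quadratic lid model: real margins deviate from parabolas; the fit
  averages that deviation into the residual rather than modelling it.
- The autodiff core is CPU-only and single-threaded beyond BLAS; it is
  sized for the toy-scale study, not for full-resolution training.
- Curvature near-vertical at the canthi cannot be represented in the
  y(x) parameterisation; the corneal-span restriction keeps the fit far
  from that regime.
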