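# Methods

## The segmentation model

`mfsunet` implements an encoder–decoder network for binary segmentation of
thyroid nodules in 2-D grayscale ultrasound, organised around three
operators:

**Selective state-space scan (the core of every Mamba branch).**  The
continuous model is the linear ODE h′(t) = A·h(t) + B·x(t), y(t) = C·h(t)
with an N-dimensional hidden state per channel.  We discretise A by
zero-order hold, Ābar = exp(Δ·A), and the input matrix by the customary
Euler simplification B̄ = Δ·B (the exact diagonal ZOH form
(exp(Δ·A) − 1)/A · B is available via `method="zoh"` / `zoh_exact`).  The
step Δ, and the projections B and C, are produced from the input sequence
by learned linear maps, with Δ passed through a softplus so it stays
positive — the "selective" parameterisation that lets the recurrence
attend to or forget tokens based on content.  A is parameterised as
−exp(A_log) with A_log initialised to log(n+1) per state index n
(negative-real initialisation), so the recurrence is stable
(Ābar ∈ (0, 1]) for any Δ > 0.  State dimension defaults to N = 16 and
block expansion to 2; scaled-down runs use smaller values (below).

Each Mamba branch is the standard gated design: input projection to an
expanded width E, depthwise causal 1-D convolution (kernel 4) with SiLU,
the selective scan, a learnable per-channel skip, a SiLU-gated
multiplicative branch, and an output projection.  Convolution and gate are
individually toggleable; with both off the branch reduces to linear maps
around the scan, which is the configuration the numpy/oracle composition
test pins down.

**Multi-Path Vision (MPV) block.**  A feature map X (H×W×C) is
layer-normalised (over channels, ε = 1e−5), flattened along four
directional scan paths — row-major forward/backward and column-major
forward/backward, the standard 2-D cross-scan — and run through four
independent Mamba branches.  Each branch output is restored to the 2-D
grid and combined with a learnable per-channel residual scale β
(initialised to 1): Y_i = unflatten(Mamba_i(flatten(X_norm))) + β_i⊙X_norm.
The four Y_i are concatenated (4C channels), normalised again, and
projected back to C by a bias-carrying linear map with no activation.
The residual is added after unflattening so it is well-typed in 2-D.

**Feature-Gating (FG) attention gate.**  On every skip connection, the
encoder feature x^l and the decoder gating signal g (taken one stage
deeper, before that stage's upsampling) are mapped by 1×1 convolutions
with biases to a shared intermediate width C_int = C_l/2 (min 1), added,
passed through ReLU, compressed to one channel by ψ, and squashed by a
sigmoid into α ∈ (0, 1).  The gate upsamples g bilinearly
(align-corners-off, half-pixel centres; nearest available) and returns
x^l ⊙ α.  α modulates only the encoder path, not the decoder.

**Supervised Label Rectification (SLR).**  During training, a 1×1 head
(shared with the final output head) maps the last decoder feature map to
an intermediate probability map; thresholding at 0.5 (the two-class
argmax, lowest index on ties) and comparing against the label yields a
hard error mask M.  Features are then mixed punitively with weighting
λ ∈ [0, 1] and penalty γ > 0:

    F_mixed = (1 − λ)·F_dec⊙(1 − M) − λγ·F_dec⊙M,   F_out = F_dec + F_mixed

so agreeing regions are scaled by (2 − λ) and disagreeing regions by
(1 − λγ).  Defaults λ = 0.5, γ = 1.0 (the optimum of the prescribed
5×5 grid search; grids λ ∈ {0.1,…,0.9}, γ ∈ {0.5,…,2.5}).  The mask is a
constant for backpropagation — argmax is non-differentiable — so gradients
flow through F_dec only.  At inference the operator is a strict
pass-through: naively setting M = 0 would rescale features by (2 − λ) and
shift train/test statistics.  F_out replaces F_dec for the output head
(the rectified features feed forward, not just the loss path).

**Assembly.**  Stages halve resolution with a strided 2×2 convolution
(space-to-depth + pointwise linear; max-pool available) and restore it
with a 2×2 transposed convolution (pointwise + depth-to-space; bilinear +
pointwise available).  Every encoder and decoder stage contains an MPV
block; gated skips are concatenated with the upsampled decoder feature and
fused by a 1×1 map.  The default geometry is four stages with widths
(32, 64, 128, 256).  The binary head is a single-channel 1×1 convolution +
sigmoid; its bias is initialised at the foreground log-odds (default prior
0.1) so early predictions match the class prior rather than p = 0.5, which
shortens the initial all-background phase under heavy class imbalance.
Multi-class softmax heads are not implemented in the network (the
rectification operators themselves are N-class-generic).

## Training protocol

Composite loss: equal-weighted soft-Dice (smoothing 1 in numerator and
denominator) plus pixel-mean binary cross-entropy with probabilities
clipped to [1e−7, 1 − 1e−7].  AdamW (β = 0.9/0.999, decoupled weight decay
1e−5) at initial learning rate 1e−4 for full-scale runs, 300 epochs, batch
8; the learning rate halves whenever the composite validation loss fails
to improve for 10 consecutive epochs.  Augmentation applies one shared
transform per sample — random horizontal flip, rotation within ±15°,
isotropic scale in [0.9, 1.1] — bilinear for the image, nearest for masks.
The best-on-validation-Dice weights are retained; checkpoints embed the
optimizer, scheduler and RNG state so a resumed run reproduces the
uninterrupted trajectory exactly.

Splits are patient-grouped 80/10/10: a patient's images never span two
splits, and evaluation hard-fails if an evaluated patient id appears in
the training manifest.

## Numerical implementation

No autodiff framework is assumed: the package ships a compact tape-based
reverse-mode engine on numpy (`mfsunet._tensor`) whose custom operators
(layer norm, bilinear/nearest resampling, max-pool, depthwise
convolutions, the scan) carry analytic adjoints; the sequential scan and
its adjoint are numba-jitted single sweeps, with the Euler discretisation
fused into the kernel on the training path.  Networks train in float32
(configurable); the functional SSM surface preserves float64 inputs, and
the per-timestep scan oracle used in tests is plain Python, deliberately
unvectorised and independent of the kernel path.  All randomness flows
through explicitly seeded numpy generators, so builds, phantom data and
training runs are bit-reproducible on one device.

Conventions for degenerate inputs: overlap metrics are 1 when both masks
are empty and 0 when exactly one is; HD95 on an empty mask returns the
image diagonal (configurable sentinel) with a warning; percentiles
interpolate linearly between order statistics; HD95 compares all
foreground pixels by default, with a boundary-pixels-only mode
(foreground minus erosion) behind a flag — the brute-force oracle tests
cover both, and neither is asserted to be "the" canonical choice.  The
paired t-test raises on zero-variance differences.

## Synthetic phantoms

The generator emulates the features of thyroid ultrasound that make
segmentation hard: multiplicative speckle (a Rayleigh field smoothed to
grain size ~1 px, mean-normalised, mixed at strength 0.4), a single
hypo-intense nodule (background level 0.55, contrast 0.30) whose outline
is a rotated ellipse modulated by radial harmonics (modes 2–5, total
amplitude ≤ 0.2) and renormalised to a target area drawn from 2–18% of the
image, Gaussian boundary blur (σ = 1.5 px), an optional soft-edged
vertical acoustic-shadow band (probability 0.3, gain 0.55), and a
boundary-jittered label variant whose flips are confined within 2 px of
the true contour (a smooth clipped random displacement field).  Each
synthetic patient contributes 5–15 re-rendered views of one nodule
geometry so grouped splitting is meaningful; small datasets cap views per
patient so at least three patients exist.

What the phantoms do *not* model: real speckle correlation structure and
attenuation physics, multi-nodule scenes, probe/operator variability,
calcifications, or genuine inter-observer disagreement beyond boundary
displacement.  Passing the phantom-scale tests therefore demonstrates
that the operators are implemented correctly and that the network can
learn this class of low-contrast, noisy, boundary-ambiguous targets — not
that clinical-grade accuracy on DDTI/TG3K/TN3K is reproduced, which would
require the real datasets and full-scale GPU training.

## Scaled problem sizes

The test suite and the acceptance script run everything on CPU at phantom
scale, chosen as the package's own smoke configuration: 64 phantoms at
64×64, a two-stage width-8 network with N = 4 and expansion 1, at most 30
epochs at learning rate 1e−2 without augmentation, three seeds.  The
higher learning rate and disabled augmentation are the appropriate recipe
for this tiny regime (240 optimisation steps); the full-scale defaults
remain those of the training-protocol section.

## Known limitations

* Binary head only; N-class support exists in the functional
  rectification/metric operators but not in the assembled network.
* The scan is a sequential kernel — linear-time but not a parallel prefix
  scan; fine on CPU at package scale.
* The SLR intermediate head shares parameters with the final head; an
  unshared head would receive no gradient (the mask is hard), so sharing
  is the only self-consistent default.
* `slr_grid_search` treats a failing cell as data (NaN + message), not as
  a fatal error; the arg-max ignores failed cells.
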