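# Methods

`sparsect` studies learned post-processing (LPP) for sparse-view computed
tomography at desk scale: how well a shallow three-layer CNN can stand in
for a deep residual UNet when both are used to clean up filtered
back-projection (FBP) reconstructions, and what each costs in parameters,
FLOPs and receptive field.  Everything below is computed by the package
itself; the test suite and `scripts/acceptance.py` re-derive the quantities
stated here.

## The reconstruction problem

A 2D object `x` (values in [0, 1], square grid, pixel size 1) is observed
through line integrals — a sinogram of `n_views x n_detectors` entries.
Two acquisition protocols are modelled:

* **full-range**: 360 views, 1° apart, over the full circle;
* **half-range**: 180 views over [0°, 180°) — a limited-angle scan.

The presets use a fan beam with a flat (virtual, axis-centred) detector,
source–axis and axis–detector distances both twice the image width.  The
fan geometry matters: with a parallel beam, a 360°/1° scan and a 180°/180-
view scan contain the same information, and the two protocols would not be
distinguishable.  A parallel beam is retained for unit tests because its
projections have closed forms (chord lengths of a disk, view-independent
mass).

Rays are integrated by marching at half-pixel steps with bilinear
interpolation — linear in the image by construction, accurate to well
under one pixel-length against the analytic disk chord.

Measurement noise is additive white Gaussian at a *relative energy*
`level`: `e = level * (||b||_2 / sqrt(m)) * xi`, `xi ~ N(0, I_m)`, so the
expected `||e||_2 / ||b||_2` equals `level` (about 1% realized spread at
desk sinogram sizes).  The training level is 1e-2; the out-of-domain
protocol doubles it.  "Noise level" in the literature this emulates is not
defined anywhere explicit; the relative-L2 reading is this package's
declared convention and is recorded in every sinogram's metadata.

## FBP

Rows are convolved with the band-limited ramp obtained by FFT of the
sampled discrete ramp kernel (h[0] = 1/4, h[odd n] = −1/(πn)², zero-padded
to the next power of two), optionally windowed (Hann, cosine) and cut off
at a fraction of Nyquist; default is the plain ramp at full cutoff.  Two
deliberate numerical choices:

* the truncated kernel's small positive DC term is **kept**: zeroing it
  (the "ramp has zero DC gain" idealization) biases flat regions down by
  about 1% and produces cupping.  Constant detector rows are therefore
  suppressed to ~1e-3 of their mean, not to machine zero.
* fan-flat sinograms get the standard cosine pre-weight
  `D/sqrt(D²+u²)` before filtering and an inverse-square distance weight
  `(D/U)²` in back-projection; scans spanning more than 180° are scaled by
  half (each line is measured twice).  The 180° fan scan is *less* than a
  short scan and no Parker weighting is applied — the limited-angle
  artefacts it produces are the study object, not a defect.

Dense-view parallel FBP of an (area-rasterized) disk reaches a relative
error of about 0.04 at 128²; a binary-edged disk cannot do better than
about 0.07 under any FBP implementation tried (including the scikit-image
reference), which is why phantoms are rasterized with 4x4 area weighting —
the correct discretization of a continuous-domain phantom.

## Phantom families

* **chest-like** (in-domain): a soft-tissue body ellipse, two mirrored
  hypodense lung-like regions, a dense spine-like object, 3–6 random
  blobs, plus zero-mean Gaussian texture (σ = 0.01 by default) inside the
  object support.  The texture models the fact that clinical ground truths
  are themselves reconstructions and never noise-free; a network trained
  on perfectly clean targets would face a different task.
* **flat-sharp** (out-of-domain): noise-free flat regions containing
  small, sharp, high-contrast objects — deliberately different low-level
  statistics from the training family.
* **shepp-logan**: the canonical head phantom (modified intensities, so
  the summed image lies in [0, 1]); used for analytic projector checks.

Randomization is per-image from spawned seed sequences; train and test
splits use disjoint streams of the same user seed.  Images whose summed
ellipse intensities leave [0, 1] are affinely rescaled with a log record
(never clipped).

What the generator does **not** emulate: anatomical realism, scanner blur,
polychromatic/beam-hardening physics, Poisson counting statistics, 3D
context.  Passing the desk-scale tests therefore demonstrates that the
workflow and its comparisons behave as designed — not that either network
reaches clinical-grade quality on real CT.

## Networks

Both networks map an FBP image `y` to a restored image.

**3L-SSNet** — three stride-1 conv blocks, single scale, direct map
`x̄ = F(y)`; hidden blocks are Conv + BatchNorm + ReLU, the output conv is
linear.  The published description of this architecture is internally
inconsistent (kernels {9,5,3} at a constant 128 channels does not match
the published ~85k parameter count), so two variants are shipped:

* `table-consistent` (default): 9×9 (1→128), 3×3 (128→64), 5×5 (64→1) —
  85,696 conv weights, 4.49e10 FLOPs at 512² — matching the published
  cost figures within 1% / 2.1%;
* `as-text`: 9×9 (1→128), 5×5 (128→128), 3×3 (128→1) — 421,120 weights.

Both have a 15×15 maximum receptive field.

**ResUNet** — encoder–decoder with L = 4 pooling stages, 3 convs (3×3,
BatchNorm + ReLU) per level, channels doubling from c0 (64 at reference
scale; 16 in the desk suite), 2×2/2 max-pooling, nearest-neighbour
upsampling followed by a 3×3 conv, *additive* skip connections, and a
global residual link: `x̄ = y + R(y)` with a tanh-activated final conv
(the residual is bounded by 1 in magnitude).  Pooling and upsampling
operators are not pinned down in the source description; max-pool and
nearest-up + conv are the package's choices (the latter keeps parameters
below concatenation-style UNets).  Batch-norm is omitted on each
network's output conv so the output range is not renormalized.

Weights use He initialization; the final conv of both networks is scaled
by 0.01 at initialization ("near-identity start"), so the fresh residual
net reproduces its input exactly and the fresh direct net starts near zero
output — standard practice for restoration networks and necessary at desk
scale, where training budgets are hundreds of steps rather than tens of
thousands.

## Receptive-field calculus

`receptive_field` implements the layer-wise recursion
`r_0 = 1, r_t = r_{t−1} + (k_t − 1)·∏_{i≤t} s_i` (the published form, and
the package default).  For a layer with kernel > 1 *and* stride > 1 — a
2×2/2 pool — this recursion multiplies the kernel extent by the layer's
own stride as well, which over-counts the true input support; the
alignment-exact rule uses `∏_{i<t} s_i` (`convention="support"`).  The two
agree on all stride-1 stacks (so the 3L-SSNet's 15×15 is unambiguous) and
whenever strided layers have kernel 1.  `empirical_rf` measures the true
support by an adjoint pass through a positively-weighted linearized copy
of the stack (1/k² conv weights, average pooling, linear activations) and
matches the support convention exactly on randomized conv/pool stacks.

Applying the recursion to the ResUNet encoder path (3 convs per level,
four 2×2/2 pools, bottleneck) gives a maximum receptive field of 217
(18.0% of a 512² input).  The figure of 172×172 / 11.28% printed alongside
the architecture in the source material is not reconstructible from its
stated configuration under either convention; the package reports the
computed value and documents the discrepancy rather than matching the
printed one.

## Cost accounting

FLOPs: 2 operations per multiply–accumulate, convolution layers only,
at a stated input size (biases, normalization, activations and pooling are
excluded; for any stride-1 pool-free network this reduces to
`2 · pixels · conv_weights`, which is asserted as a cross-check).
Parameters: the headline figure is convolution weights; biases and
batch-norm affine pairs are included in the all-trainable count.  The
convention string is embedded in every report.

## Training

Objective: empirical mean over the training set of the per-image squared
L2 loss (summed over pixels).  Reference recipe: batch 8; ResUNet uses
SGD with Nesterov momentum 0.99, 3L-SSNet uses Adam (β = 0.9/0.999, a
documented substitution for SGD, which stalls for the direct map);
polynomial learning-rate decay `lr(t) = (lr0 − lr1)(1 − t/T)^p + lr1`
from 1e-2 to 1e-5 (p = 1; the decay exponent is not specified upstream),
and global gradient-norm clipping at 5.  Training is single-threaded
deterministic given the seed; a non-finite loss aborts with a diagnostic.

One network is trained per acquisition protocol.  This is not merely
faithfulness to the reference workflow: pooling both protocols into one
training set makes the batch-norm statistics a mixture of two input
distributions, the network learns to rely on batch composition, and its
inference-mode (running-statistics) performance on pure-protocol inputs
collapses toward the identity map.  The effect is reproducible and is the
reason `concatenate`-and-train is supported but not the default.

Two further desk-scale findings shaped the defaults:

* **The reference recipe is too hot for short trainings.**  With the
  summed-pixel loss, initial gradient norms are ~1e4; after clipping, every
  update has norm 5·lr, and with momentum 0.99 the first epochs apply a
  long sequence of large, highly correlated steps.  At 80² / ~200 steps
  this reproducibly drives the ResUNet's last decoder level into a
  dying-ReLU state (all its batch-norm shifts end up negative; the
  residual head then emits exact zeros and cannot recover — the network
  degenerates to the identity map).  The labelled *reference* preset keeps the
  published-recipe values verbatim; the *desk* preset uses Adam 1e-3 → 1e-6 for
  the three-layer net (1e-2 oscillates at this step count) and
  SGD-Nesterov momentum 0.9, 3e-3 → 1e-5 for the UNet.
* **Inference statistics.**  At a few hundred steps the exponential
  running averages lag the final weights enough to cost several RE
  points at inference.  `train` therefore finishes with a precise
  batch-norm recalibration: one pass over the training set with frozen
  weights replaces each layer's running statistics with the exact
  population aggregate (mean of batch means; mean of batch variances
  plus the variance of batch means).  Inference then uses these stored
  statistics by default.  A per-input-statistics convention
  (``inference_stats="image"``) is also available; it suits the
  scale-invariant residual corrector but discards the absolute-intensity
  information the direct map needs, and is not the default.  Running
  statistics are part of the checkpoint.

### Desk scale

The desk-scale study — the package's default and what the test suite
runs — uses 80×80 images (divisible by 2^4, as the UNet requires),
100 training phantoms per protocol (so each network sees 200 pairs across
the two protocol-specific trainings), 12 test phantoms per protocol,
15 epochs, batch 8, ResUNet width c0 = 16, and the table-consistent
3L-SSNet.  These sizes were chosen once so that the full study (four
trainings plus evaluation) completes in tens of minutes of single-core
NumPy/BLAS compute; they are stated here because every aggregate quality
number the package prints at desk scale depends on them.  The 512-scale
"reference" preset (c0 = 64, 50 epochs) is available through the same API for
anyone with the compute to run it.

### What the desk study shows — and what it cannot

The two presets behave very differently at desk image sizes.  The
half-range protocol is limited-angle: its FBP baseline is structurally
degraded (missing frequency sectors) at any image size, and both trained
networks improve on it decisively in RE, SSIM and FSIM.  The full-range
protocol, however, is pinned at 360 views — at 80² that is *above* the
view-sampling limit (~π/2 · 80 ≈ 126 views), so the sparse-view regime the
protocol represents at 512² (360 of ~800 needed views) does not survive
image-size scaling: the full-range FBP baseline is near-optimal (its error
is essentially the 1% measurement noise).  Against such a baseline the
trained networks still win on RE (they denoise), but not on SSIM: the
in-domain family's intrinsic texture lives at the same amplitude and scale
as the measurement noise, so any denoiser removes both, and SSIM penalizes
the structure loss.  The package reports this honestly rather than
weakening the FBP implementation; note that beating a *correct* FBP at
dense sampling is a categorically harder task than beating an unscaled
one.

## Metrics

* `RE = ||x − gt||_2 / ||gt||_2` — unsquared (the squared variant is one
  flag away; the upstream typography is ambiguous).
* PSNR is reported in two variants: `20 log10(n·max(gt)/||x−gt||_2)` (the
  printed formula, with n the pixel count) and the textbook
  `20 log10(max(gt)/RMSE)`; they differ by exactly `10 log10 n`.  Both are
  always reported because published tables print two PSNR numbers whose
  relationship matches neither convention alone.
* SSIM: Wang et al. standard (11×11 Gaussian window σ = 1.5, K1 = 0.01,
  K2 = 0.03), via scikit-image.
* FSIM: phase congruency from a 4-scale × 4-orientation log-Gabor bank
  (minimum wavelength 6, multiplier 2, σ_onf = 0.55, Rayleigh noise
  threshold at k = 2), Scharr gradient magnitude, T1 = 0.85, T2 = 160 on a
  0–255 range, weighted by the maximum phase congruency, with the standard
  low-pass downsampling for images larger than ~256 px.  Implemented from
  the published definition; verified by its axioms (identity → 1, bounded
  in (0, 1], monotone under noise and blur).

Data range is `max(gt) − min(gt)` throughout.

## Out-of-domain protocol

`run_ood` evaluates a trained model under `unseen-noise` (2e-2, in-domain
family) or `unseen-image` (flat-sharp family, training noise) and always
computes the paired in-domain baseline with identical seeds, so the
robustness gap is a logged difference, not an assertion.  No contract is
made about *which* network degrades more — that is an empirical finding
of each run.

## Known limitations

* The NumPy training stack is single-core; desk-scale conclusions are
  directional (does the network improve on its FBP input?), not absolute
  quality claims at clinical resolution.
* The half-range fan protocol is reconstructed without short-scan
  weighting by design; its FBP baseline is correspondingly poor.
* Batch-norm inference uses running statistics; models trained on mixed
  input distributions degrade at inference (see Training) — a property of
  batch normalization itself that the package documents rather than hides.
* The empirical receptive-field probe requires the stack's pooling chain
  to divide the probe input size; it raises a clear error otherwise.
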