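# Methods

## Problem and signal model

Hepatic iron concentration is quantified clinically through the effective
transverse relaxation rate R2* = 1/T2* of liver parenchyma, measured with a
multi-gradient-echo (mGRE) acquisition.  The magnitude signal of a voxel is
modeled as a mono-exponential decay

    S(TE) = S0 · exp(−TE · R2*),

with TE the echo time.  Echo times are stored in milliseconds throughout the
package (the clinical convention) and converted to seconds inside every decay
computation so that R2* is natively in s⁻¹.  The default schedule is the
12-echo clinical protocol TE = 0.93 + 1.34·k ms (k = 0..11, last echo
15.67 ms).

Magnitude reconstruction makes the noise Rician: an observed magnitude is
`sqrt((S + n1)² + n2²)` with `n1, n2 ~ N(0, σ_g²)`.  Rician noise has a
nonzero floor (mean σ·sqrt(π/2) at zero signal), which biases naive decay
fitting precisely where iron overload is severe and the signal decays into
the floor within a few echoes.

Numerical choice: the Rician first moment is evaluated in its Laguerre form
`σ·sqrt(π/2)·L_{1/2}(−s²/2σ²)` using exponentially *scaled* Bessel functions
(`scipy.special.ive`), which keeps a single branch exact and overflow-free
from s/σ = 0 to far beyond 100 (verified against direct quadrature of the
Rice density at ~1e−15).  No separate asymptotic series is needed.

## Synthetic livers

Clinical mGRE series of iron-overload patients are not publicly available,
so training and evaluation use synthetic subjects:

- 64×128 slices (the clinical acquisition matrix), an elliptical "liver" on
  an empty background, with mildly jittered centre/axes per seed;
- parenchymal R2* drawn from a Gaussian-smoothed random field (correlation
  length 4 px) whose values are rank-mapped to an exactly uniform marginal
  on 45–956 s⁻¹ — the span from normal liver to severe overload.  The rank
  map preserves the spatial correlation of the smooth field while making the
  per-subject R2* histogram uniform;
- a few small circular "vessels" with low R2* (25 s⁻¹) and brighter S0;
- parenchymal S0 around 216.6 arbitrary units (±5 % smooth variation), so
  that the benchmark noise levels σ_g = 7…17 correspond to the clinical SNR
  ladder (first-echo parenchyma signal / σ).

What the generator does *not* emulate: anatomy beyond one ellipse, motion and
breathing artifacts, partial-volume mixtures, fat–water modulation, spatially
varying or non-central-chi noise, and the image texture of real liver
parenchyma.  Passing tests therefore demonstrate correctness of the methods
under the stated noise model and a calibrated recovery ordering between
estimators, not clinical performance.

The ground truth here is exact by construction — unlike reference maps
derived from denoised clinical data — so parameter recovery is measured
against the true maps, with no reference-estimation step in between.

## Model-based fitting baselines

All fitters operate pixel-wise on the masked voxels with a vectorized
projected Levenberg–Marquardt solver (analytic Jacobians, per-voxel damping,
objective non-increasing across accepted steps; relative tolerance 1e−10 or
200 iterations; R2* clamped to (0, 2000] s⁻¹ to stop runaway fits on pure
noise; initialization by log-linear least squares).

- `loglinear`: OLS on log-signal; exact on clean data; excludes non-positive
  echoes.
- `nlls`: plain least squares on the mono-exponential.
- `offset`: S0·exp(−TE·R2*) + C with C ≥ 0 approximating the noise floor.
- `truncation`: iteratively drops trailing echoes whose *estimated clean*
  signal falls below 2σ, refits on the retained prefix until stable, keeps at
  least 3 echoes.  The published automatic-truncation rules this stands in
  for are not fully specified in the literature available to this package;
  the 2σ-floor/minimum-3 scheme is this package's explicit definition.
- `m1ncm`: fits measured magnitudes to the exact Rician expectation of the
  decaying signal (first-moment noise correction), with the analytic
  derivative of the Rician moment in the Jacobian.
- `m2ncm`: the second-moment variant (fits y² to s² + 2σ²), provided behind
  the same interface.

Measured bias structure (Monte Carlo, S0 = 216.6, σ = 17, R2* = 800 s⁻¹):
plain least squares underestimates severely (the elevated tail flattens the
apparent decay), the offset model overestimates, the truncation model
underestimates moderately, and M¹NCM is closest with a small positive bias.
The signed direction of the plain-NLLS bias is not asserted anywhere as a
contract; what the package guarantees (and tests) is that M¹NCM's absolute
bias is smaller than plain least squares' at every tested R2*.

The noise level σ can be supplied or estimated from a signal-free background
ROI as 0.80 × the mean magnitude across all echoes — the Rayleigh-mean
inversion, whose exact constant sqrt(2/π) = 0.7979… is available as an
option; the conventional rounded 0.80 is the default (≤ 0.3 % systematic).

PCANR-style spatially regularized fitting is not implemented; the benchmark
harness accepts externally computed R2* maps so such a method can be scored
on the same subjects.

## Cascade networks

The learning method is a two-stage cascade: a denoising network Φ cleans the
12-echo stack, then a mapping network U produces (S0, R2*) maps.

**Denoiser** — a DnCNN-style residual network of separable convolution
layers: each layer applies 10 per-channel 3×3 spatial kernels (depthwise)
followed by a pointwise convolution mixing all maps into 40 channels, batch
norm, ReLU; 8 layers by default, the last restoring the echo count with no
activation; the network predicts the noise and subtracts it from the input.
The separable reading (depthwise-then-pointwise) is one of several
consistent with the published description of this family; it is the one
whose per-layer parameter arithmetic matches the reported scale of such
models.

**Mapper** — a standard 2D U-Net (depth 4, base width 32 by default, widths
doubling per level, two 3×3 conv+BN+ReLU per block, 2×2 max-pool, transposed
-conv upsampling with skip concatenations, final 1×1 conv to 2 channels).
The S0 channel passes through a softplus so it is strictly positive; the R2*
channel is linear during training and clamped ≥ 0 at inference.  The exact
channel widths of the published full-scale models are not recoverable from
their textual description; their reported totals (≈8.77 M and ≈8.63 M
trainable parameters) are treated as reference metadata, and the default
configuration here lands in the same magnitude without asserting equality.

**Losses.**  The denoiser minimizes mean squared error against noise-free
images.  The mapper minimizes the *model-consistency* (physics) loss: images
are re-synthesized from the predicted maps through the decay model and
compared with the noise-free references.  The maps are never directly
supervised; gradients flow through the exponential.  Both losses are means
(not sums) over elements, so values are batch-size invariant — the norms of
the underlying formulation up to a constant.  By construction
`loss_mapping(maps, X, te) == loss_denoising(synthesize_decay(maps, te), X)`.

**Normalization and conditioning.**  Intensities are divided by the corpus
S0 scale (216.6) before the networks; the R2* head is scaled by
1000 s⁻¹/unit so both outputs live near unit magnitude.  The decay exponent
is clipped to [−60, 20] with gradients masked at the clip (pure overflow
guard).  The mapper's head starts with small weights and biases placing S0
near 1 and R2* near 500 s⁻¹; the denoiser's final layer starts near zero so
the residual network begins close to the identity.  Both choices remove the
exploding-exponential failure mode of the physics loss at initialization.

**Training.**  Adam, initial learning rate 0.01 halved every dozen epochs,
mini-batch 128 by default, fully deterministic given the seed (weight init,
shuffling).  The two stages are trained separately; when the denoiser is
supplied to mapper training it is frozen (bit-identical weights before and
after).  Noise policies: fixed σ (one level for the whole corpus) or mixed
(σ = 1..19 step 2, assigned round-robin so levels are evenly proportioned).
After the epoch loop, batch-norm running statistics are re-estimated with a
frozen-weight pass over the corpus (mean of batch means; mean of batch
variances plus variance of batch means): with short schedules the momentum
running averages lag the weights, and the exponential in the physics loss
punishes that mismatch brutally at inference time.

**Epochs** default to 40 for full runs and a handful for desk-scale runs;
the published training protocol does not state an epoch count.

## Scaled-down benchmark conditions

The learning benchmark runs at desk scale on one CPU: 40 training subjects
and 8 held-out subjects at σ_g = 15; patches at stride 24 with horizontal
and vertical flip augmentation (30 patches of 32×32×12 per subject, 1,200
per corpus); reduced widths (4 denoiser layers with 4 spatial kernels per
channel and 24 temporal channels; mapper depth 3, base width 16); batch 32;
8 epochs.  Training corpora, test subjects and noise realizations all
derive from one seed.  Three design choices matter for making such short
runs stable, all selected on training-side evidence (loss trajectories
across seeds):

- global gradient-norm clipping at 1.0 — at learning rate 0.01 the physics
  loss occasionally produces an exploding first-epoch batch that a short run
  never recovers from;
- the post-training batch-norm re-estimation described above;
- a shallower mapper (depth 3) and small batches, which buy several times
  more optimizer steps inside the epoch budget; with too few steps the
  mapper semi-collapses toward a spatially flat R2* output.

At this scale the absolute NRMSE values (≈10–15 % in the liver) are well
above the published full-scale numbers (hours of GPU training on clinically
derived textures); the benchmark's claim is the *ordering* — the trained
cascade beats pixel-wise least squares on the same noisy subjects by tens of
percentage points — not the magnitudes.  One full-scale property does not
survive the scale-down: with 8-epoch training the cascade typically lands
0.2–1.5 NRMSE points *behind* the single-stage mapper (the denoiser removes
about 70 % of the noise energy, but its spatially structured residual costs
the downstream mapper roughly as much as the noise reduction buys).  The
mixed-noise cascade, by contrast, benefits substantially from its near-clean
low-σ training subjects and outperforms the fixed-σ model here.

## Patch pipeline

Patches are 32×32 across all 12 echoes, extracted on a stride-8 grid by
default (65 per 64×128 slice), anchored at pixel 0, final row/column included
only if fully contained.  Augmentation applies rot90/180/270 and horizontal/
vertical flips consistently to images, maps and masks (the pointwise decay
model commutes with these).  Corpus manifests record per-patch provenance
(subject, offset, augmentation op) and a content hash; identical seeds give
identical manifests.

## Evaluation

- NRMSE: ‖ref − est‖₂ / ‖ref‖₂ over a region (whole liver including
  vessels), reported as % in summaries.
- SSIM: the *global* single-window form from region-wide means, variances
  and covariance with k1 = 0.01, k2 = 0.03 and L = max−min of the reference
  over the region.  The formulation is stated with global statistics, so the
  single-window form is the default; a sliding-window variant (scikit-image)
  is available.
- Representative R2*: the arithmetic mean over a parenchyma mask (vessels
  excluded) drawn on the reference and applied to every method's map.
- Bland–Altman: mean difference ± 1.96·SD limits (SD with n−1).
- Wilcoxon signed-rank (scipy): zero differences dropped, tie-averaged
  ranks, exact null for n ≤ 12, normal approximation with continuity
  correction beyond.

## Known limitations

- The phantom is geometrically trivial; results do not transfer to clinical
  texture claims.
- Non-central chi noise, spatially varying σ, complex-valued fitting and
  fat–water models are out of scope.
- A trained cascade applies only to the TE schedule and echo count it was
  trained with; prediction refuses mismatches.
- Desk-scale training runs are short; the cascade/baseline comparison is a
  qualitative ordering under the stated conditions.
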