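# Methods

This note documents the model, the phantom simulator, the numerical choices,
and the limitations of `regsct`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Noisy-label translation model

The training set consists of pairs (x, ỹ): a CBCT slice and a planning-CT
slice of the same anatomy acquired at a different time. We model the
misalignment as ỹ = y ∘ T, where y is the (unobserved) aligned reference, T
a smooth random displacement field, and ∘ bilinear resampling. The
generator G is trained so that its output, *after* spatial correction by a
registration network R, matches the noisy label:

- correction: `L_corr = mean |ỹ − G(x) ∘ R(G(x), ỹ)|` — L1 after warping
  the generated image by the field R predicts from the pair;
- smoothness: a squared forward-difference penalty on that field, keeping
  the correction a plausible deformation rather than an arbitrary resampling;
- adversarial: least-squares patch-GAN terms (real = 1, fake = 0);
  the discriminator judges ỹ as its real sample.

At inference only G runs: clip → normalize → resample → G → denormalize →
resample back. R and D are training-time devices.

### Why least squares, and why real = 1

The adversarial objective's functional form is a design choice: least
squares is stable at batch size 1 and pairs naturally with patch
discriminators. The real = 1 / fake = 0 convention is the field's standard;
the loss definitions here are stated self-consistently under it.

### Smoothness normalisation

`L_smooth` is the sum over the two displacement components and the two
spatial directions of the *mean* squared forward difference (edge rows
excluded from each direction's mean). Under this normalisation a field
whose row-component increases by exactly one pixel per row scores exactly
1.0, which makes the magnitude interpretable: it is the squared
pixels-per-pixel strain.

## Architectures

- **Generator**: 7×7 stem convolution (reflection-padded), two 3×3 stride-2
  downsampling convolutions, nine residual blocks (3×3, instance norm,
  ReLU, reflection padding), two 3×3 stride-2 transposed convolutions, 7×7
  head, tanh. Channel widths default to 64/128/256 and are configurable;
  the down/residual/up skeleton is the contract.
- **Registration U-Net**: input is the channel-concatenation of the
  generated image and the noisy label; an encoder of one stride-1 plus
  three stride-2 3×3 convolutions (16/32/64/128 channels by default),
  a decoder of transposed convolutions with skip concatenations, leaky-ReLU
  activations, no normalisation layers. The 3×3 output head is
  **zero-initialised**, so the predicted field — and hence the correction —
  starts at the identity, and the correction loss at step 0 equals plain L1.
- **Patch discriminator**: 4×4 convolutions with strides 2, 2, 2, 1, 1 and
  instance norm from the second layer (a 70×70-receptive-field patch
  classifier). A 256×256 input yields a 30×30 score map. A stride of 4 in
  all four layers would collapse 256→1 and contradict a patch map, so
  stride 2 is used; inputs too small to produce a 1×1 map raise a shape
  error.

## Autodiff engine

No GPU framework is a dependency: `regsct.autodiff` is a tape-based
reverse-mode engine over numpy with exactly the operations the model needs.
Convolutions are computed as sums over kernel taps of small matrix
products, which at batch size 1 and these channel widths outperforms an
im2col patch matrix. The warp operator (`grid_sample`) is differentiable in
both the image and the field; out-of-grid samples clamp to the border, and
the coordinate gradient is zeroed where clamping is active. All gradients
are verified against central finite differences in `tests/test_autodiff.py`.

Border policy: clamp-to-edge was chosen over zero/−1 padding because padded
values would inject spurious air rims into the correction loss at slice
borders.

## Preprocessing

HU values are clipped to [−1000, 2000] (air through dense bone; prevents
extreme bone values from dominating training) and mapped affinely to
[−1, 1]; the inverse map restores HU exactly (≤1e-3 HU round trip in
float32). Resampling is bilinear — matching the warp's interpolation — with
pixel spacing rescaled. Image metrics are computed on clipped HU: the
window is part of the measurement definition here, since the model only
ever sees windowed data.

## Phantom simulator

`regsct.phantom` manufactures the study conditions with known ground truth:

- **Anatomy**: a soft-tissue ellipse (default 40 HU) inside a bone ring
  (800 HU) on an air background (−1000 HU), with optional interior air
  cavities and fractional geometry jitter. Piecewise-constant by design, so
  deterministic examples have exact histograms.
- **Degradation** (CBCT formation), in order: warp by a random smooth
  deformation (Gaussian-smoothed white noise rescaled to a stated peak
  displacement — the label noise, returned as ground truth), Gaussian
  blur, global HU shift, radial cupping bias `amplitude · (r/r_max)²`
  (the canonical CBCT scatter artifact shape), additive Gaussian noise,
  final clip to the HU window. Deformation precedes intensity corruption so
  spatial and intensity errors are independent, as the noise model assumes.
- **Profiles**: four named profiles order the severity qualitatively as the
  clinic observes it — `synergy` has by far the largest HU shift (−290 HU,
  chosen so soft tissue at 40 HU lands near −250, mirroring the reported
  CBCT peak near −220 against a pCT peak near 70) plus the strongest
  cupping, noise and blur; `halcyon`, `trilogy` and `vitalbeam` are milder
  (−40 to −60 HU shifts). These are configuration defaults, not claims
  about specific machines.
- **Seeding**: sample i of a dataset uses
  `SeedSequence([master_seed, i]) mod 2^31` for its phantom and that value
  plus one for its degradation, so any sample is reproducible in isolation
  from the recorded per-sample seed.

What the phantoms do **not** emulate: anthropomorphic anatomy, physically
modelled scatter or beam hardening, 3-D cone-beam geometry, scanner FOV
differences. Passing tests therefore demonstrate the mechanics of the
method — that registration-corrected training absorbs misalignment and the
translator restores HU under these corruptions — not clinical performance.

## Training regime

Adam with lr 1e-4, β = (0.5, 0.999), batch size 1, weight decay 1e-4
applied uniformly to G, R and D (classic L2-in-gradient form). Update
order per sample: D on its real/fake term (fake detached), then G and R
jointly on the weighted total. Samples are visited in a seeded random
order; a fixed seed reproduces the loss trajectory bit-for-bit on one
device. When a validation set is supplied, per-epoch validation MAE (HU) is
logged and the generator snapshot with the lowest validation MAE is
retained — a model-selection rule this package defines for itself.

The printed objective is the unweighted sum of the three terms; the weights
are exposed as configuration. The bundled toy study uses (w_corr, w_smooth,
w_adv) = (20, 10, 1) — the correction-dominated weighting established for
this model family — with lr 3e-4, which converges within its five epochs;
the equal-weight objective also improves but needs more epochs than the toy
budget at 64×64.

### Problem sizes used by tests and the acceptance script

Full-scale runs (256×256, 80 epochs, default widths) are supported but take
hours on CPU. The shipped studies use 64×64 slices, reduced channel widths
(generator base 16, registration base 16, discriminator base 32), 200
samples across the four profiles, and 5 epochs — the smallest configuration
at which the qualitative claims (universal per-profile improvement;
registration recovery) are stable. The registration-recovery experiment
trains R alone (G fixed to the identity) on eight (y, y∘T) pairs with 5-px
peak deformations on a 16-px smoothness scale (large-scale anatomical
change) for 2,000 iterations with standard momentum (β₁ = 0.9 — appropriate
for plain regression, unlike the GAN's 0.5), lr 1e-3 dropped to 3e-4 after
1,200 iterations (the drop escapes a late edge-matching plateau), and
w_smooth = 0.02; it measures the drop in correction loss from its step-0
value.

## Evaluation

MAE (Eq.-level mean |Δ|), MSE (standard mean squared difference — the
printed formula in the source literature squares the *mean* absolute
difference, which would equal MAE² and be inconsistent with the PSNR
definition, so the standard form is implemented), PSNR = 10·log₁₀(peak²/MSE)
with the peak defaulting to the reference image's maximum (identical images
flag infinity rather than raising), and SSIM in its single-window global
form — means, variances, and cross-covariance over the whole image with
c1 = (0.01·L)², c2 = (0.03·L)², L = 3000 HU (the window span). A
conventional 11×11 Gaussian-windowed SSIM is available (`windowed=True`)
for comparability with reports that use it. No body mask is applied.

HU histograms discard voxels outside [−500, 500] before binning, removing
the dominant air peak so soft-tissue distribution differences are visible;
counts are normalised over the included voxels only.

Group comparison is deliberately thin: Kruskal–Wallis across accelerator
profiles with Holm-corrected pairwise Mann-Whitney tests, via
scipy/statsmodels.

## DVH analysis

D_p is the dose received by at least p% of the masked volume (the standard
radiotherapy reading). The cumulative DVH uses 1,000 dose levels by default
with linear interpolation between levels; curve-derived quantiles are
clamped into [Dmin, Dmax] to remove sub-bin discretisation overshoot, which
preserves the ordering invariant Dmin ≤ D98 ≤ D95 ≤ D50 ≤ D2 ≤ Dmax
exactly. Dmin/Dmax are raw voxel extremes (clinical systems vary; the raw
convention is documented rather than near-extreme percentiles). The
difference rate Dr = (D_sCT − D_pCT)/D_pCT is undefined (NaN) for a
non-positive reference; pass rates count |Dr| ≤ threshold. No
treatment-planning dose engine is included — dose grids come from
`synthetic_dose` or user files — so clinical dose-difference tables are out
of reach by design.

## Command-line configuration

`regsct train` reads a single YAML file:

```yaml
manifest: sim/manifest.csv     # from `regsct simulate`
out_dir: run/                  # checkpoint.npz, losses.csv, val_mae.csv
val_fraction: 0.2              # leading fraction held out for model selection
log_every: 1                   # epochs between stderr progress lines
train:                         # TrainConfig fields
  epochs: 5
  image_size: 64
  seed: 7
  learning_rate: 3.0e-4        # defaults: lr 1e-4, betas (0.5, 0.999),
                               # batch_size 1, weight_decay 1e-4
weights: {w_corr: 20.0, w_smooth: 10.0, w_adv: 1.0}
models:                        # optional; defaults are the full-size nets
  generator: {base_channels: 16}
  registration: {base_channels: 16}
  discriminator: {base_channels: 32}
```

Every subcommand writes a `provenance.json` (command, full config, seed,
package version) beside its outputs; CSV outputs carry fixed headers
(`metrics.csv`: case, profile, comparison, mae, mse, psnr, ssim;
`dvh` output: metric, pct_gy[, sct_gy, dr_percent]).

## Known limitations

- 2-D slices only; the method operates per-slice and no 3-D generation or
  3-D convolution is provided.
- The phantom's piecewise-constant tissue makes the translation task easier
  than clinical data; absolute metric values are not comparable to clinical
  reports.
- The tanh output bound means exact −1000 HU (air) is reached only
  asymptotically, leaving a small residual error floor in air regions.
- Checkpoints store parameters positionally with a version tag; changing
  architecture configs invalidates them (by design, with an error).
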