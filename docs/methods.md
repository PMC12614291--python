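# Methods

## Problem and model

Cone-beam CT (CBCT) acquired on the treatment machine carries the day's
anatomy but unreliable Hounsfield units: cupping bias, streaks, noise and
a small circular field of view (FOV). `cbctdiff` implements a conditional
denoising diffusion probabilistic model (DDPM) that translates a CBCT
slice into a synthetic CT (sCT) with CT-grade intensities while keeping
the CBCT's anatomy, trained on rigidly registered (planning CT, CBCT)
slice pairs in normalized units.

The forward process corrupts a clean slice `x_0` over `T` steps,

    q(x_t | x_{t-1}) = N(sqrt(1 - beta_t) x_{t-1}, beta_t I),
    x_t = sqrt(abar_t) x_0 + sqrt(1 - abar_t) eps,   abar_t = prod(1 - beta_i),

and a U-Net `eps_theta(x_t, y_0, t)` is trained to predict `eps` with the
clean CBCT `y_0` concatenated as a second input channel at every step
(*channel conditioning*). Sampling runs the standard ancestral update

    x_{t-1} = (x_t - (1 - alpha_t)/sqrt(1 - abar_t) eps_hat) / sqrt(alpha_t)
              + sigma_t z,

with `z = 0` at `t = 1`. The method's distinctive step is *noised
conditioning*: instead of starting at pure noise, the guiding CBCT is
itself diffused to an intermediate timestep `t_con` and denoising starts
there. The justification is exact: when one noise realisation drives both
images, `x_t - y_t = sqrt(abar_t) (x_0 - y_0)`, so a partially noised CBCT
converges to the same latent neighbourhood as the partially noised CT it
should correspond to. `t_con` trades anatomy preservation (low `t_con`)
against artifact destruction and correction opportunity (high `t_con`);
`t_con = T` degenerates to a pure-noise start, `t_con = 0` returns the
CBCT unchanged.

## Noise schedules

Three schedules over `T = 1000` steps with `beta` bounds `[1e-4, 0.02]`:

* **linear** — even `beta` ramp between the bounds;
* **cosine** — defined through `abar_t = cos^2(((t/T + s)/(1 + s)) pi/2)`
  with offset `s = 0.008`; betas derived from consecutive ratios and
  clipped to `[beta_min, 0.999]`. This retains far more signal late in the
  trajectory (`abar_900 ≈ 0.024` vs `2.8e-4` linear), which is why noised
  conditioning with a cosine schedule already works at `t_con = 0.9 T`.
  A `cosine_beta` config variant interpolates `beta` itself on a raised-
  cosine ramp instead, for the reading in which the bounds apply to the
  cosine betas directly;
* **sigmoid** — logistic `beta` ramp between the bounds, steepness `k = 6`.

Timesteps are 1-based; `abar_0 = 1` is stored explicitly. The reverse
variance is fixed at `sigma_t^2 = beta_t` (the network predicts only the
noise); the posterior `beta-tilde` variant is available by config. With
`T = 1` every kind degenerates to a single `beta_min` step, keeping the
construction deterministic.

Two tail caveats, both verified numerically and tested at the ranges where
the properties hold: the derived cosine betas saturate at their upper clip
in the final ~1% of steps, so the cosine-over-linear retention ordering
reverses for `t ≳ 0.995 T` (both retentions are below 1e-4 there); it
holds throughout `[0.6 T, 0.97 T]`, which is the regime noised
conditioning uses.

## Timestep samplers

Training draws `t` from a configurable distribution over `{1..T}`:
uniform; exponential with weight `exp(-t / tau)`, `tau = T/4` by default;
triangular with weight `T - t + 1`. The weighted samplers put more mass on
low timesteps, where denoising (fine detail on nearly clean images) is
hardest and converges slowest. Draws use inverse-CDF lookup on the
tabulated pmf. Losses are not reweighted when sampling non-uniformly — the
training loop follows the plain objective. Note the exponential pmf with
`tau = T/4` is flatter than the triangular pmf at the very top of the
range, so its CDF dominance over triangular holds through the bulk
(`k ≲ 0.9 T`) but not in the extreme tail.

## Denoiser

A 2-channel-in / 1-channel-out U-Net: `depth` resolution levels with
channel widths `base_width * min(2^level, 8)`, `blocks_per_level` residual
blocks per level (GroupNorm → SiLU → 3x3 conv, twice, plus a learned skip
when widths change), average-pool downsampling, nearest-neighbour
upsampling with skip concatenation, and single-head spatial self-attention
at configurable levels (default: the deepest level, plus the bottleneck).
The timestep enters as a sinusoidal embedding passed through a small MLP
and added per residual block as a per-channel bias. The output head is
initialised near zero so the initial prediction is almost unbiased while
remaining sensitive to all inputs.

Because no tensor framework is assumed, the network runs on a small
in-repo reverse-mode autodiff engine over NumPy (im2col/GEMM convolutions,
GroupNorm, attention, pooling); every primitive is validated against
central finite differences in the test suite, and training uses a plain
Adam implementation. The toy configuration (depth 3, base width 16,
~0.5 M parameters on 32x32 slices) trains on one CPU in minutes; a
6-level, 2-blocks-per-level configuration of the same family
(~2e8 parameters) is constructible for 256x256 work but is not exercised
by the tests.

Training defaults in the experiment harness: Adam, batch 8, 3000 steps
with cosine learning-rate decay from 1e-3 to 1e-4, uniform timestep
sampler; all exposed in the config. The decay matters at toy scale: the
DC component of a 32x32 slice carries ~1/1024 of the MSE weight, so the
global HU level is the slowest thing the denoiser learns, and stopping at
a high learning rate occasionally leaves slices anatomically correct
(NCC ≈ 0.99) but globally offset by hundreds of HU. Per-step
losses are recorded with the timestep that produced them, binned into
deciles of `T`, to reproduce the band-convergence diagnostic: high-t bands
(mostly-noise inputs, coarse structure) converge quickly; low-t bands lag.

## Synthetic paired data

Real paired clinical data cannot be shipped, so the generator produces
rigid pairs with the structure the method assumes. The planning-CT slice
is piecewise-constant anatomy: air background (-1000 HU), an elliptical
soft-tissue body (40 HU, randomized centre and semi-axes giving body area
fractions of roughly 0.25-0.5), a posterior spine plus two random bone
blobs (1000 HU), and usually one anterior air cavity. The CBCT applies, in
a fixed order chosen so noise-free specs are exactly invertible:

1. body-contour rescale ×0.98 (weight change between acquisitions),
2. rigid shift of (1, 1) px (set-up error),
3. radial cupping bias, amplitude 60 HU depressing the centre,
4. six streak lines of ±120 HU through the object,
5. additive Gaussian noise, SD 20 HU,
6. circular FOV crop at 0.9 of the half-width, filled with air,
7. clip to [-1000, 3000] HU.

These amplitudes were chosen once to land the CBCT-vs-pCT masked MAE in
the low hundreds of HU with NCC far from 1 — clearly degraded but
anatomically faithful, comparable in severity to clinical head-and-neck
CBCT. What the generator does *not* emulate: genuine projection physics
(no Radon/FDK reconstruction), beam hardening tied to actual bone paths,
anatomical deformation between the pair beyond a global contour rescale,
or scanner-specific texture. Passing the end-to-end tests therefore shows
the conditional sampler recovers clean HU maps from this artifact family;
it does not certify clinical image quality.

Preprocessing matches the clinical chain: resample to 1.0 x 1.0 x 3.0 mm
by linear interpolation, centre-crop (air-padded), clip HU to
[-1000, 3000], rescale affinely to [-1, 1]. The map is exactly invertible
on its range, and every pair carries a unit tag so HU-space metrics refuse
normalized inputs.

## Evaluation

Metrics are computed inside the circular CBCT-FOV mask (by default the
same radius fraction used for the degradation, 0.9; a smaller mask is
available for headrest-style exclusions): MAE in HU; PSNR as
`10 log10(R^2 / MSE)` with fixed `R = 4000` HU (the clipped window, so
scores are comparable across images) capped at 100 dB for identical
images; NCC as zero-mean normalized correlation. Per-slice values
aggregate as mean ± SD. Diagnostics: signed HU difference maps, histograms
truncated at -950 HU to keep air from dominating, and the latent
convergence curve (cosine similarity / Euclidean distance between the pair
noised with a shared realisation).

## Scaled-down study and what it shows

The default experiment: 220 generated pairs (200 train / 20 held out),
32x32 slices, cosine schedule with `T = 1000`, toy denoiser, 3000 Adam
steps, sampling at `t_con = 1000` and `t_con = 800` with stochastic `z`
and fixed seeds. These sizes keep a full run around a quarter-hour on one
CPU while preserving the study's contrasts, which reproduce at this scale:

* sCT masked MAE beats the CBCT baseline at `t_con = 0.8 T`;
* the pure-noise start (`t_con = T`) is far worse than the CBCT — the
  toy model cannot synthesise anatomy from noise plus a conditioning
  channel alone, so partial noising is what makes the few-shot setting
  work;
* early in training, the highest-decile timestep band has markedly lower
  loss than the lowest band.

Magnitudes are not comparable to a clinical study and are not asserted —
only directions and closed-form identities are.

## Numerical choices and edge cases

* All schedule mathematics in float64; network training in float32.
* Recurrence/product identity for `abar` holds to 1e-12; the oracle
  sampler test bounds accumulated reverse-loop error at 1e-3 per pixel
  over 1000 steps.
* `z = 0` is enforced at `t = 1`; supplying noise there is a contract
  violation.
* Empty masks, constant images inside a mask (NCC), shape mismatches,
  out-of-range normalized values and invalid specs raise typed errors.
* Sampled sCTs are clipped to [-1, 1] before conversion to HU; outside-FOV
  content is immaterial to metrics since scoring is mask-local.
* Determinism: every stochastic operation takes an explicit generator; a
  run's global seed fans out to named sub-seeds (data, init, train,
  sample) via `SeedSequence`, so reruns are bit-identical on one machine
  and stages can be varied independently.

## Known limitations

The phantom family is geometric, not physical; the toy network is far
below clinical capacity; slices are 2D with no volumetric consistency; the
sweep harnesses (t_con grid, training-set-size sensitivity) retrain one
model per row and are priced for workstation use, not CI. Accelerated
samplers (DDIM etc.), learned variances and deformable registration are
out of scope.
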