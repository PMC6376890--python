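# Methods

## Model and procedure

An observed image is modelled as `g_noisy = g + n` with `n` i.i.d.
zero-mean Gaussian, variance σ² on the unit intensity scale. De-noising
proceeds by (1) a J-level 2-D discrete wavelet transform, (2) elementwise
shrinkage of every detail (horizontal/vertical/diagonal) subband with a
per-subband threshold λ, the approximation subband passing through
untouched, (3) inverse transform and clipping to `[0, peak]`. Because an
orthogonal wavelet transform preserves white noise (each coefficient
carries noise of the same σ), a threshold proportional to σ separates
noise-dominated from signal-dominated coefficients.

## Shrinkage rules

* **hard** `ŵ = w·1{|w| ≥ λ}` — unbiased above λ but discontinuous at
  ±λ, which produces pseudo-Gibbs oscillations near edges.
* **soft** `ŵ = sgn(w)(|w| − λ)⁺` — continuous but biased by λ for
  every surviving coefficient.
* **semisoft** — zero below λ₁, identity above λ₂, linear ramp between;
  when only λ is given we take λ₁ = λ, λ₂ = 2λ, the common convention.
* **improved** — see README for the formula. Design notes:
  * The sub-threshold denominator uses the base-100 logarithm of
    `|w|/λ`. Algebraically the branch equals
    `w·(m/2.1)·(|w|/λ)^log₁₀₀(2.1)` with exponent ≈ 0.1611, so it decays
    to zero very slowly; any log base reproduces the branch value
    `λ·m/2.1` at the threshold, and base 100 was chosen as the slowest
    such decay, consistent with the rule's published description.
  * Default `m = 1.05 = 2.1/2` is the unique value joining the two
    branches continuously (both one-sided limits `λ/2`); `m` remains
    configurable but other values introduce a jump at ±λ.
  * `|w| = λ` is assigned to the sub-threshold branch; at the default
    `m` both branches agree there anyway.
  * Above-threshold correction `w·m·2.1^(99 − 100|w|/λ)` is evaluated in
    log space so large `|w|/λ` underflows to zero instead of overflowing;
    beyond `|w| = 2λ` it is below 1e-12, i.e. the rule is numerically the
    identity there.
  * `ŵ(0) = 0` by continuity (the printed sub-threshold expression is
    singular at 0; its limit is 0).

All rules are odd, sign-preserving, monotone nondecreasing, and (for
`m ≤ 2.1`) shrinking: `|ŵ| ≤ |w|`.

### The cost of the λ/2 anchor

The continuity anchor forces the improved rule to retain the fraction
`(m/2.1)·(|w|/λ)^0.1611 ≈ 0.5` of *every* sub-threshold coefficient. In
flat image regions those coefficients are pure noise, so the rule keeps
residual noise energy of roughly `0.2·δ²` per detail coefficient that
hard/soft thresholding remove entirely. The benefit — half of each small
*signal* coefficient survives, and no threshold discontinuity — dominates
at low noise (the rule wins the benchmark at variance 0.01), but the
retained-noise term grows with δ², and from variance ≈ 0.03 upward hard
thresholding yields higher PSNR on every phantom we generate. The
benchmark harness and acceptance script report this ordering as measured
rather than asserting the published uniform superiority, which we could
not reproduce under this (only self-consistent) reading of the rule.

## Threshold selection

* Universal: `λ = δ√(2 ln MN)` (natural log, the standard VisuShrink
  convention).
* Level-dependent: `λⱼ = δ√(2 ln(MN(1 − α·j)))`, the literal reading with
  `(1 − α·j)` inside the log argument. A guard rejects
  `MN(1 − α·j) ≤ 1` with an explicit message. `λⱼ` is strictly below the
  universal threshold and strictly decreasing in `α·j`.
* Level indexing: j = 1 is the finest level. The default α schedule is
  linear from 0.1 (finest) to 0.3 (coarsest) — small α at high
  frequencies keeps the threshold near-universal where noise dominates,
  larger α at low frequencies lowers it where signal dominates. Note the
  default schedule satisfies the `α·j < 1` guard only for J ≤ 3 (at
  J = 4 the coarsest level has α·j = 1.2); deeper decompositions need a
  user-supplied schedule, and the guard error says so.
* Noise scale: `δ̂ = median(|d₁diag|)/0.6745` (MAD on the finest diagonal
  subband), robust to sparse signal outliers; or a user-fixed δ. δ = 0
  makes every threshold 0 and de-noising the identity.

## Pipeline defaults

Wavelet `sym4`, J = 3 levels, symmetric boundary extension — common
de-noising defaults, recorded in `CoeffSet.meta`; all configurable.
Images are processed as floats on [0, 1]; 8/16-bit files are mapped by
peak division on read and inverted on write. Reconstruction is exact to
< 1e-8 on untouched coefficients (including odd image sizes, where the
transform pads by one sample and the pipeline crops back).

## Metrics

MSE is computed on the 0–255 scale (`255·pixels/peak`, no integer
quantization) over i = 1..M, j = 1..N; PSNR = `10·log₁₀(255²/MSE)` with a
fixed peak of 255 and an `inf` sentinel at MSE = 0. The published
comparison tables this package's metrics are validated against contain 36
(MSE, PSNR) cell pairs of which 24 are self-consistent under this formula
to ±0.01 dB; the 12 inconsistent cells are recorded as printing errors in
`wavedn/reference.py` and excluded from validation.

## Synthetic data

Phantoms (`ellipses`, `shepp_logan_like`, `piecewise_smooth`) are
deterministic [0, 1] images with piecewise-constant plateaus and sharp
curved edges, emulating single-channel anatomical images: flat tissue
regions where residual noise is visible and edges where pseudo-Gibbs
artifacts arise. They do not emulate MRI texture, partial-volume
gradients, bias fields, or Rician noise statistics, so benchmark numbers
characterize the method under the idealized additive-Gaussian model only.
Noise is `N(0, σ²)` i.i.d. per pixel at the study variances
{0.01, 0.03, 0.05, 0.1}, mean fixed at 0, clipped to [0, 1] after
addition, seeded via `numpy.random.default_rng`.

The benchmark harness pairs each rule with its conventional selection:
classical rules use the universal threshold, the improved rule the
level-dependent one (the pairing the improved rule was designed around);
a `noisy` pseudo-rule (δ forced to 0, i.e. identity) provides the
baseline. Each (variance, seed) cell draws its own independent RNG stream
so grid cells cannot leak state; 10 seeds and a 256×256 phantom keep the
full default grid under a few seconds on one core.

## Known limitations

Single-channel 2-D images only; decimated DWT (no cycle spinning), no
SURE/BayesShrink selection, no Poisson/Rician noise models. The improved
rule's sub-threshold noise retention (above) is inherent to its printed
form, not an implementation choice.
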