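# Methods

This note records the model, the estimators, the numerical choices and the
limitations of `beeflight` — in particular the places where the design was
genuinely open and a decision had to be made.

## Model and reduction

The planar flight is described by speed `v(t)` and heading `θ(t)` via two
coupled Langevin equations with deterministic drifts and stationary,
possibly correlated, noise terms. At the fixed sampling interval `Δt` the
turning angle is `φ_n = wrap(θ_{n+1} − θ_n)`. Estimating the drift vector
field over the `(φ, v)` state space shows (i) an angle drift that is linear
in `φ` with slope `−1/Δt` — i.e. the angle decays completely within one
observation step — and (ii) weak cross-dependencies. Both justify the
reduced model the simulator implements:

    φ_n   = wrap(σ_φ(v_n) · g_n),                 g: unit-SD Gaussian, ACF C_g
    v_n+1 = max(0, v_n + h_v(v_n) Δt + ξ_n),      ξ: SD σ_ξ (m/s per step), ACF C_ξ

Noise units: `ξ` is a **per-step speed increment**, matching the residual
definition `ξ_n = (v_{n+1} − v_n) − h_v(v_n)Δt` used in estimation. Keeping
estimation and simulation in the same discretization avoids any `√Δt`
bookkeeping between the two halves of the pipeline. The position update uses
the pre-step heading and speed (explicit Euler), which makes
`derive_kinematics(simulate(...))` a strict round trip.

## Default configuration

The defaults define the study conditions of every test; they were chosen
once, from the qualitative structure the method targets, and are not tuned:

| quantity | default | unit | rationale |
|---|---|---|---|
| `Δt` | 0.02 | s | 50 Hz-class tracking |
| `v*` (fixed point) | 0.27 | m/s | drift zero of the two-piece fit |
| drift rates below/above `v*` | 5.0 / 1.0 | 1/s | restoring force stronger below the preferred speed (a slow bee accelerates briskly; a fast one keeps its momentum) |
| third piece above | 0.55 m/s, rate 4.0 | m/s, 1/s | steeper deceleration in the rare high-speed regime |
| `σ_φ(v)` | `0.7·e^{−v/0.15} + 0.35` | rad | decays with speed to a positive offset |
| angle-noise ACF | white | — | see "Angle-noise correlation" below |
| `σ_ξ` | 0.025 | m/s/step | puts the stationary speed SD near 0.1 m/s, speeds in 0–0.8 m/s |
| speed-noise ACF | `1.1·e^{−τ/0.01} − 0.1·e^{−τ/0.06}` | τ in s | anti-correlated dip of ≈ −0.04 at lags 2–4 while keeping the PSD nonnegative (S(0) > 0), so the spectral generator reproduces it without clipping |
| camera resolution `δ` | 1.5 | mm | mm-scale video tracking |
| gap model | rate 0.002/step, lengths 1–4 | — | plausible stand-in; real gap statistics are unpublished |

With these settings the non-negativity clamp fires on far less than 1% of
steps, speeds occupy 0–0.8 m/s with ~1% of samples above 0.55 m/s (enough to
resolve the third drift piece at 10⁶ steps), and the turning-angle SD stays
well below the wrapping scale so linear SDs of wrapped angles are unbiased
in practice.

**Angle-noise correlation.** The simulator fully supports correlated angle
noise (e.g. the steep power-law family `(1+τ/Δt)^{−κ}`), and the pipeline
detects and fits it. The *default* generator nevertheless draws turning
angles i.i.d. conditional on speed, for a structural reason: any lag-1
angle-noise correlation `ρ(1)` shifts the one-step-decay diagnostic
`slope·Δt` from −1 to `ρ(1) − 1`. A generator with appreciably correlated
angle noise therefore cannot exhibit the exact one-step decay that the
reduction (and its acceptance check) rests on. Since the fast noise
correlations are ignorable for all but the shortest-time dynamics, white
angle noise is the consistent default; correlated variants are exercised in
the tests with `κ = 3`.

## Estimators

**Drift field.** Binned conditional means of the one-step increments
`((φ_{n+1}−φ_n)/Δt, (v_{n+1}−v_n)/Δt)` given `(φ_n, v_n)`, on 40 equal
`φ`-bins over `(−π, π]` × 0.02 m/s speed bins over [0, 0.8]; bins with fewer
than 50 samples are marked missing. Two deliberate details:

* The `φ`-increment is the plain difference of the wrapped angles, not a
  re-wrapped difference. The turning angle is a bounded variable; wrapping
  the increment itself maps, e.g., a jump from −3 rad to +3 rad onto a small
  step and thereby biases the conditional mean toward zero — measurably
  (slope·Δt ≈ −0.99 instead of −1.00 with wide angle distributions).
* Regressions use the per-bin **mean state**, not the geometric bin center.
  With a concentrated state distribution the in-bin mass leans toward the
  mode; against bin centers this attenuates fitted slopes by `w²/(12σ²)`
  (≈1% at the default binning), which is ten standard errors at 10⁶ steps.

**Piecewise-linear drift fit.** Continuous piecewise linear WLS (weights
1/SE²) with 1 or 2 knots grid-searched over interior bin locations, ties
broken toward the lower knot; `v*` is the downward zero crossing. Knot
locations are invariant under adding any globally linear term — which is
what makes the changepoint recovery robust to the two bias corrections
below, and to the biases they remove.

**Finite-correlation-time (Markov) bias.** With correlated noise the state
`v_n` and the upcoming noise `ξ_n` are correlated, so the conditional-moment
estimator picks up a spurious slope `Cov(ξ,v)/Var(v)/Δt` with
`Cov = σ_ξ² Σ_j a^j ρ(j+1)` and `a = 1 + h'Δt` the one-step relaxation
factor. For the default anti-correlated noise this is a ~20% relative slope
bias — the Markov approximation is genuinely violated. `fit_full_model`
subtracts the implied continuous piecewise-linear term (per-piece `a_i`,
anchored at the mean speed, same knots) using the *fitted* noise ACF, and
iterates drift → residuals → ACF → corrected drift twice. Residual slope
error after correction is a few percent.

**Quantization corrections.** Rounding positions to the camera grid `δ`
adds per-axis uniform errors of variance `δ²/12`. Derived consequences (all
verified against direct simulation to ~1%):

* variance added to a single speed: `δ²/(6Δt²)`;
* variance added to the residual increment (three positions, shared middle
  error, drift evaluated at the measured speed):
  `[(4 + 2c̄) + 2h'Δt(2 + c̄)]·δ²/(12Δt²)` with `c̄ = E[cos φ]`;
* spurious drift slope from the shared error:
  `−(2 + c̄)δ²/(12Δt²)/Var(v̂)` per step — at `δ = 1.5 mm`, `Δt = 0.02 s`
  this is of the same order as the true drift, so it **must** be removed
  before fitting (`quantization_bias_correction`);
* the quantization error in the residuals is correlated only at lags 1–2,
  so on camera data those lags are excluded from the ACF fit (the analogue
  of the familiar lag-1 discretization artifact) and the remaining ACF is
  rescaled from the observed to the corrected variance.

Known residual limitation: the measurement error also attenuates fitted
drift slopes by ≈ `Var(u)/Var(v̂)` (~12% at the default camera settings) and
smears the changepoints by the speed-error SD (~0.03 m/s); neither is
corrected. Clean-data recovery tolerances therefore do not transfer to
slopes estimated from quantized data, while the fixed point and the
corrected noise variance do.

**σ_φ(v).** Linear SD of the wrapped angles per speed bin (the per-speed
distributions are concentrated; full circular statistics would change the
third decimal), with χ²-based 95% CIs, fitted by weighted nonlinear least
squares to the shifted-exponential or shifted-power-law family (the latter
floored at the first bin center as `v → 0`).

**ACFs.** Biased-normalization sample ACF (divide by total N and lag-0
autocovariance), pooled over gap-free segments with the global mean and
never a product across a segment boundary; Bartlett large-lag SE
`sqrt((1 + 2Σ_{j<k} r_j²)/N)`. Parametric families are fitted by WLS with
weights 1/SE²; the power-law families use the 1-shifted form
`(1 + τ/Δt)^{−κ}` so lag 0 is finite. A constant (zero-variance) input
yields the degenerate white ACF with a warning. The angle noise is
classified as white unless some lag in 1–10 exceeds 3 SE (a 2-SE rule fires
on white noise about once per 20 lags).

**Colored-noise synthesis.** ACF → circularly symmetrized sequence → real
DFT → clip negatives (counted) → shape white Gaussian noise → inverse DFT.
Twice the requested length is generated and the first half kept, which
suppresses the wrap-around correlation of the circular embedding; the
output is re-standardized to exactly mean 0 and the requested SD because
clipping and truncation perturb the variance. The default speed-noise ACF
is nonnegative definite at the lengths used (zero clipped bins), so the
realized ACF matches the target within sampling error.

**Geometric null model.** The projected-normal angle density (direction of
`(R + a_x, a_y)`, `R` = speed / per-axis acceleration SD) is implemented
with the numerically stable form
`p(φ) = e^{−R²/2}/2π + q·Φ(q)·e^{−(R sin φ)²/2}/√(2π)`, `q = R cos φ`, and
is certified in the tests against a brute-force Monte-Carlo sampler — the
comparison uses bin-averaged densities, because at 10⁷ draws the MC error
is small enough to resolve within-bin curvature. Its SD decays like `1/R`,
i.e. to zero: observed σ_φ offsets `c > 0` are incompatible with
speed-independent accelerations.

## Gap and zone handling

Short tracking gaps (≤ 2 samples by default) are linearly interpolated;
observed samples are never modified; boundary gaps are truncated. Samples
inside exclusion zones are removed outright and never interpolated (they
were observed, just unwanted), so a zone crossing always splits a
trajectory. Any remaining un-interpolatable gap also splits, since a
fixed-rate segment cannot carry a hole; the nominal split threshold
(`min_split`, default 5) is retained in the configuration but intermediate
gap lengths break segments too. Segments shorter than 3 samples are
dropped. Zero-displacement steps (possible after quantization) carry the
previous heading, set `φ = 0`, and are flagged; flagged steps are excluded
from all estimation.

## Validation metrics

`validate_model` quantifies what is otherwise a visual comparison: the
two-sample KS distance between speed samples, and for each ACF the fraction
of lags (1–50) where the simulated and reference curves differ by more than
twice their combined large-lag SE. The conventional thresholds used in the
tests (KS < 0.05, excess < 0.1) are package conventions. Because the speed
series decorrelates over ~50 steps, the effective sample size is N/100;
meaningful KS comparisons need several 10⁵ steps per side, which is what
the self-validation test uses.

## Problem sizes

Changepoint recovery runs at 5×10⁵ (two-piece) and 1–1.5×10⁶ steps
(three-piece: the upper knot sits in the ~1% occupancy tail); full parameter
recovery at 10⁶ steps split over 20 trajectories; the Monte-Carlo oracle at
10⁷ draws per speed ratio. These sizes resolve every fitted feature at the
stated tolerances while keeping the whole suite in the minutes range.

## What the synthetic data does and does not establish

The generator reproduces the *statistical* structure the estimators assume:
fixed-rate sampling, piecewise-linear drift with a preferred speed,
speed-dependent wrapped-normal angle noise, short-range anti-correlated
speed noise, camera quantization, tracking gaps and zone exclusions. Passing
recovery tests therefore establishes the estimation pipeline's correctness
and its robustness to those observation artifacts. It does not establish
that real flights follow this model — arena-boundary effects, flight-mode
intermittency, 3D motion and inter-individual variability are all outside
the generator (and the model). Gap statistics are a plausible stand-in, not
measured values.
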