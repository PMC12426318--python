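# Methods

## The problem

Personal light exposure, measured as melanopic EDI in lux by wearable
loggers, is analyzed on a logarithmic scale: physiological responses are
roughly log-linear in illuminance, and a single day spans zero to more
than 10⁵ lux.  Sensors have a detection floor (typically about 1 lux);
any darker sample is recorded as exactly 0 lux.  The result is a
zero-inflated, heavy-tailed, strongly diurnal time series in which the
zeros are informative (true darkness) but have no logarithm.  The
package addresses the two places this bites: putting the data on an
axis, and fitting a model to it.

## Symlog and related transforms

`scales.symlog_forward` maps lux (or lux differences) through a map that
is linear on `[-T, T]` and base-`b` logarithmic outside.  Two modes:

- **continuous** (default): `f(x) = L·x/T` inside the band and
  `sign(x)·(L + log_b(|x|/T))` outside.  Continuous, odd, strictly
  increasing, `C⁰` everywhere; invertible in closed form
  (`symlog_inverse`, verified to 1e-12 relative error over twelve
  decades).  This is the convention of established plotting libraries
  and the default for every figure.
- **literal**: identity inside the band, `sign(x)·log_b|x|` outside.
  This textbook piecewise form is discontinuous at `|x| = T` (for
  `T = 1, b = 10` it jumps from 1 to 0) and non-injective: the log
  branch maps `(1, 10]` into `(0, 1]`, which the linear branch also
  covers.  It is kept for fidelity checks; inversion inside the
  ambiguous band `|y| ≤ max(T, |log_b T|)` raises instead of guessing.

Defaults `T = 1` lux, `b = 10`, `L = 1`: one transformed unit per decade
above 1 lux, with everything below 1 lux (including 0) compressed into
one unit.  Values exactly at `±T` take the linear branch.

`pseudo_log(x, σ, b) = asinh(x/2σ)/ln b` is the smooth alternative; its
offset from `log_b x` converges to a constant for large `x`, but the
lack of a sharp linear/log boundary makes the applied scaling harder to
read off, which is why symlog is the default.

Tick construction (`symlog_ticks`) places 0 and the signed decades
`±b^k ≥ T` inside the data range, falling back to linear ticks for
sub-decade ranges.

## Zero treatments

Four strategies make zero-inflated lux series log-modelable
(`scales.ZeroTreatment`):

1. `drop_zeros` — zeros become missing.  Distinct states: missing ≠ 0
   throughout the package, since this treatment is the only thing that
   converts one into the other.
2. `add_epsilon` — add the IEEE-754 double machine epsilon
   (`machine_epsilon()`, defined operationally by `1 + ε ≠ 1`,
   `1 + ε/2 = 1`; ≈ 2.220446e-16).  The runtime value is used, never a
   hard-coded constant.
3. `add_constant` — add 0.1 lux by default, i.e. one decade below a
   1-lux detection floor (−1 log₁₀ lux against the floor's 0 log₁₀).
4. `none` — leave the data alone, for families with their own zero
   mass.

`back_adjust_predictions` inverts the additive treatments after
modeling: `10^pred − offset`, clamped at 0 lux.  The composition
back-adjust ∘ log10 ∘ treat is the identity on positive lux.

## Compound Poisson–Gamma (Tweedie) layer

For power `1 < p < 2` the Tweedie law with mean `μ` and dispersion `φ`
(variance `φμ^p`) equals the compound sum `Σ_{i≤N} G_i`,
`N ~ Poisson(λ)`, `G_i ~ Gamma(α, γ)` with

    λ = μ^(2−p) / (φ(2−p)),   α = (2−p)/(p−1),   γ = φ(p−1)μ^(p−1).

`tweedie.rvs` samples by drawing `N` and then the Gamma sum directly
(`N = 0` gives exactly 0); `p = 1, φ` scales a Poisson, `p = 2` is the
Gamma special case.  The density for `y > 0` is the series over the
Poisson index,

    f(y) = Σ_{j≥1} e^{−λ} λ^j / j! · GammaPDF(y; jα, γ),

evaluated in log space around the dominant index
`j* ≈ y^(2−p)/(φ(2−p))`: a window around `j*` is summed (points of
similar `j*` are chunked together for vectorization) and widened until
the edge terms fall below 1e-12 of the peak, with a hard cap of 2·10⁵
indices that raises rather than silently truncating.  The point mass at
zero is `exp(−λ)`.  Tests verify normalization to 1e-6 by quadrature
across a `(p, μ, φ)` grid, agreement with the Poisson/Gamma boundary
laws to 1e-10, agreement with a 10⁶-draw histogram, and agreement with
mgcv's independent `ldTweedie` implementation.

**Power/dispersion estimation** (`profile_power`): over a grid of `p`
(default 1.01–1.99, step 0.01), the mean is the sample mean (the MLE of
a log-link intercept for any Tweedie power), the dispersion is the
Pearson moment estimate `Σ(y−μ̂)²/μ̂^p / (n − edf)`, and the exact series
log-likelihood is recorded; the grid maximizer is returned.  How the
dispersion is estimated at each grid point is a genuine design choice —
a full inner MLE over `φ` is the main alternative — and the Pearson
statistic was chosen for robustness and interpretability (it is the
conventional overdispersion diagnostic).  On week-sized samples
(n = 2016) at `(p = 1.73, φ = 1.5)` the profile recovers `p` within
±0.1 and `φ` within ±20% (tested over seeds).

## Cyclic-spline additive model

`gam.fit` fits `g(E[y]) = β₀ + group + s(time-of-day, by=group)`.

**Basis.**  The cyclic cubic regression spline with `k` equally spaced
knots on `[0, period)` (defaults `k = 24`, period 86400 s) is
parameterized by the spline's values at the knots; the cyclic
tridiagonal natural-spline system links knot values to knot second
derivatives, making the curve and its first two derivatives periodic by
construction (verified to 1e-10).  The penalty is the integrated squared
second derivative `S = Dᵀ B⁻¹ D` — symmetric, PSD, null space exactly
the constants.  Basis rows sum to 1 for every `t` (the construction
interpolates).

**Identifiability.**  Each per-group smooth is constrained to sum to
zero over that group's observed rows (reparameterized through the null
space of the column-sum vector), so group main effects carry the level
differences.

**Smoothing selection.**  GCV (`n·RSS/(n−edf)²`, deviance in place of
RSS for Tweedie) over a 31-point log-spaced λ grid from 1e-4 to 1e6,
coordinate-wise across smooths until stable.  Penalties are
Frobenius-normalized so the grid brackets the optimum regardless of the
period's units.  REML-style selection (as mgcv defaults to) was the
alternative; GCV was chosen for transparency and testability (grid
optimality is asserted directly).  Exact numerical equivalence with
mgcv is a non-goal, but on shared fixtures the fitted curves agree to a
few percent of the response SD.

**Families.**  `gaussian` (identity), `gaussian_log10` (log10 of the
treated lux), `tweedie` (log link on raw lux).  The Tweedie fit uses
penalized IRLS with working weights `μ^(2−p)` and step-halving;
iteration stops when the relative penalized-deviance change falls below
1e-8, or when no descent step remains (the optimum to working
precision).  λ is selected once at `p = 1.5`, then the power is profiled
with λ held fixed: a coarse 1.1–1.9 (step 0.1) pass followed by a ±0.09
refinement at step 0.02, each grid point scored by the exact series
log-likelihood at its Pearson `φ̂`.  The two-stage grid keeps a full
week's fit under a second without changing the optimum found by the
flat fine grid on test data.

**AR1 correction** (Gaussian families only — the generalized Tweedie
family lacks a tractable whitening working model, so model 4 carries
its residual autocorrelation, as its diagnostics note): `ρ` is the
lag-1 autocorrelation of the unwhitened fit's residuals; one
whitening-refit pass transforms rows `(yₜ − ρyₜ₋₁, Xₜ − ρXₜ₋₁)` with the
first row of each contiguous run scaled by `√(1−ρ²)`, restarting at
group changes and sampling gaps.  Whitening with the true `ρ` on
AR1-simulated data restores |lag-1 autocorrelation| < 0.05.

**Diagnostics.**  `r2_adjusted = 1 − [RSS/(n−edf)]/[TSS/(n−1)]` on the
model's own response scale; `scaled_pearson_residuals =
(y−μ̂)/√(φ̂V(μ̂))` with `V = 1` (Gaussian) or `μ^p` (Tweedie).  Adjusted
R² values are reported side by side across families but flagged
non-commensurable: models 1–3 are scored on transformed (and for model
1, pruned) data, model 4 on raw lux.

## Four-model harness

`harness.compare_models` runs the fixed treatment/family/AR1
combinations of the table in the README on one shared series and time
grid.  Transition windows are ±60 min (a documented parameter; the
width is not canonical) around every boundary between a zero run and a
positive run, merged when overlapping.  Per model it records the
overall and transition-window maxima of |scaled Pearson residual|, the
maximum back-adjusted fitted lux inside the windows, and an *overshoot*
flag: fitted lux in the windows exceeding the maximum lux observed
anywhere in the series — the signature artifact of the machine-epsilon
treatment, whose spline must traverse ~15 log units at every dawn and
dusk.  Model 1's predictions over zero-run clock times are flagged
extrapolated, since the model saw no data there.  A model failure is
recorded as a failed table row, not an exception.

## Synthetic data

`simulate.SimConfig` defines the study conditions the generator
emulates: one week at 5-min sampling (n = 2016 per source), civil dawn
06:00 and dusk 20:00, environment daylight as a powered half-sine
(`peak · sin^1.5`) peaking at 10^4.5 lux, a 250-lux indoor plateau, 30%
outdoor attenuation at the wearable, multiplicative lognormal noise of
0.2 decades, and a 1-lux detection floor that records sub-threshold
light as exactly 0.  The participant follows a behavioral schedule
(sleep 23:00–07:00, indoor office blocks, three half-hour outdoor
commutes, one half-hour dark indoor episode so daytime zeros occur).
Defaults are fixed once as a plausible temperate-latitude late-spring
scenario; dawn/dusk are inputs, not computed from solar geometry.

What the generator does *not* emulate: weather and cloud dynamics,
spectral composition, device-specific noise floors above 1 lux,
multi-subject variability, and real behavioral irregularity.  Passing
tests therefore demonstrate that the methods behave as claimed on data
with the right distributional shape (diurnal cycle, log-scale noise,
floor-censored zeros, heavy daytime tail), not that any particular
field dataset will reproduce specific diagnostic values.

`simulate_tweedie_series` draws independent CPG noise around an
arbitrary smooth positive mean curve (`diurnal_mu`: raised-cosine in
log10 from 5 lux at night to 500 lux at midday) for parameter-recovery
studies.

## Numerical choices and degenerate inputs

- Penalized solves add a 1e-10 relative ridge before Cholesky.
- Linear predictors are clipped at ±30 before exponentiation in the
  Tweedie IRLS.
- `estimate_ar1` requires ≥3 residuals and non-degenerate variance, and
  clips to (−0.999, 0.999).
- All-zero responses: the Tweedie profile raises (mean not
  identifiable); `gaussian_log10` raises on non-positive responses and
  directs to a zero treatment.
- Empty day/night subsets warn (splitting) or render annotated empty
  panels (histograms) rather than failing.
- Samplers take explicit integer seeds or Generators; every stochastic
  routine in the package is reproducible under its seed.

## Problem sizes

Tests and the acceptance script run at the study-condition sizes: 10⁵
draws for sampler calibration (10⁶ for the histogram cross-check),
n = 2016 per source for one synthetic week, five seeds for the recovery
study.  The full suite completes in about a minute; the acceptance
script in about ten seconds.

## Known limitations

- Smoothing selection is GCV, not REML; fits agree with mgcv closely
  but not digit for digit.
- The Tweedie power grid resolution is 0.02 inside the fit (0.01 in the
  i.i.d. profile); uncertainty in `p̂` is not quantified.
- AR1 correction is a single estimate-whiten-refit pass, not an
  iterated or jointly estimated covariance model.
- No confidence bands on smooths; diagnostics are point summaries.
- Timestamps are timezone-naive local wall-clock times; DST transitions
  and multi-day/multi-subject decompositions are out of scope.
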