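# Methods

This note records the models, conventions and numerical choices behind
`hiverhythm`, in enough detail to reproduce or audit any stage.

## Data model

A series is one hive's temperature (°C) or CO₂ concentration (%) on a
regular grid of 5, 15 or 30 minutes, timezone-naive local clock time.
Missing stretches are kept *on* the grid as NaN points flagged `gap`; an
isolated single missing sample is filled by linear interpolation and flagged
`interpolated` (longer holes are never filled). Keeping the grid uniform
lets the classical periodogram and cosinor assume even sampling, while the
Lomb–Scargle stage simply drops gap points. All fitting operates on
contiguous 72 h windows ("3-d subsets"); light-regime comparisons pool two
consecutive subsets per hive into 6-day "intervals".

## Detrending

Residuals are raw values minus a **centered** running average spanning 48 h,
`48·60/Δt + 1` samples (odd by construction, e.g. 97 at 30-min sampling).
Rationale for centering: a trailing average lags trends and would rotate
every acrophase, and phase is the analysis endpoint. The window passes
linear trends exactly (residual 0) and attenuates a sinusoid of period P by
the closed-form factor

    1 − sin(n·ωΔt/2) / (n·sin(ωΔt/2)),   ω = 2π/P,

exposed as `ma_attenuation` and asserted against measurement in the tests.
Two consequences worth knowing:

- because the odd window covers two full 24 h cycles *plus one repeated
  endpoint*, a 24 h sinusoid leaves a residual running mean of order 1/n
  (~1 % of amplitude at 30-min sampling) rather than exactly zero;
- windows that reach past the data are invalid — the first and last 24 h
  are trimmed, not renormalized — and windows covering a gap produce
  invalid positions rather than partial averages, avoiding silent bias.

The 24 h of edge trim is why every scenario generator pads its schedule
with one day of ambient data on each side: the detrended series then covers
the full experimental span.

## Classical periodogram and rhythm strength

For a gap-free subset of N mean-removed values, ordinates are computed at
the Fourier frequencies j/(N·Δt), j = 1..⌊N/2⌋, scaled so that their sum
equals the corrected sum of squares (N−1)·s² (interior ordinates carry
weight 2|Xⱼ|²/N; for even N the Nyquist ordinate enters once with weight
|Xⱼ|²/N). Dividing by the total gives the **proportion of sums of
squares** per frequency, which sums to one for every nondegenerate subset
and is invariant under rescaling of the measurement units. The Parseval
identity is asserted in tests rather than trusted, and the whole transform
is checked against a quadratic-time DFT oracle to 1e-9 relative. Strength
tables are conventionally restricted to periods ≥ 8 h; a 72 h window's grid
contains 72, 36, 24, 18, … h, so the 24 h ordinate is the third Fourier
frequency. Requesting an off-grid period (e.g. 48 h) is an error naming the
nearest grid periods, not a silent interpolation. Constant subsets raise a
degenerate-variance error.

## Lomb–Scargle period estimation

Free-running periods are estimated on ≥ 3-day raw spans with the normalized
Lomb–Scargle periodogram (scipy's implementation), on a frequency grid of
integer multiples of 1/(T·oversample) restricted to periods between 2 and
30 h. Aligning the grid with (oversampled) Fourier multiples makes the
evenly-sampled case probe its exact Fourier frequencies. The default
oversampling is 4× (spectral resolution ≈ 1.1 h at a 25 h period for 6-day
spans); the pipeline uses 12× (≈ 0.36 h) since reported mean periods carry
standard errors of a few tenths of an hour. The peak period is the argmax
of the power with exact ties broken toward the longer period; no quadratic
interpolation is applied. Per-hive normalized powers are averaged pointwise
with standard errors sd/√n, and peak periods are summarized as mean ± SE.
At least 32 valid points are required.

## Cosinor

The model `y = M + A·cos(2πt/τ + φ)` is linearized onto
`[1, cos(ωt), sin(ωt)]` and solved by least squares, with t in hours from
**local midnight of the subset's first calendar day** — a common angular
reference so acrophases from different hives and subsets are comparable.
With β on the cosine and γ on the sine regressor, A = √(β²+γ²) and the
quadrant-correct acrophase is atan2(−γ, β), mapped into (−2π, 0]; the peak
occurs −φ·τ/2π hours after midnight. Rhythm presence is tested by the
zero-amplitude F statistic ((RSS₀−RSS)/2)/(RSS/(n−3)) with df (2, n−3),
RSS₀ from the intercept-only fit; its type-I error is verified at α = 0.05
over 1000 null replicates. Flat subsets return a flagged degenerate
zero-amplitude fit instead of raising, so batch runs survive dead sensors.

Per-subset "daylength" is the trial period maximizing R² over a grid
(default 16–32 h in 0.05 h steps, clipped to (span/3, span)); ties go to
the smaller period. Grid search was chosen over nonlinear optimization
because the objective is cheap, the grid resolution (0.05 h = 3 min)
exceeds the precision at which 3-day periods are interpretable, and the
result is deterministic.

## Circular statistics

Acrophases are wrapped into [0, 2π) and pooled per interval (two subsets ×
all hives; 16 hives give n = 32 per group).

- **von Mises fit**: μ = atan2(ΣsinΘ, ΣcosΘ); κ from the standard
  three-branch inversion of the mean resultant length R̄ (series
  approximation below 0.53, rational approximation to 0.85, reciprocal
  form above). κ is capped at 1e6 for degenerate samples; R̄ = 0 yields
  κ = 0 with undefined μ.
- **Watson U² goodness of fit** uses the probability integral transform
  under the fitted (μ̂, κ̂). Because both parameters are estimated, the
  null distribution is approximated by a seeded parametric bootstrap that
  refits every replicate (default 1000); the categorical p-range
  (">0.1" … "<0.001") is the bin the bootstrap p falls in. The bootstrap
  is vectorized and its α = 0.05 rejection rate is verified on von Mises
  data.
- **Watson two-sample U²** is computed from the pooled empirical CDFs,
  `U² = (n₁n₂/N²)·(Σd² − (Σd)²/N)` with d the running CDF difference, and
  compared to the asymptotic critical values 0.152 / 0.187 / 0.268 / 0.385
  for p = 0.1 / 0.05 / 0.01 / 0.001. An optional label-shuffling
  permutation p (seeded) serves as the exact companion; tests require the
  table range and a 10 000-permutation p to agree up to one bin boundary,
  which is the honest statement of how far the asymptotic table can be
  trusted at n₁ = n₂ ≈ 16–32. Combined samples under 17 trigger no error
  but the table is unreliable there.
- **Circular median**: the sample angle minimizing the mean circular
  absolute deviation; ties break toward the smaller circular MAD (median
  distance to the candidate), then the smaller angle. The reported spread
  is the median circular distance to the median. The smaller-angle
  tie-break is deliberately deterministic and therefore not
  rotation-equivariant in exact ties; generic samples are equivariant, as
  the property tests check.
- **Rose bins**: half-open bins [k·2π/n, (k+1)·2π/n), boundary angles to
  the higher bin; 24 bins = 1 clock hour each.
- **Clock conversion**: a nonnegative angular difference δ maps to
  δ·τ/2π decimal hours; minutes are **truncated** (floor), not rounded —
  truncation reproduces all four published-style conversions
  (2.518 → 9 h 37, 3.395 → 12 h 58, 4.157 → 15 h 52, 3.123 → 11 h 55)
  whereas rounding does not. A 1e-9 rounding shield protects floor() from
  float dust. Negative inputs are an error: callers map differences into
  [0, 2π) first, matching the convention of reporting phase changes as
  positive numbers.
- **Phase contrast** between groups is the circular difference of mean
  directions mod 2π (medians are computable but mean directions match the
  von Mises/Watson framing).

## Group comparisons

Rhythm-strength contrasts are paired two-tailed Wilcoxon signed-rank tests
on per-hive 24 h proportions across subset pairs, grouped into families
(variable × site) whose size m is the Bonferroni divisor. Zero differences
are dropped before ranking (the classic convention); tied absolute
differences get average ranks. For n ≤ 25 the exact sign-flip null is
enumerated by convolution on a half-integer rank lattice — valid in the
presence of ties, where closed-form tables are not — and the two-sided p is
2·min(tail probabilities) capped at 1; scipy's exact method is the oracle
in tie-free cases and its continuity-corrected normal approximation is used
above n = 25. Pairs with fewer than 3 nonzero differences are reported as
skipped with a reason. Periods are compared by tie-corrected
Kruskal–Wallis with a χ² p on (groups − 1) df.

## Synthetic generator

The generator is phenomenological: no clustering, metabolic-heat or gas
exchange physics. Each hive × variable series is

    y(t) = mesor + slope·t + AR1(t) + A(t)·cos(2πt/24 + φ(t))
           + a₁ₕ·cos(2πt/1h)·[in CSU] + ε(t),

with iid Gaussian ε and a stationary AR(1) wander as the slow trend. All
rhythm dynamics live in the phase offset φ(t) of a fixed 24 h carrier:

- **darkness**: φ drifts linearly at 2π(24/τ_free − 1) rad/day, which makes
  the signal an exact cosine at the free-running period τ_free;
- **12L:12D**: the clock keeps free-running for a lag (default 2 d), then
  the wrapped offset from the light-defined target phase decays
  exponentially at `entrain_rate_per_day` (default 1/d);
- **ambient**: same relaxation toward the ambient-entrained phase with no
  lag.

The light target sits π radians from the ambient mean phase, matching a
lighting schedule ~12 h out of phase with the ambient day. Amplitude steps
down by `amplitude_decay` at each 3-d block boundary while in cold storage
(temperature default 0.96/block; CO₂ 1.0, i.e. stable) and is restored
outside. The 1 h artifact emulates the hourly ventilation cycle of the
storage room.

Scenario presets encode the four experiment designs (fall CSU, fall
outside, summer CSU, winter CSU) with their hive counts, sampling
intervals and schedules; the winter schedule is 12 d dark + 33 d light +
12 d ambient at 5-min sampling for 16 hives. Defaults chosen where the
designs leave them open: in-CSU hive temperature mesor 20 °C with ±1.5 °C
daily amplitude and 0.25 °C noise; CO₂ mesor 1.5 % with ±0.5 % amplitude;
ambient-entrained peaks at ~15:00 (temperature) and ~03:00 (CO₂);
free-running periods 25.4 h (temperature) and 27.5 h (CO₂) with 0.8 h
between-hive jitter; inter-hive phase dispersion κ = 8 (circular sd ≈ 1.4 h)
— κ is a free parameter of the presets, since no measured value exists.
Randomness uses one seed per scenario with per-hive substreams (seed + hive
index). Truth tables record, per 3-d block, the carrier phase and drift at
block midpoint, the implied instantaneous period, amplitude and regime.

**What the generator does not emulate** — and what passing tests therefore
do not demonstrate about field data: weather-driven ambient covariates,
sensor calibration drift and discretization, brood dynamics and colony-size
differences, non-sinusoidal waveforms (real hive CO₂ is notably peaky),
hive death or sensor dropout patterns, and any coupling between temperature
and CO₂ within a hive.

## Recovery semantics and known limitations

- Noiseless end-to-end recovery is exact (≪ 0.01 rad) for blocks whose
  dynamics are stationary across the block *and* its two neighbours;
  the 48 h detrending window reaches 24 h into adjacent blocks, so a
  regime switch or an amplitude step next door biases a block's fitted
  acrophase by up to ~0.02 rad. Transition blocks mix free-run and
  relaxation inside one window and have no single programmed phase or
  period; recovery tests treat dark blocks as period checks, stationary
  blocks as phase checks, and skip the transitions.
- The asymptotic two-sample Watson table is used at n as low as 16+16,
  where its bins can disagree with a permutation p near bin boundaries.
- Bootstrap and permutation p-values are seeded and reproducible; their
  resolution is 1/(replicates+1).
- Test and example problem sizes (3–8 hives, 15/30-min sampling) are
  deliberate scalings of the native designs (16 hives at 5 min); the
  acceptance script runs the winter pipeline at native scale.
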