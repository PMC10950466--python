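# Methods

This note records the models, defaults and numerical choices behind each
pipeline stage, what the synthetic-flight generator does and does not
emulate, and the known limitations.

## Wingbeat detection

The detector works on the heave (dorsoventral) acceleration axis, which
oscillates once per wingbeat.  Steps, with defaults:

1. Orientation correction (optional): over a user-chosen level-flight
   window of at least 2 s, the mean acceleration vector is rotated onto
   (0, 0, 1) g via a Rodrigues rotation applied to all samples.  Rotations
   preserve per-sample norms, so dynamic acceleration is untouched.
2. Smooth the raw heave with a centred 20-sample moving average (0.1 s at
   200 Hz), truncated at the edges.  A 20-sample average has spectral nulls
   at multiples of 10 Hz, so typical high-frequency tag noise is strongly
   attenuated while a 5–8 Hz flapping fundamental passes.
3. Differentiate with a centred difference spanning 20 samples
   (`x[i+10] − x[i−10]`): symmetric, hence phase-neutral.  A trailing
   difference would shift all peak times by a constant without changing
   per-beat periods; centred is kept for interpretability of peak times.
4. Candidate peaks are positive-to-negative transitions of the
   differential.  A candidate survives if the raw peak-to-trough excursion
   of its cycle (candidate to next candidate) reaches `min_prominence_g`
   (default 0.5 g; with `None`, an automatic 0.25 × median candidate
   excursion stands in for the per-flight manual tuning practitioners do).
5. Peak times are refined to sub-sample precision with a parabola through
   the smoothed-signal maximum.  Without this, periods are quantized to the
   5 ms sampling interval, which adds ±0.06 Hz of spurious per-beat
   frequency jitter — comparable to the stroke-to-stroke variability the
   analysis measures, so the refinement matters for the SD responses, not
   just cosmetics.

Per-beat frequency is the reciprocal period to the previous peak (the first
peak of a series carries none and is excluded from segment means).
Amplitude is the raw peak-to-trough heave within the half-open cycle
between consecutive peaks — note this is a raw-signal excursion, so its
segment mean rises slightly with stroke-to-stroke variability even when the
underlying mean stroke is unchanged; this is a property of the measurement,
shared with field practice, and is visible in the synthetic benchmarks.

## Turbulence proxy and spectral fit

The per-segment proxy is the IQR of pressure fluctuations, defined as
residuals about a within-segment ordinary-least-squares linear trend.
Detrending is deliberate: without it a steady climb masquerades as
turbulence.  A `detrend=False` switch is kept for sensitivity analysis.
Quartiles use linear interpolation (NumPy default, R type 7) so values are
bit-reproducible.  Segments shorter than 10 s are rejected, mirroring the
segmentation rule.

The inertial-subrange fit estimates `A` in `S(f) = A·f^{−5/3}` from a Welch
periodogram (Hann window, 512-sample segments, 50% overlap) by least
squares in log–log space with the slope *fixed* at −5/3 — the power law is
imposed, only the constant is estimated — over a default band of 0.1–5 Hz.
The log-space residual SD is returned as a goodness measure (white noise
fits visibly worse than a true −5/3 signal of equal variance).

Boundary-layer scales: `w* = (g·z_i·Q_{0v}/θ_v)^{1/3}` (Deardorff scale,
g = 9.81 m s⁻², zero under non-positive heat flux) and `u* = √(|τ|/ρ)`.
Climatology comparisons use the pooled-variance two-sample t-test
(df = n₁ + n₂ − 2).

## Flight path

Altitude ASL uses the ISA hypsometric inversion
`h = (T₀/L)·[1 − (P/p₀)^{L·R_d/g}]` with T₀ = 288.15 K, L = 0.0065 K m⁻¹,
R_d = 287.053 J kg⁻¹ K⁻¹, g = 9.80665 m s⁻², applied to pressure smoothed
with a centred 2 s moving average and referenced to the release-site
sea-level pressure.  The simulator uses the exact forward map, so
round-trip error reflects only smoothing and sensor noise.  Climb rate is
the first difference of altitude resampled to a 1 Hz grid ("per second" is
taken literally).  AGL subtracts bilinear terrain elevation sampled under
GPS positions linearly interpolated to pressure timestamps.

Headings are great-circle bearings (tracks span kilometres; a planar
approximation was rejected); turning angles are wrapped heading differences
in (−180°, 180°], clockwise positive (the sign convention is arbitrary but
fixed — only the circular SD enters the analysis).  Circular SD is
`√(−2 ln R)` with R the mean resultant length; R below 1e−12 is flagged
degenerate and returns +inf.  Airspeed and headwind component come from the
wind triangle with wind interpolated linearly in time from hourly records
and held spatially constant per flight (reanalysis cells dwarf track
extent); the headwind projection uses the track-step (ground-velocity)
direction.

## Synthetic flights

The generator encodes the study conditions the pipeline assumes:

* Heave: per-beat sinusoid, `f_k ~ N(f₀ + (df/dT)·T, σ_f0 + γ_f·T)` and
  half-amplitude `A_k ~ N(A₀, σ_A0 + γ_A·T)`, truncated at 0.1× base.
  Defaults: f₀ = 6 Hz, A₀ = 2 g (pigeon-like flapping), σ₀ = 0.05,
  γ = 0.15 per unit T.  Stroke-to-stroke draws are per beat, not per
  sample, because the per-segment SD of per-beat quantities is the measured
  response.  An `amp_compensates` switch ties the mean amplitude to
  f₀·A₀/f(T) for the efficiency-preserving scenario (frequency down,
  amplitude up, product exactly constant).
* Altitude: mean level (default 480 m ASL over 400 m terrain ≈ 80 m AGL,
  matching a low cruising pigeon) plus optional constant climb and slow
  sinusoid, plus an exact-discretization Ornstein–Uhlenbeck displacement
  with relaxation time τ = 5 s and stationary SD 2·T metres.  OU is the
  simplest stationary process with tunable variance and correlation time;
  no particular gust spectrum is claimed for it.  Pressure is the exact ISA
  forward map plus 0.05 hPa sensor noise.
* Track: constant air velocity (19 m s⁻¹, near typical pigeon airspeed)
  along a fixed heading, plus wind (default 2, 1 m s⁻¹) and horizontal OU
  gust velocities with SD 0.5·T m s⁻¹, integrated on a local tangent plane
  around a release site at (8.97° E, 47.73° N).
* T is piecewise constant on the same 15 s grid the analysis uses, so
  ground truth aligns with pipeline segments by construction.  All
  randomness flows from one seed through named substreams.

`make_flight_set` emulates a release campaign: per-flight headings ±30°
around the base, small per-flight constant climb rates (±0.3 m s⁻¹), birds
rotating over the flights, and per-segment T drawn from a five-level ladder
{0, 0.5, 1, 2, 3}.

What the generator does **not** emulate: gliding/flap-bounce phases,
posture changes, GPS multipath and dropouts, pressure-sensor drift,
spatially varying wind, and any behavioural response of the bird to the
turbulence it experiences.  Passing tests therefore demonstrate that the
pipeline recovers known signal structure of this kind, not that field data
are free of those complications.

A separate spectral synthesizer produces Gaussian series with one-sided
spectrum `A·f^{−5/3}` by inverse-FFT shaping with random phases, used to
validate the spectral fit end to end.

## Segment table and effect models

Flights are segmented into consecutive 15 s windows from flight start; a
trailing window is kept only if ≥ 10 s.  Segment responses are computed
from samples in `[start, end)` only; rows with fewer than two wingbeats or
any undefined response are dropped with a logged reason.  Covariate means
(headwind, climb rate) use all in-window 1 Hz samples rather than midpoint
values — the midpoint alternative was considered and rejected as noisier.
Square-root transforms are applied to the turbulence proxy and mean AGL.

Each response sub-model is
`y = β₀ + Σ_j f_j(x_j) + b_flight + ε`, with cubic B-spline smooths
(k = 10 basis functions, knots equally spaced over the observed range,
basis columns centred for identifiability) and a per-flight random
intercept implemented as a ridge-penalized dummy block (the standard mixed-
model equivalence; the reported random-intercept variance is σ²/λ_re).
Turbulence and headwind enter every sub-model; climb rate and √AGL enter
the six kinematic/airspeed sub-models.

Each smooth carries a single penalty `λ_j (S̃ + 0.05·I)` where S̃ is the
second-order difference matrix normalized to unit spectral norm.  The
identity share means large λ_j shrinks the whole block to flat — null
effects vanish rather than defaulting to a free linear trend (shrinkage
smooths in the mgcv `select = TRUE` spirit).  Smoothing parameters minimize
GCV with the usual effective-dof inflation γ = 1.4 that guards against GCV
undersmoothing, by bounded Powell search over log λ ∈ [−6, 16]; a 1e−8
ridge floor keeps the normal equations well conditioned.  The fit is fully
deterministic.  An optional AR(1) pass estimates a lag-1 within-flight
residual autocorrelation, quasi-differences rows and refits (default off;
the segment-level autocorrelation in the synthetic benchmarks is
negligible).  A single multivariate fit with temporally/spatially
correlated errors would be the fuller treatment; the per-response
approximation was chosen because all reported quantities are per-response,
and the cross-check against mgcv's shrinkage-smooth GAM with a flight
random effect (in the test suite) shows matching partial-effect shapes and
magnitudes.

Responses can be Box–Cox transformed (profile-likelihood λ on a grid
[−2, 2] step 0.05, boundary hits warned); effects are then reported on the
transformed scale.  Effect sizes evaluate the centred partial effect of
√turbulence at the observed covariate minimum and maximum — observed, not
theoretical, extremes — divided by the observed response range, in percent.
The "effect at minimum" is the centred partial effect evaluated at the
minimum (not a difference from the mean); both readings are computable from
the returned partial-effect functions.

## Problem sizes and calibration

Synthetic benchmarks run at a deliberately scaled-down campaign size chosen
to keep the whole suite fast while preserving the statistical structure:
20 flights × 150 s (≈ 200 segments) for effect-recovery and
null-calibration runs, 10 flights for scenario checks, and 20 replicate
seeds wherever a seed-averaged quantity is reported.  Under the null
(all turbulence gains zero) single-replicate regression p-values are
uniform by construction, so null checks report medians over replicates
rather than single draws.

## Known limitations

* The turbulence proxy is qualitative: it ranks conditions, it is not an
  eddy-dissipation rate.  Its within-segment detrending removes only linear
  altitude trends.
* Penalized-spline extrapolation beyond the observed covariate range is
  clamped to the boundary knots; partial effects are only defined over the
  observed range.
* The wind-triangle airspeed inherits reanalysis wind error wholesale; no
  within-flight wind estimation is attempted.
* Terrain handling assumes a regular lon/lat grid in a plain CSV; no
  projection support.
* GCV occasionally leaves residual wiggle in very small tables (≲ 100
  rows); effect summaries at covariate extremes are the quantities most
  sensitive to this, which is why the calibration benchmarks run at the
  ~200-segment scale.
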