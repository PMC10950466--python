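# gustwing

Atmospheric turbulence buffets flapping fliers, and birds compensate both by
shifting their mean wingbeat kinematics and by making stroke-to-stroke
adjustments.  `gustwing` is a Python pipeline for quantifying those
responses from raw biologger streams: tri-axial acceleration (200 Hz),
barometric pressure (20 Hz) and GPS fixes (1 Hz) recorded on free-flying
birds, together with reanalysis wind and surface-flux extracts and a terrain
grid.  It is written for movement ecologists and biomechanists who want a
tested, scriptable version of this analysis rather than a chain of
point-and-click tools.

## What it computes

* **Wingbeat kinematics** — tag-orientation correction (rotate the mean
  acceleration vector of a level-flight window onto the heave axis), then
  wingbeat detection: smooth the raw heave over 20 samples, difference the
  smoothed signal over 20 samples, take positive-to-negative transitions of
  the differential as peaks, and reject candidates below a peak-to-trough
  prominence threshold.  Per beat: frequency `f_k = 1/(t_k − t_{k−1})` and
  amplitude = peak-to-trough raw heave within the cycle (a proxy for stroke
  amplitude).  Flapping wing speed `f̄ · Ā` per segment proxies propulsive
  effort.
* **Turbulence proxy** — per 15 s segment, the interquartile range of
  barometric-pressure fluctuations (residuals about a within-segment linear
  trend): turbulent vertical displacement makes flight height, hence tag
  pressure, jitter.  For anemometer wind series, the Kolmogorov
  inertial-subrange constant `A` in `S(f) = A·f^{−5/3}` is fitted with the
  slope fixed at −5/3.  Boundary-layer context comes from the Deardorff
  convective velocity `w* = (g·z_i·Q_{0v}/θ_v)^{1/3}` and the friction
  velocity `u* = √(|τ|/ρ)`.
* **Flight path** — altitude ASL from the ISA hypsometric inversion of 2 s
  smoothed pressure, referenced to release-site sea-level pressure;
  per-second climb rate `Vz`; altitude AGL by subtracting bilinear terrain
  elevation; great-circle headings, turning angles and their circular SD
  (tortuosity) per segment; airspeed and headwind component from the wind
  triangle `v_air = v_ground − w`.
* **Effect-size models** — one row per 15 s segment (trailing pieces under
  10 s are excluded), eight responses (mean and SD of wingbeat frequency,
  amplitude and airspeed; mean altitude AGL; tortuosity), covariates
  `√turbulence`, headwind component, climb rate and `√altitude AGL`.  Each
  response is fitted as a penalized additive model: cubic B-spline smooths
  with shrinkage (null effects flatten), a per-flight random intercept, and
  GCV-chosen smoothing parameters.  Effects are summarized as the centred
  partial effect of turbulence at the observed minimum and maximum
  turbulence, as a percentage of the observed response range.

A synthetic-flight generator (`gustwing.synthetic_flight`) produces flights
with known ground truth — per-beat kinematics whose stroke-to-stroke SD
grows with a configured turbulence level, Ornstein–Uhlenbeck flight-height
gusts, and wind-advected tracks — so every stage can be validated without
any field data.

## Worked example

```python
import numpy as np
import gustwing as gw
from gustwing import segments_stats as ss

wind = gw.WindRecord(np.array([0.0, 3600.0]), np.array([2.0, 2.0]),
                     np.array([1.0, 1.0]))
flights = gw.make_flight_set(8, seed=5)          # synthetic release campaign
table = ss.build_segment_table(
    [ss.flight_products(rec, wind=wind, terrain=400.0) for rec, _ in flights]
)
print(f"{len(table)} segments from {table.flight_id.nunique()} flights")

fits = ss.fit_all_responses(table)
print(ss.turbulence_effect_table(fits, table).round(2).to_string(index=False))
```

prints

```
80 segments from 8 flights
         response  range_of_response  pct_at_max_turbulence  pct_at_min_turbulence
mean_altitude_agl              73.57                  -0.00                  -0.00
       tortuosity               3.55                  36.49                 -27.33
mean_wb_frequency               0.27                  -0.00                   0.00
mean_wb_amplitude               0.40                  38.23                 -27.07
    mean_airspeed               3.39                   0.00                   0.00
  sd_wb_frequency               0.38                  37.12                 -35.48
  sd_wb_amplitude               0.86                  43.15                 -35.36
      sd_airspeed               1.75                  56.10                 -23.68
```

These simulated flights have turbulence driving only the stroke-to-stroke
variability of the kinematics, and the fitted effect table recovers exactly
that structure: large positive turbulence effects on the SD responses
(37–56% of their range at maximum turbulence), with the mean wingbeat
frequency and the responses that carry no built-in turbulence signal shrunk
to essentially zero.  (The mean-amplitude effect is real too: amplitude is
measured as a raw peak-to-trough excursion, so higher stroke-to-stroke
variability also raises its segment mean.)  Tortuosity and airspeed SD
respond because gusts perturb the simulated track.

The same pipeline is scriptable from the shell:

```
gustwing --seed 3 simulate --out flight1/        # sensor CSVs + ground truth
gustwing wingbeats --accel flight1/accel.csv --out wb.csv
gustwing track --gps flight1/gps.csv --wind wind.csv --out track.csv
gustwing segments --flight-dir flight1 --wind wind.csv --out segments.csv
gustwing fit --segments segments.csv --out fits/
gustwing report --fits fits/
```

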