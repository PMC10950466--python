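"""Synthetic homing-flight generator with known ground truth.

Every downstream stage of the pipeline — wingbeat detection, barometric
altitude, the pressure-IQR turbulence proxy, the wind triangle and the
effect-size models — is validated against flights generated here, where the
turbulence level, wind, and the true stroke-to-stroke kinematics are known
exactly.

The generative model:

* **Heave.**  The flapping signal is a unit gravity offset plus a per-beat
  sinusoid: beat k has its own frequency f_k ~ N(f0 + df/dT·T, σ_f0 + γ_f·T)
  and half-amplitude A_k ~ N(A0, σ_A0 + γ_A·T), both truncated at 0.1× their
  base value.  Stroke-to-stroke variability therefore grows linearly with
  the segment's turbulence level T, which is the structure the per-segment
  SD responses are meant to recover.
* **Altitude and pressure.**  True altitude is a slow trend (mean level,
  optional constant climb, optional slow sinusoid) plus an
  Ornstein–Uhlenbeck vertical displacement whose stationary SD is
  proportional to T — turbulent flights have more variable flight height.
  Tag pressure is the exact ISA forward map of true altitude plus sensor
  noise, so the pipeline's hypsometric inversion round-trips cleanly.
* **Track.**  Ground velocity is a constant air velocity (configured
  airspeed along a fixed heading) plus the configured wind plus horizontal
  OU gusts scaled by T; positions integrate this on a local tangent plane
  around the release site.

T is piecewise constant on the same 15 s grid the analysis segments use, so
per-segment truth aligns with pipeline segments by construction.  All
randomness flows from one seed through named substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core_io import (
    AccelTrace,
    FlightRecord,
    GpsTrack,
    PressureTrace,
    SensorStreams,
    ValidationError,
)
from .flightpath import isa_pressure_at_altitude

SEGMENT_S = 15.0

_SUBSTREAMS = ("beats", "ou_vertical", "ou_east", "ou_north", "sensor_noise", "spectral")


@dataclass
class SimConfig:
    """Knobs of the generative model.  Defaults emulate a solo pigeon homing
    flight: ~6 Hz flapping, ~19 m/s airspeed, ~480 m ASL over ~400 m
    terrain, light wind."""

    duration_s: float = 150.0
    f0_hz: float = 6.0            # base wingbeat frequency
    a0_g: float = 2.0             # base heave half-amplitude (peak-to-trough = 2·a0)
    turbulence: float | Sequence[float] = 1.0  # T, scalar or per-15 s piece
    sigma_f0_hz: float = 0.05     # stroke-to-stroke frequency SD at T = 0
    sigma_a0_g: float = 0.05      # stroke-to-stroke amplitude SD at T = 0
    gamma_f: float = 0.15         # d SD(frequency)/dT, Hz per unit T
    gamma_a: float = 0.15         # d SD(amplitude)/dT, g per unit T
    freq_turbulence_slope: float = 0.0  # d mean frequency/dT, Hz per unit T
    amp_turbulence_slope: float = 0.0   # d mean amplitude/dT, g per unit T
    amp_compensates: bool = False  # amplitude tracks 1/frequency (constant product)
    tau_ou_s: float = 5.0         # OU relaxation time of gust displacement
    gust_alt_sd_per_t: float = 2.0   # stationary SD of vertical displacement, m per unit T
    gust_vel_sd_per_t: float = 0.5   # stationary SD of horizontal gust velocity, m/s per unit T
    mean_altitude_m: float = 480.0   # ASL
    climb_rate_m_s: float = 0.0
    trend_amp_m: float = 0.0      # slow sinusoidal altitude wander
    trend_period_s: float = 90.0
    wind_u: float = 2.0
    wind_v: float = 1.0
    airspeed_m_s: float = 19.0
    heading_deg: float = 45.0     # geographic, 0 = north
    accel_noise_g: float = 0.02
    pressure_noise_hpa: float = 0.05
    gps_noise_m: float = 0.0
    start_lon: float = 8.97
    start_lat: float = 47.73
    p0_sealevel_hpa: float = 1013.25
    accel_rate_hz: float = 200.0
    pressure_rate_hz: float = 20.0
    gps_rate_hz: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s < 30.0:
            raise ValidationError("duration must be at least 30 s")
        if self.f0_hz <= 0 or self.a0_g <= 0 or self.tau_ou_s <= 0:
            raise ValidationError("f0, A0 and tau_ou must be positive")
        t = np.atleast_1d(np.asarray(self.turbulence, dtype=float))
        if np.any(~np.isfinite(t)) or np.any(t < 0):
            raise ValidationError("turbulence levels must be finite and >= 0")
        for name in ("sigma_f0_hz", "sigma_a0_g", "gamma_f", "gamma_a",
                     "gust_alt_sd_per_t", "gust_vel_sd_per_t",
                     "accel_noise_g", "pressure_noise_hpa", "gps_noise_m"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0")

    def turbulence_at(self, t: np.ndarray) -> np.ndarray:
        """Piecewise-constant T on the 15 s segment grid."""
        levels = np.atleast_1d(np.asarray(self.turbulence, dtype=float))
        idx = np.minimum((np.asarray(t, float) // SEGMENT_S).astype(int), levels.size - 1)
        return levels[idx]


@dataclass
class GroundTruth:
    segment_bounds: list[tuple[float, float]]
    segment_turbulence: np.ndarray     # true T per 15 s segment
    beat_times: np.ndarray             # start time of each wingbeat cycle
    beat_frequency: np.ndarray         # true f_k, Hz
    beat_amplitude: np.ndarray         # true peak-to-trough heave, g (= 2·A_k)
    altitude_time: np.ndarray
    altitude_m: np.ndarray             # true ASL on the pressure grid
    wind: tuple[float, float]
    config: SimConfig = field(repr=False, default=None)


def _substream_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {n: np.random.default_rng(c) for n, c in zip(_SUBSTREAMS, children)}


def _ou_series(rng, n: int, dt: float, tau: float, sd: np.ndarray) -> np.ndarray:
    """Exact-discretization OU path with (piecewise) stationary SD ``sd``."""
    alpha = np.exp(-dt / tau)
    innov = np.sqrt(1.0 - alpha * alpha)
    xi = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = sd[0] * xi[0]
    for i in range(1, n):
        x[i] = alpha * x[i - 1] + sd[i] * innov * xi[i]
    return x


def _draw_beats(cfg: SimConfig, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sequential per-beat draws; each beat occupies 1/f_k seconds."""
    times, freqs, amps = [], [], []
    t = 0.0
    while t < cfg.duration_s:
        T = float(cfg.turbulence_at(np.array([t]))[0])
        f_mean = cfg.f0_hz + cfg.freq_turbulence_slope * T
        if cfg.amp_compensates:
            a_mean = cfg.f0_hz * cfg.a0_g / f_mean
        else:
            a_mean = cfg.a0_g + cfg.amp_turbulence_slope * T
        f = max(rng.normal(f_mean, cfg.sigma_f0_hz + cfg.gamma_f * T), 0.1 * cfg.f0_hz)
        a = max(rng.normal(a_mean, cfg.sigma_a0_g + cfg.gamma_a * T), 0.1 * cfg.a0_g)
        times.append(t)
        freqs.append(f)
        amps.append(a)
        t += 1.0 / f
    return np.array(times), np.array(freqs), np.array(amps)


def simulate_flight(config: SimConfig) -> tuple[FlightRecord, GroundTruth]:
    """Generate one flight and its ground truth.  Same config (and seed)
    gives bit-identical output."""
    config.validate()
    cfg = config
    rngs = _substream_rngs(cfg.seed)

    # --- heave from per-beat sinusoids -------------------------------------
    beat_t, beat_f, beat_a = _draw_beats(cfg, rngs["beats"])
    dt_a = 1.0 / cfg.accel_rate_hz
    t_acc = np.arange(0.0, cfg.duration_s, dt_a)
    k = np.searchsorted(beat_t, t_acc, side="right") - 1
    phase = 2.0 * np.pi * beat_f[k] * (t_acc - beat_t[k])
    heave = 1.0 + beat_a[k] * np.sin(phase)
    noise = rngs["sensor_noise"]
    if cfg.accel_noise_g > 0:
        heave = heave + noise.normal(0.0, cfg.accel_noise_g, t_acc.size)
    surge = noise.normal(0.0, cfg.accel_noise_g, t_acc.size) if cfg.accel_noise_g > 0 else np.zeros_like(t_acc)
    sway = noise.normal(0.0, cfg.accel_noise_g, t_acc.size) if cfg.accel_noise_g > 0 else np.zeros_like(t_acc)
    accel = AccelTrace(t_acc, surge, sway, heave, rate_hz=cfg.accel_rate_hz)

    # --- altitude trend + OU displacement, pressure via forward ISA --------
    dt_p = 1.0 / cfg.pressure_rate_hz
    t_pre = np.arange(0.0, cfg.duration_s, dt_p)
    T_pre = cfg.turbulence_at(t_pre)
    trend = (cfg.mean_altitude_m + cfg.climb_rate_m_s * t_pre
             + cfg.trend_amp_m * np.sin(2.0 * np.pi * t_pre / cfg.trend_period_s))
    z_ou = _ou_series(rngs["ou_vertical"], t_pre.size, dt_p, cfg.tau_ou_s,
                      cfg.gust_alt_sd_per_t * T_pre)
    altitude = trend + z_ou
    p = isa_pressure_at_altitude(altitude, cfg.p0_sealevel_hpa)
    if cfg.pressure_noise_hpa > 0:
        p = p + noise.normal(0.0, cfg.pressure_noise_hpa, t_pre.size)
    pressure = PressureTrace(t_pre, p, rate_hz=cfg.pressure_rate_hz)

    # --- track: air velocity + wind + horizontal OU gusts ------------------
    dt_g = 1.0 / cfg.gps_rate_hz
    t_gps = np.arange(0.0, cfg.duration_s + 0.5 * dt_g, dt_g)
    T_gps = cfg.turbulence_at(t_gps)
    theta = np.radians(cfg.heading_deg)
    v_air = cfg.airspeed_m_s * np.array([np.sin(theta), np.cos(theta)])
    gust_e = _ou_series(rngs["ou_east"], t_gps.size, dt_g, cfg.tau_ou_s,
                        cfg.gust_vel_sd_per_t * T_gps)
    gust_n = _ou_series(rngs["ou_north"], t_gps.size, dt_g, cfg.tau_ou_s,
                        cfg.gust_vel_sd_per_t * T_gps)
    ve = v_air[0] + cfg.wind_u + gust_e
    vn = v_air[1] + cfg.wind_v + gust_n
    east = np.concatenate([[0.0], np.cumsum(ve[:-1]) * dt_g])
    north = np.concatenate([[0.0], np.cumsum(vn[:-1]) * dt_g])
    if cfg.gps_noise_m > 0:
        east = east + noise.normal(0.0, cfg.gps_noise_m, east.size)
        north = north + noise.normal(0.0, cfg.gps_noise_m, north.size)
    m_per_deg_lat = 111_320.0
    m_per_deg_lon = m_per_deg_lat * np.cos(np.radians(cfg.start_lat))
    gps = GpsTrack(t_gps, cfg.start_lon + east / m_per_deg_lon,
                   cfg.start_lat + north / m_per_deg_lat, rate_hz=cfg.gps_rate_hz)

    record = FlightRecord(
        flight_id=f"sim{cfg.seed:06d}",
        bird_id=f"bird{cfg.seed % 10:02d}",
        release_time=0.0,
        streams=SensorStreams(accel, pressure, gps),
        p0_sealevel_hpa=cfg.p0_sealevel_hpa,
    )

    n_full = int(cfg.duration_s // SEGMENT_S)
    bounds = [(i * SEGMENT_S, (i + 1) * SEGMENT_S) for i in range(n_full)]
    tail = cfg.duration_s - n_full * SEGMENT_S
    if tail >= 10.0:
        bounds.append((n_full * SEGMENT_S, cfg.duration_s))
    seg_T = cfg.turbulence_at(np.array([b[0] for b in bounds]))
    truth = GroundTruth(
        segment_bounds=bounds,
        segment_turbulence=seg_T,
        beat_times=beat_t,
        beat_frequency=beat_f,
        beat_amplitude=2.0 * beat_a,
        altitude_time=t_pre,
        altitude_m=altitude,
        wind=(cfg.wind_u, cfg.wind_v),
        config=cfg,
    )
    return record, truth


def simulate_turbulent_wind(
    A: float, fs: float, duration_s: float, seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Gaussian wind-speed series whose one-sided spectrum follows the
    inertial-subrange law S(f) = A·f^(−5/3), synthesized by inverse-FFT
    shaping with random phases."""
    if A <= 0:
        raise ValidationError("spectral constant A must be positive")
    if fs <= 0:
        raise ValidationError("sampling rate must be positive")
    n = int(round(duration_s * fs))
    if n < 64:
        raise ValidationError("series too short: need at least 64 samples")
    if rng is None:
        rng = _substream_rngs(seed)["spectral"]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    target = np.zeros_like(freqs)
    target[1:] = A * freqs[1:] ** (-5.0 / 3.0)
    # E|X_k|^2 = S(f_k)·fs·n/2 gives the target one-sided periodogram
    scale = np.sqrt(target * fs * n / 4.0)
    coeff = scale * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    coeff[0] = 0.0
    if n % 2 == 0:
        coeff[-1] = np.sqrt(2.0) * coeff[-1].real
    return np.fft.irfft(coeff, n=n)


def make_flight_set(
    n_flights: int,
    seed: int,
    turbulence_levels: Sequence[float] | None = None,
    base_config: SimConfig | None = None,
    n_birds: int = 5,
) -> list[tuple[FlightRecord, GroundTruth]]:
    """A batch of flights with per-segment T drawn from ``turbulence_levels``
    (default: a 5-level ladder on [0, 3]); flights rotate over ``n_birds``
    birds, mirroring a multi-bird release campaign.  Each flight gets its
    own heading (±30° around the base) and a small constant climb rate so
    the headwind-component and climb-rate covariates vary between flights
    the way real release days do."""
    if turbulence_levels is None:
        turbulence_levels = [0.0, 0.5, 1.0, 2.0, 3.0]
    base = base_config or SimConfig()
    master = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(master.spawn(n_flights)):
        pick = np.random.default_rng(child)
        n_seg = max(int(base.duration_s // SEGMENT_S), 1)
        levels = pick.choice(np.asarray(turbulence_levels, float), size=n_seg)
        sub_seed = int(pick.integers(0, 2**31 - 1))
        cfg = replace(
            base,
            turbulence=levels,
            seed=sub_seed,
            heading_deg=base.heading_deg + float(pick.uniform(-30.0, 30.0)),
            climb_rate_m_s=base.climb_rate_m_s + float(pick.uniform(-0.3, 0.3)),
        )
        rec, truth = simulate_flight(cfg)
        rec.flight_id = f"flight{i:03d}"
        rec.bird_id = f"bird{i % n_birds:02d}"
        out.append((rec, truth))
    return out
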