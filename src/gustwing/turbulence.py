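"""Pressure-based turbulence proxy, inertial-subrange spectral fit and
boundary-layer velocity scales.

The per-segment turbulence proxy is the interquartile range of barometric
pressure fluctuations: turbulent vertical displacement makes flight height —
hence tag pressure — jitter, so the spread of within-segment pressure
residuals indexes the turbulence the bird flew through.  Fluctuations are
residuals from a within-segment linear trend, which separates steady climb
or descent from turbulent displacement.

For anemometer wind series the Kolmogorov inertial subrange predicts a
one-sided spectrum S(f) = A·f^(−5/3); fitting the power law with the slope
fixed at −5/3 yields the constant A as a qualitative turbulence measure.

Boundary-layer context comes from two standard velocity scales: the
Deardorff convective velocity w* = (g·zi·Q0v/θv)^(1/3) for thermal
turbulence and the friction velocity u* = sqrt(|τ|/ρ) for mechanical
(shear) turbulence, both computable from reanalysis surface fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .core_io import PressureTrace, ValidationError

G_M_PER_S2 = 9.81  # conventional value in the Deardorff scale


class SegmentTooShortError(ValidationError):
    """Segment shorter than the minimum usable duration."""


@dataclass
class TurbulenceContext:
    segment_id: str
    proxy: float        # IQR of detrended within-segment pressure, hPa
    sqrt_proxy: float   # model covariate
    w_star: float = float("nan")
    u_star: float = float("nan")


@dataclass
class SpectralFit:
    constant: float          # A in S(f) = A f^(-5/3)
    band: tuple[float, float]
    goodness: float          # residual SD around the fit in log space


def pressure_fluctuation_iqr(
    time: np.ndarray, pressure: np.ndarray, min_duration_s: float = 10.0,
    detrend: bool = True,
) -> float:
    """IQR (hPa) of pressure residuals about a within-segment linear trend.

    Detrending isolates turbulent fluctuation from steady climb/descent;
    quartiles use linear interpolation (NumPy default, R type 7) so results
    are bit-reproducible.  ``detrend=False`` is kept for sensitivity
    analysis.  Raises :class:`SegmentTooShortError` below ``min_duration_s``.
    """
    time = np.asarray(time, dtype=float)
    pressure = np.asarray(pressure, dtype=float)
    if time.size < 4 or time[-1] - time[0] < min_duration_s:
        raise SegmentTooShortError(
            f"segment of {0.0 if time.size == 0 else time[-1] - time[0]:.1f} s "
            f"is below the {min_duration_s:.0f} s minimum"
        )
    if detrend:
        coef = np.polyfit(time - time[0], pressure, 1)
        resid = pressure - np.polyval(coef, time - time[0])
    else:
        resid = pressure - pressure.mean()
    q1, q3 = np.percentile(resid, [25.0, 75.0])
    return float(q3 - q1)


def segment_turbulence(
    trace: PressureTrace, start: float, end: float, segment_id: str = "",
    detrend: bool = True,
) -> TurbulenceContext:
    """Turbulence proxy for one [start, end) window of a pressure trace."""
    mask = (trace.time >= start) & (trace.time < end)
    proxy = pressure_fluctuation_iqr(trace.time[mask], trace.pressure[mask],
                                     detrend=detrend)
    return TurbulenceContext(segment_id, proxy, float(np.sqrt(proxy)))


def spectral_constant(
    wind: np.ndarray, fs: float, band: tuple[float, float] = (0.1, 5.0),
    nperseg: int = 512,
) -> SpectralFit:
    """Fixed-slope −5/3 fit to the Welch spectrum of a wind-speed series.

    Least squares of log S on log f with the slope held at −5/3 over
    ``band``; the intercept gives the spectral constant A, and the residual
    SD in log space measures how well the inertial-subrange law holds.
    """
    wind = np.asarray(wind, dtype=float)
    if wind.size < 64:
        raise ValidationError("spectral_constant needs at least 64 samples")
    f_lo, f_hi = band
    if not 0 < f_lo < f_hi < fs / 2:
        raise ValidationError("band must satisfy 0 < f_lo < f_hi < fs/2")
    nper = min(nperseg, wind.size)
    freqs, pxx = signal.welch(wind, fs=fs, nperseg=nper)
    mask = (freqs >= f_lo) & (freqs <= f_hi) & (pxx > 0)
    if not mask.any():
        raise ValidationError("no spectral estimates inside the requested band")
    logf, logs = np.log(freqs[mask]), np.log(pxx[mask])
    log_a = float(np.mean(logs + (5.0 / 3.0) * logf))
    resid = logs - (log_a - (5.0 / 3.0) * logf)
    return SpectralFit(float(np.exp(log_a)), (f_lo, f_hi), float(np.std(resid)))


def convective_velocity(q0v_km_s: float, zi_m: float, theta_v_k: float) -> float:
    """Deardorff convective velocity scale w* (m/s).

    ``q0v_km_s`` is the surface kinematic virtual heat flux (K·m/s),
    ``zi_m`` the boundary-layer depth, ``theta_v_k`` a reference virtual
    potential temperature.  Zero under stable or neutral stratification
    (non-positive heat flux).
    """
    if zi_m <= 0:
        raise ValidationError("boundary-layer depth must be positive")
    if not 200.0 < theta_v_k < 330.0:
        raise ValidationError("virtual potential temperature outside (200, 330) K")
    if q0v_km_s <= 0:
        return 0.0
    return float((G_M_PER_S2 * zi_m * q0v_km_s / theta_v_k) ** (1.0 / 3.0))


def shear_velocity(tau_x: float, tau_y: float, rho: float) -> float:
    """Friction velocity u* = sqrt(|τ|/ρ) (m/s) from surface stress
    components (N/m²) and air density (kg/m³)."""
    if rho <= 0:
        raise ValidationError("air density must be positive")
    return float(np.sqrt(np.hypot(tau_x, tau_y) / rho))


def climatology_ttest(sample_a, sample_b) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test (t, df, two-sided p) comparing
    flight-day boundary-layer scales against the multi-year climatology;
    df = n_a + n_b − 2."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs at least 2 values")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), int(a.size + b.size - 2), float(res.pvalue)
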