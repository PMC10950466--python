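"""Barometric altitude, climb rate, track geometry and the wind triangle.

Altitude above sea level comes from the hypsometric inversion of the ISA
lower-atmosphere model applied to 2 s-smoothed barometric pressure,
referenced to the sea-level pressure recorded at the release site.  Climb
rate Vz is the per-second first difference of 1 Hz-resampled altitude.
Altitude above ground subtracts terrain elevation sampled under the
(interpolated) GPS position.  Track headings are great-circle bearings
between consecutive fixes; turning angles are their wrapped differences
(clockwise positive), and their circular standard deviation per segment is
the tortuosity measure.  Airspeed and headwind component come from the wind
triangle: air velocity = ground velocity − wind.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import GpsTrack, PressureTrace, TerrainGrid, ValidationError, WindRecord, sample_terrain
from .kinematics import running_mean

logger = logging.getLogger(__name__)

# ISA lower-atmosphere constants
T0_K = 288.15          # sea-level standard temperature
LAPSE_K_PER_M = 0.0065
RD_J_PER_KG_K = 287.053
G_M_PER_S2 = 9.80665
_HYPSO_EXP = LAPSE_K_PER_M * RD_J_PER_KG_K / G_M_PER_S2  # ≈ 0.19026


@dataclass
class AltitudeSeries:
    time: np.ndarray
    altitude_asl: np.ndarray
    altitude_agl: np.ndarray | None = None


def isa_pressure_at_altitude(h_m, p0_hpa: float = 1013.25):
    """Forward ISA map: pressure at altitude h (used by the simulator, so
    pressure→altitude round-trips are exact up to smoothing and noise)."""
    return p0_hpa * (1.0 - LAPSE_K_PER_M * np.asarray(h_m, float) / T0_K) ** (1.0 / _HYPSO_EXP)


def pressure_to_altitude(
    trace: PressureTrace, p0_sealevel: float, smooth_seconds: float = 2.0
) -> AltitudeSeries:
    """Altitude ASL from barometric pressure via the ISA hypsometric inversion,
    after a centred moving-average smooth of ``smooth_seconds``."""
    if not 900.0 < p0_sealevel < 1100.0:
        raise ValidationError("p0_sealevel must lie in (900, 1100) hPa")
    if np.any(trace.pressure <= 0):
        raise ValidationError("non-positive pressure sample")
    window = max(int(round(smooth_seconds * trace.rate_hz)), 1)
    window = min(window, len(trace))
    p = running_mean(trace.pressure, window)
    if np.mean(p > p0_sealevel + 5.0) > 0.5:
        warnings.warn(
            "pressure persistently exceeds sea-level reference by > 5 hPa "
            "(below-sea-level altitudes)", stacklevel=2,
        )
    h = (T0_K / LAPSE_K_PER_M) * (1.0 - (p / p0_sealevel) ** _HYPSO_EXP)
    return AltitudeSeries(trace.time.copy(), h)


def climb_rate(alt: AltitudeSeries) -> tuple[np.ndarray, np.ndarray]:
    """Per-second climb rate Vz: first difference of altitude ASL resampled
    to a 1 Hz grid.  Returns ``(seconds, vz)``; vz[i] covers [t_i, t_i+1)."""
    t, h = alt.time, alt.altitude_asl
    if t[-1] - t[0] < 2.0:
        raise ValidationError("climb_rate needs at least 2 s of altitude data")
    grid = np.arange(np.ceil(t[0]), np.floor(t[-1]) + 1e-9)
    h1 = np.interp(grid, t, h)
    return grid[:-1], np.diff(h1)


def altitude_agl(
    alt: AltitudeSeries, gps: GpsTrack, terrain: TerrainGrid
) -> AltitudeSeries:
    """Subtract terrain elevation under the track from altitude ASL.

    GPS positions are linearly interpolated to the pressure timestamps.
    Raises an error naming the first fix outside the terrain grid.
    """
    lon = np.interp(alt.time, gps.time, gps.lon)
    lat = np.interp(alt.time, gps.time, gps.lat)
    try:
        ground = sample_terrain(terrain, lon, lat)
    except Exception:
        for i, (lo, la) in enumerate(zip(lon, lat)):
            try:
                sample_terrain(terrain, lo, la)
            except Exception:
                raise ValidationError(
                    f"fix at t={alt.time[i]:.2f}s (lon={lo:.5f}, lat={la:.5f}) "
                    "falls outside the terrain grid"
                ) from None
        raise
    return AltitudeSeries(alt.time.copy(), alt.altitude_asl.copy(),
                          alt.altitude_asl - ground)


_EARTH_R = 6371000.0


def great_circle_bearing(lon1, lat1, lon2, lat2):
    """Initial great-circle bearing in degrees (0 = north, 90 = east)."""
    lam1, phi1, lam2, phi2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlam = lam2 - lam1
    y = np.sin(dlam) * np.cos(phi2)
    x = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlam)
    return np.degrees(np.arctan2(y, x)) % 360.0


def great_circle_distance(lon1, lat1, lon2, lat2):
    """Haversine distance in metres."""
    lam1, phi1, lam2, phi2 = map(np.radians, (lon1, lat1, lon2, lat2))
    a = (np.sin((phi2 - phi1) / 2) ** 2
         + np.cos(phi1) * np.cos(phi2) * np.sin((lam2 - lam1) / 2) ** 2)
    return 2 * _EARTH_R * np.arcsin(np.sqrt(a))


def wrap_angle(deg):
    """Wrap angles into (−180, 180]."""
    out = -((-np.asarray(deg, float) + 180.0) % 360.0 - 180.0)
    return out


def turning_angles(gps: GpsTrack) -> tuple[np.ndarray, np.ndarray]:
    """Heading differences between consecutive pairs of fixes.

    Returns ``(times, angles)`` where angles[i] = wrap(heading_{i+1} −
    heading_i) in (−180, 180], clockwise positive; times are those of the
    middle fix of each triple.
    """
    if len(gps) < 3:
        raise ValidationError("turning_angles needs at least 3 fixes")
    hdg = great_circle_bearing(gps.lon[:-1], gps.lat[:-1], gps.lon[1:], gps.lat[1:])
    return gps.time[1:-1], wrap_angle(np.diff(hdg))


def circular_sd(angles_deg) -> float:
    """Circular standard deviation sqrt(−2 ln R) in degrees, R the mean
    resultant length; +inf when the angles are perfectly dispersed (R = 0)."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size < 2:
        raise ValidationError("circular_sd needs at least 2 angles")
    R = min(float(np.hypot(np.sin(a).mean(), np.cos(a).mean())), 1.0)
    if R <= 1e-12:
        logger.warning("circular_sd: degenerate uniform angle set (R = 0)")
        return float("inf")
    return float(np.degrees(np.sqrt(-2.0 * np.log(R))))


def airspeed_hwc(ground_velocity, wind) -> tuple[float, float]:
    """Wind-triangle decomposition of one track step.

    ``ground_velocity`` and ``wind`` are (east, north) vectors in m/s.
    Airspeed is |ground − wind|; the headwind component is the wind's signed
    projection against the track direction (positive = headwind).
    """
    vg = np.asarray(ground_velocity, dtype=float)
    w = np.asarray(wind, dtype=float)
    if not (np.all(np.isfinite(vg)) and np.all(np.isfinite(w))):
        raise ValidationError("airspeed_hwc: non-finite input vector")
    air = vg - w
    speed = float(np.linalg.norm(vg))
    if speed == 0:
        raise ValidationError("airspeed_hwc: zero ground speed, track direction undefined")
    hwc = float(-np.dot(w, vg / speed))
    return float(np.linalg.norm(air)), hwc


def interpolate_wind(wind: WindRecord, at_time) -> np.ndarray:
    """Hourly wind linearly interpolated in time (held constant beyond the
    record ends); spatial variation over a single track is neglected."""
    u = np.interp(at_time, wind.time, wind.u_east)
    v = np.interp(at_time, wind.time, wind.v_north)
    return np.stack([u, v], axis=-1)


def track_steps(gps: GpsTrack, wind: WindRecord | None = None):
    """Per-fix-pair track table: heading, ground speed, turning angle,
    airspeed and headwind component (the latter two NaN without wind).

    Step i covers fixes i → i+1 and is stamped with the time of fix i.
    """
    import pandas as pd

    if len(gps) < 3:
        raise ValidationError("track_steps needs at least 3 fixes")
    lon1, lat1, lon2, lat2 = gps.lon[:-1], gps.lat[:-1], gps.lon[1:], gps.lat[1:]
    hdg = great_circle_bearing(lon1, lat1, lon2, lat2)
    dist = great_circle_distance(lon1, lat1, lon2, lat2)
    dt = np.diff(gps.time)
    speed = dist / dt
    turn = np.full(hdg.size, np.nan)
    turn[1:] = wrap_angle(np.diff(hdg))
    air = np.full(hdg.size, np.nan)
    hwc = np.full(hdg.size, np.nan)
    if wind is not None:
        w = interpolate_wind(wind, gps.time[:-1])
        theta = np.radians(hdg)
        vg = np.column_stack([speed * np.sin(theta), speed * np.cos(theta)])
        delta = vg - w
        air = np.linalg.norm(delta, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            that = vg / speed[:, None]
        hwc = -np.einsum("ij,ij->i", w, that)
    return pd.DataFrame(
        {
            "time": gps.time[:-1],
            "heading": hdg,
            "ground_speed": speed,
            "turning_angle": turn,
            "airspeed": air,
            "hwc": hwc,
        }
    )
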