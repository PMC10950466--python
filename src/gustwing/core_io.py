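"""Sensor-stream containers, delimited-text readers/writers and terrain grids.

A flight is carried as three synchronized streams — tri-axial acceleration
(nominally 200 Hz), barometric pressure (20 Hz) and GPS fixes (1 Hz) — all
on a shared time base in seconds since flight start.  Streams are plain
comma-delimited text, one stream per file; the time column may be numeric
seconds or ISO-8601 timestamps (converted to seconds from the first sample).
No cross-stream resampling happens at read time: consumers decide how to
align grids.

Terrain is a regular lon/lat grid of elevations (metres ASL), read from a
3-column ``lon,lat,elevation`` CSV, and queried by bilinear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator


class FormatError(ValueError):
    """A file does not match the expected column schema."""


class ValidationError(ValueError):
    """A stream violates a structural invariant (ordering, range, finiteness)."""


class OutOfBoundsError(ValueError):
    """A query point falls outside the terrain grid."""


def _check_monotone(time: np.ndarray, what: str) -> None:
    if time.size > 1:
        bad = np.nonzero(np.diff(time) <= 0)[0]
        if bad.size:
            raise ValidationError(
                f"{what}: time not strictly increasing at index {int(bad[0]) + 1} "
                f"(t={time[bad[0] + 1]!r} follows t={time[bad[0]]!r})"
            )


def _infer_rate(time: np.ndarray, default: float) -> float:
    if time.size < 2:
        return default
    dt = float(np.median(np.diff(time)))
    return 1.0 / dt if dt > 0 else default


@dataclass
class AccelTrace:
    """Tri-axial acceleration in g: surge (anterior–posterior), sway
    (lateral), heave (dorsoventral — the flapping axis)."""

    time: np.ndarray
    surge: np.ndarray
    sway: np.ndarray
    heave: np.ndarray
    rate_hz: float = 200.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        for name in ("surge", "sway", "heave"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        _check_monotone(self.time, "acceleration")
        if self.rate_hz <= 0:
            raise ValidationError("acceleration: rate_hz must be positive")
        if not np.all(np.isfinite(self.heave)):
            raise ValidationError("acceleration: non-finite heave sample")

    def __len__(self) -> int:
        return self.time.size


@dataclass
class PressureTrace:
    """Barometric pressure in hPa."""

    time: np.ndarray
    pressure: np.ndarray
    rate_hz: float = 20.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        _check_monotone(self.time, "pressure")
        if np.any((self.pressure <= 300.0) | (self.pressure >= 1100.0)):
            raise ValidationError(
                "pressure: values outside the plausible (300, 1100) hPa range"
            )

    def __len__(self) -> int:
        return self.time.size


@dataclass
class GpsTrack:
    """GPS fixes in decimal degrees (WGS84), nominally 1 Hz."""

    time: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    ground_speed: Optional[np.ndarray] = None
    rate_hz: float = 1.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        if self.ground_speed is not None:
            self.ground_speed = np.asarray(self.ground_speed, dtype=float)
        _check_monotone(self.time, "gps")
        if np.any(np.abs(self.lat) > 90.0):
            raise ValidationError("gps: |lat| > 90")
        if np.any(np.abs(self.lon) > 180.0):
            raise ValidationError("gps: |lon| > 180")

    def __len__(self) -> int:
        return self.time.size


@dataclass
class WindRecord:
    """Hourly wind components (positive u = air moving east, v = north)."""

    time: np.ndarray
    u_east: np.ndarray
    v_north: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.u_east = np.asarray(self.u_east, dtype=float)
        self.v_north = np.asarray(self.v_north, dtype=float)
        if not (np.all(np.isfinite(self.u_east)) and np.all(np.isfinite(self.v_north))):
            raise ValidationError("wind: non-finite component")


@dataclass
class SensorStreams:
    accel: AccelTrace
    pressure: PressureTrace
    gps: GpsTrack


@dataclass
class FlightRecord:
    """One flight: identifiers, synchronized streams and the reference
    sea-level pressure used to convert barometric pressure to altitude."""

    flight_id: str
    bird_id: str
    release_time: float
    streams: SensorStreams
    p0_sealevel_hpa: float = 1013.25

    def __post_init__(self) -> None:
        if not self.flight_id or not self.bird_id:
            raise ValidationError("flight/bird identifiers must be non-empty")
        s = self.streams
        t0 = max(s.accel.time[0], s.pressure.time[0], s.gps.time[0])
        t1 = min(s.accel.time[-1], s.pressure.time[-1], s.gps.time[-1])
        if t1 <= t0:
            raise ValidationError(
                f"flight {self.flight_id}: sensor streams do not overlap in time"
            )

    @property
    def duration(self) -> float:
        s = self.streams
        return float(
            min(s.accel.time[-1], s.pressure.time[-1], s.gps.time[-1])
            - max(s.accel.time[0], s.pressure.time[0], s.gps.time[0])
        )


_SCHEMAS = {
    "accel": ("time", "surge", "sway", "heave"),
    "pressure": ("time", "pressure_hpa"),
    "gps": ("time", "lon", "lat"),
    "wind": ("time", "u", "v"),
}


def _time_to_seconds(col: pd.Series) -> np.ndarray:
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float)
    ts = pd.to_datetime(col, utc=True, format="ISO8601")
    return (ts - ts.iloc[0]).dt.total_seconds().to_numpy()


def read_sensor_csv(path, stream_kind: str):
    """Read one sensor stream from a delimited text file.

    ``stream_kind`` is one of ``accel``, ``pressure``, ``gps``, ``wind``.
    Column schemas: accel ``time,surge,sway,heave``; pressure
    ``time,pressure_hpa``; gps ``time,lon,lat[,ground_speed]``; wind
    ``time,u,v``.  Raises :class:`FormatError` naming any missing column and
    :class:`ValidationError` on the first out-of-order timestamp.
    """
    if stream_kind not in _SCHEMAS:
        raise ValueError(f"unknown stream kind {stream_kind!r}")
    df = pd.read_csv(path)
    for col in _SCHEMAS[stream_kind]:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    time = _time_to_seconds(df["time"])
    if stream_kind == "accel":
        return AccelTrace(
            time,
            df["surge"].to_numpy(float),
            df["sway"].to_numpy(float),
            df["heave"].to_numpy(float),
            rate_hz=_infer_rate(time, 200.0),
        )
    if stream_kind == "pressure":
        return PressureTrace(
            time, df["pressure_hpa"].to_numpy(float), rate_hz=_infer_rate(time, 20.0)
        )
    if stream_kind == "gps":
        gs = df["ground_speed"].to_numpy(float) if "ground_speed" in df.columns else None
        return GpsTrack(
            time,
            df["lon"].to_numpy(float),
            df["lat"].to_numpy(float),
            ground_speed=gs,
            rate_hz=_infer_rate(time, 1.0),
        )
    return WindRecord(time, df["u"].to_numpy(float), df["v"].to_numpy(float))


def write_sensor_csv(path, trace) -> None:
    """Write a stream back to its canonical CSV schema (full float precision)."""
    if isinstance(trace, AccelTrace):
        df = pd.DataFrame(
            {"time": trace.time, "surge": trace.surge, "sway": trace.sway, "heave": trace.heave}
        )
    elif isinstance(trace, PressureTrace):
        df = pd.DataFrame({"time": trace.time, "pressure_hpa": trace.pressure})
    elif isinstance(trace, GpsTrack):
        df = pd.DataFrame({"time": trace.time, "lon": trace.lon, "lat": trace.lat})
        if trace.ground_speed is not None:
            df["ground_speed"] = trace.ground_speed
    elif isinstance(trace, WindRecord):
        df = pd.DataFrame({"time": trace.time, "u": trace.u_east, "v": trace.v_north})
    else:
        raise TypeError(f"cannot serialize {type(trace).__name__}")
    df.to_csv(path, index=False, float_format="%.12g")


@dataclass
class TerrainGrid:
    """Regular lon/lat elevation grid (metres ASL); bilinear sampling."""

    lon: np.ndarray
    lat: np.ndarray
    elevation: np.ndarray  # shape (nlat, nlon)
    _interp: RegularGridInterpolator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.elevation.shape != (self.lat.size, self.lon.size):
            raise ValidationError("terrain: elevation shape must be (nlat, nlon)")
        if not np.all(np.isfinite(self.elevation)):
            raise ValidationError("terrain: non-finite elevation")
        self._interp = RegularGridInterpolator(
            (self.lat, self.lon), self.elevation, method="linear", bounds_error=True
        )


def read_terrain_csv(path) -> TerrainGrid:
    """Read a ``lon,lat,elevation`` CSV laid out on a regular grid."""
    df = pd.read_csv(path)
    for col in ("lon", "lat", "elevation"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    lons = np.unique(df["lon"].to_numpy(float))
    lats = np.unique(df["lat"].to_numpy(float))
    if lons.size * lats.size != len(df):
        raise FormatError(f"{path}: points do not form a complete regular grid")
    pivot = df.pivot_table(index="lat", columns="lon", values="elevation").sort_index()
    return TerrainGrid(lons, lats, pivot.to_numpy())


def sample_terrain(grid: TerrainGrid, lon, lat):
    """Bilinear elevation at (lon, lat); scalar in/scalar out.

    Raises :class:`OutOfBoundsError` for points outside the grid extent.
    """
    lon_a = np.atleast_1d(np.asarray(lon, dtype=float))
    lat_a = np.atleast_1d(np.asarray(lat, dtype=float))
    try:
        vals = grid._interp(np.column_stack([lat_a, lon_a]))
    except ValueError as exc:
        raise OutOfBoundsError(f"terrain query outside grid bounds: {exc}") from None
    return float(vals[0]) if np.isscalar(lon) or np.ndim(lon) == 0 else vals
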