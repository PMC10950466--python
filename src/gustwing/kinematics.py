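"""Tag-orientation correction and wingbeat detection from heave acceleration.

A back-mounted accelerometer's heave (dorsoventral) axis oscillates once per
wingbeat at roughly 5–8 Hz in pigeons.  The detector follows the standard
biologging recipe: smooth the raw heave over a fixed number of samples to
suppress high-frequency noise, difference the smoothed signal over the same
span, take positive-to-negative transitions of the differential as candidate
peaks, and discard candidates whose raw peak-to-trough excursion falls below
a prominence threshold (false peaks from residual ripple).  Per-beat
frequency is the reciprocal of the period between consecutive surviving
peaks; per-beat amplitude is the raw peak-to-trough heave within the cycle
and serves as a proxy for angular stroke amplitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_io import AccelTrace, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class Wingbeat:
    peak_time: float
    frequency: float  # Hz; NaN for the first beat of a series (period undefined)
    amplitude: float  # peak-to-trough raw heave within the cycle, g


@dataclass
class WingbeatSeries:
    beats: list[Wingbeat]
    flight_id: str = ""
    settings: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.beats)

    @property
    def peak_times(self) -> np.ndarray:
        return np.array([b.peak_time for b in self.beats])

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([b.frequency for b in self.beats])

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([b.amplitude for b in self.beats])


def correct_orientation(trace: AccelTrace, level_window: tuple[float, float]) -> AccelTrace:
    """Rotate the acceleration frame so gravity lies on the heave axis.

    ``level_window`` is a [t0, t1] interval of level flight at least 2 s
    long; the mean acceleration vector over it is rotated onto (0, 0, 1),
    and the same rotation is applied to every sample.  Rotations preserve
    per-sample vector norms, so dynamic acceleration content is untouched.
    """
    t0, t1 = level_window
    if t1 - t0 < 2.0:
        raise ValidationError(
            "orientation correction needs a segment of level flight of at least 2 s"
        )
    mask = (trace.time >= t0) & (trace.time <= t1)
    if not mask.any():
        raise ValidationError("level window lies outside the trace")
    g_vec = np.array(
        [trace.surge[mask].mean(), trace.sway[mask].mean(), trace.heave[mask].mean()]
    )
    norm = np.linalg.norm(g_vec)
    if norm == 0:
        raise ValidationError("zero mean acceleration in level window")
    a = g_vec / norm
    b = np.array([0.0, 0.0, 1.0])
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-15:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        # Rodrigues rotation taking a onto b
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))
    xyz = np.vstack([trace.surge, trace.sway, trace.heave])
    rs, rw, rh = R @ xyz
    return AccelTrace(trace.time.copy(), rs, rw, rh, rate_hz=trace.rate_hz)


def running_mean(x: np.ndarray, window_events: int) -> np.ndarray:
    """Centred moving average over ``window_events`` samples, truncated at
    the edges so the output length equals the input length."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValidationError("running_mean: empty series")
    if not 1 <= window_events <= x.size:
        raise ValidationError(
            f"running_mean: window {window_events} outside [1, {x.size}]"
        )
    kernel = np.ones(window_events)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return sums / counts


def _centred_difference(x: np.ndarray, span: int) -> np.ndarray:
    """d[i] = x[i + span/2] − x[i − span/2], edges held at the nearest sample."""
    h = max(span // 2, 1)
    idx = np.arange(x.size)
    return x[np.minimum(idx + h, x.size - 1)] - x[np.maximum(idx - h, 0)]


def detect_wingbeats(
    trace: AccelTrace,
    smooth_events: int = 20,
    diff_events: int = 20,
    min_prominence_g: float | None = None,
    flight_id: str = "",
) -> WingbeatSeries:
    """Detect wingbeats in the heave signal.

    Candidates are positive-to-negative transitions of the centred
    differential of the smoothed heave; a candidate survives only if the raw
    peak-to-trough excursion of its cycle (candidate to next candidate)
    reaches ``min_prominence_g``.  When ``min_prominence_g`` is None an
    automatic threshold of 0.25 × the median candidate excursion is used
    (the per-flight tuning a user would otherwise do by eye).

    Returns an empty series — with a warning — if every candidate is
    rejected; an all-quiet trace is not an error.
    """
    if trace.time[-1] - trace.time[0] < 1.0:
        raise ValidationError("detect_wingbeats: trace shorter than 1 s")
    if min_prominence_g is not None and min_prominence_g < 0:
        raise ValidationError("detect_wingbeats: min_prominence_g must be >= 0")

    heave = trace.heave
    smoothed = running_mean(heave, smooth_events)
    diff = _centred_difference(smoothed, diff_events)
    cand = np.nonzero((diff[:-1] > 0) & (diff[1:] <= 0))[0]

    settings = {
        "smooth_events": smooth_events,
        "diff_events": diff_events,
        "min_prominence_g": min_prominence_g,
    }
    if cand.size == 0:
        logger.warning("no wingbeat candidates detected (flight %s)", flight_id or "?")
        return WingbeatSeries([], flight_id, settings)

    # cycle k spans [cand[k], cand[k+1]); last cycle runs to the trace end
    bounds = np.append(cand, heave.size - 1)
    excursions = np.array(
        [np.ptp(heave[bounds[k] : bounds[k + 1] + 1]) for k in range(cand.size)]
    )
    if min_prominence_g is None:
        min_prominence_g = 0.25 * float(np.median(excursions))
        settings["min_prominence_g"] = min_prominence_g
    keep = cand[excursions >= min_prominence_g]
    if keep.size == 0:
        logger.warning(
            "all %d wingbeat candidates below prominence %.3g g (flight %s)",
            cand.size, min_prominence_g, flight_id or "?",
        )
        return WingbeatSeries([], flight_id, settings)

    # sub-sample peak times: parabola through the smoothed maximum, so the
    # per-beat period is not quantized to the sampling interval (which would
    # inflate the stroke-to-stroke frequency SD)
    dt = float(np.median(np.diff(trace.time)))
    peak_t = np.empty(keep.size)
    for k, i in enumerate(keep):
        j = i
        while 0 < j < smoothed.size - 1 and smoothed[j + 1] > smoothed[j]:
            j += 1
        while 0 < j < smoothed.size - 1 and smoothed[j - 1] > smoothed[j]:
            j -= 1
        if 0 < j < smoothed.size - 1:
            denom = smoothed[j - 1] - 2.0 * smoothed[j] + smoothed[j + 1]
            delta = 0.5 * (smoothed[j - 1] - smoothed[j + 1]) / denom if denom < 0 else 0.0
            delta = float(np.clip(delta, -1.0, 1.0))
        else:
            delta = 0.0
        peak_t[k] = trace.time[j] + delta * dt
    mono = np.ones(keep.size, dtype=bool)
    mono[1:] = np.diff(peak_t) > 0
    keep, peak_t = keep[mono], peak_t[mono]
    kb = np.append(keep, heave.size - 1)
    beats = []
    for k in range(keep.size):
        amp = float(np.ptp(heave[kb[k] : kb[k + 1] + 1]))
        freq = float(1.0 / (peak_t[k] - peak_t[k - 1])) if k > 0 else float("nan")
        beats.append(Wingbeat(float(peak_t[k]), freq, amp))
    return WingbeatSeries(beats, flight_id, settings)


def flapping_wing_speed(mean_frequency: float, mean_amplitude: float) -> float:
    """Product of mean wingbeat frequency (Hz) and mean heave amplitude (g):
    a per-segment proxy for propulsive effort, computed by callers
    separately for ascent (Vz > 0) and descent (Vz < 0) subsets."""
    if mean_frequency < 0 or mean_amplitude < 0:
        raise ValidationError("flapping_wing_speed: inputs must be non-negative")
    return mean_frequency * mean_amplitude
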