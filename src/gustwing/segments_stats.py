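"""Per-segment analysis table and effect-size models.

Flights are cut into consecutive 15 s segments (a trailing piece is kept
only if it is at least 10 s).  Each segment becomes one analysis row with
eight responses — mean altitude AGL, track tortuosity (circular SD of
turning angle), mean and SD of wingbeat frequency, amplitude and airspeed —
and four covariates: the square root of the pressure-IQR turbulence proxy,
the headwind component, mean climb rate and the square root of mean
altitude AGL.

Each response is modelled additively: penalized cubic B-spline smooths of
the covariates plus a per-flight random intercept (a ridge-penalized dummy
block, the classic mixed-model equivalence).  Every smooth carries a
second-order difference penalty plus a separate shrinkage penalty on its
whole coefficient block so that null effects shrink to flat rather than to
a free linear trend; smoothing parameters are chosen by GCV.  Effect sizes
are reported the way movement ecologists compare sub-models: the centred
partial effect of turbulence evaluated at the lowest and highest observed
turbulence, expressed as a percentage of the observed response range.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, optimize, stats

from .core_io import FlightRecord, TerrainGrid, ValidationError, WindRecord
from . import flightpath, kinematics, turbulence

logger = logging.getLogger(__name__)

RESPONSES = [
    "mean_altitude_agl",
    "tortuosity",
    "mean_wb_frequency",
    "mean_wb_amplitude",
    "mean_airspeed",
    "sd_wb_frequency",
    "sd_wb_amplitude",
    "sd_airspeed",
]
#: responses whose sub-models also get climb rate and altitude covariates
KINEMATIC_RESPONSES = [
    "mean_wb_frequency", "mean_wb_amplitude", "mean_airspeed",
    "sd_wb_frequency", "sd_wb_amplitude", "sd_airspeed",
]
BASE_COVARIATES = ["sqrt_turbulence", "hwc"]
EXTRA_COVARIATES = ["climb_rate", "sqrt_altitude_agl"]


def covariates_for(response: str) -> list[str]:
    cov = list(BASE_COVARIATES)
    if response in KINEMATIC_RESPONSES:
        cov += EXTRA_COVARIATES
    return cov


def segment_flight(
    flight_duration: float, window_s: float = 15.0, min_tail_s: float = 10.0
) -> tuple[list[tuple[float, float]], int]:
    """Contiguous windows from flight start; returns (bounds, n_excluded).

    The trailing partial window is kept iff it is at least ``min_tail_s``
    long, otherwise it is dropped and counted as excluded.
    """
    if flight_duration < min_tail_s:
        return [], 1
    n_full = int(flight_duration // window_s)
    bounds = [(i * window_s, (i + 1) * window_s) for i in range(n_full)]
    tail = flight_duration - n_full * window_s
    excluded = 0
    if tail >= min_tail_s:
        bounds.append((n_full * window_s, flight_duration))
    elif tail > 0:
        excluded = 1
    return bounds, excluded


def flight_products(
    record: FlightRecord,
    wind: WindRecord | None = None,
    terrain: TerrainGrid | float | None = None,
    min_prominence_g: float | None = 0.5,
    detrend_turbulence: bool = True,
) -> dict:
    """Run the single-flight stages feeding the segment table.

    ``terrain`` may be a grid, a constant ground elevation (m ASL), or None
    (ground taken at sea level).  Returns wingbeats, altitude (ASL and AGL),
    the 1 Hz climb-rate series and the per-step track table.
    """
    s = record.streams
    beats = kinematics.detect_wingbeats(
        s.accel, min_prominence_g=min_prominence_g, flight_id=record.flight_id
    )
    alt = flightpath.pressure_to_altitude(s.pressure, record.p0_sealevel_hpa)
    if isinstance(terrain, TerrainGrid):
        alt = flightpath.altitude_agl(alt, s.gps, terrain)
    else:
        ground = float(terrain) if terrain is not None else 0.0
        alt.altitude_agl = alt.altitude_asl - ground
    vz_t, vz = flightpath.climb_rate(alt)
    track = flightpath.track_steps(s.gps, wind)
    return {
        "record": record,
        "wingbeats": beats,
        "altitude": alt,
        "vz_time": vz_t,
        "vz": vz,
        "track": track,
        "detrend_turbulence": detrend_turbulence,
    }


def _seg_stats(values: np.ndarray) -> tuple[float, float]:
    v = values[np.isfinite(values)]
    if v.size == 0:
        return float("nan"), float("nan")
    return float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else float("nan")


def build_segment_table(products: list[dict]) -> pd.DataFrame:
    """Assemble the per-segment analysis table from per-flight products.

    Rows with any undefined response (fewer than two wingbeats, missing
    airspeed, degenerate tortuosity) are dropped with a logged reason, so
    the row count equals the segmentation output minus logged drops.
    """
    rows = []
    for prod in sorted(products, key=lambda p: p["record"].flight_id):
        rec: FlightRecord = prod["record"]
        s = rec.streams
        bounds, _ = segment_flight(rec.duration)
        beats = prod["wingbeats"]
        bt, bf, ba = beats.peak_times, beats.frequencies, beats.amplitudes
        alt = prod["altitude"]
        track = prod["track"]
        for i, (t0, t1) in enumerate(bounds):
            seg_id = f"{rec.flight_id}_s{i:03d}"
            try:
                ctx = turbulence.segment_turbulence(
                    s.pressure, t0, t1, seg_id, detrend=prod["detrend_turbulence"]
                )
            except turbulence.SegmentTooShortError as exc:
                logger.info("dropping %s: %s", seg_id, exc)
                continue
            in_beat = (bt >= t0) & (bt < t1)
            f_seg = bf[in_beat]
            a_seg = ba[in_beat]
            f_seg = f_seg[np.isfinite(f_seg)]
            if f_seg.size < 2 or a_seg.size < 2:
                logger.info("dropping %s: fewer than 2 wingbeats", seg_id)
                continue
            in_alt = (alt.time >= t0) & (alt.time < t1)
            in_vz = (prod["vz_time"] >= t0) & (prod["vz_time"] < t1)
            trk = track[(track["time"] >= t0) & (track["time"] < t1)]
            turns = trk["turning_angle"].dropna().to_numpy()
            air = trk["airspeed"].dropna().to_numpy()
            hwc = trk["hwc"].dropna().to_numpy()
            if turns.size < 2 or air.size < 2 or not in_alt.any() or not in_vz.any():
                logger.info("dropping %s: incomplete track/altitude coverage", seg_id)
                continue
            tort = flightpath.circular_sd(turns)
            mean_agl = float(alt.altitude_agl[in_alt].mean())
            if not np.isfinite(tort) or mean_agl < 0:
                logger.info("dropping %s: degenerate tortuosity or negative AGL", seg_id)
                continue
            mean_air, sd_air = _seg_stats(air)
            t_mid = 0.5 * (t0 + t1)
            rows.append({
                "segment_id": seg_id,
                "flight_id": rec.flight_id,
                "bird_id": rec.bird_id,
                "start_s": t0,
                "end_s": t1,
                "duration_s": t1 - t0,
                "mid_time_s": t_mid,
                "mid_lon": float(np.interp(t_mid, s.gps.time, s.gps.lon)),
                "mid_lat": float(np.interp(t_mid, s.gps.time, s.gps.lat)),
                "mean_altitude_agl": mean_agl,
                "tortuosity": float(tort),
                "mean_wb_frequency": float(f_seg.mean()),
                "sd_wb_frequency": float(f_seg.std(ddof=1)),
                "mean_wb_amplitude": float(a_seg.mean()),
                "sd_wb_amplitude": float(a_seg.std(ddof=1)),
                "mean_airspeed": mean_air,
                "sd_airspeed": sd_air,
                "turbulence_proxy": ctx.proxy,
                "sqrt_turbulence": ctx.sqrt_proxy,
                "hwc": float(hwc.mean()) if hwc.size else float("nan"),
                "climb_rate": float(prod["vz"][in_vz].mean()),
                "sqrt_altitude_agl": float(np.sqrt(mean_agl)),
                "n_wingbeats": int(a_seg.size),
            })
    table = pd.DataFrame(rows)
    need = RESPONSES + BASE_COVARIATES + EXTRA_COVARIATES
    if len(table):
        bad = ~np.isfinite(table[need].to_numpy()).all(axis=1)
        if bad.any():
            for sid in table.loc[bad, "segment_id"]:
                logger.info("dropping %s: undefined response/covariate", sid)
            table = table.loc[~bad].reset_index(drop=True)
    return table


def standardize_responses(
    table: pd.DataFrame, responses: list[str] | None = None
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Centre and scale each response to mean 0, SD 1; returns the scaled
    table and {response: (mean, sd)} for back-transformation."""
    responses = responses or RESPONSES
    out = table.copy()
    scale: dict[str, tuple[float, float]] = {}
    for r in responses:
        x = table[r].to_numpy(float)
        mu, sd = float(x.mean()), float(x.std(ddof=1))
        if sd == 0 or not np.isfinite(sd):
            raise ValidationError(f"response {r!r} has zero variance")
        out[r] = (x - mu) / sd
        scale[r] = (mu, sd)
    return out, scale


def boxcox_lambda(x, grid_lo: float = -2.0, grid_hi: float = 2.0,
                  step: float = 0.05) -> float:
    """Box–Cox λ maximizing the normal-errors profile likelihood on a grid."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValidationError("Box-Cox requires strictly positive data")
    grid = np.arange(grid_lo, grid_hi + step / 2, step)
    llf = np.array([stats.boxcox_llf(l, x) for l in grid])
    lam = float(grid[int(np.argmax(llf))])
    if lam in (grid[0], grid[-1]):
        warnings.warn(f"Box-Cox lambda hit the grid boundary at {lam}", stacklevel=2)
    return lam


# ---------------------------------------------------------------------------
# penalized additive fitter
# ---------------------------------------------------------------------------

@dataclass
class _Smooth:
    name: str
    knots: np.ndarray
    degree: int
    col_mean: np.ndarray
    sl: slice

    def basis(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, float), self.knots[self.degree],
                    self.knots[-self.degree - 1])
        B = interpolate.BSpline.design_matrix(x, self.knots, self.degree).toarray()
        return B - self.col_mean


def _spline_knots(x: np.ndarray, k: int, degree: int) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        hi = lo + 1e-8
    inner = np.linspace(lo, hi, k - degree + 1)
    return np.concatenate([[lo] * degree, inner, [hi] * degree])


@dataclass
class ModelFit:
    """One response sub-model: coefficients, smoothing parameters, centred
    partial-effect functions and fit diagnostics."""

    response: str
    covariates: list[str]
    boxcox: float | None
    coef: np.ndarray = field(repr=False)
    intercept: float
    smooths: dict[str, _Smooth] = field(repr=False)
    flight_levels: list[str]
    flight_sl: slice
    lambdas: np.ndarray
    edf: float
    sigma2: float
    random_intercept_var: float
    fitted: np.ndarray = field(repr=False)
    response_values: np.ndarray = field(repr=False)
    partial_centre: dict[str, float] = field(repr=False)
    deviance_explained: float
    ar1_rho: float = 0.0

    def partial_effect(self, covariate: str, x) -> np.ndarray:
        """Centred smooth contribution f_j(x) (mean 0 over the fitting data)."""
        sm = self.smooths[covariate]
        f = sm.basis(np.atleast_1d(np.asarray(x, float))) @ self.coef[sm.sl]
        return f - self.partial_centre[covariate]


def _design(table: pd.DataFrame, covariates: list[str], k: int, degree: int,
            smooths: dict[str, _Smooth] | None = None):
    """Centred spline blocks + flight dummy block.  Returns X, penalty list,
    smooth map, flight levels and the dummy slice."""
    n = len(table)
    cols = [np.ones((n, 1))]
    pen: list[tuple[np.ndarray, slice]] = []
    sm_map: dict[str, _Smooth] = {}
    pos = 1
    for cov in covariates:
        x = table[cov].to_numpy(float)
        if smooths is None:
            knots = _spline_knots(x, k, degree)
            B = interpolate.BSpline.design_matrix(
                np.clip(x, knots[degree], knots[-degree - 1]), knots, degree
            ).toarray()
            cm = B.mean(axis=0)
            sm = _Smooth(cov, knots, degree, cm, slice(pos, pos + B.shape[1]))
        else:
            sm = smooths[cov]
            sm = _Smooth(cov, sm.knots, sm.degree, sm.col_mean,
                         slice(pos, pos + sm.col_mean.size))
        Bc = sm.basis(x)
        cols.append(Bc)
        p = Bc.shape[1]
        D = np.diff(np.eye(p), n=2, axis=0)
        S = D.T @ D
        # normalize the wiggliness penalty and fold in a small identity
        # component so one lambda both smooths and (when large) shrinks the
        # whole block to flat — the select=TRUE-style null-space shrinkage
        S = S / np.linalg.norm(S, 2) + SHRINKAGE_EPS * np.eye(p)
        pen.append((S, sm.sl))
        sm_map[cov] = sm
        pos += p
    levels = sorted(table["flight_id"].unique().tolist())
    Z = (table["flight_id"].to_numpy()[:, None] == np.array(levels)[None, :]).astype(float)
    fl_sl = slice(pos, pos + len(levels))
    cols.append(Z)
    pen.append((np.eye(len(levels)), fl_sl))  # ridge == random intercept
    X = np.hstack(cols)
    return X, pen, sm_map, levels, fl_sl


def _penalty_matrix(pen, lambdas, p):
    S = np.zeros((p, p))
    for (Sj, sl), lam in zip(pen, lambdas):
        S[sl, sl] += lam * Sj
    return S


GCV_GAMMA = 1.4       # edf inflation guarding against GCV undersmoothing
SHRINKAGE_EPS = 0.05  # identity share of each smooth's penalty (null shrinkage)
_LOGLAM_BOUNDS = (-6.0, 16.0)


def _fit_penalized(X, y, pen, maxiter: int = 400):
    """GCV-optimal penalized least squares; returns beta, lambdas, edf, sigma2.

    One log-smoothing-parameter per penalty block, optimized by bounded
    Powell search on the GCV score (with the usual edf inflation gamma).
    Fully deterministic.
    """
    n, p = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    ridge = 1e-8 * np.eye(p)  # conditioning floor

    def solve(loglam):
        lam = np.exp(np.clip(loglam, *_LOGLAM_BOUNDS))
        A = XtX + _penalty_matrix(pen, lam, p) + ridge
        try:
            beta = np.linalg.solve(A, Xty)
            edf = float(np.trace(np.linalg.solve(A, XtX)))
        except np.linalg.LinAlgError:
            return None, None, np.inf
        rss = float(np.sum((y - X @ beta) ** 2))
        denom = max(n - GCV_GAMMA * edf, 1e-6)
        return beta, edf, n * rss / denom**2

    def gcv(loglam):
        return solve(loglam)[2]

    x0 = np.zeros(len(pen))
    res = optimize.minimize(
        gcv, x0, method="Powell",
        bounds=[_LOGLAM_BOUNDS] * len(pen),
        options={"maxiter": maxiter, "xtol": 0.02, "ftol": 1e-9},
    )
    beta, edf, _ = solve(res.x)
    rss = float(np.sum((y - X @ beta) ** 2))
    sigma2 = rss / max(len(y) - edf, 1.0)
    return beta, np.exp(np.clip(res.x, *_LOGLAM_BOUNDS)), edf, sigma2


def fit_response_model(
    table: pd.DataFrame,
    response: str,
    covariates: list[str] | None = None,
    k: int = 10,
    degree: int = 3,
    boxcox: float | None = None,
    ar1: bool = False,
) -> ModelFit:
    """Fit one response sub-model with penalized smooths and a flight
    random intercept.

    ``boxcox`` applies a Box–Cox transform to the response before fitting
    (the reported effects are then on the transformed scale).  ``ar1``
    adds one whitening pass: a lag-1 autocorrelation estimated from
    within-flight residuals, rows quasi-differenced, model refitted.
    The fit is deterministic: refitting the same table gives identical
    coefficients.
    """
    covariates = covariates if covariates is not None else covariates_for(response)
    if len(table) < 50:
        raise ValidationError("need at least 50 segments to fit")
    if table["flight_id"].nunique() < 3:
        raise ValidationError("need at least 3 flights for a random intercept")
    y = table[response].to_numpy(float)
    if boxcox is not None:
        y = stats.boxcox(y, lmbda=boxcox)
    cov_vals = table[covariates].to_numpy(float)
    corr = np.corrcoef(cov_vals, rowvar=False) if len(covariates) > 1 else np.eye(1)
    for i in range(len(covariates)):
        if np.std(cov_vals[:, i]) == 0:
            raise ValidationError(f"rank-deficient design: constant term {covariates[i]!r}")
        for j in range(i + 1, len(covariates)):
            if abs(corr[i, j]) > 0.9999:
                raise ValidationError(
                    "rank-deficient design: collinear terms "
                    f"{covariates[i]!r} and {covariates[j]!r}"
                )
    X, pen, sm_map, levels, fl_sl = _design(table, covariates, k, degree)
    beta, lambdas, edf, sigma2 = _fit_penalized(X, y, pen)

    rho = 0.0
    if ar1:
        resid = y - X @ beta
        order = table.sort_values(["flight_id", "start_s"]).index.to_numpy()
        fid = table["flight_id"].to_numpy()
        num = den = 0.0
        for f in levels:
            r = resid[order][fid[order] == f]
            if r.size > 2:
                num += float(np.dot(r[1:], r[:-1]))
                den += float(np.dot(r[:-1], r[:-1]))
        rho = num / den if den > 0 else 0.0
        rho = float(np.clip(rho, -0.95, 0.95))
        Xw, yw = X.copy(), y.copy()
        for f in levels:
            idx = order[fid[order] == f]
            Xw[idx[1:]] = X[idx[1:]] - rho * X[idx[:-1]]
            yw[idx[1:]] = y[idx[1:]] - rho * y[idx[:-1]]
        beta, lambdas, edf, sigma2 = _fit_penalized(Xw, yw, pen)

    fitted = X @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = float(np.sum((y - fitted) ** 2))
    lam_re = lambdas[-1]
    centres = {
        cov: float((sm_map[cov].basis(table[cov].to_numpy(float)) @ beta[sm_map[cov].sl]).mean())
        for cov in covariates
    }
    return ModelFit(
        response=response,
        covariates=covariates,
        boxcox=boxcox,
        coef=beta,
        intercept=float(beta[0]),
        smooths=sm_map,
        flight_levels=levels,
        flight_sl=fl_sl,
        lambdas=lambdas,
        edf=edf,
        sigma2=sigma2,
        random_intercept_var=float(sigma2 / lam_re) if lam_re > 0 else float("inf"),
        fitted=fitted,
        response_values=y,
        partial_centre=centres,
        deviance_explained=float(1.0 - rss / tss) if tss > 0 else float("nan"),
        ar1_rho=rho,
    )


@dataclass
class EffectSummary:
    """Partial effect of one covariate at its observed extremes, as a
    percentage of the observed response range (the effect-table row)."""

    response: str
    covariate: str
    response_range: float
    effect_at_min: float
    effect_at_max: float
    pct_at_min: float
    pct_at_max: float


def effect_range_percent(
    fit: ModelFit, covariate: str, table: pd.DataFrame
) -> EffectSummary:
    """Centred partial effect at the covariate's observed min and max,
    each divided by (response max − min) and reported in percent."""
    x = table[covariate].to_numpy(float)
    y = fit.response_values
    rng = float(y.max() - y.min())
    if rng <= 0:
        raise ValidationError("response range must be positive")
    e_min = float(fit.partial_effect(covariate, x.min())[0])
    e_max = float(fit.partial_effect(covariate, x.max())[0])
    return EffectSummary(fit.response, covariate, rng, e_min, e_max,
                         100.0 * e_min / rng, 100.0 * e_max / rng)


def fit_all_responses(
    table: pd.DataFrame, k: int = 10, ar1: bool = False,
    boxcox_map: dict[str, float] | None = None,
) -> dict[str, ModelFit]:
    """Fit the eight response sub-models with their assigned covariates."""
    boxcox_map = boxcox_map or {}
    return {
        r: fit_response_model(table, r, k=k, ar1=ar1, boxcox=boxcox_map.get(r))
        for r in RESPONSES
    }


def turbulence_effect_table(
    fits: dict[str, ModelFit], table: pd.DataFrame
) -> pd.DataFrame:
    """Effect-summary table: per response, the observed range and the
    turbulence partial effect at minimum and maximum turbulence as % of
    that range."""
    rows = []
    for r, fit in fits.items():
        s = effect_range_percent(fit, "sqrt_turbulence", table)
        rows.append({
            "response": r,
            "range_of_response": s.response_range,
            "pct_at_max_turbulence": s.pct_at_max,
            "pct_at_min_turbulence": s.pct_at_min,
        })
    return pd.DataFrame(rows)


def flapping_speed_regression(
    table: pd.DataFrame, subset: str = "ascent"
) -> tuple[float, float, int]:
    """Simple linear regression of segment flapping wing speed (mean
    frequency × mean amplitude) on the turbulence covariate, separately for
    ascents (Vz > 0) and descents (Vz < 0).  Returns (slope, p, df)."""
    if subset == "ascent":
        sub = table[table["climb_rate"] > 0]
    elif subset == "descent":
        sub = table[table["climb_rate"] < 0]
    else:
        raise ValueError("subset must be 'ascent' or 'descent'")
    if len(sub) < 3:
        raise ValidationError("too few segments in subset for regression")
    fws = sub["mean_wb_frequency"] * sub["mean_wb_amplitude"]
    res = stats.linregress(sub["sqrt_turbulence"], fws)
    return float(res.slope), float(res.pvalue), len(sub) - 2
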