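"""Synthetic mobile-sensor campaign generator.

Emulates a tram-borne ozone campaign: a handful of sensors ride fixed
back-and-forth routes through a city, sampling a latent ozone-like field
that is the sum of

* a deterministic diurnal mean µ(t) — a raised sinusoid peaking in the early
  afternoon, clipped at zero;
* a zero-mean Gaussian field Y(x, t) with a metric spatio-temporal
  variogram (bounded family), drawn jointly for all mobile sample points
  *and* the fixed station's sub-hourly samples from one dense covariance
  factorization, so the station series is a genuine functional of the same
  field;
* i.i.d. micro-scale noise with variance equal to the model nugget.

Each sensor then corrupts its readings with a per-sensor linear fault
(the inverse of the calibration model) plus measurement noise, yielding raw
ppb-scale observations; the fixed station reports hourly averages in µg/m³.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import cholesky
from scipy.spatial.distance import pdist, squareform

from .data import FixedStationSeries, ObservationSet
from .errors import (
    InvalidFaultError,
    InvalidInputError,
    InvalidRouteError,
    SimulationError,
)
from .variogram import VariogramModel

logger = logging.getLogger(__name__)

#: Maximum number of points in one dense covariance factorization.
DENSE_SOLVE_CAP = 4000


@dataclass
class RouteSpec:
    """A tram route: a polyline traversed back and forth at constant speed."""

    route_id: str
    polyline: np.ndarray  # (k, 2) vertices in meters
    speed: float = 8.0  # m/s
    sampling_interval: float = 20.0  # seconds

    def __post_init__(self) -> None:
        self.polyline = np.asarray(self.polyline, dtype=float)
        if self.polyline.ndim != 2 or self.polyline.shape[0] < 2 or self.polyline.shape[1] != 2:
            raise InvalidRouteError("polyline needs >= 2 (x, y) vertices")
        if not self.speed > 0:
            raise InvalidInputError("speed must be > 0")
        if not self.sampling_interval > 0:
            raise InvalidInputError("sampling_interval must be > 0")
        seg = np.diff(self.polyline, axis=0)
        self._seg_len = np.hypot(seg[:, 0], seg[:, 1])
        self.length = float(self._seg_len.sum())
        if self.length <= 0:
            raise InvalidRouteError(f"route {self.route_id!r} has zero length")
        self._cum = np.concatenate([[0.0], np.cumsum(self._seg_len)])

    def position(self, t) -> tuple[np.ndarray, np.ndarray]:
        """Position at elapsed time(s) t, bouncing between the endpoints."""
        t = np.asarray(t, dtype=float)
        u = np.mod(self.speed * t, 2.0 * self.length)
        s = np.where(u <= self.length, u, 2.0 * self.length - u)
        xs = np.interp(s, self._cum, self.polyline[:, 0])
        ys = np.interp(s, self._cum, self.polyline[:, 1])
        return xs, ys


@dataclass
class FieldSpec:
    """The latent ozone-like field: diurnal mean plus a Gaussian residual
    field with a known metric variogram.

    ``base`` and ``amplitude`` are in µg/m³; the mean is
    ``max(0, base + amplitude · cos(2π (hour − peak_hour) / 24))``.
    """

    base: float = 40.0
    amplitude: float = 25.0
    peak_hour: float = 14.0
    variogram: VariogramModel = field(
        default_factory=lambda: VariogramModel(
            "exponential", sill=60.0, nugget=2.0, range_=30000.0, K=100.0
        )
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise InvalidInputError("diurnal amplitude must be >= 0")
        if self.variogram.family not in ("spherical", "exponential"):
            raise InvalidInputError(
                "simulation requires a spherical or exponential variogram "
                "(bounded and positive definite in space-time)"
            )

    def mean(self, t) -> np.ndarray:
        """Diurnal mean µ(t); t in seconds since campaign start (epoch at
        midnight by convention)."""
        hour = (np.asarray(t, dtype=float) / 3600.0) % 24.0
        mu = self.base + self.amplitude * np.cos(
            2.0 * np.pi * (hour - self.peak_hour) / 24.0
        )
        return np.maximum(mu, 0.0)


@dataclass
class SensorFaultSpec:
    """True per-sensor linear fault: raw = (true − a*) / b* + noise."""

    additive: float = 0.0  # a*, µg/m³
    multiplicative: float = 1.0  # b*, dimensionless > 0
    noise_sd: float = 0.0  # raw-scale (ppb) measurement noise sd

    def __post_init__(self) -> None:
        if self.multiplicative == 0:
            raise InvalidFaultError("multiplicative bias b* must be nonzero")
        if not self.multiplicative > 0:
            raise InvalidFaultError("multiplicative bias b* must be > 0")
        if self.noise_sd < 0:
            raise InvalidInputError("noise sd must be >= 0")


def generate_trajectories(
    routes: list[RouteSpec], duration: float, *, t_start: float = 0.0
) -> pd.DataFrame:
    """Sample every route's back-and-forth trajectory over ``duration``.

    Returns a frame with columns sensor_id (= route id), x, y, t; each route
    contributes ``floor(duration / sampling_interval) + 1`` samples, all of
    which lie on the route polyline.
    """
    if not duration > 0:
        raise InvalidInputError("duration must be > 0")
    frames = []
    for route in routes:
        k = int(np.floor(duration / route.sampling_interval)) + 1
        elapsed = np.arange(k) * route.sampling_interval
        xs, ys = route.position(elapsed)
        frames.append(
            pd.DataFrame(
                {
                    "sensor_id": route.route_id,
                    "x": xs,
                    "y": ys,
                    "t": t_start + elapsed,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _simulate_gaussian(
    points: np.ndarray, model: VariogramModel, rng: np.random.Generator
) -> np.ndarray:
    """Draw the smooth field + nugget noise at (x, y, t) points.

    The smooth component uses C(d) = sill − gamma_continuous(d) on the metric
    distance; the nugget is added as i.i.d. micro-scale noise (not in the
    joint covariance off-diagonals). Cholesky with escalating diagonal
    jitter; simulation error after 3 escalations.
    """
    n = len(points)
    if n > DENSE_SOLVE_CAP:
        raise SimulationError(
            f"{n} points exceed the dense-solve cap {DENSE_SOLVE_CAP}; thin first"
        )
    smooth = np.zeros(n)
    if model.sill > 0:
        xyt = np.column_stack(
            [points[:, 0], points[:, 1], model.K * points[:, 2]]
        )
        d = squareform(pdist(xyt))
        # smooth (no-nugget) covariance: sill − gamma_continuous(d)
        cov = model.sill - (model.gamma_d(d) - np.where(d > 0, model.nugget, 0.0))
        jitter = 1e-10 * max(model.sill, 1.0)
        L = None
        for _ in range(4):
            try:
                L = cholesky(cov + jitter * np.eye(n), lower=True)
                break
            except np.linalg.LinAlgError:
                logger.warning("covariance factorization failed; jitter -> %g", jitter * 10)
                jitter *= 10.0
        if L is None:
            raise SimulationError("covariance factorization failed after jitter escalation")
        smooth = L @ rng.standard_normal(n)
    if model.nugget > 0:
        smooth = smooth + rng.normal(0.0, np.sqrt(model.nugget), n)
    return smooth


def simulate_field(
    points: pd.DataFrame | np.ndarray,
    spec: FieldSpec,
    *,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Latent field values µ(t) + Y(x, t) + nugget noise at the given points.

    ``points`` is an (n, 3) array or a frame with x, y, t columns.
    Reproducible under ``spec.seed`` when no generator is passed.
    """
    if isinstance(points, pd.DataFrame):
        pts = points[["x", "y", "t"]].to_numpy(dtype=float)
    else:
        pts = np.asarray(points, dtype=float)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    mu = spec.mean(pts[:, 2])
    if spec.variogram.sill == 0 and spec.variogram.nugget == 0:
        return mu
    return mu + _simulate_gaussian(pts, spec.variogram, rng)


def corrupt_sensors(
    latent: np.ndarray,
    sensor_ids: np.ndarray,
    faults: dict[str, SensorFaultSpec],
    *,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Invert the calibration model per sensor: X = (Z − a*) / b* + ε.

    ``ε ~ Normal(0, noise_sd)`` independently per sample; reproducible under
    the given generator or seed. Every sensor present must have a fault spec.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    latent = np.asarray(latent, dtype=float)
    sensor_ids = np.asarray(sensor_ids)
    out = np.empty_like(latent)
    for sid in pd.unique(sensor_ids):
        if sid not in faults:
            raise InvalidFaultError(f"no fault spec for sensor {sid!r}")
        f = faults[sid]
        m = sensor_ids == sid
        out[m] = (latent[m] - f.additive) / f.multiplicative
    noise_sd = np.array([faults[s].noise_sd for s in sensor_ids], dtype=float)
    if np.any(noise_sd > 0):
        out = out + rng.standard_normal(len(out)) * noise_sd
    return out


def station_series_from_field(
    spec: FieldSpec,
    station_xy: tuple[float, float],
    duration: float,
    *,
    per_hour: int = 6,
    rng: np.random.Generator | None = None,
    bbox: tuple[float, float, float, float] | None = None,
) -> FixedStationSeries:
    """Hourly station series from a (fresh) field draw at the station.

    Node k sits at t = 3600·k; its value is the mean of the latent field
    sampled on a fine sub-hour grid (``per_hour`` samples per hour) within
    the centered window [t − 1800, t + 1800] clipped to the campaign. For a
    joint draw with mobile points use :func:`simulate_campaign` instead.
    """
    if duration < 7200:
        raise InvalidInputError("station series needs duration >= 2 hours")
    if bbox is not None:
        x0, y0, x1, y1 = bbox
        if not (x0 <= station_xy[0] <= x1 and y0 <= station_xy[1] <= y1):
            logger.warning("station %s outside configured bounding box", station_xy)
    sub_t = _station_subgrid(duration, per_hour)
    pts = np.column_stack(
        [np.full(len(sub_t), station_xy[0]), np.full(len(sub_t), station_xy[1]), sub_t]
    )
    latent = simulate_field(pts, spec, rng=rng)
    times, values = _hourly_nodes(sub_t, latent, duration)
    return FixedStationSeries(x=station_xy[0], y=station_xy[1], times=times, values=values)


def _station_subgrid(duration: float, per_hour: int) -> np.ndarray:
    step = 3600.0 / per_hour
    return np.arange(0.0, duration + 0.5 * step, step)


def _hourly_nodes(sub_t: np.ndarray, latent: np.ndarray, duration: float):
    n_nodes = int(np.floor(duration / 3600.0)) + 1
    times = 3600.0 * np.arange(n_nodes)
    values = np.empty(n_nodes)
    for k, tk in enumerate(times):
        m = (sub_t >= tk - 1800.0) & (sub_t < tk + 1800.0)
        values[k] = latent[m].mean()
    return times, values


# ---------------------------------------------------------------------------
# Default campaign
# ---------------------------------------------------------------------------


def default_routes() -> list[RouteSpec]:
    """Four tram-like routes: 4–5 km polylines radiating from the center of
    a city whose maximum pairwise extent is ~10 km (city-scale, with
    cross-route separations from ~1 km downtown to ~10 km end to end)."""
    return [
        RouteSpec("line4", [(-5200.0, -800.0), (-2800.0, -300.0), (-800.0, 200.0)]),
        RouteSpec("line7", [(600.0, 300.0), (2600.0, 900.0), (4800.0, 1700.0)]),
        RouteSpec("line8", [(-500.0, 1200.0), (300.0, 3000.0), (1100.0, 5200.0)]),
        RouteSpec("line13", [(-900.0, -1000.0), (-100.0, -3000.0), (900.0, -5000.0)]),
    ]


#: Per-sensor fault defaults: additive/multiplicative biases of low-cost
#: ozone cells (b ~ 2 absorbs the ppb -> µg/m³ conversion) and raw-scale
#: noise chosen so the calibrated measurement-noise variance lands in the
#: few-(µg/m³)² range of typical fitted nuggets.
DEFAULT_FAULTS = {
    "line4": SensorFaultSpec(additive=4.0, multiplicative=1.9, noise_sd=0.75),
    "line7": SensorFaultSpec(additive=-2.0, multiplicative=2.1, noise_sd=0.75),
    "line8": SensorFaultSpec(additive=1.5, multiplicative=2.0, noise_sd=0.75),
    "line13": SensorFaultSpec(additive=-3.5, multiplicative=1.8, noise_sd=0.75),
}


@dataclass
class SamplingWindow:
    """One block of mobile sampling: start time, length (s), the sampling
    interval every route uses inside the block, and a per-route clock
    stagger (route i starts at ``start + i · stagger``) so that pairs of
    sensors realize diverse temporal lags instead of a single lag grid."""

    start: float
    length: float
    interval: float
    stagger: float = 17.0

    def __post_init__(self) -> None:
        if self.start < 0 or not self.length > 0 or not self.interval > 0:
            raise InvalidInputError("window needs start >= 0, length > 0, interval > 0")
        if self.stagger < 0:
            raise InvalidInputError("stagger must be >= 0")


def default_windows() -> list[SamplingWindow]:
    """Default mobile sampling: one full service day, 05:00–23:00, one
    sample per 75 s per route — the operating span that carries the whole
    diurnal ozone cycle (calibration and validation both need it), at the
    densest interval that keeps mobile + station points inside the joint
    Gaussian-draw cap."""
    return [SamplingWindow(start=5 * 3600.0, length=18 * 3600.0, interval=75.0)]


@dataclass
class CampaignSpec:
    """Everything needed to generate one synthetic campaign.

    The station reports hourly averages over the whole ``duration``
    (default two days); the trams sample inside ``windows``.
    """

    routes: list[RouteSpec] = field(default_factory=default_routes)
    field_spec: FieldSpec = field(default_factory=FieldSpec)
    faults: dict[str, SensorFaultSpec] = field(default_factory=lambda: dict(DEFAULT_FAULTS))
    duration: float = 86400.0  # station span, seconds
    windows: list[SamplingWindow] = field(default_factory=default_windows)
    station_xy: tuple[float, float] = (200.0, 100.0)
    station_per_hour: int = 6
    seed: int = 0

    @property
    def prediction_window(self) -> SamplingWindow:
        """The densest (smallest-interval) window: the prediction day."""
        return min(self.windows, key=lambda w: w.interval)


@dataclass
class Campaign:
    """A generated campaign: raw ppb observations, the calibrated-truth
    latent values, and the fixed-station hourly series."""

    raw: ObservationSet  # raw ppb mobile observations
    truth: ObservationSet  # latent µg/m³ values at the same points
    station: FixedStationSeries
    spec: CampaignSpec

    def prediction_subset(self, obs: ObservationSet) -> ObservationSet:
        """Restrict a set to the dense prediction-day window (the validation
        scenarios use only that day; the rest feeds variography)."""
        w = self.spec.prediction_window
        t = obs.df["t"].to_numpy()
        return obs.subset((t >= w.start) & (t <= w.start + w.length))


def simulate_campaign(spec: CampaignSpec | None = None, *, seed: int | None = None) -> Campaign:
    """Generate a full campaign with one joint Gaussian draw.

    Mobile trajectory points and the station's sub-hour points enter a single
    covariance factorization, so the station series carries the same field
    realization the sensors ride through. Trajectories whose total sample
    count would exceed the dense cap are stride-thinned per route.
    """
    spec = spec or CampaignSpec()
    if seed is not None:
        spec = replace(spec, field_spec=replace(spec.field_spec, seed=seed), seed=seed)
    frames = []
    for w in spec.windows:
        for i, route in enumerate(spec.routes):
            route_w = replace(route, sampling_interval=w.interval)
            frames.append(
                generate_trajectories(
                    [route_w], w.length, t_start=w.start + i * w.stagger
                )
            )
    traj = pd.concat(frames, ignore_index=True)

    sub_t = _station_subgrid(spec.duration, spec.station_per_hour)
    n_station = len(sub_t)
    budget = DENSE_SOLVE_CAP - n_station
    if len(traj) > budget:
        stride = int(np.ceil(len(traj) / budget))
        keep = traj.groupby("sensor_id").cumcount() % stride == 0
        traj = traj[keep].reset_index(drop=True)
        logger.warning("thinned trajectories by stride %d to fit the dense cap", stride)

    mobile_pts = traj[["x", "y", "t"]].to_numpy(dtype=float)
    station_pts = np.column_stack(
        [
            np.full(n_station, spec.station_xy[0]),
            np.full(n_station, spec.station_xy[1]),
            sub_t,
        ]
    )
    all_pts = np.vstack([mobile_pts, station_pts])
    rng = np.random.default_rng(spec.field_spec.seed)
    latent = simulate_field(all_pts, spec.field_spec, rng=rng)
    mobile_latent = latent[: len(mobile_pts)]
    station_latent = latent[len(mobile_pts) :]

    times, values = _hourly_nodes(sub_t, station_latent, spec.duration)
    station = FixedStationSeries(
        x=spec.station_xy[0], y=spec.station_xy[1], times=times, values=values
    )

    raw_values = corrupt_sensors(
        mobile_latent,
        traj["sensor_id"].to_numpy(),
        spec.faults,
        rng=rng,
    )
    ids = traj["sensor_id"].to_numpy()
    raw = ObservationSet.from_arrays(
        ids, traj["x"], traj["y"], traj["t"], raw_values, calibrated=False
    )
    truth = ObservationSet.from_arrays(
        ids, traj["x"], traj["y"], traj["t"], mobile_latent, calibrated=True
    )
    return Campaign(raw=raw, truth=truth, station=station, spec=spec)


def write_truth(truth: ObservationSet, path) -> None:
    """Truth CSV (sensor, point, latent µg/m³) for downstream evaluation."""
    truth.df.rename(columns={"value": "latent"}).to_csv(
        path, index=False, float_format="%.12g"
    )
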