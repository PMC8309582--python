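"""Shared data model and CSV readers/writers.

Conventions used throughout the package:

* coordinates are planar meters east (``x``) and north (``y``) of a
  configurable origin (lat/lon inputs are projected on read);
* time ``t`` is float seconds since the campaign epoch (the absolute
  timestamp of ``t = 0``); all temporal lags are in seconds;
* concentrations are µg/m³ once calibrated, ppb while raw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    ExtrapolationError,
    InvalidInputError,
    SchemaError,
)
from .geo import project_to_local
from .units import MOLECULAR_WEIGHT_O3, ppb_to_ugm3_factor

logger = logging.getLogger(__name__)

OBS_COLUMNS = ["sensor_id", "x", "y", "t", "value", "calibrated"]


@dataclass(frozen=True)
class Observation:
    """One sensed concentration at a space-time point."""

    sensor_id: str
    x: float  # meters east of the local origin
    y: float  # meters north of the local origin
    t: float  # seconds since campaign start
    value: float  # µg/m³ if calibrated, ppb if raw
    calibrated: bool = False


@dataclass
class ObservationSet:
    """An ordered collection of observations backed by a DataFrame.

    Rows are sorted by ``t`` (then ``sensor_id``); no two rows may share the
    same ``(sensor_id, t)``. Raw (uncalibrated) values are expected to be
    nonnegative; negatives are kept but counted and logged, since a linear
    sensor fault model can legitimately undershoot zero.
    """

    df: pd.DataFrame
    epoch: datetime | None = None  # absolute timestamp of t = 0 (UTC)
    origin: tuple[float, float] | None = None  # (lat, lon) of (x, y) = (0, 0)

    def __post_init__(self) -> None:
        missing = [c for c in OBS_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"observation frame missing columns: {missing}")
        df = self.df.loc[:, OBS_COLUMNS].copy()
        for col in ("x", "y", "t", "value"):
            df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        df["sensor_id"] = df["sensor_id"].astype(str)
        df["calibrated"] = df["calibrated"].astype(bool)
        num = df[["x", "y", "t", "value"]].to_numpy()
        if not np.all(np.isfinite(num)):
            raise InvalidInputError("x, y, t, value must all be finite")
        if np.any(df["t"].to_numpy() < 0):
            raise InvalidInputError("t must be >= 0 (seconds since campaign start)")
        if df.duplicated(subset=["sensor_id", "t"]).any():
            raise InvalidInputError("duplicate (sensor_id, t) observation")
        n_neg_raw = int(((~df["calibrated"]) & (df["value"] < 0)).sum())
        if n_neg_raw:
            logger.warning("observation set contains %d negative raw values", n_neg_raw)
        df = df.sort_values(["t", "sensor_id"], kind="mergesort").reset_index(drop=True)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sensors(self) -> list[str]:
        return sorted(self.df["sensor_id"].unique())

    @property
    def xyz(self) -> np.ndarray:
        """(n, 3) array of (x, y, t)."""
        return self.df[["x", "y", "t"]].to_numpy()

    @property
    def values(self) -> np.ndarray:
        return self.df["value"].to_numpy()

    def subset(self, mask_or_index) -> "ObservationSet":
        sub = self.df.loc[mask_or_index]
        return ObservationSet(sub.reset_index(drop=True), self.epoch, self.origin)

    def for_sensor(self, sensor_id: str) -> "ObservationSet":
        return self.subset(self.df["sensor_id"] == str(sensor_id))

    def with_values(self, values: np.ndarray, *, calibrated: bool | None = None) -> "ObservationSet":
        df = self.df.copy()
        df["value"] = np.asarray(values, dtype=float)
        if calibrated is not None:
            df["calibrated"] = bool(calibrated)
        return ObservationSet(df, self.epoch, self.origin)

    @staticmethod
    def from_arrays(
        sensor_id,
        x,
        y,
        t,
        value,
        *,
        calibrated: bool = False,
        epoch: datetime | None = None,
        origin: tuple[float, float] | None = None,
    ) -> "ObservationSet":
        n = len(np.atleast_1d(t))
        df = pd.DataFrame(
            {
                "sensor_id": np.broadcast_to(np.asarray(sensor_id, dtype=object), (n,)),
                "x": np.broadcast_to(np.asarray(x, dtype=float), (n,)),
                "y": np.broadcast_to(np.asarray(y, dtype=float), (n,)),
                "t": np.asarray(t, dtype=float),
                "value": np.asarray(value, dtype=float),
                "calibrated": np.full(n, bool(calibrated)),
            }
        )
        return ObservationSet(df, epoch, origin)


@dataclass
class FixedStationSeries:
    """Hourly reference series F(t) with linear interpolation between nodes.

    No extrapolation: querying outside the node span raises
    :class:`ExtrapolationError`; callers must clamp or exclude.
    """

    x: float
    y: float
    times: np.ndarray  # seconds since campaign start, strictly increasing
    values: np.ndarray  # µg/m³

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise InvalidInputError("station series needs >= 2 nodes")
        if self.times.size != self.values.size:
            raise InvalidInputError("times and values differ in length")
        if not np.all(np.diff(self.times) > 0):
            raise InvalidInputError("node times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("node values must be finite")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def covers(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (t >= self.times[0]) & (t <= self.times[-1])

    def interpolate(self, t):
        """Piecewise-linear F(t); exact at nodes; errors outside the span."""
        arr = np.asarray(t, dtype=float)
        if not np.all(self.covers(arr)):
            lo, hi = self.span
            raise ExtrapolationError(
                f"time outside station span [{lo}, {hi}]; no extrapolation"
            )
        out = np.interp(arr, self.times, self.values)
        return float(out) if np.isscalar(t) or arr.ndim == 0 else out


def interpolate_station(series: FixedStationSeries, t):
    """Functional alias for :meth:`FixedStationSeries.interpolate`."""
    return series.interpolate(t)


@dataclass
class GridSpec:
    """A regular prediction grid: lower-left corner, cell counts and size,
    plus the time slices to predict at. Cell centers sit at
    ``(x_min + (i + 0.5) * cell_size, y_min + (j + 0.5) * cell_size)``."""

    x_min: float
    y_min: float
    n_x: int
    n_y: int
    cell_size: float
    times: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_x < 1 or self.n_y < 1:
            raise InvalidInputError("grid needs n_x, n_y >= 1")
        if not self.cell_size > 0:
            raise InvalidInputError("cell_size must be > 0")
        self.times = [float(t) for t in self.times]
        if not self.times:
            raise InvalidInputError("grid needs at least one prediction time")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("grid times must be increasing")

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.x_min + (np.arange(self.n_x) + 0.5) * self.cell_size
        ys = self.y_min + (np.arange(self.n_y) + 0.5) * self.cell_size
        return xs, ys


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

#: Column mapping for OpenSense-style mobile ozone exports.
OPENSENSE_SCHEMA = {
    "sensor_id": "node_id",
    "timestamp": "utc_timestamp",
    "lat": "latitude",
    "lon": "longitude",
    "value": "ozone",
    "unit": None,  # OpenSense ozone is raw ppb with no unit column
}

_EPOCH_FMT = "%Y-%m-%dT%H:%M:%S.%f%z"


def _as_utc(dt: datetime) -> datetime:
    if dt.tzinfo is None:
        return dt.replace(tzinfo=timezone.utc)
    return dt.astimezone(timezone.utc)


def read_observations(
    path,
    *,
    columns: dict | None = None,
    epoch: datetime | None = None,
    origin: tuple[float, float] | None = None,
    convert_to_ugm3: bool = False,
    molecular_weight: float = MOLECULAR_WEIGHT_O3,
    default_unit: str = "ugm3",
) -> ObservationSet:
    """Read an observation CSV into an :class:`ObservationSet`.

    The file must have a header with ``sensor_id``, a timestamp column
    (ISO-8601 UTC) or a ``t`` seconds column, coordinates as ``x``/``y``
    meters or ``lat``/``lon`` degrees (projected using ``origin``), ``value``,
    and optionally ``unit`` in {``ppb``, ``ugm3``}. Malformed rows are
    dropped with a logged count. ``columns`` remaps header names
    (see :data:`OPENSENSE_SCHEMA` for the OpenSense preset).
    """
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"empty observation file: {path}") from None
    if raw.empty:
        raise EmptyInputError(f"no data rows in {path}")
    if columns:
        rename = {v: k for k, v in columns.items() if v is not None and v in raw.columns}
        raw = raw.rename(columns=rename)

    if "sensor_id" not in raw.columns or "value" not in raw.columns:
        raise SchemaError("observation CSV requires sensor_id and value columns")
    has_xy = "x" in raw.columns and "y" in raw.columns
    has_ll = "lat" in raw.columns and "lon" in raw.columns
    if not (has_xy or has_ll):
        raise SchemaError("observation CSV requires x/y or lat/lon columns")
    if not has_xy and origin is None:
        raise SchemaError("lat/lon input requires a projection origin")
    if "timestamp" not in raw.columns and "t" not in raw.columns:
        raise SchemaError("observation CSV requires a timestamp or t column")

    n_in = len(raw)
    df = pd.DataFrame()
    df["sensor_id"] = raw["sensor_id"].astype(str)
    df["value"] = pd.to_numeric(raw["value"], errors="coerce").astype(float)

    if "t" in raw.columns:
        df["t"] = pd.to_numeric(raw["t"], errors="coerce")
        if epoch is None and "timestamp" in raw.columns:
            ts = pd.to_datetime(raw["timestamp"], errors="coerce", utc=True)
            if ts.notna().any():
                first = ts[ts.notna()].iloc[0]
                epoch = _as_utc(first.to_pydatetime()) - pd.Timedelta(
                    seconds=float(df["t"][ts.notna()].iloc[0])
                )
    else:
        ts = pd.to_datetime(raw["timestamp"], errors="coerce", utc=True)
        if epoch is None:
            if ts.notna().any():
                epoch = _as_utc(ts.min().to_pydatetime())
            else:
                raise SchemaError("no parsable timestamps to derive an epoch from")
        df["t"] = (ts - pd.Timestamp(_as_utc(epoch))).dt.total_seconds()

    if has_xy:
        df["x"] = pd.to_numeric(raw["x"], errors="coerce")
        df["y"] = pd.to_numeric(raw["y"], errors="coerce")
    else:
        lat = pd.to_numeric(raw["lat"], errors="coerce")
        lon = pd.to_numeric(raw["lon"], errors="coerce")
        ok = lat.notna() & lon.notna()
        x = np.full(n_in, np.nan)
        y = np.full(n_in, np.nan)
        if ok.any():
            x[ok.to_numpy()], y[ok.to_numpy()] = project_to_local(
                lat[ok].to_numpy(), lon[ok].to_numpy(), origin
            )
        df["x"], df["y"] = x, y

    unit = (
        raw["unit"].astype(str).str.lower()
        if "unit" in raw.columns
        else pd.Series([default_unit] * n_in)
    )
    is_ppb = unit.eq("ppb").to_numpy()
    calibrated = ~is_ppb
    if convert_to_ugm3 and is_ppb.any():
        factor = ppb_to_ugm3_factor(molecular_weight)
        df.loc[is_ppb, "value"] = df.loc[is_ppb, "value"] * factor
        calibrated = np.full(n_in, True)
    df["calibrated"] = calibrated

    good = df[["x", "y", "t", "value"]].notna().all(axis=1) & (df["t"] >= 0)
    n_dropped = int(n_in - good.sum())
    if n_dropped:
        logger.warning("dropped %d malformed rows while reading %s", n_dropped, path)
    df = df[good].reset_index(drop=True)
    if df.empty:
        raise EmptyInputError(f"no valid observations in {path}")
    return ObservationSet(df, epoch=epoch, origin=origin)


def write_observations(obs: ObservationSet, path) -> None:
    """Write an observation CSV that round-trips through
    :func:`read_observations` (values to 1e-9)."""
    df = obs.df.copy()
    out = pd.DataFrame()
    out["sensor_id"] = df["sensor_id"]
    if obs.epoch is not None:
        ts = pd.Timestamp(_as_utc(obs.epoch)) + pd.to_timedelta(df["t"], unit="s")
        out["timestamp"] = ts.dt.strftime("%Y-%m-%dT%H:%M:%S.%fZ")
    out["t"] = df["t"]
    out["x"] = df["x"]
    out["y"] = df["y"]
    out["value"] = df["value"]
    out["unit"] = np.where(df["calibrated"], "ugm3", "ppb")
    out.to_csv(path, index=False, float_format="%.12g")


def read_station(
    path,
    *,
    x: float = 0.0,
    y: float = 0.0,
    epoch: datetime | None = None,
) -> FixedStationSeries:
    """Read a fixed-station CSV (columns ``timestamp`` or ``t``, ``value``)."""
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"empty station file: {path}") from None
    if "value" not in raw.columns:
        raise SchemaError("station CSV requires a value column")
    if "t" in raw.columns:
        t = pd.to_numeric(raw["t"], errors="coerce").to_numpy()
    elif "timestamp" in raw.columns:
        ts = pd.to_datetime(raw["timestamp"], errors="coerce", utc=True)
        if epoch is None:
            epoch = _as_utc(ts.min().to_pydatetime())
        t = (ts - pd.Timestamp(_as_utc(epoch))).dt.total_seconds().to_numpy()
    else:
        raise SchemaError("station CSV requires a timestamp or t column")
    v = pd.to_numeric(raw["value"], errors="coerce").to_numpy()
    good = np.isfinite(t) & np.isfinite(v)
    n_dropped = int(len(raw) - good.sum())
    if n_dropped:
        logger.warning("dropped %d malformed station rows from %s", n_dropped, path)
    return FixedStationSeries(x=x, y=y, times=t[good], values=v[good])


def write_station(series: FixedStationSeries, path) -> None:
    pd.DataFrame({"t": series.times, "value": series.values}).to_csv(
        path, index=False, float_format="%.12g"
    )
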