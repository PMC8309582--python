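"""Per-sensor linear calibration against the fixed reference station.

Each low-cost sensor i is assumed to read the true concentration through a
linear distortion, Z_i = a_i + b_i · X_i, where X_i is the raw ppb signal.
The coefficients are estimated per sensor by ordinary least squares of the
interpolated station value F(t) on the sensor's raw readings,

    F(t) = a_i + b_i · X_i(t) + ε,

using all of the sensor's data across all days (one fit per sensor), and the
same (a_i, b_i) are then applied as Z_i = a_i + b_i · X_i. The additive term
forces each sensor's mean toward the station mean; this is intrinsic to the
scheme and is kept as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import FixedStationSeries, ObservationSet
from .errors import (
    DegenerateRegressorError,
    InsufficientDataError,
    MissingCalibrationError,
)

logger = logging.getLogger(__name__)


@dataclass
class CalibrationCoefficients:
    """OLS calibration for one sensor."""

    sensor_id: str
    a: float  # additive bias, µg/m³
    b: float  # multiplicative bias, dimensionless
    n_points: int
    residual_sd: float  # µg/m³

    def apply(self, raw):
        return self.a + self.b * np.asarray(raw, dtype=float)


def fit_calibration(
    obs: ObservationSet, station: FixedStationSeries, *, sensor_id: str | None = None
) -> CalibrationCoefficients:
    """Fit (a, b) for one sensor by OLS of F(t) on the raw values.

    Observations outside the station's span are excluded (no extrapolation)
    with a logged count. Raises if fewer than 2 usable points remain or the
    raw values have zero variance.
    """
    sub = obs if sensor_id is None else obs.for_sensor(sensor_id)
    sensors = sub.df["sensor_id"].unique()
    if len(sensors) != 1:
        raise InsufficientDataError(
            "fit_calibration works on a single sensor; got "
            f"{sorted(map(str, sensors))} (use fit_all_sensors)"
        )
    sid = str(sensors[0])
    t = sub.df["t"].to_numpy()
    inside = station.covers(t)
    n_out = int((~inside).sum())
    if n_out:
        logger.warning("sensor %s: %d observations outside station span excluded", sid, n_out)
    x = sub.values[inside]
    tt = t[inside]
    if len(x) < 2:
        raise InsufficientDataError(f"sensor {sid}: <2 usable points inside station span")
    if np.ptp(x) == 0:
        raise DegenerateRegressorError(f"sensor {sid}: raw values all equal")
    f = station.interpolate(tt)

    xm, fm = x.mean(), f.mean()
    sxx = float(np.sum((x - xm) ** 2))
    b = float(np.sum((x - xm) * (f - fm)) / sxx)
    a = float(fm - b * xm)
    resid = f - (a + b * x)
    dof = max(len(x) - 2, 1)
    return CalibrationCoefficients(
        sensor_id=sid,
        a=a,
        b=b,
        n_points=int(len(x)),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
    )


def fit_all_sensors(
    obs: ObservationSet, station: FixedStationSeries
) -> dict[str, CalibrationCoefficients]:
    """One independent OLS fit per sensor present in the set."""
    return {sid: fit_calibration(obs.for_sensor(sid), station) for sid in obs.sensors}


def apply_calibration(
    obs: ObservationSet, coefficients: dict[str, CalibrationCoefficients]
) -> ObservationSet:
    """Z = a + b · X per sensor; order and count preserved, flag set."""
    missing = [s for s in obs.sensors if s not in coefficients]
    if missing:
        raise MissingCalibrationError(f"no coefficients for sensors: {missing}")
    values = obs.values.copy()
    ids = obs.df["sensor_id"].to_numpy()
    for sid, coef in coefficients.items():
        m = ids == sid
        values[m] = coef.apply(values[m])
    return obs.with_values(values, calibrated=True)


def write_coefficients(coeffs: dict[str, CalibrationCoefficients], path) -> None:
    pd.DataFrame(
        [
            {
                "sensor_id": c.sensor_id,
                "a": c.a,
                "b": c.b,
                "n_points": c.n_points,
                "residual_sd": c.residual_sd,
            }
            for c in coeffs.values()
        ]
    ).to_csv(path, index=False, float_format="%.12g")


def read_coefficients(path) -> dict[str, CalibrationCoefficients]:
    df = pd.read_csv(path)
    out = {}
    for row in df.itertuples(index=False):
        out[str(row.sensor_id)] = CalibrationCoefficients(
            sensor_id=str(row.sensor_id),
            a=float(row.a),
            b=float(row.b),
            n_points=int(row.n_points),
            residual_sd=float(row.residual_sd),
        )
    return out
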