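"""Spatio-temporal variography with a metric anisotropy model.

The package models the semivariance of the (residual) concentration field
with a *metric* spatio-temporal variogram

    gamma(h, u) = gamma_joint( sqrt(h² + (K·u)²) )

where ``h`` is the spatial lag in meters, ``u`` the temporal lag in seconds,
and ``K`` (m/s) the spatio-temporal anisotropy: the number of space units
equivalent to one time unit. ``gamma_joint`` is a bounded one-dimensional
family (spherical, exponential with practical range, or bounded-linear:
linear up to the range, flat after) with a partial sill above a nugget.

Empirical variograms are accumulated on a rectangular (spatial x temporal)
bin grid from all point pairs within configurable lag limits; model
parameters (sill, nugget, range, K) are then fitted by bound-constrained
quasi-Newton (L-BFGS-B) least squares on the bin surface, with multistart.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.distance import pdist

from .data import FixedStationSeries, ObservationSet
from .errors import (
    EmptyVariogramError,
    FitFailureError,
    InsufficientDataError,
    InvalidInputError,
)

logger = logging.getLogger(__name__)

FAMILIES = ("spherical", "exponential", "bounded_linear")


def _shape(family: str, d: np.ndarray, range_: float) -> np.ndarray:
    """Normalized variogram shape g(d) in [0, 1]."""
    if family == "spherical":
        q = np.minimum(d / range_, 1.0)
        return 1.5 * q - 0.5 * q**3
    if family == "exponential":
        return 1.0 - np.exp(-3.0 * d / range_)  # practical range
    if family == "bounded_linear":
        return np.minimum(d / range_, 1.0)
    raise InvalidInputError(f"unknown variogram family: {family!r}")


@dataclass
class VariogramModel:
    """A metric spatio-temporal variogram model.

    Parameters
    ----------
    family:
        One of ``spherical``, ``exponential``, ``bounded_linear``.
    sill:
        Partial sill above the nugget, (µg/m³)².
    nugget:
        Nugget, (µg/m³)²; the limit of gamma from above at zero lag
        (gamma(0, 0) itself is exactly 0).
    range_:
        Range in metric distance, meters. For the exponential family this is
        the *practical* range (factor 3 inside the exponent).
    K:
        Spatio-temporal anisotropy, meters per second.
    """

    family: str
    sill: float
    nugget: float
    range_: float
    K: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise InvalidInputError(f"unknown variogram family: {self.family!r}")
        if self.sill < 0 or self.nugget < 0:
            raise InvalidInputError("sill and nugget must be >= 0")
        if not self.range_ > 0:
            raise InvalidInputError("range must be > 0")
        if not self.K > 0:
            raise InvalidInputError("K must be > 0")

    def metric_distance(self, h, u) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        u = np.asarray(u, dtype=float)
        return np.sqrt(h**2 + (self.K * u) ** 2)

    def evaluate(self, h, u):
        """gamma(h, u); exactly 0 at (0, 0), nugget + sill·g(d) for d > 0."""
        h_arr = np.asarray(h, dtype=float)
        u_arr = np.asarray(u, dtype=float)
        if np.any(h_arr < 0) or np.any(u_arr < 0):
            raise InvalidInputError("lags must be nonnegative")
        out = self.gamma_d(self.metric_distance(h_arr, u_arr))
        return float(out) if out.ndim == 0 else out

    def gamma_d(self, d) -> np.ndarray:
        """gamma as a function of metric distance (0 at d = 0)."""
        d = np.asarray(d, dtype=float)
        return np.where(d > 0, self.nugget + self.sill * _shape(self.family, d, self.range_), 0.0)

    def gamma_point(self, d) -> np.ndarray:
        """Limit-from-above semivariance to a *target* point: nugget at d = 0.

        Used for the data-to-target vector of the kriging systems so that a
        positive nugget smooths (the estimator filters micro-scale noise)
        while a zero nugget keeps kriging exact at data locations.
        """
        d = np.asarray(d, dtype=float)
        return self.nugget + self.sill * _shape(self.family, d, self.range_)

    def covariance(self, d) -> np.ndarray:
        """C(d) = (sill + nugget) − gamma(d) (bounded families only)."""
        return (self.sill + self.nugget) - self.gamma_d(np.asarray(d, dtype=float))

    @property
    def total_sill(self) -> float:
        return self.sill + self.nugget

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "sill": self.sill,
            "nugget": self.nugget,
            "range": self.range_,
            "K": self.K,
        }

    @staticmethod
    def from_dict(d: dict) -> "VariogramModel":
        return VariogramModel(
            family=d["family"],
            sill=float(d["sill"]),
            nugget=float(d["nugget"]),
            range_=float(d.get("range", d.get("range_"))),
            K=float(d["K"]),
        )


def evaluate_model(model: VariogramModel, h, u):
    """Functional alias for :meth:`VariogramModel.evaluate`."""
    return model.evaluate(h, u)


# ---------------------------------------------------------------------------
# Empirical variogram
# ---------------------------------------------------------------------------


@dataclass
class EmpiricalVariogram:
    """Binned sample semivariances on a (spatial x temporal) lag grid."""

    spatial_edges: np.ndarray  # meters, strictly increasing, starts at 0
    temporal_edges: np.ndarray  # seconds
    gamma: np.ndarray  # (n_s, n_t) mean semivariance per bin; NaN if empty
    counts: np.ndarray  # (n_s, n_t) pair counts
    meta: dict = field(default_factory=dict)

    @property
    def spatial_centers(self) -> np.ndarray:
        e = self.spatial_edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def temporal_centers(self) -> np.ndarray:
        e = self.temporal_edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def nonempty(self) -> np.ndarray:
        return self.counts > 0

    def temporal_margin(self) -> tuple[np.ndarray, np.ndarray]:
        """Pair-weighted mean gamma per temporal bin (over all spatial bins)."""
        w = self.counts.astype(float)
        g = np.where(self.nonempty, self.gamma, 0.0)
        tot = w.sum(axis=0)
        marg = np.where(tot > 0, (g * w).sum(axis=0) / np.maximum(tot, 1.0), np.nan)
        return self.temporal_centers, marg


def _max_pairwise_distance(xy: np.ndarray) -> float:
    """Diameter of the point set (meters); via the convex hull when large."""
    if len(xy) < 2:
        return 0.0
    if len(xy) <= 500:
        return float(pdist(xy).max())
    try:
        from scipy.spatial import ConvexHull

        hull = xy[np.unique(ConvexHull(xy).vertices)]
        return float(pdist(hull).max())
    except Exception:  # collinear/degenerate clouds
        sub = xy[:: max(1, len(xy) // 2000)]
        return float(pdist(sub).max())


def _direction_mask(dx: np.ndarray, dy: np.ndarray, axis: str, tol: float) -> np.ndarray:
    """Pairs whose displacement azimuth is within ``tol`` degrees of an axis.

    The azimuth is folded into [0°, 90°] from north (axes are undirected).
    Ties exactly on the 45° diagonal go to east-west, and pairs with zero
    spatial displacement (undefined azimuth) go to north-south, so that with
    ``tol = 45`` the two axes exactly partition all pairs.
    """
    zero = (dx == 0.0) & (dy == 0.0)
    az = np.degrees(np.arctan2(np.abs(dx), np.abs(dy)))  # 0 = N-S, 90 = E-W
    if axis in ("ns", "north-south", "north_south"):
        keep = (az <= tol) & (az != 45.0)
        return keep | zero
    if axis in ("ew", "east-west", "east_west"):
        keep = (90.0 - az) <= tol
        return keep & ~zero
    raise InvalidInputError(f"unknown direction axis: {axis!r}")


def empirical_variogram(
    obs: ObservationSet,
    *,
    n_spatial_bins: int = 12,
    n_temporal_bins: int = 12,
    max_spatial_lag: float | None = None,
    max_temporal_lag: float | None = None,
    direction: str | None = None,
    tolerance: float = 45.0,
    chunk: int = 256,
) -> EmpiricalVariogram:
    """Accumulate the sample spatio-temporal variogram surface.

    For every unordered pair within the lag limits (and, if ``direction`` is
    given, whose displacement azimuth is within ``tolerance`` of that axis),
    ``(z_i − z_j)² / 2`` is accumulated into the equal-width bin of
    ``(|Δspace|, |Δtime|)``. ``max_spatial_lag`` defaults to half the maximum
    pairwise spatial distance (beyond which pair counts thin out);
    ``max_temporal_lag`` defaults to half the temporal span, but should
    normally be set manually — see :func:`suggest_temporal_cutoff`.
    """
    if len(obs) < 2:
        raise InsufficientDataError("variogram needs >= 2 observations")
    if n_spatial_bins < 1 or n_temporal_bins < 1:
        raise InvalidInputError("bin counts must be >= 1")
    x = obs.df["x"].to_numpy()
    y = obs.df["y"].to_numpy()
    t = obs.df["t"].to_numpy()
    z = obs.df["value"].to_numpy()
    n = len(x)

    if max_spatial_lag is None:
        max_spatial_lag = 0.5 * _max_pairwise_distance(np.column_stack([x, y]))
        if max_spatial_lag <= 0:
            max_spatial_lag = 1.0
    if max_temporal_lag is None:
        span = float(t.max() - t.min())
        max_temporal_lag = 0.5 * span if span > 0 else 1.0

    s_edges = np.linspace(0.0, float(max_spatial_lag), n_spatial_bins + 1)
    t_edges = np.linspace(0.0, float(max_temporal_lag), n_temporal_bins + 1)
    sums = np.zeros((n_spatial_bins, n_temporal_bins))
    counts = np.zeros((n_spatial_bins, n_temporal_bins), dtype=np.int64)

    s_width = s_edges[1] - s_edges[0]
    t_width = t_edges[1] - t_edges[0]
    for i in range(n - 1):
        dx = x[i + 1 :] - x[i]
        dy = y[i + 1 :] - y[i]
        hs = np.hypot(dx, dy)
        us = np.abs(t[i + 1 :] - t[i])
        keep = (hs <= max_spatial_lag) & (us <= max_temporal_lag)
        if direction is not None:
            keep &= _direction_mask(dx, dy, direction, tolerance)
        if not keep.any():
            continue
        si = np.minimum((hs[keep] / s_width).astype(np.int64), n_spatial_bins - 1)
        ti = np.minimum((us[keep] / t_width).astype(np.int64), n_temporal_bins - 1)
        sq = 0.5 * (z[i + 1 :][keep] - z[i]) ** 2
        np.add.at(sums, (si, ti), sq)
        np.add.at(counts, (si, ti), 1)

    if counts.sum() == 0:
        raise EmptyVariogramError("no pairs within the lag limits")
    gamma = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return EmpiricalVariogram(
        spatial_edges=s_edges,
        temporal_edges=t_edges,
        gamma=gamma,
        counts=counts,
        meta={
            "max_spatial_lag": float(max_spatial_lag),
            "max_temporal_lag": float(max_temporal_lag),
            "direction": direction,
            "tolerance": float(tolerance) if direction else None,
            "n_obs": n,
        },
    )


def directional_pair(
    obs: ObservationSet,
    axis: str,
    *,
    tolerance: float = 45.0,
    **kwargs,
) -> EmpiricalVariogram:
    """Directional variogram restricted to the north-south or east-west axis."""
    return empirical_variogram(obs, direction=axis, tolerance=tolerance, **kwargs)


def suggest_temporal_cutoff(
    obs: ObservationSet,
    *,
    candidates=None,
    n_bins: int = 12,
    rel_slope: float = 0.05,
) -> float:
    """Suggest the smallest temporal lag limit at which the temporal margin
    of the variogram stops increasing (relative slope < ``rel_slope`` per
    bin over the last bins) — mechanizing the rule of increasing the cutoff
    step by step until a sill appears. Advisory only; the config decides.
    """
    t = obs.df["t"].to_numpy()
    span = float(t.max() - t.min())
    if candidates is None:
        candidates = span * np.array([0.05, 0.1, 0.2, 0.3, 0.5])
    candidates = np.sort(np.asarray(candidates, dtype=float))
    for cut in candidates:
        if cut <= 0:
            continue
        try:
            emp = empirical_variogram(obs, n_temporal_bins=n_bins, max_temporal_lag=cut)
        except EmptyVariogramError:
            continue
        _, marg = emp.temporal_margin()
        tail = marg[~np.isnan(marg)][-3:]
        if len(tail) >= 2:
            scale = float(np.nanmax(np.abs(marg))) or 1.0
            if np.all(np.diff(tail) / scale < rel_slope):
                return float(cut)
    return float(candidates[-1])


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Outcome of a multistart bound-constrained variogram fit."""

    model: VariogramModel
    objective: float  # mean squared deviation over nonempty bins
    status: str
    n_starts: int
    starts: list[dict] = field(default_factory=list)
    meta: dict = field(default_factory=dict)


def default_bounds(emp: EmpiricalVariogram) -> dict:
    """Default parameter bounds for fitting: sill/nugget in [0, 10x the
    empirical gamma scale], range in [10 m, 10x the maximum spatio-temporal
    lag extent], K in [0.1, 1e4] m/s."""
    g = emp.gamma[emp.nonempty]
    scale = max(float(np.nanmax(g)) if g.size else 1.0, 1e-12)
    max_h = float(emp.spatial_edges[-1])
    max_u = float(emp.temporal_edges[-1])
    # the largest metric lag representable on the bin grid at moderate K
    extent = max(max_h, float(np.hypot(max_h, 1e3 * max_u)) / 1e1)
    return {
        "sill": (0.0, 10.0 * scale),
        "nugget": (0.0, 10.0 * scale),
        "range": (10.0, 10.0 * extent),
        "K": (0.1, 1e4),
    }


def fit_metric_model(
    emp: EmpiricalVariogram,
    family: str = "exponential",
    *,
    bounds: dict | None = None,
    n_starts: int = 8,
    seed: int = 0,
    weighted: bool = False,
) -> FitResult:
    """Fit (sill, nugget, range, K) to the empirical surface.

    Minimizes the (by default unweighted) mean over nonempty bins of the
    squared deviation between the sample semivariance at the bin center and
    the model, by L-BFGS-B from ``n_starts`` jittered initializations; the
    best solution over all starts is returned. A pair-count-weighted
    objective is available via ``weighted`` but is off by default.
    """
    mask = emp.nonempty
    n_bins = int(mask.sum())
    if n_bins < 4:
        raise InsufficientDataError(
            f"need >= 4 nonempty bins to fit 4 parameters, got {n_bins}"
        )
    hc, uc = np.meshgrid(emp.spatial_centers, emp.temporal_centers, indexing="ij")
    h = hc[mask]
    u = uc[mask]
    g = emp.gamma[mask]
    w = emp.counts[mask].astype(float) if weighted else np.ones(n_bins)
    w = w / w.sum()

    b = default_bounds(emp)
    if bounds:
        b.update(bounds)
    lo = np.array([b["sill"][0], b["nugget"][0], b["range"][0], b["K"][0]])
    hi = np.array([b["sill"][1], b["nugget"][1], b["range"][1], b["K"][1]])

    def objective(theta: np.ndarray) -> float:
        sill, nugget, range_, K = theta
        d = np.sqrt(h**2 + (K * u) ** 2)
        resid = g - (nugget + sill * _shape(family, d, max(range_, 1e-9)))
        return float(np.sum(w * resid**2))

    rng = np.random.default_rng(seed)
    g_scale = float(np.nanmax(g))
    max_h = float(emp.spatial_edges[-1])
    max_u = float(emp.temporal_edges[-1])
    heuristic = np.array(
        [
            max(g_scale - float(np.nanmin(g)), 0.1 * g_scale),
            max(float(np.nanmin(g)), 1e-6),
            max(0.5 * max_h, b["range"][0]),
            np.clip(max_h / max(max_u, 1e-9), b["K"][0], b["K"][1]),
        ]
    )
    starts = [np.clip(heuristic, lo, hi)]
    lo_pos = np.where(lo > 0, lo, np.minimum(1e-6, hi / 1e6))
    for _ in range(max(0, n_starts - 1)):
        starts.append(
            np.exp(rng.uniform(np.log(lo_pos), np.log(np.maximum(hi, lo_pos * 1.001))))
        )

    best = None
    records: list[dict] = []
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            options={"maxiter": 1000, "ftol": 1e-15, "gtol": 1e-13},
        )
        records.append(
            {
                "x0": x0.tolist(),
                "x": res.x.tolist(),
                "fun": float(res.fun),
                "success": bool(res.success),
            }
        )
        if np.all(np.isfinite(res.x)) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitFailureError(f"all {len(starts)} starts failed: {records}")

    sill, nugget, range_, K = np.clip(best.x, lo, hi)
    model = VariogramModel(
        family, float(sill), float(nugget), float(max(range_, 1e-9)), float(K)
    )
    return FitResult(
        model=model,
        objective=float(best.fun),
        status="converged" if best.success else "max-iterations",
        n_starts=len(starts),
        starts=records,
        meta={"weighted": weighted, "exponential_range_is_practical": True},
    )


# ---------------------------------------------------------------------------
# Residual helpers (which field each kriging variant models)
# ---------------------------------------------------------------------------


def subtract_station(obs: ObservationSet, station: FixedStationSeries) -> ObservationSet:
    """Residuals Z − F(t): the field simple kriging models (known mean F)."""
    inside = station.covers(obs.df["t"].to_numpy())
    if not inside.all():
        logger.warning(
            "excluding %d observations outside the station span", int((~inside).sum())
        )
    sub = obs.subset(inside)
    f = station.interpolate(sub.df["t"].to_numpy())
    return sub.with_values(sub.values - f)


def estimated_drift_residuals(
    obs: ObservationSet, station: FixedStationSeries
) -> ObservationSet:
    """Residuals of the OLS fit Z ~ 1 + F(t): the field KED variography uses."""
    inside = station.covers(obs.df["t"].to_numpy())
    sub = obs.subset(inside)
    f = station.interpolate(sub.df["t"].to_numpy())
    A = np.column_stack([np.ones(len(sub)), f])
    coef, *_ = np.linalg.lstsq(A, sub.values, rcond=None)
    return sub.with_values(sub.values - A @ coef)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def write_empirical(emp: EmpiricalVariogram, path) -> None:
    hc, uc = np.meshgrid(emp.spatial_centers, emp.temporal_centers, indexing="ij")
    pd.DataFrame(
        {
            "h_center": hc.ravel(),
            "u_center": uc.ravel(),
            "gamma": emp.gamma.ravel(),
            "count": emp.counts.ravel(),
        }
    ).to_csv(path, index=False, float_format="%.12g")


def write_model(fit: FitResult, path) -> None:
    payload = fit.model.to_dict() | {
        "objective": fit.objective,
        "status": fit.status,
        "n_starts": fit.n_starts,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_model(path) -> VariogramModel:
    with open(path) as fh:
        return VariogramModel.from_dict(json.load(fh))
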