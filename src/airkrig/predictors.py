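"""Point predictors: three kriging variants and spatio-temporal IDW.

All three kriging estimators are linear in the neighboring observations and
solve a small dense system built from the metric variogram model:

* **Simple kriging in residuals (SK)** — the fixed station series F(t) is
  taken as the known, time-varying mean; the residuals Z − F(t) form a
  zero-mean second-order-stationary field and are kriged in covariance form
  with C(d) = (sill + nugget) − gamma(d).
* **Ordinary kriging (OK)** — constant unknown mean; the variogram-form
  system with a Lagrange multiplier enforcing sum(weights) = 1.
* **Kriging with external drift (KED)** — the unknown mean is a linear
  combination of drift functions, here f0 ≡ 1 and f1(x, t) = F(t); the
  bordered system enforces sum(w · f_l(data)) = f_l(target) for each drift.

The deterministic baseline is inverse-distance weighting with the combined
space-time distance d = sqrt(Δx² + Δy² + C·Δt²), power p (default 2); C is
tuned by cross-validation.

Kriging is local by default: the systems are solved over the ``n_max``
metric-nearest neighbors of each target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .data import FixedStationSeries, ObservationSet
from .errors import (
    DriftDegenerateError,
    EmptyNeighborhoodError,
    FoldError,
    InvalidInputError,
    SingularSystemError,
)
from .variogram import VariogramModel

logger = logging.getLogger(__name__)


@dataclass
class NeighborhoodSpec:
    """Prediction neighborhood: the ``n_max`` nearest observations in the
    metric space-time distance sqrt(Δx² + Δy² + (K·Δt)²), optionally within
    ``max_radius`` meters (metric). ``n_max=None`` means use every
    observation (global prediction). Kriging defaults to a local
    50-neighbor search; IDW, following its textbook formula, defaults to a
    global sum over all data."""

    n_max: int | None = 50
    max_radius: float | None = None

    def __post_init__(self) -> None:
        if self.n_max is not None and self.n_max < 1:
            raise InvalidInputError("n_max must be >= 1 (or None for global)")


@dataclass
class IDWParams:
    """Inverse-distance weighting parameters: power ``p`` and the temporal
    scaling ``C`` multiplying squared seconds inside the distance."""

    p: float = 2.0
    C: float = 1.0

    def __post_init__(self) -> None:
        if not self.p > 0:
            raise InvalidInputError("p must be > 0")
        if self.C < 0:
            raise InvalidInputError("C must be >= 0")


@dataclass
class DriftSpec:
    """External drift functions f_l(x, y, t); f0 ≡ 1 is always present."""

    functions: list[tuple[str, Callable]] = field(default_factory=list)

    @staticmethod
    def station_drift(station: FixedStationSeries) -> "DriftSpec":
        return DriftSpec(functions=[("F(t)", lambda x, y, t: station.interpolate(t))])

    def matrix(self, x, y, t) -> np.ndarray:
        n = len(np.atleast_1d(x))
        cols = [np.ones(n)]
        for _, fn in self.functions:
            cols.append(np.broadcast_to(np.asarray(fn(x, y, t), dtype=float), (n,)))
        return np.column_stack(cols)

    @property
    def names(self) -> list[str]:
        return ["1"] + [name for name, _ in self.functions]


@dataclass
class KrigingSolution:
    """Weights, multipliers, prediction and kriging variance at one target."""

    weights: np.ndarray
    multipliers: np.ndarray  # Lagrange (OK) or drift (KED) multipliers; empty for SK
    prediction: float
    variance: float  # clamped at 0 with a warning if numerically negative
    neighbor_index: np.ndarray | None = None


def _clamp_variance(var: float) -> float:
    if var < 0:
        if var < -1e-8:
            logger.warning("negative kriging variance %g clamped to 0", var)
        return 0.0
    return float(var)


def _metric_coords(x, y, t, K: float) -> np.ndarray:
    return np.column_stack(
        [np.asarray(x, float), np.asarray(y, float), K * np.asarray(t, float)]
    )


def _dedup_idx(pts: np.ndarray) -> np.ndarray | None:
    """Indices keeping the first of exactly duplicated rows; None if unique."""
    _, first = np.unique(pts, axis=0, return_index=True)
    if len(first) == len(pts):
        return None
    return np.sort(first)


def _dedup(pts: np.ndarray, *arrays):
    """Drop exactly duplicated (x, y, K·t) rows, keeping the first."""
    keep = _dedup_idx(pts)
    if keep is None:
        return (pts, *arrays)
    return (pts[keep], *(a[keep] for a in arrays))


def _solve(A: np.ndarray, b: np.ndarray, *, jitter_scale: float, n_data: int) -> np.ndarray:
    """Solve a (possibly bordered) kriging system with escalating diagonal
    jitter on the data block; raises SingularSystemError when hopeless."""
    jitter = 0.0
    for attempt in range(4):
        M = A
        if jitter > 0:
            M = A.copy()
            M[np.arange(n_data), np.arange(n_data)] += jitter
        try:
            sol = np.linalg.solve(M, b)
        except np.linalg.LinAlgError:
            sol = None
        if sol is not None and np.all(np.isfinite(sol)):
            resid = float(np.linalg.norm(M @ sol - b))
            if resid <= 1e-6 * max(float(np.linalg.norm(b)), 1.0):
                return sol
        jitter = jitter_scale * 1e-10 * (10.0**attempt)
        if attempt < 3:
            logger.warning("kriging system ill-conditioned; retrying with jitter %g", jitter)
    raise SingularSystemError("kriging system singular after jitter escalation")


# ---------------------------------------------------------------------------
# Array-level solver cores (shared by the point API and batch prediction)
# ---------------------------------------------------------------------------


def _sk_core(
    pts: np.ndarray,
    resid: np.ndarray,
    model: VariogramModel,
    tgt: np.ndarray,
    f0: float,
    *,
    literal_system: bool = False,
) -> tuple[np.ndarray, float, float]:
    d0 = cdist(pts, tgt[None, :]).ravel()
    D = cdist(pts, pts)
    total = model.total_sill
    c0 = total - model.gamma_point(d0)
    if literal_system:
        lam = _solve(model.gamma_d(D), model.gamma_point(d0), jitter_scale=total, n_data=len(resid))
    else:
        # covariance form; C(0) = sill + nugget on the diagonal
        lam = _solve(total - model.gamma_d(D), c0, jitter_scale=total, n_data=len(resid))
    pred = f0 + float(lam @ resid)
    var = _clamp_variance(total - float(lam @ c0))
    return lam, pred, var


def _ok_core(
    pts: np.ndarray, z: np.ndarray, model: VariogramModel, tgt: np.ndarray
) -> tuple[np.ndarray, float, float, float]:
    n = len(z)
    d0 = cdist(pts, tgt[None, :]).ravel()
    g0 = model.gamma_point(d0)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = model.gamma_d(cdist(pts, pts))
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    b = np.concatenate([g0, [1.0]])
    sol = _solve(A, b, jitter_scale=model.total_sill, n_data=n)
    lam, mu = sol[:n], float(sol[n])
    return lam, mu, float(lam @ z), _clamp_variance(float(lam @ g0) + mu)


def _ked_core(
    pts: np.ndarray,
    z: np.ndarray,
    Fm: np.ndarray,
    model: VariogramModel,
    tgt: np.ndarray,
    f_target: np.ndarray,
    drift_names: list[str],
) -> tuple[np.ndarray, np.ndarray, float, float]:
    n, p = Fm.shape
    col_ptp = np.ptp(Fm, axis=0)
    scale = np.maximum(np.abs(Fm).max(axis=0), 1.0)
    degenerate = [drift_names[j] for j in range(1, p) if col_ptp[j] <= 1e-10 * scale[j]]
    if degenerate or np.linalg.matrix_rank(Fm) < p:
        raise DriftDegenerateError(
            f"drift matrix rank-deficient (degenerate drift: {degenerate or drift_names})",
            drift_name=(degenerate[0] if degenerate else None),
        )
    d0 = cdist(pts, tgt[None, :]).ravel()
    g0 = model.gamma_point(d0)
    A = np.zeros((n + p, n + p))
    A[:n, :n] = model.gamma_d(cdist(pts, pts))
    A[:n, n:] = Fm
    A[n:, :n] = Fm.T
    b = np.concatenate([g0, f_target])
    sol = _solve(A, b, jitter_scale=model.total_sill, n_data=n)
    w, m = sol[:n], sol[n:]
    return w, m, float(w @ z), _clamp_variance(float(w @ g0) + float(m @ f_target))


def _idw_core(
    pts_sq: np.ndarray, z: np.ndarray, p: float
) -> float:
    """pts_sq: squared combined distances to the target."""
    hit = pts_sq < 1e-18
    if hit.any():
        return float(z[np.argmax(hit)])
    w = pts_sq ** (-p / 2.0)
    return float((w / w.sum()) @ z)


# ---------------------------------------------------------------------------
# Public point API
# ---------------------------------------------------------------------------


def _neighbor_arrays(obs: ObservationSet):
    df = obs.df
    return (
        df["x"].to_numpy(),
        df["y"].to_numpy(),
        df["t"].to_numpy(),
        df["value"].to_numpy(),
    )


def select_neighbors(
    obs: ObservationSet,
    target: tuple[float, float, float],
    spec: NeighborhoodSpec,
    *,
    K: float,
) -> np.ndarray:
    """Indices of the ``n_max`` metric-nearest observations to the target.

    Ties in distance are broken toward earlier time, then smaller sensor_id.
    Raises if a radius is set and nothing falls inside it.
    """
    if len(obs) == 0:
        raise EmptyNeighborhoodError("no observations")
    pts = _metric_coords(obs.df["x"], obs.df["y"], obs.df["t"], K)
    tgt = np.array([target[0], target[1], K * target[2]])
    d = cdist(pts, tgt[None, :]).ravel()
    if spec.max_radius is not None:
        inside = d <= spec.max_radius
        if not inside.any():
            raise EmptyNeighborhoodError(
                f"no observation within metric radius {spec.max_radius}"
            )
    else:
        inside = np.ones(len(d), dtype=bool)
    idx = np.flatnonzero(inside)
    order = np.lexsort(
        (obs.df["sensor_id"].to_numpy()[idx], obs.df["t"].to_numpy()[idx], d[idx])
    )
    return idx[order[: spec.n_max]]


def simple_kriging_residual(
    neighbors: ObservationSet,
    station: FixedStationSeries,
    model: VariogramModel,
    target: tuple[float, float, float],
    *,
    literal_system: bool = False,
) -> KrigingSolution:
    """Simple kriging of the residuals Z − F(t) with known zero mean.

    Solved in covariance form, C(d) = (sill + nugget) − gamma(d), which is
    the well-posed SK system for a bounded (second-order stationary) model;
    ``literal_system=True`` instead solves the unconstrained variogram-form
    equations Γλ = γ0 for comparison. Prediction is F(t0) + Σλ·(Z − F(t_i));
    variance is (sill + nugget) − Σλ·C(d_i0). Targets or data outside the
    station span are rejected (no extrapolation).
    """
    x, y, t, z = _neighbor_arrays(neighbors)
    if len(x) == 0:
        raise EmptyNeighborhoodError("no neighbors")
    f_t = station.interpolate(t)  # raises outside the span
    f0 = station.interpolate(target[2])
    pts = _metric_coords(x, y, t, model.K)
    pts, z, f_t = _dedup(pts, z, f_t)
    tgt = np.array([target[0], target[1], model.K * target[2]])
    lam, pred, var = _sk_core(
        pts, z - f_t, model, tgt, f0, literal_system=literal_system
    )
    return KrigingSolution(
        weights=lam, multipliers=np.empty(0), prediction=pred, variance=var
    )


def ordinary_kriging(
    neighbors: ObservationSet,
    model: VariogramModel,
    target: tuple[float, float, float],
) -> KrigingSolution:
    """Ordinary kriging: variogram-form bordered system with Σλ = 1.

    Prediction Σλ·Z; variance Σλ·γ_i0 + µ (µ the Lagrange multiplier).
    Exactly duplicated points are deduplicated before solving.
    """
    x, y, t, z = _neighbor_arrays(neighbors)
    if len(x) == 0:
        raise EmptyNeighborhoodError("no neighbors")
    pts = _metric_coords(x, y, t, model.K)
    pts, z = _dedup(pts, z)
    tgt = np.array([target[0], target[1], model.K * target[2]])
    lam, mu, pred, var = _ok_core(pts, z, model, tgt)
    return KrigingSolution(
        weights=lam, multipliers=np.array([mu]), prediction=pred, variance=var
    )


def kriging_external_drift(
    neighbors: ObservationSet,
    drift: DriftSpec,
    model: VariogramModel,
    target: tuple[float, float, float],
) -> KrigingSolution:
    """Kriging with external drift: unknown mean Σ a_l f_l(x, t).

    The bordered system couples the variogram block with the drift matrix;
    the unbiasedness constraints Σw·f_l(data) = f_l(target) hold for every
    drift. Variance is Σw·γ_i0 + Σ m_l f_l(target). A rank-deficient drift
    matrix (e.g. all station values equal) raises DriftDegenerateError —
    callers may catch it and fall back to ordinary kriging.
    """
    x, y, t, z = _neighbor_arrays(neighbors)
    if len(x) < 2:
        raise EmptyNeighborhoodError("KED needs >= 2 neighbors")
    pts = _metric_coords(x, y, t, model.K)
    pts, z, x, y, t = _dedup(pts, z, x, y, t)
    Fm = drift.matrix(x, y, t)
    f_target = drift.matrix([target[0]], [target[1]], [target[2]]).ravel()
    tgt = np.array([target[0], target[1], model.K * target[2]])
    w, m, pred, var = _ked_core(pts, z, Fm, model, tgt, f_target, drift.names)
    return KrigingSolution(weights=w, multipliers=m, prediction=pred, variance=var)


def idw_predict(
    neighbors: ObservationSet,
    params: IDWParams,
    target: tuple[float, float, float],
) -> float:
    """Spatio-temporal inverse-distance weighting.

    d_i = sqrt((x_i−x)² + (y_i−y)² + C·(t_i−t)²); if any d_i < 1e-9 the
    coincident observation's value is returned; otherwise weights are
    d_i^(−p) normalized to sum to 1.
    """
    x, y, t, z = _neighbor_arrays(neighbors)
    if len(x) == 0:
        raise EmptyNeighborhoodError("no neighbors")
    dsq = (
        (x - target[0]) ** 2
        + (y - target[1]) ** 2
        + params.C * (t - target[2]) ** 2
    )
    return _idw_core(dsq, z, params.p)


# ---------------------------------------------------------------------------
# Batch prediction
# ---------------------------------------------------------------------------

METHODS = ("sk", "ok", "ked", "idw")


def predict_points(
    obs: ObservationSet,
    station: FixedStationSeries | None,
    model: VariogramModel | None,
    method: str,
    targets: np.ndarray,
    *,
    neighborhood: NeighborhoodSpec | None = None,
    idw_params: IDWParams | None = None,
    ked_fallback_to_ok: bool = False,
) -> pd.DataFrame:
    """Predict at each (x, y, t) target row with one method.

    Returns a frame (x, y, t, prediction, variance, fallback); variance is
    NaN for IDW. ``ked_fallback_to_ok`` converts drift-degenerate KED solves
    into OK solves with a flagged record. Targets whose neighborhood is
    empty (radius set) or whose system stays singular yield NaN rows.
    """
    if method not in METHODS:
        raise InvalidInputError(f"unknown method {method!r}; expected one of {METHODS}")
    if method in ("sk", "ked") and station is None:
        raise InvalidInputError(f"method {method} requires a station series")
    if method != "idw" and model is None:
        raise InvalidInputError(f"method {method} requires a variogram model")
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if neighborhood is None:
        # kriging is local by default; IDW follows its global formula
        neighborhood = NeighborhoodSpec(n_max=None if method == "idw" else 50)
    if method == "idw":
        idw_params = idw_params or IDWParams()
        K_sel = float(np.sqrt(idw_params.C))
    else:
        K_sel = model.K

    x_a, y_a, t_a, z_a = _neighbor_arrays(obs)
    sid_a = obs.df["sensor_id"].to_numpy()
    f_a = None
    f_tgt = None
    if method in ("sk", "ked"):
        f_a = station.interpolate(t_a)  # rejects data outside the span
        f_tgt = station.interpolate(targets[:, 2])  # rejects targets outside
    drift_names = ["1", "F(t)"]

    pts = _metric_coords(x_a, y_a, t_a, K_sel)
    tgt_all = _metric_coords(targets[:, 0], targets[:, 1], targets[:, 2], K_sel)
    dmat = cdist(tgt_all, pts)
    n_max = neighborhood.n_max

    if method == "idw" and n_max is None and neighborhood.max_radius is None:
        # global IDW vectorizes over the whole batch
        dsq = dmat**2
        with np.errstate(divide="ignore"):
            w = dsq ** (-idw_params.p / 2.0)
        for r in np.flatnonzero(dsq.min(axis=1) < 1e-18):
            w[r] = 0.0
            w[r, int(np.argmax(dsq[r] < 1e-18))] = 1.0  # coincident datum wins
        pred = (w @ z_a) / w.sum(axis=1)
        out = pd.DataFrame(
            {
                "x": targets[:, 0],
                "y": targets[:, 1],
                "t": targets[:, 2],
                "prediction": pred,
                "variance": np.nan,
                "fallback": False,
            }
        )
        return out

    rows = []
    for i in range(len(targets)):
        d = dmat[i]
        if neighborhood.max_radius is not None:
            cand = np.flatnonzero(d <= neighborhood.max_radius)
            if cand.size == 0:
                rows.append((np.nan, np.nan, True))
                continue
        else:
            cand = np.arange(len(d))
        if n_max is not None and len(cand) > n_max:
            part = np.argpartition(d[cand], n_max - 1)[: min(2 * n_max, len(cand))]
            cand = cand[part]
        order = np.lexsort((sid_a[cand], t_a[cand], d[cand]))
        idx = cand[order[:n_max] if n_max is not None else order]
        keep = _dedup_idx(pts[idx])
        if keep is not None:
            idx = idx[keep]
        x0, y0, t0 = targets[i]
        npts, nz = pts[idx], z_a[idx]
        try:
            if method == "sk":
                _, pred, var = _sk_core(
                    npts, nz - f_a[idx], model, np.array([x0, y0, model.K * t0]),
                    float(f_tgt[i]),
                )
                rows.append((pred, var, False))
            elif method == "ok":
                _, _, pred, var = _ok_core(npts, nz, model, np.array([x0, y0, model.K * t0]))
                rows.append((pred, var, False))
            elif method == "ked":
                Fm = np.column_stack([np.ones(len(nz)), f_a[idx]])
                f_target = np.array([1.0, float(f_tgt[i])])
                try:
                    _, _, pred, var = _ked_core(
                        npts, nz, Fm, model, np.array([x0, y0, model.K * t0]),
                        f_target, drift_names,
                    )
                    rows.append((pred, var, False))
                except DriftDegenerateError:
                    if not ked_fallback_to_ok:
                        raise
                    logger.warning(
                        "KED drift degenerate at target %d; falling back to OK", i
                    )
                    _, _, pred, var = _ok_core(
                        npts, nz, model, np.array([x0, y0, model.K * t0])
                    )
                    rows.append((pred, var, True))
            else:
                rows.append((_idw_core(d[idx] ** 2, z_a[idx], idw_params.p), np.nan, False))
        except SingularSystemError:
            rows.append((np.nan, np.nan, True))
    out = pd.DataFrame(rows, columns=["prediction", "variance", "fallback"])
    out.insert(0, "t", targets[:, 2])
    out.insert(0, "y", targets[:, 1])
    out.insert(0, "x", targets[:, 0])
    return out


def tune_idw_C(
    training: ObservationSet,
    *,
    grid: Sequence[float] | None = None,
    folds: int = 4,
    seed: int = 0,
    p: float = 2.0,
    neighborhood: NeighborhoodSpec | None = None,
) -> float:
    """Choose the IDW temporal scaling C by k-fold cross-validation.

    Returns the grid value minimizing the mean RMSE over a random k-fold
    point split of the training data; ties (within 1e-12) break toward the
    smaller C. Default grid: 10 values log-spaced in [1e-4, 1e4].
    """
    if grid is None:
        grid = np.logspace(-4, 4, 10)
    grid = [float(c) for c in grid]
    if len(grid) == 0:
        raise InvalidInputError("empty candidate grid")
    if len(grid) == 1:
        return grid[0]
    if folds < 2:
        raise InvalidInputError("need >= 2 folds")
    n = len(training)
    if n < folds:
        raise FoldError(f"cannot split {n} points into {folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_ids = np.array_split(perm, folds)
    for f in fold_ids:
        if len(f) == 0:
            raise FoldError("empty test fold")
    scores = []
    for C in grid:
        errs = []
        for f in fold_ids:
            test_mask = np.zeros(n, dtype=bool)
            test_mask[f] = True
            train = training.subset(~test_mask)
            test = training.subset(test_mask)
            pred = predict_points(
                train,
                None,
                None,
                "idw",
                test.xyz,
                neighborhood=neighborhood,
                idw_params=IDWParams(p=p, C=C),
            )["prediction"].to_numpy()
            errs.append(np.sqrt(np.mean((pred - test.values) ** 2)))
        scores.append(float(np.mean(errs)))
    scores_arr = np.asarray(scores)
    best = scores_arr.min()
    candidates = [c for c, s in zip(grid, scores_arr) if s <= best + 1e-12]
    return min(candidates)
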