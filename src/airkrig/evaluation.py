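"""Validation scenarios, cross-validation and performance indicators.

Three train/test scenarios probe increasingly hard prediction regimes:

1. ``random_points`` — points held out uniformly at random regardless of
   location: reconstruction between sampled places (interpolation);
2. ``path_segments`` — contiguous-in-time runs within single sensors held
   out: extrapolation to places *close to* the sampling paths;
3. ``leave_line_out`` — entire routes held out: extrapolation *far from*
   the sampling points.

Each scenario cell is evaluated with k seeded re-draws ("folds"; random
scenarios cannot form disjoint quarters at arbitrary training fractions)
and three indicators per fold: RMSE, BIAS and the Pearson correlation,
plus the relative RMSE improvement of each kriging method over IDW.

Variogram models are fitted once on the full campaign and reused across
folds; IDW's temporal scaling C is tuned once and frozen across folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import FixedStationSeries, ObservationSet
from .errors import FoldError, InvalidInputError, SplitError
from .predictors import (
    IDWParams,
    NeighborhoodSpec,
    predict_points,
    tune_idw_C,
)
from .variogram import (
    VariogramModel,
    empirical_variogram,
    estimated_drift_residuals,
    fit_metric_model,
    subtract_station,
)

logger = logging.getLogger(__name__)

SCENARIOS = ("random_points", "path_segments", "leave_line_out")


@dataclass
class ScenarioSpec:
    """One validation scenario.

    ``fraction`` is the training fraction for kinds 1–2; ``held_out`` is the
    list of route/sensor ids for kind 3. ``segment_mean``/``segment_sd``
    parameterize the run-length distribution of kind 2 (in samples).
    """

    kind: str
    fraction: float | None = None
    held_out: list[str] | None = None
    segment_mean: float = 20.0
    segment_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SCENARIOS:
            raise InvalidInputError(f"unknown scenario kind {self.kind!r}")
        if self.kind in ("random_points", "path_segments"):
            if self.fraction is None or not (0.0 < self.fraction < 1.0):
                raise InvalidInputError("training fraction must be in (0, 1)")
        elif not self.held_out:
            raise InvalidInputError("leave_line_out needs held-out route ids")


@dataclass
class MetricsTriple:
    """RMSE, BIAS and Pearson correlation of predictions vs. truths."""

    rmse: float
    bias: float
    corr: float  # NaN when undefined (zero variance on either side)

    @property
    def corr_defined(self) -> bool:
        return not np.isnan(self.corr)


def compute_metrics(predictions, truths) -> MetricsTriple:
    """RMSE = sqrt(mean((Z*−Z)²)); BIAS = mean(Z*−Z); CORR = Pearson.

    The correlation is NaN (flagged undefined) when either side is constant.
    """
    p = np.asarray(predictions, dtype=float)
    z = np.asarray(truths, dtype=float)
    if p.shape != z.shape:
        raise InvalidInputError("predictions and truths differ in length")
    if p.size < 1:
        raise InvalidInputError("need at least one prediction")
    err = p - z
    rmse = float(np.sqrt(np.mean(err**2)))
    bias = float(np.mean(err))
    sp = p - p.mean()
    sz = z - z.mean()
    denom = np.sqrt(np.sum(sp**2) * np.sum(sz**2))
    corr = float(np.sum(sp * sz) / denom) if denom > 0 else float("nan")
    return MetricsTriple(rmse=rmse, bias=bias, corr=corr)


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------


def split_random_points(
    obs: ObservationSet, fraction: float, seed: int = 0
) -> tuple[ObservationSet, ObservationSet]:
    """Uniform random partition with |train| = round(fraction · n)."""
    n = len(obs)
    if n < 2:
        raise SplitError("need >= 2 observations to split")
    if not (0.0 < fraction < 1.0):
        raise SplitError("fraction must be in (0, 1)")
    n_train = int(round(fraction * n))
    if n_train == 0 or n_train == n:
        raise SplitError(f"fraction {fraction} yields an empty train or test set")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_mask = np.zeros(n, dtype=bool)
    train_mask[perm[:n_train]] = True
    return obs.subset(train_mask), obs.subset(~train_mask)


def split_path_segments(
    obs: ObservationSet,
    fraction: float,
    *,
    segment_mean: float = 20.0,
    segment_sd: float = 10.0,
    seed: int = 0,
) -> tuple[ObservationSet, ObservationSet]:
    """Hold out contiguous-in-time runs within single sensors.

    Run lengths are drawn from Normal(mean, sd), rounded and clipped to >= 1
    sample, and accumulated until the test size reaches (1 − fraction) · n
    (the last run is truncated, so |test| is within ±1 of the target).
    """
    n = len(obs)
    if n < 2:
        raise SplitError("need >= 2 observations to split")
    if not (0.0 < fraction < 1.0):
        raise SplitError("fraction must be in (0, 1)")
    sensors = obs.sensors
    per_sensor = {
        s: np.flatnonzero((obs.df["sensor_id"] == s).to_numpy()) for s in sensors
    }
    max_track = max(len(v) for v in per_sensor.values())
    if segment_mean > max_track:
        raise SplitError(
            f"segment mean {segment_mean} exceeds the longest sensor track ({max_track})"
        )
    target = int(round((1.0 - fraction) * n))
    if target == 0 or target == n:
        raise SplitError(f"fraction {fraction} yields an empty train or test set")
    rng = np.random.default_rng(seed)
    test_mask = np.zeros(n, dtype=bool)
    count = 0
    stall = 0
    while count < target:
        sid = sensors[int(rng.integers(len(sensors)))]
        idx = per_sensor[sid]
        L = max(1, int(round(rng.normal(segment_mean, segment_sd))))
        L = min(L, target - count)  # truncate the last run
        start = int(rng.integers(len(idx)))
        run = idx[start : start + L]
        new = run[~test_mask[run]]
        if len(new) == 0:
            stall += 1
            if stall > 1000:
                raise SplitError("segment split stalled; spec may be infeasible")
            continue
        stall = 0
        if count + len(new) > target:
            new = new[: target - count]
        test_mask[new] = True
        count += len(new)
    return obs.subset(~test_mask), obs.subset(test_mask)


def split_leave_line_out(
    obs: ObservationSet, held_out: list[str]
) -> tuple[ObservationSet, ObservationSet]:
    """Hold out every observation of the given routes; deterministic."""
    known = set(obs.sensors)
    unknown = [r for r in held_out if r not in known]
    if unknown:
        raise SplitError(f"unknown route ids: {unknown}")
    mask = obs.df["sensor_id"].isin(held_out).to_numpy()
    if mask.all():
        raise SplitError("holding out every route leaves an empty training set")
    if not mask.any():
        raise SplitError("empty test set")
    return obs.subset(~mask), obs.subset(mask)


# ---------------------------------------------------------------------------
# Model fitting per method
# ---------------------------------------------------------------------------

from .variogram import FAMILIES  # noqa: E402  (family auto-selection)


def fit_models_for_methods(
    obs: ObservationSet,
    station: FixedStationSeries,
    *,
    families: dict[str, str] | None = None,
    max_temporal_lag: float | None = None,
    n_spatial_bins: int = 12,
    n_temporal_bins: int = 12,
    n_starts: int = 8,
    seed: int = 0,
) -> dict[str, VariogramModel]:
    """Fit one variogram model per kriging variant.

    OK models the calibrated data directly; SK models the station residuals
    Z − F(t); KED models the residuals of the OLS drift fit Z ~ 1 + F(t).
    By default the joint-model family of each variant is selected by the fit
    objective across the three bounded families (a misfit family distorts
    the nugget and the anisotropy K); pass ``families={"ok": "spherical"}``
    etc. to pin a family per method.
    """
    families = families or {}
    datasets = {
        "ok": obs,
        "sk": subtract_station(obs, station),
        "ked": estimated_drift_residuals(obs, station),
    }
    out = {}
    for method, data in datasets.items():
        emp = empirical_variogram(
            data,
            n_spatial_bins=n_spatial_bins,
            n_temporal_bins=n_temporal_bins,
            max_temporal_lag=max_temporal_lag,
        )
        candidates = [families[method]] if method in families else list(FAMILIES)
        fits = [
            fit_metric_model(emp, fam, n_starts=n_starts, seed=seed)
            for fam in candidates
        ]
        best = min(fits, key=lambda f: f.objective)
        out[method] = best.model
    return out


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVReport:
    """Tidy per-fold records plus fold-mean and improvement summaries."""

    records: pd.DataFrame  # method, scenario, fraction, fold, rmse, bias, corr, n_test, fallback

    def cell_means(self) -> pd.DataFrame:
        """Arithmetic fold means per (method, scenario, fraction)."""
        return (
            self.records.groupby(["method", "scenario", "fraction"], dropna=False)[
                ["rmse", "bias", "corr"]
            ]
            .mean()
            .reset_index()
        )

    def improvements(self, baseline: str = "idw") -> pd.DataFrame:
        """Percent RMSE improvement of each method over the baseline:
        100 · (RMSE_baseline − RMSE_method) / RMSE_baseline."""
        means = self.cell_means()
        base = means[means["method"] == baseline].set_index(["scenario", "fraction"])[
            "rmse"
        ]
        rows = []
        for _, r in means.iterrows():
            if r["method"] == baseline:
                continue
            key = (r["scenario"], r["fraction"])
            if key not in base.index:
                continue
            b = base.loc[key]
            rows.append(
                {
                    "method": r["method"],
                    "scenario": r["scenario"],
                    "fraction": r["fraction"],
                    "improvement_pct": 100.0 * (b - r["rmse"]) / b,
                }
            )
        return pd.DataFrame(rows)

    def write(self, records_path, summary_path=None) -> None:
        self.records.to_csv(records_path, index=False, float_format="%.12g")
        if summary_path is not None:
            means = self.cell_means()
            imp = self.improvements()
            summary = means.merge(
                imp, on=["method", "scenario", "fraction"], how="left"
            )
            summary.to_csv(summary_path, index=False, float_format="%.12g")


def run_cross_validation(
    obs: ObservationSet,
    station: FixedStationSeries,
    models: dict[str, VariogramModel],
    *,
    methods=("sk", "ok", "ked", "idw"),
    scenarios=("random_points", "path_segments", "leave_line_out"),
    fractions=(0.2, 0.4, 0.6, 0.8),
    holdouts: list[list[str]] | None = None,
    k: int = 4,
    seed: int = 0,
    neighborhood: NeighborhoodSpec | None = None,
    idw_neighborhood: NeighborhoodSpec | None = None,
    idw_params: IDWParams | None = None,
    segment_mean: float = 20.0,
    segment_sd: float = 10.0,
) -> CVReport:
    """Cross-validate every method over the scenario grid.

    Each (scenario, fraction) cell is evaluated on ``k`` folds — fresh
    seeded splits for the random scenarios, one fold per held-out route list
    for leave-line-out (default: each route in turn). Variogram models are
    passed in, fitted once upstream; IDW's C is tuned once here if
    ``idw_params`` is not given. KED folds with a degenerate drift fall back
    to OK with a flagged record.
    """
    if k < 2:
        raise InvalidInputError("need k >= 2 folds")
    neighborhood = neighborhood or NeighborhoodSpec()
    idw_neighborhood = idw_neighborhood or NeighborhoodSpec(n_max=None)
    for m in methods:
        if m != "idw" and m not in models:
            raise InvalidInputError(f"no fitted variogram model for method {m!r}")
    if idw_params is None and "idw" in methods:
        C = tune_idw_C(obs, seed=seed, neighborhood=idw_neighborhood)
        idw_params = IDWParams(C=C)
        logger.info("tuned IDW C = %g", C)
    if holdouts is None:
        holdouts = [[s] for s in obs.sensors]

    ss = np.random.SeedSequence(seed)
    records = []
    for scenario in scenarios:
        if scenario == "leave_line_out":
            cells = [(np.nan, None)]
        else:
            cells = [(f, None) for f in fractions]
        for fraction, _ in cells:
            if scenario == "leave_line_out":
                folds = list(enumerate(holdouts))
            else:
                child = ss.spawn(1)[0]
                fold_seeds = child.generate_state(k) % (2**31)
                folds = list(enumerate(fold_seeds))
            for fold_id, fold_arg in folds:
                if scenario == "random_points":
                    train, test = split_random_points(obs, fraction, seed=int(fold_arg))
                elif scenario == "path_segments":
                    train, test = split_path_segments(
                        obs,
                        fraction,
                        segment_mean=segment_mean,
                        segment_sd=segment_sd,
                        seed=int(fold_arg),
                    )
                else:
                    train, test = split_leave_line_out(obs, fold_arg)
                if len(test) == 0 or len(train) == 0:
                    raise FoldError("empty train or test fold")
                for method in methods:
                    pred = predict_points(
                        train,
                        station,
                        models.get(method),
                        method,
                        test.xyz,
                        neighborhood=(idw_neighborhood if method == "idw" else neighborhood),
                        idw_params=idw_params,
                        ked_fallback_to_ok=True,
                    )
                    ok_mask = pred["prediction"].notna().to_numpy()
                    m = compute_metrics(
                        pred["prediction"].to_numpy()[ok_mask], test.values[ok_mask]
                    )
                    records.append(
                        {
                            "method": method,
                            "scenario": scenario,
                            "fraction": fraction,
                            "fold": fold_id,
                            "rmse": m.rmse,
                            "bias": m.bias,
                            "corr": m.corr,
                            "n_test": int(ok_mask.sum()),
                            "fallback": bool(pred["fallback"].any()),
                        }
                    )
    return CVReport(records=pd.DataFrame(records))
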