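"""Canonical recovery and comparison studies on synthetic campaigns.

These routines define the package's reference experiments — the ones its
tests assert on and its acceptance script reports. Each study regenerates
its data from scratch under the given seed, runs the relevant pipeline
stages, and returns plain dictionaries of measured quantities.

Problem sizes are chosen for a desk-scale machine: campaigns of ~3500
mobile points (the dense-factorization cap of the joint field draw), 10–20
seeds per study.
"""

from __future__ import annotations

import logging


import numpy as np
import pandas as pd

from .calibration import apply_calibration, fit_all_sensors, fit_calibration
from .data import FixedStationSeries, GridSpec, ObservationSet
from .evaluation import fit_models_for_methods, run_cross_validation
from .mapping import predict_grid
from .predictors import IDWParams, NeighborhoodSpec, tune_idw_C
from .synthetic import simulate_campaign
from .variogram import empirical_variogram, fit_metric_model

logger = logging.getLogger(__name__)

#: Temporal lag cutoff (s) used when fitting variogram models on the default
#: campaign: the metric distance K·u reaches twice the truth-scale range by
#: 600 s, past which the surface is flat and bins only add noise.
FIT_MAX_TEMPORAL_LAG = 600.0


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


# ---------------------------------------------------------------------------
# Calibration recovery
# ---------------------------------------------------------------------------


def high_variance_week_station(amplitude: float = 48.0, base: float = 50.0) -> FixedStationSeries:
    """A week-long hourly ozone series with a strong diurnal cycle (near-zero
    nights, ~95 µg/m³ peaks). The large spread (sd ≈ 34 µg/m³) makes the
    regressor variance dominate unit-scale sensor noise, which per-sensor
    OLS calibration needs to resolve small biases."""
    hours = np.arange(0.0, 7 * 86400.0 + 1.0, 3600.0)
    mu = np.maximum(
        0.0, base + amplitude * np.cos(2 * np.pi * ((hours / 3600.0) % 24.0 - 14.0) / 24.0)
    )
    return FixedStationSeries(x=0.0, y=0.0, times=hours, values=mu)


def calibration_recovery_study(
    seed: int,
    *,
    a_true: float = 3.0,
    b_true: float = 2.0,
    noise_sd: float = 1.0,
    n: int = 5000,
    n_seeds: int = 20,
) -> dict:
    """Recover per-sensor calibration faults from a week of station data.

    Noiseless part: a sensor reading exactly X = (F(t) − a*) / b* must be
    inverted to machine precision. Noisy part: with unit raw-scale noise at
    n observations, report the median absolute errors of (a, b) over
    ``n_seeds`` replicates.
    """
    station = high_variance_week_station()
    rng0 = np.random.default_rng(seed)
    t0 = np.unique(np.sort(rng0.uniform(0.0, 7 * 86400.0, 500)))
    f0 = station.interpolate(t0)
    obs0 = ObservationSet.from_arrays("s", 0.0, 0.0, t0, (f0 - a_true) / b_true)
    coef0 = fit_calibration(obs0, station)
    noiseless = {"a_error": abs(coef0.a - a_true), "b_error": abs(coef0.b - b_true)}

    errs_a, errs_b = [], []
    for s in _spawn_seeds(seed, n_seeds):
        r = np.random.default_rng(s)
        t = np.unique(np.sort(r.uniform(0.0, 7 * 86400.0, n)))
        f = station.interpolate(t)
        x = (f - a_true) / b_true + r.normal(0.0, noise_sd, len(t))
        coef = fit_calibration(ObservationSet.from_arrays("s", 0.0, 0.0, t, x), station)
        errs_a.append(abs(coef.a - a_true))
        errs_b.append(abs(coef.b - b_true))
    return {
        "noiseless": noiseless,
        "noisy_median_a_error": float(np.median(errs_a)),
        "noisy_median_b_error": float(np.median(errs_b)),
        "n": n,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# Variogram parameter recovery
# ---------------------------------------------------------------------------


def variogram_recovery_study(seed: int, *, n_seeds: int = 10) -> dict:
    """Simulate default campaigns from the known exponential metric model and
    refit it from the (detrended) latent values; report recovered/true
    parameter ratios per seed and their medians."""
    ratios = {"sill": [], "range": [], "K": []}
    truth = None
    for s in _spawn_seeds(seed, n_seeds):
        camp = simulate_campaign(seed=s)
        truth = camp.spec.field_spec.variogram
        mu = camp.spec.field_spec.mean(camp.truth.df["t"].to_numpy())
        resid = camp.truth.with_values(camp.truth.values - mu)
        emp = empirical_variogram(resid, max_temporal_lag=FIT_MAX_TEMPORAL_LAG)
        model = fit_metric_model(emp, truth.family, seed=0).model
        ratios["sill"].append(model.sill / truth.sill)
        ratios["range"].append(model.range_ / truth.range_)
        ratios["K"].append(model.K / truth.K)
    return {
        "median_ratio": {k: float(np.median(v)) for k, v in ratios.items()},
        "ratios": {k: [float(x) for x in v] for k, v in ratios.items()},
        "truth": truth.to_dict(),
        "n_seeds": n_seeds,
        "n_points_per_campaign": len(camp.truth),
    }


# ---------------------------------------------------------------------------
# Method comparison (kriging vs tuned IDW)
# ---------------------------------------------------------------------------


def method_comparison_study(
    seed: int,
    *,
    n_seeds: int = 10,
    fraction: float = 0.8,
    k: int = 4,
    scenarios=("random_points", "leave_line_out"),
) -> dict:
    """Full-pipeline comparison on default campaigns.

    Per seed: simulate, calibrate, fit per-method variogram models on the
    calibrated data, tune IDW's C, cross-validate all four methods under the
    given scenarios, and aggregate mean RMSEs and percent improvements of
    each kriging method over IDW.
    """
    records = []
    for s in _spawn_seeds(seed, n_seeds):
        camp = simulate_campaign(seed=s)
        coeffs = fit_all_sensors(camp.raw, camp.station)
        cal = apply_calibration(camp.raw, coeffs)
        models = fit_models_for_methods(
            cal, camp.station, max_temporal_lag=FIT_MAX_TEMPORAL_LAG, seed=0
        )
        pday = camp.prediction_subset(cal)
        C = tune_idw_C(pday, seed=s)
        rep = run_cross_validation(
            pday,
            camp.station,
            models,
            scenarios=scenarios,
            fractions=(fraction,),
            k=k,
            seed=s,
            idw_params=IDWParams(C=C),
        )
        cm = rep.cell_means()
        cm["seed"] = s
        cm["idw_C"] = C
        records.append(cm)
    all_means = pd.concat(records, ignore_index=True)
    rmse = (
        all_means.groupby(["method", "scenario"], dropna=False)["rmse"]
        .mean()
        .unstack("scenario")
    )
    out = {"n_seeds": n_seeds, "fraction": fraction, "rmse": {}, "improvement_pct": {}}
    for method in rmse.index:
        out["rmse"][method] = {s: float(rmse.loc[method, s]) for s in rmse.columns}
    for method in rmse.index:
        if method == "idw":
            continue
        out["improvement_pct"][method] = {
            s: float(100.0 * (rmse.loc["idw", s] - rmse.loc[method, s]) / rmse.loc["idw", s])
            for s in rmse.columns
        }
    return out


# ---------------------------------------------------------------------------
# Map variance behavior
# ---------------------------------------------------------------------------


def map_variance_study(seed: int) -> dict:
    """Kriging-variance geometry on a default campaign.

    Measures (a) the mean variance of data-adjacent vs data-distant cells in
    a mid-campaign time slice, and (b) the relative deviation of the
    variance from sill + nugget in a slice far (in metric distance) from
    every observation.
    """
    camp = simulate_campaign(seed=seed)
    coeffs = fit_all_sensors(camp.raw, camp.station)
    cal = apply_calibration(camp.raw, coeffs)
    models = fit_models_for_methods(
        cal, camp.station, max_temporal_lag=FIT_MAX_TEMPORAL_LAG, seed=0
    )
    model = models["sk"]

    t_mid = float(cal.df["t"].median())
    grid = GridSpec(x_min=-6000.0, y_min=-6000.0, n_x=12, n_y=12, cell_size=1000.0, times=[t_mid])
    pmap = predict_grid(cal, camp.station, model, "sk", grid,
                        neighborhood=NeighborhoodSpec(n_max=50))
    var = pmap.variance[0]
    xs, ys = grid.cell_centers()
    xx, yy = np.meshgrid(xs, ys)
    same_t = cal.df[np.abs(cal.df["t"] - t_mid) < 150.0]
    d_near = np.full(xx.shape, np.inf)
    for _, r in same_t.iterrows():
        d_near = np.minimum(d_near, np.hypot(xx - r.x, yy - r.y))
    near = float(var[d_near <= np.quantile(d_near, 0.2)].mean())
    far = float(var[d_near >= np.quantile(d_near, 0.8)].mean())

    # a slice hours past the last observation but inside the station span
    t_far = min(float(cal.df["t"].max()) + 3600.0 * 0.9, camp.station.span[1])
    far_grid = GridSpec(x_min=-3000.0, y_min=-3000.0, n_x=4, n_y=4, cell_size=1500.0, times=[t_far])
    far_map = predict_grid(cal, camp.station, model, "sk", far_grid)
    sat = model.total_sill
    rel_dev = float(np.max(np.abs(far_map.variance[0] - sat)) / sat)
    return {
        "near_cell_mean_variance": near,
        "far_cell_mean_variance": far,
        "saturation_relative_deviation": rel_dev,
        "sill_plus_nugget": float(sat),
        "n_cells": int(grid.n_x * grid.n_y),
    }
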