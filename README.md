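# airkrig

Spatio-temporal geostatistics for mobile air-quality sensing: calibrate raw
low-cost sensor streams against a fixed reference station, model the
space-time structure of the pollutant field with a metric variogram, predict
anywhere in the city at any moment with three kriging variants, benchmark
them against inverse-distance weighting, and render exposure and
uncertainty maps.

## The problem

A handful of ozone sensors ride fixed tram routes through a city, sampling
every minute or so along static back-and-forth trajectories, while one
reference station reports hourly averages F(t). The goal is a concentration
map Z*(x, t) — at street scale and sub-hourly resolution — with a credible
uncertainty attached, using *only* the pollution data (no land-use or
traffic covariates).

The field Z(x, t) is modeled through a **metric spatio-temporal variogram**

```
gamma(h, u) = gamma_joint( sqrt(h^2 + (K u)^2) )
```

where `h` is spatial lag (m), `u` temporal lag (s), and `K` (m/s) converts
one second into equivalent meters (the spatio-temporal anisotropy).
`gamma_joint` is a bounded family — spherical, exponential, or linear with
a sill — with nugget, partial sill and range fitted to the binned sample
variogram surface by bound-constrained L-BFGS-B least squares.

Four predictors share this model:

| method | mean assumption | uses station? | variance? |
|--------|-----------------|---------------|-----------|
| SK — simple kriging in residuals | known, = F(t) | yes | yes |
| OK — ordinary kriging | constant, unknown | no | yes |
| KED — kriging with external drift | a0 + a1 F(t), unknown a | yes | yes |
| IDW — inverse distance weighting, d = sqrt(dx²+dy²+C·dt²), p = 2 | — | no | no |

Raw sensor streams X_i (ppb) are first converted
(µg/m³ = ppb · 12.187 · M / 293, M = 48 for ozone) and calibrated per
sensor by OLS of F(t) on X_i: Z_i = a_i + b_i X_i.

Because the real tram dataset is external, the package ships a
**synthetic campaign generator**: tram-like routes, a latent ozone field
with known diurnal mean and metric covariance drawn jointly (one Gaussian
draw) for mobile and station points, per-sensor linear faults and noise.
Every claim the test suite makes is checked against this known truth.

## Worked example

```python
import airkrig as ak
from airkrig.evaluation import fit_models_for_methods, run_cross_validation

camp = ak.simulate_campaign(seed=1)                      # 3460 raw ppb obs, 1 day
coeffs = ak.fit_all_sensors(camp.raw, camp.station)      # per-sensor OLS
cal = ak.apply_calibration(camp.raw, coeffs)

models = fit_models_for_methods(cal, camp.station, max_temporal_lag=600.0, seed=0)
print(models["ked"].to_dict())
# {'family': 'exponential', 'sill': 31.85, 'nugget': 7.65,
#  'range': 50875.67, 'K': 123.24}

C = ak.tune_idw_C(camp.prediction_subset(cal), seed=1)   # C = 10000
report = run_cross_validation(
    camp.prediction_subset(cal), camp.station, models,
    scenarios=("random_points", "leave_line_out"), fractions=(0.8,),
    k=4, seed=1, idw_params=ak.IDWParams(C=C),
)
print(report.improvements().round(2).to_string(index=False))
# method       scenario  fraction  improvement_pct
#    ked leave_line_out       NaN             3.83
#    ked  random_points       0.8             4.85
#     ok leave_line_out       NaN             3.82
#     ok  random_points       0.8             4.88
#     sk leave_line_out       NaN             3.75
#     sk  random_points       0.8             4.71
```

The fitted KED model says the drift residuals decorrelate over ~51 km in
metric distance with K ≈ 123 m/s (roughly 7 minutes in time), and every
kriging variant beats the tuned IDW baseline on held-out points
(`improvement_pct` = percent RMSE reduction vs IDW), with smaller gains
when whole routes are held out — interpolation benefits more than
extrapolation. The multi-seed version of this experiment is
`airkrig.studies.method_comparison_study`.

A full pipeline is also scriptable from a YAML config:

```
airkrig -c campaign.yml simulate calibrate   # one stage per invocation
airkrig -c campaign.yml variogram
airkrig -c campaign.yml fit
airkrig -c campaign.yml evaluate
airkrig -c campaign.yml map                  # CSV + ASCII-grid rasters
```

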