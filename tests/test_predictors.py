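"""Kriging systems, IDW and neighborhood selection against dense oracles."""

import numpy as np
import pytest

import airkrig as ak
from airkrig.errors import DriftDegenerateError, EmptyNeighborhoodError
from conftest import random_neighbors


def dense_ok_oracle(pts, z, model, tgt):
    """Bordered OK system assembled and solved independently."""
    from scipy.spatial.distance import cdist

    n = len(z)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = model.gamma_d(cdist(pts, pts))
    A[:n, n] = A[n, :n] = 1.0
    b = np.concatenate([model.gamma_point(cdist(pts, tgt[None]).ravel()), [1.0]])
    sol = np.linalg.solve(A, b)
    return sol[:n], sol[n]


def dense_sk_oracle(pts, resid, model, tgt):
    from scipy.spatial.distance import cdist

    total = model.total_sill
    C = total - model.gamma_d(cdist(pts, pts))
    c0 = total - model.gamma_point(cdist(pts, tgt[None]).ravel())
    lam = np.linalg.solve(C, c0)
    return lam, float(lam @ resid), float(total - lam @ c0)


def dense_ked_oracle(pts, z, Fm, model, tgt, f_tgt):
    from scipy.spatial.distance import cdist

    n, p = Fm.shape
    A = np.zeros((n + p, n + p))
    A[:n, :n] = model.gamma_d(cdist(pts, pts))
    A[:n, n:] = Fm
    A[n:, :n] = Fm.T
    b = np.concatenate([model.gamma_point(cdist(pts, tgt[None]).ravel()), f_tgt])
    sol = np.linalg.solve(A, b)
    return sol[:n], sol[n:]


class TestSelectNeighbors:
    def test_saturation_returns_all(self, rng):
        obs = random_neighbors(rng, 8)
        idx = ak.select_neighbors(obs, (0.0, 0.0, 0.0), ak.NeighborhoodSpec(n_max=20), K=50.0)
        assert len(idx) == 8

    def test_tie_break_earlier_time_first(self):
        obs = ak.ObservationSet.from_arrays(
            ["a", "b"], [100.0, -100.0], [0.0, 0.0], [10.0, 50.0], [1.0, 2.0]
        )
        # equidistant in space; K=0 would be invalid, use target time making
        # metric distances equal: |dt| equal too
        idx = ak.select_neighbors(obs, (0.0, 0.0, 30.0), ak.NeighborhoodSpec(n_max=1), K=5.0)
        assert obs.df["t"].iloc[idx[0]] == 10.0  # earlier observation wins

    def test_matches_exhaustive_sort(self, rng):
        obs = random_neighbors(rng, 100)
        target = (250.0, -120.0, 300.0)
        K = 40.0
        idx = ak.select_neighbors(obs, target, ak.NeighborhoodSpec(n_max=10), K=K)
        d = np.sqrt(
            (obs.df["x"] - target[0]) ** 2
            + (obs.df["y"] - target[1]) ** 2
            + (K * (obs.df["t"] - target[2])) ** 2
        ).to_numpy()
        expected = set(np.argsort(d, kind="stable")[:10])
        assert set(idx) == expected

    def test_empty_radius_raises(self, rng):
        obs = random_neighbors(rng, 5)
        with pytest.raises(EmptyNeighborhoodError):
            ak.select_neighbors(
                obs, (1e6, 1e6, 0.0), ak.NeighborhoodSpec(n_max=3, max_radius=10.0), K=50.0
            )


class TestSimpleKriging:
    def test_collocated_single_neighbor_exact(self, flat_station):
        model = ak.VariogramModel("exponential", 20.0, 0.0, 5000.0, 80.0)
        obs = ak.ObservationSet.from_arrays("a", [100.0], [50.0], [600.0], [61.0])
        sol = ak.simple_kriging_residual(obs, flat_station, model, (100.0, 50.0, 600.0))
        assert sol.weights[0] == pytest.approx(1.0, abs=1e-10)
        assert sol.prediction == pytest.approx(61.0, abs=1e-8)
        assert sol.variance == pytest.approx(0.0, abs=1e-8)

    def test_far_target_reverts_to_station_mean(self, flat_station):
        model = ak.VariogramModel("spherical", 20.0, 2.0, 3000.0, 50.0)
        obs = ak.ObservationSet.from_arrays(
            ["a", "b"], [1e5, 1.1e5], [0.0, 0.0], [100.0, 200.0], [80.0, 90.0]
        )
        target = (0.0, 0.0, 3600.0)
        sol = ak.simple_kriging_residual(obs, flat_station, model, target)
        np.testing.assert_allclose(sol.weights, 0.0, atol=1e-12)
        assert sol.prediction == pytest.approx(flat_station.interpolate(3600.0))
        assert sol.variance == pytest.approx(model.total_sill)

    def test_matches_dense_solve(self, rng, flat_station, exp_model):
        obs = random_neighbors(rng, 12, scale_t=3000.0)
        target = (40.0, -90.0, 1500.0)
        sol = ak.simple_kriging_residual(obs, flat_station, exp_model, target)
        pts = np.column_stack(
            [obs.df["x"], obs.df["y"], exp_model.K * obs.df["t"]]
        )
        f = flat_station.interpolate(obs.df["t"].to_numpy())
        tgt = np.array([target[0], target[1], exp_model.K * target[2]])
        lam, pred_r, var = dense_sk_oracle(pts, obs.values - f, exp_model, tgt)
        np.testing.assert_allclose(sol.weights, lam, atol=1e-8)
        assert sol.prediction == pytest.approx(
            flat_station.interpolate(target[2]) + pred_r, abs=1e-8
        )
        assert sol.variance == pytest.approx(var, abs=1e-8)


class TestOrdinaryKriging:
    def test_single_neighbor_weight_one(self, exp_model):
        obs = ak.ObservationSet.from_arrays("a", [500.0], [0.0], [60.0], [42.0])
        sol = ak.ordinary_kriging(obs, exp_model, (0.0, 0.0, 0.0))
        assert sol.weights[0] == pytest.approx(1.0, abs=1e-12)
        assert sol.prediction == pytest.approx(42.0)

    def test_symmetric_pair_averages(self, exp_model):
        obs = ak.ObservationSet.from_arrays(
            ["a", "b"], [-700.0, 700.0], [0.0, 0.0], [100.0, 100.0], [10.0, 20.0]
        )
        sol = ak.ordinary_kriging(obs, exp_model, (0.0, 0.0, 100.0))
        np.testing.assert_allclose(sol.weights, [0.5, 0.5], atol=1e-10)
        assert sol.prediction == pytest.approx(15.0)

    def test_matches_dense_solve_and_weight_sum(self, rng, exp_model):
        obs = random_neighbors(rng, 12)
        target = (10.0, 20.0, 200.0)
        sol = ak.ordinary_kriging(obs, exp_model, target)
        pts = np.column_stack([obs.df["x"], obs.df["y"], exp_model.K * obs.df["t"]])
        tgt = np.array([target[0], target[1], exp_model.K * target[2]])
        lam, mu = dense_ok_oracle(pts, obs.values, exp_model, tgt)
        np.testing.assert_allclose(sol.weights, lam, atol=1e-8)
        assert sol.weights.sum() == pytest.approx(1.0, abs=1e-10)
        assert sol.multipliers[0] == pytest.approx(mu, abs=1e-8)

    def test_duplicate_points_deduplicated(self, exp_model):
        obs = ak.ObservationSet.from_arrays(
            ["a", "b", "c"], [500.0, 500.0, -300.0], [0.0, 0.0, 100.0],
            [60.0, 60.0, 90.0], [42.0, 42.0, 13.0],
        )
        sol = ak.ordinary_kriging(obs, exp_model, (0.0, 0.0, 70.0))
        assert len(sol.weights) == 2  # exact duplicate dropped
        assert np.isfinite(sol.prediction)


class TestKrigingExternalDrift:
    def test_constant_drift_rejected(self, exp_model):
        # a station that is constant over the neighbors' times
        station = ak.FixedStationSeries(0, 0, [0.0, 3600.0], [50.0, 50.0])
        obs = ak.ObservationSet.from_arrays(
            ["a", "b", "c"], [0.0, 500.0, 900.0], [0.0, 0.0, 0.0],
            [100.0, 200.0, 300.0], [40.0, 50.0, 60.0],
        )
        drift = ak.DriftSpec.station_drift(station)
        with pytest.raises(DriftDegenerateError):
            ak.kriging_external_drift(obs, drift, exp_model, (0.0, 0.0, 150.0))

    def test_exact_at_data_point_with_zero_nugget(self, flat_station):
        model = ak.VariogramModel("exponential", 15.0, 0.0, 4000.0, 60.0)
        t = np.array([0.0, 900.0, 1800.0, 2700.0])
        f = flat_station.interpolate(t)
        z = 5.0 + 1.3 * f  # field exactly affine in the drift
        obs = ak.ObservationSet.from_arrays(
            [f"s{i}" for i in range(4)], [0.0, 800.0, -600.0, 300.0],
            [0.0, 100.0, 400.0, -200.0], t, z,
        )
        drift = ak.DriftSpec.station_drift(flat_station)
        sol = ak.kriging_external_drift(obs, drift, model, (800.0, 100.0, 900.0))
        assert sol.prediction == pytest.approx(z[1], abs=1e-8)
        assert sol.variance == pytest.approx(0.0, abs=1e-8)

    def test_matches_dense_solve_and_constraints(self, rng, flat_station, exp_model):
        obs = random_neighbors(rng, 12, scale_t=3000.0)
        target = (-100.0, 60.0, 2000.0)
        drift = ak.DriftSpec.station_drift(flat_station)
        sol = ak.kriging_external_drift(obs, drift, exp_model, target)
        t = obs.df["t"].to_numpy()
        Fm = np.column_stack([np.ones(12), flat_station.interpolate(t)])
        f_tgt = np.array([1.0, flat_station.interpolate(target[2])])
        pts = np.column_stack([obs.df["x"], obs.df["y"], exp_model.K * t])
        tgt = np.array([target[0], target[1], exp_model.K * target[2]])
        w, m = dense_ked_oracle(pts, obs.values, Fm, exp_model, tgt, f_tgt)
        np.testing.assert_allclose(sol.weights, w, atol=1e-8)
        np.testing.assert_allclose(sol.multipliers, m, atol=1e-8)
        # unbiasedness constraints for both drifts
        np.testing.assert_allclose(Fm.T @ sol.weights, f_tgt, atol=1e-8)


class TestOracleSweep:
    def test_all_three_match_dense_solves_on_random_instances(self, flat_station):
        """100 random instances, n <= 15: SK, OK and KED agree with generic
        dense bordered-system solves to 1e-8."""
        rng = np.random.default_rng(77)
        families = ("spherical", "exponential", "bounded_linear")
        for trial in range(100):
            n = int(rng.integers(3, 16))
            model = ak.VariogramModel(
                families[trial % 3],
                sill=float(rng.uniform(5, 80)),
                nugget=float(rng.uniform(0, 5)),
                range_=float(rng.uniform(2000, 30000)),
                K=float(rng.uniform(10, 300)),
            )
            obs = random_neighbors(rng, n, scale_t=3000.0)
            target = (
                float(rng.uniform(-2000, 2000)),
                float(rng.uniform(-2000, 2000)),
                float(rng.uniform(0, 3000)),
            )
            pts = np.column_stack([obs.df["x"], obs.df["y"], model.K * obs.df["t"]])
            tgt = np.array([target[0], target[1], model.K * target[2]])

            ok = ak.ordinary_kriging(obs, model, target)
            lam, _ = dense_ok_oracle(pts, obs.values, model, tgt)
            np.testing.assert_allclose(ok.weights, lam, atol=1e-8)

            sk = ak.simple_kriging_residual(obs, flat_station, model, target)
            f = flat_station.interpolate(obs.df["t"].to_numpy())
            lam_s, _, _ = dense_sk_oracle(pts, obs.values - f, model, tgt)
            np.testing.assert_allclose(sk.weights, lam_s, atol=1e-8)

            Fm = np.column_stack([np.ones(n), f])
            f_tgt = np.array([1.0, flat_station.interpolate(target[2])])
            ked = ak.kriging_external_drift(
                obs, ak.DriftSpec.station_drift(flat_station), model, target
            )
            w, _ = dense_ked_oracle(pts, obs.values, Fm, model, tgt, f_tgt)
            np.testing.assert_allclose(ked.weights, w, atol=1e-8)


class TestExactnessAndSmoothing:
    def test_zero_nugget_exact_at_data_locations(self, rng, flat_station):
        model = ak.VariogramModel("exponential", 30.0, 0.0, 8000.0, 90.0)
        obs = random_neighbors(rng, 10, scale_t=3000.0)
        i = 4
        target = tuple(obs.df[["x", "y", "t"]].iloc[i])
        datum = obs.values[i]
        drift = ak.DriftSpec.station_drift(flat_station)
        for sol in (
            ak.simple_kriging_residual(obs, flat_station, model, target),
            ak.ordinary_kriging(obs, model, target),
            ak.kriging_external_drift(obs, drift, model, target),
        ):
            assert sol.prediction == pytest.approx(datum, abs=1e-8)
            assert sol.variance < 1e-8

    def test_positive_nugget_smooths(self, rng, flat_station):
        model = ak.VariogramModel("exponential", 30.0, 4.0, 8000.0, 90.0)
        obs = random_neighbors(rng, 10, scale_t=3000.0)
        i = 2
        target = tuple(obs.df[["x", "y", "t"]].iloc[i])
        datum = obs.values[i]
        for sol in (
            ak.simple_kriging_residual(obs, flat_station, model, target),
            ak.ordinary_kriging(obs, model, target),
        ):
            assert abs(sol.prediction - datum) > 0.0

    def test_translation_invariance(self, rng, flat_station, exp_model):
        obs = random_neighbors(rng, 9, scale_t=3000.0)
        shifted = obs.with_values(obs.values + 11.5)
        target = (50.0, 80.0, 1000.0)
        ok1 = ak.ordinary_kriging(obs, exp_model, target)
        ok2 = ak.ordinary_kriging(shifted, exp_model, target)
        assert ok2.prediction == pytest.approx(ok1.prediction + 11.5, abs=1e-8)
        p1 = ak.idw_predict(obs, ak.IDWParams(C=100.0), target)
        p2 = ak.idw_predict(shifted, ak.IDWParams(C=100.0), target)
        assert p2 == pytest.approx(p1 + 11.5, abs=1e-10)
        # SK shifts by sum(lambda) * c, not c in general
        sk1 = ak.simple_kriging_residual(obs, flat_station, exp_model, target)
        sk2 = ak.simple_kriging_residual(shifted, flat_station, exp_model, target)
        assert sk2.prediction == pytest.approx(
            sk1.prediction + 11.5 * sk1.weights.sum(), abs=1e-8
        )

    def test_ok_variance_at_least_sk_variance(self, rng, flat_station, exp_model):
        for _ in range(10):
            obs = random_neighbors(rng, 8, scale_t=3000.0)
            target = (
                float(rng.uniform(-2000, 2000)),
                float(rng.uniform(-2000, 2000)),
                float(rng.uniform(0, 3000)),
            )
            sk = ak.simple_kriging_residual(obs, flat_station, exp_model, target)
            ok = ak.ordinary_kriging(obs, exp_model, target)
            assert ok.variance >= sk.variance - 1e-9


class TestIDW:
    def test_closed_form_two_points(self):
        obs = ak.ObservationSet.from_arrays(
            ["a", "b"], [1.0, 2.0], [0.0, 0.0], [0.0, 1.0], [10.0, 40.0]
        )
        # distances 1 and 2 with C=0, p=2 -> weights 0.8 / 0.2 -> 16
        pred = ak.idw_predict(obs, ak.IDWParams(p=2.0, C=0.0), (0.0, 0.0, 0.0))
        assert pred == pytest.approx(16.0)

    def test_equal_distances_give_mean(self):
        obs = ak.ObservationSet.from_arrays(
            ["a", "b", "c"], [100.0, -100.0, 0.0], [0.0, 0.0, 100.0],
            [0.0, 1.0, 2.0], [10.0, 20.0, 60.0],
        )
        pred = ak.idw_predict(obs, ak.IDWParams(C=0.0), (0.0, 0.0, 50.0))
        assert pred == pytest.approx(30.0)

    def test_coincident_point_returned(self):
        obs = ak.ObservationSet.from_arrays(
            ["a", "b"], [0.0, 500.0], [0.0, 0.0], [100.0, 100.0], [33.0, 99.0]
        )
        pred = ak.idw_predict(obs, ak.IDWParams(C=1.0), (0.0, 0.0, 100.0))
        assert pred == 33.0

    def test_c_zero_invariant_to_time_shifts(self, rng):
        obs = random_neighbors(rng, 12)
        target = (100.0, -50.0, 500.0)
        p1 = ak.idw_predict(obs, ak.IDWParams(C=0.0), target)
        shifted = ak.ObservationSet.from_arrays(
            obs.df["sensor_id"], obs.df["x"], obs.df["y"],
            obs.df["t"] + 12345.0, obs.values,
        )
        p2 = ak.idw_predict(shifted, ak.IDWParams(C=0.0), target)
        assert p2 == pytest.approx(p1, rel=1e-12)

    def test_weights_sum_to_one_permutation_equivariant(self, rng):
        obs = random_neighbors(rng, 15)
        target = (0.0, 0.0, 300.0)
        p1 = ak.idw_predict(obs, ak.IDWParams(C=50.0), target)
        perm = rng.permutation(15)
        shuffled = obs.subset(perm)
        p2 = ak.idw_predict(shuffled, ak.IDWParams(C=50.0), target)
        assert p2 == pytest.approx(p1, rel=1e-12)


class TestTuneIdwC:
    def test_single_candidate_returned(self, rng):
        obs = random_neighbors(rng, 30)
        assert ak.tune_idw_C(obs, grid=[7.5]) == 7.5

    def test_pure_temporal_field_prefers_positive_c(self, rng):
        # values depend only on time: C = 0 ignores the only predictive axis
        n = 80
        t = np.sort(rng.uniform(0, 2000, n))
        obs = ak.ObservationSet.from_arrays(
            [f"s{i%4}" for i in range(n)],
            rng.uniform(-3000, 3000, n), rng.uniform(-3000, 3000, n),
            t, 50.0 + 10.0 * np.sin(t / 200.0),
        )
        c_star = ak.tune_idw_C(obs, grid=[0.0, 400.0], folds=4, seed=1)
        assert c_star == 400.0

    def test_tie_breaks_toward_smaller_c(self, rng):
        obs = random_neighbors(rng, 20)
        # constant values: every C gives identical RMSE -> smallest C wins
        const = obs.with_values(np.full(20, 5.0))
        assert ak.tune_idw_C(const, grid=[3.0, 1.0, 2.0], folds=2, seed=0) == 1.0


class TestBatchPrediction:
    def test_batch_agrees_with_point_api(self, rng, flat_station, exp_model):
        obs = random_neighbors(rng, 40, scale_t=3000.0)
        targets = np.array([[0.0, 0.0, 500.0], [300.0, -200.0, 1500.0]])
        for method in ("sk", "ok", "ked"):
            batch = ak.predict_points(
                obs, flat_station, exp_model, method, targets,
                neighborhood=ak.NeighborhoodSpec(n_max=10),
            )
            for i, tgt in enumerate(targets):
                idx = ak.select_neighbors(
                    obs, tuple(tgt), ak.NeighborhoodSpec(n_max=10), K=exp_model.K
                )
                nb = obs.subset(idx)
                if method == "sk":
                    sol = ak.simple_kriging_residual(nb, flat_station, exp_model, tuple(tgt))
                elif method == "ok":
                    sol = ak.ordinary_kriging(nb, exp_model, tuple(tgt))
                else:
                    sol = ak.kriging_external_drift(
                        nb, ak.DriftSpec.station_drift(flat_station), exp_model, tuple(tgt)
                    )
                assert batch["prediction"][i] == pytest.approx(sol.prediction, abs=1e-9)
                assert batch["variance"][i] == pytest.approx(sol.variance, abs=1e-9)

    def test_global_idw_batch_matches_point_api(self, rng):
        obs = random_neighbors(rng, 30)
        params = ak.IDWParams(C=200.0)
        targets = np.array([[10.0, 20.0, 100.0], [-500.0, 300.0, 400.0]])
        batch = ak.predict_points(obs, None, None, "idw", targets, idw_params=params)
        for i, tgt in enumerate(targets):
            assert batch["prediction"][i] == pytest.approx(
                ak.idw_predict(obs, params, tuple(tgt)), rel=1e-12
            )

    def test_ked_fallback_to_ok_flagged(self, exp_model):
        station = ak.FixedStationSeries(0, 0, [0.0, 3600.0], [50.0, 50.0])
        obs = ak.ObservationSet.from_arrays(
            ["a", "b", "c"], [0.0, 400.0, -300.0], [0.0, 100.0, 50.0],
            [100.0, 300.0, 500.0], [40.0, 50.0, 45.0],
        )
        out = ak.predict_points(
            obs, station, exp_model, "ked", np.array([[0.0, 0.0, 200.0]]),
            ked_fallback_to_ok=True,
        )
        assert bool(out["fallback"][0])
        ok = ak.ordinary_kriging(obs, exp_model, (0.0, 0.0, 200.0))
        assert out["prediction"][0] == pytest.approx(ok.prediction, abs=1e-9)
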