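"""IDW engine, evaluation metrics, splitting and the density experiment."""

import numpy as np
import pandas as pd
import pytest

from gediagb.interpolation import (
    IDWInterpolator,
    evaluate_interpolation,
    idw_predict,
    idw_rasterize,
    regression_metrics,
    run_density_experiment,
    split_train_validation,
)

from conftest import brute_force_idw


def points_df(xy, values, variable="pai"):
    df = pd.DataFrame(xy, columns=["x", "y"])
    df["shot_id"] = np.arange(len(df))
    df["beam"] = "B0"
    df["track"] = "T0"
    df[variable] = values
    return df


class TestIDW:
    def test_single_point_returns_its_value_everywhere(self):
        df = points_df([[10.0, 10.0]], [7.3])
        assert idw_predict([[500.0, -200.0]], df, "pai")[0] == pytest.approx(7.3)

    def test_exact_interpolation_at_measured_points(self, rng):
        xy = rng.uniform(0, 1000, (50, 2))
        vals = rng.normal(5, 2, 50)
        df = points_df(xy, vals)
        pred = idw_predict(xy, df, "pai")
        assert np.allclose(pred, vals, atol=1e-12)

    def test_hand_computed_three_point_example(self):
        # distances 1, 2, 4 with values 0, 6, 12 and p=2:
        # (0*1 + 6*0.25 + 12*0.0625) / 1.3125 = 12/7
        df = points_df([[1.0, 0.0], [2.0, 0.0], [4.0, 0.0]], [0.0, 6.0, 12.0])
        pred = idw_predict([[0.0, 0.0]], df, "pai", n_neighbors=0)
        assert pred[0] == pytest.approx(12.0 / 7.0, rel=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        xy = rng.uniform(0, 5000, (400, 2))
        vals = rng.normal(40, 9, 400)
        df = points_df(xy, vals)
        queries = rng.uniform(0, 5000, (300, 2))
        for k in (0, 12):
            ours = idw_predict(queries, df, "pai", n_neighbors=k)
            oracle = brute_force_idw(queries, xy, vals, power=2.0, n_neighbors=k)
            assert np.allclose(ours, oracle, rtol=1e-10, atol=1e-10)

    def test_neighbor_limit_equals_all_points_when_few_points(self, rng):
        xy = rng.uniform(0, 100, (9, 2))
        vals = rng.normal(0, 1, 9)
        df = points_df(xy, vals)
        q = rng.uniform(0, 100, (40, 2))
        a = idw_predict(q, df, "pai", n_neighbors=12)
        b = idw_predict(q, df, "pai", n_neighbors=0)
        assert np.array_equal(a, b)

    def test_predictions_within_convex_bounds(self, rng):
        xy = rng.uniform(0, 2000, (120, 2))
        vals = rng.normal(10, 3, 120)
        df = points_df(xy, vals)
        pred = idw_predict(rng.uniform(-500, 2500, (1000, 2)), df, "pai")
        assert pred.min() >= vals.min() - 1e-12
        assert pred.max() <= vals.max() + 1e-12

    def test_search_radius_yields_nodata(self):
        df = points_df([[0.0, 0.0]], [5.0])
        pred = idw_predict([[1000.0, 0.0]], df, "pai", max_search_radius_m=100.0)
        assert np.isnan(pred[0])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            idw_predict([[0.0, 0.0]], points_df(np.empty((0, 2)), []), "pai")

    def test_sklearn_estimator_contract(self):
        from sklearn.base import clone

        est = IDWInterpolator(power=1.5, n_neighbors=4)
        assert clone(est).get_params()["power"] == 1.5
        xy = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        fitted = est.fit(xy, np.array([1.0, 2.0, 3.0]))
        assert fitted is est
        r2 = est.score(xy, np.array([1.0, 2.0, 3.0]))
        assert r2 == pytest.approx(1.0)  # exact interpolator scores perfectly


class TestRasterize:
    def test_constant_values_give_constant_raster(self, rng):
        xy = rng.uniform(0, 1000, (30, 2))
        df = points_df(xy, np.full(30, 4.2))
        grid = idw_rasterize(df, "pai", (0, 0, 1000, 1000), cell_size_m=100.0)
        assert np.allclose(grid.values, 4.2, atol=1e-12)

    def test_matches_brute_force_on_grid(self, rng):
        xy = rng.uniform(0, 500, (200, 2))
        vals = rng.normal(0, 1, 200)
        df = points_df(xy, vals)
        grid = idw_rasterize(df, "pai", (0, 0, 500, 500), cell_size_m=50.0, n_neighbors=0)
        gx, gy = grid.cell_centers()
        oracle = brute_force_idw(
            np.column_stack([gx.ravel(), gy.ravel()]), xy, vals, n_neighbors=0
        ).reshape(grid.values.shape)
        assert np.allclose(grid.values, oracle, rtol=1e-10, atol=1e-10)

    def test_ascii_grid_round_trip(self, rng, tmp_path):
        from gediagb.raster import read_ascii_grid, write_ascii_grid

        xy = rng.uniform(0, 300, (20, 2))
        df = points_df(xy, rng.normal(3, 1, 20))
        grid = idw_rasterize(df, "pai", (0, 0, 300, 300), cell_size_m=30.0)
        p = tmp_path / "g.asc"
        write_ascii_grid(grid, p)
        back = read_ascii_grid(p)
        assert back.values == pytest.approx(grid.values, abs=1e-8)
        assert back.cell_size_m == grid.cell_size_m


class TestSplit:
    def test_70_30_partition_counts_and_determinism(self, rng):
        t = points_df(rng.uniform(0, 100, (1000, 2)), rng.normal(0, 1, 1000))
        tr1, va1 = split_train_validation(t, 0.7, seed=5)
        tr2, va2 = split_train_validation(t, 0.7, seed=5)
        assert len(tr1) == 700 and len(va1) == 300
        pd.testing.assert_frame_equal(tr1, tr2)
        pd.testing.assert_frame_equal(va1, va2)

    def test_partition_is_disjoint_and_exhaustive(self, rng):
        t = points_df(rng.uniform(0, 100, (97, 2)), rng.normal(0, 1, 97))
        tr, va = split_train_validation(t, 0.7, seed=3)
        ids = sorted([*tr.shot_id, *va.shot_id])
        assert ids == sorted(t.shot_id)
        assert not set(tr.shot_id) & set(va.shot_id)

    def test_different_seeds_differ(self, rng):
        t = points_df(rng.uniform(0, 100, (200, 2)), rng.normal(0, 1, 200))
        tr1, _ = split_train_validation(t, 0.7, seed=1)
        tr2, _ = split_train_validation(t, 0.7, seed=2)
        assert set(tr1.shot_id) != set(tr2.shot_id)

    def test_tiny_or_bad_fraction_rejected(self):
        t = points_df([[0.0, 0.0]], [1.0])
        with pytest.raises(ValueError):
            split_train_validation(t, 0.7)
        t2 = points_df([[0.0, 0.0], [1.0, 1.0]], [1.0, 2.0])
        with pytest.raises(ValueError):
            split_train_validation(t2, 1.0)


class TestMetrics:
    def test_perfect_prediction(self):
        m = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m.r2, m.rmse, m.mae) == (1.0, 0.0, 0.0)

    def test_hand_checked_vectors(self):
        m = regression_metrics([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert m.rmse == pytest.approx(0.8165, abs=5e-5)
        assert m.mae == pytest.approx(0.6667, abs=5e-5)
        assert m.r2 == pytest.approx(0.0, abs=1e-12)

    def test_rmse_at_least_mae(self, rng):
        obs = rng.normal(0, 1, 100)
        pred = obs + rng.normal(0, 0.5, 100)
        m = regression_metrics(obs, pred)
        assert m.rmse >= m.mae >= 0.0 and m.r2 <= 1.0

    def test_constant_observations_flagged_not_nan_propagated(self):
        m = regression_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert not m.r2_defined
        assert np.isnan(m.r2)
        assert np.isfinite(m.rmse) and np.isfinite(m.mae)


class TestDensityExperiment:
    def test_row_count_and_determinism(self, small_scene):
        _, _, table = small_scene
        res1 = run_density_experiment(
            table, intervals=(5, 11), variables=("pai", "rg"), seed=9
        )
        res2 = run_density_experiment(
            table, intervals=(5, 11), variables=("pai", "rg"), seed=9
        )
        assert len(res1) == 4  # |intervals| x |variables|
        pd.testing.assert_frame_equal(res1, res2)

    def test_dense_sampling_of_smooth_field_is_accurate(self, small_scene):
        # noise-free footprints on a smooth field: interval 1 keeps every
        # shot, so validation points sit 60 m from train points and IDW
        # recovers the field almost exactly
        _, _, table = small_scene
        res = run_density_experiment(
            table, intervals=(1,), variables=("pai", "rg", "cover"), seed=2
        )
        assert (res.r2 > 0.9).all()

    def test_unknown_variable_rejected(self, small_scene):
        _, _, table = small_scene
        with pytest.raises(KeyError):
            run_density_experiment(table, intervals=(5,), variables=("nope",))

    def test_evaluation_excludes_validation_from_sources(self, small_scene):
        # with a search radius smaller than the thinned spacing every
        # prediction would be nodata -> ValueError, proving validation
        # points are not their own neighbors
        _, _, table = small_scene
        from gediagb.gedi_io import thin_footprints

        thinned = thin_footprints(table, 50)
        train, valid = split_train_validation(thinned, 0.7, seed=1)
        with pytest.raises(ValueError, match="nodata"):
            evaluate_interpolation(train, valid, "pai", max_search_radius_m=1e-3)
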