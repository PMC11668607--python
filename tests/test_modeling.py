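"""Feature extraction, correlation screening, CV and map prediction."""

import numpy as np
import pandas as pd
import pytest

from gediagb.modeling import (
    ModelConfig,
    correlation_screen,
    extract_features,
    fit_and_cross_validate,
    make_estimator,
    predict_map,
)
from gediagb.raster import RasterGrid


def const_raster(value, variable="pai", n=10, cell=100.0):
    return RasterGrid(0.0, n * cell, cell, np.full((n, n), value), variable=variable)


def plots_df(n, rng, agb=None):
    return pd.DataFrame(
        {
            "plot_id": [f"P{i}" for i in range(n)],
            "x": rng.uniform(50, 950, n),
            "y": rng.uniform(50, 950, n),
            "agb_t_per_hm2": rng.uniform(20, 200, n) if agb is None else agb,
        }
    )


class TestExtractFeatures:
    def test_constant_raster_gives_constant_feature(self, rng):
        plots = plots_df(10, rng)
        fm, report = extract_features(plots, {"pai": const_raster(3.3)})
        assert len(fm) == 10 and len(report) == 0
        assert (fm["pai"] == 3.3).all()

    def test_all_plots_outside_extent_excluded_with_report(self, rng):
        plots = plots_df(5, rng)
        plots["x"] += 10000.0
        with pytest.warns(UserWarning, match="excluded"):
            fm, report = extract_features(plots, {"pai": const_raster(1.0)})
        assert len(fm) == 0 and len(report) == 5
        assert report.reason.str.startswith("outside").all()

    def test_nodata_cells_excluded(self, rng):
        grid = const_raster(2.0)
        grid.values[:, :] = np.nan
        plots = plots_df(4, rng)
        with pytest.warns(UserWarning):
            fm, report = extract_features(plots, {"pai": grid})
        assert len(fm) == 0 and report.reason.str.startswith("nodata").all()

    def test_feature_tracks_field_through_interpolation(self, small_scene):
        # noise-free footprints -> IDW surface -> plot sampling recovers
        # the underlying field up to interpolation error
        from gediagb.interpolation import idw_rasterize

        spec, fields, table = small_scene
        grid = idw_rasterize(table, "rg", spec.extent, cell_size_m=120.0)
        rng = np.random.default_rng(3)
        n = 60
        plots = pd.DataFrame(
            {
                "plot_id": [f"P{i}" for i in range(n)],
                "x": rng.uniform(500, 11500, n),
                "y": rng.uniform(500, 11500, n),
                "agb_t_per_hm2": np.zeros(n),
            }
        )
        fm, _ = extract_features(plots, {"rg": grid})
        true = fields["rg"].value_at(fm.x.to_numpy(), fm.y.to_numpy())
        assert np.corrcoef(fm["rg"], true)[0, 1] > 0.9


class TestCorrelationScreen:
    def test_identical_feature_ranks_first_with_unit_r(self, rng):
        fm = plots_df(50, rng)
        fm["same"] = fm["agb_t_per_hm2"]
        fm["noise"] = rng.normal(0, 1, 50)
        top = correlation_screen(fm, top_k=2)
        assert top.iloc[0]["variable"] == "same"
        assert top.iloc[0]["r"] == pytest.approx(1.0)
        assert bool(top.iloc[0]["sig_0.01"])

    def test_negated_feature_has_negative_unit_r(self, rng):
        fm = plots_df(30, rng)
        fm["neg"] = -fm["agb_t_per_hm2"]
        top = correlation_screen(fm, top_k=1)
        assert top.iloc[0]["r"] == pytest.approx(-1.0)

    def test_known_correlation_recovered(self, rng):
        # bivariate normal with rho = 0.6, n = 200
        n = 200
        x = rng.normal(0, 1, n)
        y = 0.6 * x + np.sqrt(1 - 0.36) * rng.normal(0, 1, n)
        fm = plots_df(n, rng, agb=y)
        fm["feat"] = x
        top = correlation_screen(fm, top_k=1)
        assert top.iloc[0]["r"] == pytest.approx(0.6, abs=0.1)

    def test_zero_variance_feature_flagged_and_ranked_last(self, rng):
        fm = plots_df(25, rng)
        fm["flat"] = 1.0
        fm["ok"] = fm["agb_t_per_hm2"] + rng.normal(0, 20, 25)
        tab = correlation_screen(fm, top_k=2)
        assert tab.iloc[0]["variable"] == "ok"
        assert tab.iloc[-1]["variable"] == "flat"
        assert not tab.iloc[-1]["defined"]

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            correlation_screen(plots_df(2, rng))


class TestCrossValidation:
    def test_folds_partition_and_oof_covers_every_row(self, rng):
        fm = plots_df(60, rng)
        fm["f1"] = rng.normal(0, 1, 60)
        cv = fit_and_cross_validate(fm, ModelConfig("knn", seed=0), features=["f1"])
        assert cv.n_folds == 10
        assert cv.oof_predictions["predicted"].notna().all()
        assert len(cv.fold_metrics) == 10

    def test_rf_recovers_noiseless_linear_response(self, rng):
        n = 200
        x = rng.uniform(0, 10, n)
        fm = plots_df(n, rng, agb=3.0 * x + 5.0)
        fm["f1"] = x
        cv = fit_and_cross_validate(fm, ModelConfig("rf", seed=1), features=["f1"])
        assert cv.oof_metrics.r2 > 0.9

    def test_permuted_response_scores_near_zero(self, rng):
        n = 200
        x = rng.normal(0, 1, n)
        fm = plots_df(n, rng, agb=rng.permutation(3.0 * x))
        fm["f1"] = x
        cv = fit_and_cross_validate(fm, ModelConfig("rf", seed=2), features=["f1"])
        assert cv.oof_metrics.r2 <= 0.1

    def test_constant_response_flagged(self, rng):
        fm = plots_df(40, rng, agb=np.full(40, 5.0))
        fm["f1"] = rng.normal(0, 1, 40)
        cv = fit_and_cross_validate(fm, ModelConfig("knn", seed=0), features=["f1"])
        assert not cv.r2_defined
        assert np.isfinite(cv.mean_rmse)

    def test_identical_seed_reproduces_folds(self, rng):
        fm = plots_df(50, rng)
        fm["f1"] = rng.normal(0, 1, 50)
        a = fit_and_cross_validate(fm, ModelConfig("rf", seed=7), features=["f1"])
        b = fit_and_cross_validate(fm, ModelConfig("rf", seed=7), features=["f1"])
        assert np.array_equal(
            a.oof_predictions["predicted"], b.oof_predictions["predicted"]
        )

    def test_unsupported_algorithm_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig("gbm")

    def test_too_few_rows_rejected(self, rng):
        fm = plots_df(5, rng)
        fm["f1"] = 1.0
        with pytest.raises(ValueError):
            fit_and_cross_validate(fm, ModelConfig("rf"), features=["f1"])


class TestPredictMap:
    def _trained(self, rng, algorithm="rf"):
        fm = plots_df(80, rng)
        fm["pai"] = rng.uniform(1, 5, 80)
        fm["rg"] = rng.uniform(20, 60, 80)
        cfg = ModelConfig(algorithm, seed=0)
        est = make_estimator(cfg)
        est.fit(fm[["pai", "rg"]].to_numpy(), fm["agb_t_per_hm2"].to_numpy())
        return est, fm

    def test_constant_features_give_constant_map(self, rng):
        est, _ = self._trained(rng)
        rasters = {"pai": const_raster(3.0, "pai"), "rg": const_raster(40.0, "rg")}
        grid, summary = predict_map(est, rasters, ["pai", "rg"])
        assert np.allclose(grid.values, grid.values[0, 0])
        assert summary.min == pytest.approx(summary.max)

    def test_summary_order_statistics_and_total(self, rng):
        est, _ = self._trained(rng)
        pai = const_raster(3.0, "pai")
        pai.values += rng.normal(0, 0.3, pai.values.shape)
        rasters = {"pai": pai, "rg": const_raster(40.0, "rg")}
        grid, s = predict_map(est, rasters, ["pai", "rg"])
        assert s.min <= s.mean <= s.max
        area_hm2 = s.mapped_cells * (100.0**2) / 1e4
        assert s.total_1e4_t == pytest.approx(s.mean * area_hm2 / 1e4, rel=1e-9)

    def test_averaging_predictors_bounded_by_training_range(self, rng):
        for algo in ("rf", "knn"):
            est, fm = self._trained(rng, algo)
            pai = const_raster(3.0, "pai")
            pai.values += rng.normal(0, 1.0, pai.values.shape)
            rasters = {"pai": pai, "rg": const_raster(40.0, "rg")}
            grid, _ = predict_map(est, rasters, ["pai", "rg"])
            y = fm["agb_t_per_hm2"]
            assert np.nanmin(grid.values) >= y.min() - 1e-9
            assert np.nanmax(grid.values) <= y.max() + 1e-9

    def test_nodata_features_propagate_to_map(self, rng):
        est, _ = self._trained(rng)
        pai = const_raster(3.0, "pai")
        pai.values[0, :] = np.nan
        rasters = {"pai": pai, "rg": const_raster(40.0, "rg")}
        grid, s = predict_map(est, rasters, ["pai", "rg"])
        assert np.isnan(grid.values[0]).all()
        assert s.mapped_cells == grid.values.size - grid.values.shape[1]

    def test_misaligned_rasters_rejected(self, rng):
        est, _ = self._trained(rng)
        rasters = {
            "pai": const_raster(3.0, "pai"),
            "rg": const_raster(40.0, "rg", n=12),
        }
        with pytest.raises(ValueError, match="misaligned"):
            predict_map(est, rasters, ["pai", "rg"])
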