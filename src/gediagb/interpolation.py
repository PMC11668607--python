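"""Inverse-distance-weighted interpolation and the footprint-density experiment.

The interpolator predicts a value at x0 as the weighted average of the
N nearest measured points,

    Z*(x0) = sum_i w_i Z(x_i),   w_i = d_i^-p / sum_j d_j^-p

with p the distance power (1 or 2 in common practice; default 2). IDW
is an exact interpolator: a query coinciding with a measured point
returns that point's value. Accuracy is scored with the coefficient of
determination R2, the root mean square error and the mean absolute
error between observed and predicted values.

``run_density_experiment`` measures how interpolation accuracy responds
to footprint density: for each thinning interval k it keeps every k-th
shot per beam, splits the survivors 70/30, interpolates each variable
from the 70 % and scores it on the held-out 30 %.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .gedi_io import thin_footprints
from .raster import RasterGrid

__all__ = [
    "IDWInterpolator",
    "EvaluationMetrics",
    "idw_predict",
    "idw_rasterize",
    "split_train_validation",
    "evaluate_interpolation",
    "run_density_experiment",
    "regression_metrics",
]

ZERO_DISTANCE_M = 1e-9


class IDWInterpolator(RegressorMixin, BaseEstimator):
    """Inverse-distance-weighting spatial regressor (sklearn estimator).

    Parameters
    ----------
    power : float, default 2.0
        Distance exponent p (> 0).
    n_neighbors : int, default 12
        Measured points per prediction; 0 uses all points.
    max_search_radius_m : float or None, default None
        Neighbors beyond this distance are ignored; a query with no
        neighbor in radius yields NaN (nodata). None = unlimited.

    A query within 1e-9 m of a measured point returns that point's value
    exactly. Ties among equidistant Nth neighbors resolve to the point
    earliest in the training order (sort by shot_id upstream for a
    data-independent rule).
    """

    def __init__(
        self,
        power: float = 2.0,
        n_neighbors: int = 12,
        max_search_radius_m: Optional[float] = None,
    ):
        self.power = power
        self.n_neighbors = n_neighbors
        self.max_search_radius_m = max_search_radius_m

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_points, 2) planar coordinates")
        if len(X) == 0:
            raise ValueError("cannot fit IDW on an empty point set")
        if y.shape != (len(X),):
            raise ValueError("y must be one value per point")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("coordinates and values must be finite")
        if not self.power > 0:
            raise ValueError("power must be positive")
        if self.n_neighbors < 0:
            raise ValueError("n_neighbors must be >= 0")
        self.X_ = X
        self.y_ = y
        self.tree_ = cKDTree(X)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "tree_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        k = self.n_neighbors if self.n_neighbors else len(self.X_)
        k = min(k, len(self.X_))
        bound = np.inf if self.max_search_radius_m is None else self.max_search_radius_m
        dist, idx = self.tree_.query(X, k=k, distance_upper_bound=bound)
        dist = np.asarray(dist, dtype=float).reshape(len(X), -1)
        idx = np.asarray(idx).reshape(len(X), -1)

        out = np.full(len(X), np.nan)
        valid = np.isfinite(dist)  # cKDTree marks out-of-radius with inf
        any_valid = valid.any(axis=1)
        # exact-interpolator short-circuit
        exact = valid & (dist < ZERO_DISTANCE_M)
        has_exact = exact.any(axis=1)
        for i in np.flatnonzero(has_exact):
            out[i] = self.y_[idx[i, np.argmax(exact[i])]]

        todo = np.flatnonzero(any_valid & ~has_exact)
        if todo.size:
            d = dist[todo]
            w = np.where(valid[todo], d, 1.0) ** (-self.power)
            w[~valid[todo]] = 0.0
            vals = self.y_[np.where(valid[todo], idx[todo], 0)]
            out[todo] = (w * vals).sum(axis=1) / w.sum(axis=1)
        return out


def idw_predict(
    points,
    measured: pd.DataFrame,
    variable: str,
    power: float = 2.0,
    n_neighbors: int = 12,
    max_search_radius_m: Optional[float] = None,
) -> np.ndarray:
    """Functional wrapper: interpolate ``variable`` from a footprint table."""
    if len(measured) == 0:
        raise ValueError("measured table is empty")
    src = measured.sort_values("shot_id") if "shot_id" in measured else measured
    est = IDWInterpolator(power, n_neighbors, max_search_radius_m)
    est.fit(src[["x", "y"]].to_numpy(), src[variable].to_numpy(float))
    return est.predict(np.atleast_2d(np.asarray(points, dtype=float)))


def idw_rasterize(
    measured: pd.DataFrame,
    variable: str,
    extent: tuple[float, float, float, float],
    cell_size_m: float = 30.0,
    power: float = 2.0,
    n_neighbors: int = 12,
    max_search_radius_m: Optional[float] = None,
) -> RasterGrid:
    """Interpolate a footprint variable to a wall-to-wall grid.

    Every cell center is predicted; cells with no neighbor within the
    search radius become nodata (NaN).
    """
    xmin, ymin, xmax, ymax = extent
    if not (xmax > xmin and ymax > ymin):
        raise ValueError(f"degenerate extent {extent}")
    n_cols = max(1, int(np.ceil((xmax - xmin) / cell_size_m)))
    n_rows = max(1, int(np.ceil((ymax - ymin) / cell_size_m)))
    grid = RasterGrid(
        origin_x=xmin,
        origin_y=ymin + n_rows * cell_size_m,
        cell_size_m=cell_size_m,
        values=np.full((n_rows, n_cols), np.nan),
        variable=variable,
    )
    gx, gy = grid.cell_centers()
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    pred = idw_predict(pts, measured, variable, power, n_neighbors, max_search_radius_m)
    grid.values = pred.reshape(n_rows, n_cols)
    return grid


def split_train_validation(
    table: pd.DataFrame, fraction: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded uniform random partition into train/validation.

    Disjoint and exhaustive; train size is round(n * fraction).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n = len(table)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(n * fraction))
    n_train = min(max(n_train, 1), n - 1)
    return (
        table.iloc[np.sort(perm[:n_train])].copy(),
        table.iloc[np.sort(perm[n_train:])].copy(),
    )


@dataclass(frozen=True)
class EvaluationMetrics:
    """R2 / RMSE / MAE over n scored points.

    ``r2_defined`` is False when the observations are constant (zero
    total variance): R2 has no meaning there and is reported as NaN
    rather than propagated silently.
    """

    r2: float
    rmse: float
    mae: float
    n: int
    r2_defined: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


def regression_metrics(observed, predicted) -> EvaluationMetrics:
    """R2 = 1 - SSres/SStot, RMSE = sqrt(mean residual^2), MAE = mean |residual|."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be 1-D and equal length")
    if obs.size < 2:
        raise ValueError("need at least 2 points to score")
    resid = pred - obs
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        return EvaluationMetrics(float("nan"), rmse, mae, obs.size, r2_defined=False)
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return EvaluationMetrics(r2, rmse, mae, obs.size)


def evaluate_interpolation(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    variable: str,
    power: float = 2.0,
    n_neighbors: int = 12,
    max_search_radius_m: Optional[float] = None,
) -> EvaluationMetrics:
    """Interpolate from train, score at held-out validation footprints.

    Validation points are never interpolation sources. Nodata
    predictions (no neighbor in radius) are excluded from the score; if
    every prediction is nodata the evaluation fails.
    """
    if len(validation) == 0:
        raise ValueError("validation set is empty")
    pred = idw_predict(
        validation[["x", "y"]].to_numpy(),
        train,
        variable,
        power,
        n_neighbors,
        max_search_radius_m,
    )
    ok = np.isfinite(pred)
    if not ok.any():
        raise ValueError(f"all predictions are nodata for {variable!r}")
    obs = validation[variable].to_numpy(float)
    return regression_metrics(obs[ok], pred[ok])


def run_density_experiment(
    table: pd.DataFrame,
    intervals: Sequence[int] = (10, 30, 50, 70, 100),
    variables: Optional[Sequence[str]] = None,
    fraction: float = 0.7,
    power: float = 2.0,
    n_neighbors: int = 12,
    max_search_radius_m: Optional[float] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Interpolation accuracy vs footprint density.

    For each interval k: thin per beam, split 70/30 (seeded), fit IDW on
    the train fraction for each variable and score on validation.
    Returns one row per (interval, variable): n_train, n_valid, r2,
    rmse, mae. Deterministic under the seed.
    """
    from .synthetic import METRIC_SCHEMA

    if variables is None:
        variables = [m for m in METRIC_SCHEMA if m in table.columns]
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise KeyError(f"variables absent from table: {missing}")
    rows = []
    for k in intervals:
        if int(k) < 1:
            raise ValueError(f"interval must be >= 1, got {k}")
        thinned = thin_footprints(table, int(k))
        train, valid = split_train_validation(thinned, fraction, seed)
        for var in variables:
            try:
                m = evaluate_interpolation(
                    train, valid, var, power, n_neighbors, max_search_radius_m
                )
            except ValueError as exc:
                raise ValueError(f"interval={k}, variable={var!r}: {exc}") from exc
            rows.append(
                {
                    "interval": int(k),
                    "variable": var,
                    "n_train": len(train),
                    "n_valid": m.n,
                    "r2": m.r2,
                    "rmse": m.rmse,
                    "mae": m.mae,
                }
            )
    return pd.DataFrame(rows)


def write_experiment_result(result: pd.DataFrame, csv_path=None, json_path=None) -> None:
    if csv_path is not None:
        result.to_csv(csv_path, index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(result.to_dict(orient="records"), fh, indent=1)
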