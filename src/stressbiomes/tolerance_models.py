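"""Random-forest models of the tolerance axes, with diagnostics.

Per plant functional type, two regression forests are fitted (one per
stress-tolerance axis) on the retained rotated components plus topography.
Variable importance is the mean RMSE increase after permutation; marginal
effects come from partial dependence; spatial structure left in the
residuals is checked with spatially blocked cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance as _sk_perm_importance


@dataclass
class ForestParams:
    n_trees: int = 500
    min_node_size: int = 5
    mtry: int | None = None  # default floor(p / 3), at least 1
    seed: int = 0


@dataclass
class FittedAxisModel:
    pft: str
    axis: str
    predictors: list[str]
    forest: RandomForestRegressor = field(repr=False)
    oob_rmse: float
    inbag_rmse: float
    predictions: np.ndarray = field(repr=False)
    prediction_sd: np.ndarray = field(repr=False)  # between-tree sd
    y: np.ndarray = field(repr=False)

    @property
    def oob_r2(self) -> float:
        ss_res = self.oob_rmse**2 * len(self.y)
        ss_tot = ((self.y - self.y.mean()) ** 2).sum()
        return 1.0 - ss_res / ss_tot


def _rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def fit_axis_model(
    data: pd.DataFrame,
    axis: str,
    predictors: list[str],
    params: ForestParams | None = None,
    pft: str = "",
    min_rows: int = 50,
) -> FittedAxisModel:
    """Fit one regression forest for one tolerance axis.

    Reports out-of-bag and in-bag RMSE, per-row predictions and the
    between-tree standard deviation of predictions (the uncertainty map).
    Deterministic given the seed in ``params``.
    """
    params = params or ForestParams()
    missing = [c for c in [axis, *predictors] if c not in data.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if len(data) < min_rows:
        raise ValueError(f"need at least {min_rows} rows, got {len(data)}")
    X = data[predictors].to_numpy(dtype=float)
    y = data[axis].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in predictors or response")
    if np.ptp(y) == 0:
        raise ValueError(f"response {axis!r} is constant")

    mtry = params.mtry or max(1, len(predictors) // 3)
    forest = RandomForestRegressor(
        n_estimators=params.n_trees,
        max_features=mtry,
        min_samples_leaf=params.min_node_size,
        oob_score=True,
        bootstrap=True,
        random_state=params.seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    preds = forest.predict(X)
    tree_preds = np.stack([t.predict(X) for t in forest.estimators_])
    oob = forest.oob_prediction_
    return FittedAxisModel(
        pft=pft,
        axis=axis,
        predictors=list(predictors),
        forest=forest,
        oob_rmse=_rmse(y, oob),
        inbag_rmse=_rmse(y, preds),
        predictions=preds,
        prediction_sd=tree_preds.std(axis=0),
        y=y,
    )


def permutation_importance(
    model: FittedAxisModel,
    data: pd.DataFrame,
    n_perm: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean RMSE loss after permuting each predictor ``n_perm`` times.

    Importance of predictor j is ``mean(RMSE_perm_j) - RMSE_baseline``;
    the full distribution of per-permutation losses is returned in long
    format (columns: predictor, draw, rmse_loss, plus baseline_rmse and
    mean_loss repeated per predictor) so the spread can be plotted.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = data[model.predictors].to_numpy(dtype=float)
    y = data[model.axis].to_numpy(dtype=float)
    baseline = _rmse(y, model.forest.predict(X))
    res = _sk_perm_importance(
        model.forest,
        X,
        y,
        scoring="neg_root_mean_squared_error",
        n_repeats=n_perm,
        random_state=seed,
        n_jobs=1,
    )
    # res.importances[j, r] = (-baseline) - (-rmse_perm) = rmse_perm - baseline
    rows = []
    for j, name in enumerate(model.predictors):
        losses = res.importances[j]
        for r, loss in enumerate(losses):
            rows.append(
                {
                    "predictor": name,
                    "draw": r,
                    "rmse_loss": loss,
                    "baseline_rmse": baseline,
                    "mean_loss": losses.mean(),
                }
            )
    out = pd.DataFrame(rows)
    out["n_perm"] = n_perm
    return out


def importance_ranking(importance: pd.DataFrame) -> pd.DataFrame:
    """Collapse the long importance table to one row per predictor."""
    return (
        importance.groupby("predictor", as_index=False)["rmse_loss"]
        .mean()
        .rename(columns={"rmse_loss": "mean_loss"})
        .sort_values("mean_loss", ascending=False)
        .reset_index(drop=True)
    )


def partial_dependence(
    model: FittedAxisModel,
    data: pd.DataFrame,
    predictor: str,
    n_grid: int = 25,
) -> pd.DataFrame:
    """Partial dependence of the fitted forest on one predictor.

    ``PD(v)`` is the mean prediction over all rows with the predictor
    forced to ``v``, on an equispaced grid spanning the observed 1st-99th
    percentile range.
    """
    if predictor not in model.predictors:
        raise ValueError(f"{predictor!r} is not a model predictor")
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    X = data[model.predictors].to_numpy(dtype=float)
    j = model.predictors.index(predictor)
    lo, hi = np.percentile(X[:, j], [1, 99])
    grid = np.linspace(lo, hi, n_grid)
    pd_vals = np.empty(n_grid)
    Xw = X.copy()
    for g, v in enumerate(grid):
        Xw[:, j] = v
        pd_vals[g] = model.forest.predict(Xw).mean()
    return pd.DataFrame({"predictor": predictor, "grid": grid, "pd": pd_vals})


def spatial_cv_residual_check(
    data: pd.DataFrame,
    axis: str,
    predictors: list[str],
    n_folds: int = 5,
    params: ForestParams | None = None,
    seed: int = 0,
    coord_cols: tuple[str, str] = ("center_x", "center_y"),
) -> dict:
    """Spatially blocked CV; test residuals for coordinate trends.

    Folds are contiguous spatial blocks (k-means on the hexagon centers).
    Out-of-fold residuals are regressed on x and y by OLS; the report
    carries the slopes, their p-values, the regression R^2, the CV RMSE
    and the fold labels.  A significant slope indicates spatial structure
    the forest did not capture.
    """
    if n_folds < 2 or n_folds > len(data):
        raise ValueError("n_folds must be in [2, n_rows]")
    params = params or ForestParams(seed=seed)
    coords = data[list(coord_cols)].to_numpy(dtype=float)
    km = KMeans(n_clusters=n_folds, random_state=seed, n_init=10)
    folds = km.fit_predict(coords)

    X = data[predictors].to_numpy(dtype=float)
    y = data[axis].to_numpy(dtype=float)
    resid = np.empty(len(y))
    mtry = params.mtry or max(1, len(predictors) // 3)
    for f in range(n_folds):
        test = folds == f
        forest = RandomForestRegressor(
            n_estimators=params.n_trees,
            max_features=mtry,
            min_samples_leaf=params.min_node_size,
            random_state=params.seed,
            n_jobs=1,
        )
        forest.fit(X[~test], y[~test])
        resid[test] = y[test] - forest.predict(X[test])

    ols = sm.OLS(resid, sm.add_constant(coords)).fit()
    return {
        "slopes": {"x": float(ols.params[1]), "y": float(ols.params[2])},
        "p_values": {"x": float(ols.pvalues[1]), "y": float(ols.pvalues[2])},
        "r_squared": float(ols.rsquared),
        "cv_rmse": _rmse(y, y - resid),
        "fold_labels": folds,
        "n_folds": n_folds,
    }
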