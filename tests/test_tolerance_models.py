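"""Forest models: signal recovery, importance, partial dependence, spatial CV."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stressbiomes.tolerance_models import (
    ForestParams,
    fit_axis_model,
    importance_ranking,
    partial_dependence,
    permutation_importance,
    spatial_cv_residual_check,
)

# mtry = p so single-driver toys are learned at full strength
FAST = ForestParams(n_trees=100, min_node_size=2, mtry=5, seed=0)


def _linear_frame(rng, n=300, p=5, noise=0.0, slope=2.0):
    X = rng.normal(size=(n, p))
    y = slope * X[:, 0] + rng.normal(0, noise, n)
    cols = {f"p{j}": X[:, j] for j in range(p)}
    return pd.DataFrame({"axis1": y, **cols}), [f"p{j}" for j in range(p)]


class TestFit:
    def test_strong_signal_recovered(self, rng):
        data, preds = _linear_frame(rng, noise=0.0)
        model = fit_axis_model(data, "axis1", preds, FAST)
        assert model.oob_r2 > 0.9

    def test_deterministic_given_seed(self, rng):
        data, preds = _linear_frame(rng, noise=0.5)
        m1 = fit_axis_model(data, "axis1", preds, FAST)
        m2 = fit_axis_model(data, "axis1", preds, FAST)
        np.testing.assert_array_equal(m1.predictions, m2.predictions)
        assert m1.oob_rmse == m2.oob_rmse

    def test_null_response_has_no_skill(self):
        """Median OOB R^2 over seeds is ~0 when the response is
        independent of every predictor."""
        r2 = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(400, 5))
            data = pd.DataFrame({f"p{j}": X[:, j] for j in range(5)})
            data["axis1"] = rng.normal(size=400)
            model = fit_axis_model(
                data, "axis1", [f"p{j}" for j in range(5)],
                ForestParams(n_trees=60, seed=seed),
            )
            r2.append(model.oob_r2)
        assert np.median(r2) <= 0.05

    def test_constant_response_and_schema_errors(self, rng):
        data, preds = _linear_frame(rng)
        bad = data.copy()
        bad["axis1"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_axis_model(bad, "axis1", preds, FAST)
        with pytest.raises(ValueError, match="missing"):
            fit_axis_model(data, "axis1", preds + ["ghost"], FAST)

    def test_too_few_rows_rejected(self, rng):
        data, preds = _linear_frame(rng, n=20)
        with pytest.raises(ValueError, match="rows"):
            fit_axis_model(data, "axis1", preds, FAST)


class TestImportance:
    def test_null_predictor_loss_near_zero(self, rng):
        """A pure-noise predictor's mean loss sits inside the central 95%
        of its own permutation-loss distribution around 0."""
        data, preds = _linear_frame(rng, noise=0.1)
        model = fit_axis_model(data, "axis1", preds, FAST)
        imp = permutation_importance(model, data, n_perm=100, seed=1)
        null_losses = imp.loc[imp.predictor == "p4", "rmse_loss"].to_numpy()
        driver_loss = imp.loc[imp.predictor == "p0", "rmse_loss"].mean()
        # the null predictor's own permutation distribution is centered
        # near zero and far below the planted driver's loss
        lo, hi = np.percentile(null_losses, [2.5, 97.5])
        assert lo - 1e-9 <= np.mean(null_losses) <= hi + 1e-9
        assert abs(np.mean(null_losses)) < 0.05 * driver_loss

    def test_sole_driver_ranks_first(self):
        """The single planted driver tops the ranking in >= 19/20 seeds."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            data, preds = _linear_frame(rng, n=250, noise=0.3)
            model = fit_axis_model(
                data, "axis1", preds, ForestParams(n_trees=80, seed=seed)
            )
            imp = permutation_importance(model, data, n_perm=20, seed=seed)
            if importance_ranking(imp).iloc[0]["predictor"] == "p0":
                hits += 1
        assert hits >= 19

    def test_noise_free_loss_matches_direct_recomputation(self, rng):
        """Permuting the only driver of a noise-free model produces the
        same mean loss as recomputing RMSE directly with the same
        permutations."""
        data, preds = _linear_frame(rng, n=200, p=2, noise=0.0)
        model = fit_axis_model(data, "axis1", preds, FAST)
        imp = permutation_importance(model, data, n_perm=10, seed=3)
        mean_loss = imp.loc[imp.predictor == "p0", "rmse_loss"].mean()

        X = data[preds].to_numpy()
        y = data["axis1"].to_numpy()
        base = np.sqrt(np.mean((y - model.forest.predict(X)) ** 2))
        oracle_rng = np.random.default_rng(7)
        losses = []
        for _ in range(50):
            Xp = X.copy()
            Xp[:, 0] = oracle_rng.permutation(Xp[:, 0])
            losses.append(np.sqrt(np.mean((y - model.forest.predict(Xp)) ** 2)) - base)
        assert mean_loss == pytest.approx(np.mean(losses), rel=0.15)

    def test_importance_invariant_to_column_order(self, rng):
        data, preds = _linear_frame(rng, n=200, noise=0.2)
        model = fit_axis_model(data, "axis1", preds, FAST)
        imp_a = importance_ranking(permutation_importance(model, data, 20, seed=5))
        reordered = data[["axis1"] + preds[::-1]]
        model_b = fit_axis_model(reordered, "axis1", preds, FAST)
        imp_b = importance_ranking(permutation_importance(model_b, reordered, 20, seed=5))
        assert imp_a.iloc[0]["predictor"] == imp_b.iloc[0]["predictor"]

    def test_n_perm_validation(self, rng):
        data, preds = _linear_frame(rng)
        model = fit_axis_model(data, "axis1", preds, FAST)
        with pytest.raises(ValueError):
            permutation_importance(model, data, n_perm=0)


class TestPartialDependence:
    def test_flat_for_constant_prediction(self, rng):
        data, preds = _linear_frame(rng, noise=0.0, slope=0.0)
        data["axis1"] = 5.0 + 1e-6 * rng.normal(size=len(data))  # ~constant
        model = fit_axis_model(data, "axis1", preds, FAST)
        curve = partial_dependence(model, data, "p1", n_grid=10)
        assert curve["pd"].std() < 1e-3

    def test_recovers_linear_slope(self, rng):
        data, preds = _linear_frame(rng, n=600, noise=0.0, slope=2.0)
        model = fit_axis_model(data, "axis1", preds,
                               ForestParams(n_trees=200, min_node_size=1, mtry=5, seed=0))
        curve = partial_dependence(model, data, "p0", n_grid=30)
        interior = curve.iloc[5:-5]
        slope = np.polyfit(interior["grid"], interior["pd"], 1)[0]
        assert slope == pytest.approx(2.0, abs=0.2)

    def test_monotone_driver_gives_nondecreasing_curve(self, rng):
        x = rng.uniform(-2, 2, 500)
        data = pd.DataFrame({"axis2": np.tanh(x) + rng.normal(0, 0.05, 500),
                             "clim": x, "other": rng.normal(size=500)})
        model = fit_axis_model(data, "axis2", ["clim", "other"], FAST)
        curve = partial_dependence(model, data, "clim", n_grid=20)
        interior = curve["pd"].iloc[2:-2].to_numpy()
        assert np.all(np.diff(interior) >= -0.02)

    def test_grid_validation(self, rng):
        data, preds = _linear_frame(rng)
        model = fit_axis_model(data, "axis1", preds, FAST)
        with pytest.raises(ValueError):
            partial_dependence(model, data, "p0", n_grid=1)
        with pytest.raises(ValueError):
            partial_dependence(model, data, "ghost")


def _spatial_frame(rng, n=150, trend=0.0, noise=0.3):
    coords = rng.uniform(0, 1e6, (n, 2))
    X = rng.normal(size=(n, 3))
    y = X[:, 0] + trend * coords[:, 0] / 1e6 + rng.normal(0, noise, n)
    return pd.DataFrame({
        "axis1": y, "p0": X[:, 0], "p1": X[:, 1], "p2": X[:, 2],
        "center_x": coords[:, 0], "center_y": coords[:, 1],
    })


class TestSpatialCV:
    def test_folds_partition_rows(self, rng):
        data = _spatial_frame(rng)
        report = spatial_cv_residual_check(
            data, "axis1", ["p0", "p1", "p2"], n_folds=4,
            params=ForestParams(n_trees=30, seed=0), seed=0,
        )
        folds = report["fold_labels"]
        assert len(folds) == len(data)
        assert set(folds) == set(range(4))

    def test_planted_east_west_trend_detected(self):
        """An injected linear x-trend is flagged (p < 0.01) in >= 19/20 seeds."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            data = _spatial_frame(rng, trend=1.5, noise=0.2)
            report = spatial_cv_residual_check(
                data, "axis1", ["p0", "p1", "p2"], n_folds=4,
                params=ForestParams(n_trees=40, seed=seed), seed=seed,
            )
            if report["p_values"]["x"] < 0.01:
                hits += 1
        assert hits >= 19

    def test_null_trend_pvalues_uniform(self):
        """With spatially exchangeable data, the x-trend p-values are
        approximately uniform (KS test at alpha = 0.01 over seeds)."""
        pvals = []
        for seed in range(60):
            rng = np.random.default_rng(1000 + seed)
            data = _spatial_frame(rng, n=120, trend=0.0, noise=0.3)
            report = spatial_cv_residual_check(
                data, "axis1", ["p0", "p1", "p2"], n_folds=4,
                params=ForestParams(n_trees=30, seed=seed), seed=seed,
            )
            pvals.append(report["p_values"]["x"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_fold_count_validation(self, rng):
        data = _spatial_frame(rng, n=60)
        with pytest.raises(ValueError):
            spatial_cv_residual_check(data, "axis1", ["p0"], n_folds=1)
        with pytest.raises(ValueError):
            spatial_cv_residual_check(data, "axis1", ["p0"], n_folds=61)
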