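"""LASSO selection, EM sparse regression, bootstrap evaluation, ranking."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from polysorb.model import (
    ModelConfig,
    ProteinAdsorptionModel,
    bootstrap_evaluate,
    em_sparse_regression,
    lasso_select,
    rank_coefficients,
)


def ols_coef(x: np.ndarray, y: np.ndarray) -> float:
    xc = (x - x.mean()) / x.std(ddof=0)
    yc = y - y.mean()
    return float((xc @ yc) / (xc @ xc))


class TestLassoSelect:
    def test_recovers_informative_column_among_decoys(self):
        rng = np.random.default_rng(12)
        n = 60
        X = pd.DataFrame(
            rng.standard_normal((n, 51)), columns=[f"x{i}" for i in range(51)]
        )
        y = 3.0 * X["x0"] + rng.normal(0, 0.01, n)
        selected = lasso_select(X, y, ModelConfig(seed=1))
        assert "x0" in selected

    def test_null_response_selects_almost_nothing(self):
        """1-SE rule on pure noise: <= 2 features in at least 90% of seeds."""
        rng = np.random.default_rng(99)
        n = 40
        X = pd.DataFrame(
            rng.standard_normal((n, 30)), columns=[f"x{i}" for i in range(30)]
        )
        near_empty = 0
        n_seeds = 50
        for seed in range(n_seeds):
            y = np.random.default_rng(1000 + seed).standard_normal(n)
            if len(lasso_select(X, y, ModelConfig(seed=seed))) <= 2:
                near_empty += 1
        assert near_empty >= int(0.9 * n_seeds)

    def test_duplicated_informative_column_representable(self):
        rng = np.random.default_rng(4)
        n = 50
        x = rng.standard_normal(n)
        X = pd.DataFrame(
            {"a": x, "b": x.copy(), "c": rng.standard_normal(n)}
        )
        y = 2.0 * x + rng.normal(0, 0.05, n)
        selected = lasso_select(X, y, ModelConfig(seed=3))
        assert {"a", "b"} & set(selected)

    def test_constant_response_rejected(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        with pytest.raises(ValueError, match="no variance"):
            lasso_select(X, np.ones(10), ModelConfig())


class TestEmSparseRegression:
    def test_intercept_only_on_empty_feature_set(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        fit = em_sparse_regression(pd.DataFrame(index=range(4)), y)
        assert fit.intercept == pytest.approx(2.5)
        assert fit.coefficients == {}

    def test_noise_free_equals_ols(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        y = 3.0 * (x - x.mean()) / x.std(ddof=0) + 1.0
        fit = em_sparse_regression(pd.DataFrame({"x": x}), y)
        assert fit.coefficients["x"] == pytest.approx(ols_coef(x, y), abs=1e-4)
        assert fit.converged

    def test_orthonormal_nulls_pruned_to_zero(self):
        rng = np.random.default_rng(1)
        n = 100
        Q, _ = np.linalg.qr(rng.standard_normal((n, 10)))
        X = pd.DataFrame(Q * np.sqrt(n), columns=[f"c{i}" for i in range(10)])
        y = 5.0 * X["c0"] - 3.0 * X["c1"]
        fit = em_sparse_regression(X, np.asarray(y))
        assert fit.selected == ["c0", "c1"]
        for name in fit.feature_names[2:]:
            assert fit.coefficients.get(name, 0.0) == 0.0

    def test_shrinkage_never_exceeds_ols_on_orthonormal_design(self):
        rng = np.random.default_rng(2)
        n = 80
        Q, _ = np.linalg.qr(rng.standard_normal((n, 6)))
        Xs = Q * np.sqrt(n)
        X = pd.DataFrame(Xs, columns=[f"c{i}" for i in range(6)])
        y = Xs @ np.array([4.0, -2.0, 1.0, 0.0, 0.0, 0.0]) + rng.normal(0, 0.5, n)
        fit = em_sparse_regression(X, y)
        yc = y - y.mean()
        for k, name in enumerate(fit.feature_names):
            ols = float(Xs[:, k] @ yc / (Xs[:, k] @ Xs[:, k]))
            assert abs(fit.coefficients.get(name, 0.0)) <= abs(ols) + 1e-8

    def test_objective_monotone_non_increasing(self):
        rng = np.random.default_rng(5)
        for trial in range(20):
            n, p = 40, 8
            X = pd.DataFrame(
                rng.standard_normal((n, p)), columns=[f"v{i}" for i in range(p)]
            )
            w = np.zeros(p)
            w[:3] = rng.uniform(0.5, 2.0, 3)
            y = X.to_numpy() @ w + rng.normal(0, 0.5, n)
            fit = em_sparse_regression(X, y)  # raises internally on any increase
            diffs = np.diff(fit.objective_path)
            assert np.all(diffs <= 1e-9 * (1.0 + np.abs(fit.objective_path[:-1])))


class TestBootstrapEvaluate:
    def _linear_data(self, n=40, p=10, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.standard_normal((n, p)), columns=[f"x{i}" for i in range(p)]
        )
        y = 2.0 * X["x0"] - 1.5 * X["x1"] + rng.normal(0, noise, n)
        return X, np.asarray(y)

    def test_perfect_linear_data_scores_perfectly(self):
        X, y = self._linear_data(noise=0.0)
        result = bootstrap_evaluate(X, y, ModelConfig(n_boot=10, seed=1))
        assert np.all(result.rmse < 1e-4)
        assert np.all(result.r2 > 1.0 - 1e-6)

    def test_reproducible_under_seed(self):
        X, y = self._linear_data(noise=0.3, seed=3)
        a = bootstrap_evaluate(X, y, ModelConfig(n_boot=8, seed=7))
        b = bootstrap_evaluate(X, y, ModelConfig(n_boot=8, seed=7))
        assert np.array_equal(a.rmse, b.rmse)
        assert np.array_equal(a.r2, b.r2, equal_nan=True)
        assert a.seeds == b.seeds

    def test_constant_response_gives_nan_r2(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.standard_normal((20, 5)))
        X.columns = [f"x{i}" for i in range(5)]
        result = bootstrap_evaluate(X, np.full(20, 3.0), ModelConfig(n_boot=5, seed=0))
        assert np.all(np.isnan(result.r2))
        assert np.all(result.rmse == 0.0)

    def test_standardization_fit_on_train_only(self):
        """Test rows shifted far off the training distribution must not leak."""
        X, y = self._linear_data(noise=0.1, seed=5)
        result = bootstrap_evaluate(X, y, ModelConfig(n_boot=5, seed=2))
        for fit, (train, _) in zip(result.fits, result.splits):
            if not fit.feature_names:
                continue
            sub = X.iloc[train][fit.feature_names].to_numpy()
            assert fit.x_mean == pytest.approx(sub.mean(axis=0))


class TestRankCoefficients:
    def test_single_fit_sorted_by_magnitude(self):
        X = pd.DataFrame(
            np.random.default_rng(0).standard_normal((30, 3)),
            columns=["a", "b", "c"],
        )
        y = 0.5 * X["a"] + 3.0 * X["c"]
        fit = em_sparse_regression(X, np.asarray(y))
        ranked = rank_coefficients([fit])
        nonzero = ranked[ranked["mean_coef"] != 0]
        mags = nonzero["mean_coef"].abs().to_numpy()
        assert np.all(np.diff(mags) <= 0)
        assert ranked.iloc[0]["feature"] == "c"

    def test_alternating_signs_flagged_mixed(self):
        base = dict(
            feature_names=["f"], selected=["f"], intercept=0.0, converged=True,
            n_iter=1, objective_path=[0.0], x_mean=np.zeros(1), x_scale=np.ones(1),
            y_mean=0.0, sigma_hat=0.0, lam=0.0,
        )
        from polysorb.model import SparseFit

        fits = [
            SparseFit(coefficients={"f": +1.0}, **base),
            SparseFit(coefficients={"f": -1.0}, **base),
        ]
        ranked = rank_coefficients(fits)
        assert ranked.iloc[0]["sign_consensus"] == "mixed"

    def test_selection_frequency_drives_significance(self):
        from polysorb.model import SparseFit

        def mk(coefs):
            return SparseFit(
                feature_names=["a", "b"], selected=sorted(coefs),
                coefficients=coefs, intercept=0.0, converged=True, n_iter=1,
                objective_path=[0.0], x_mean=np.zeros(2), x_scale=np.ones(2),
                y_mean=0.0, sigma_hat=0.0, lam=0.0,
            )

        fits = [mk({"a": 1.0})] * 3 + [mk({"a": 1.0, "b": 0.5})]
        ranked = rank_coefficients(fits).set_index("feature")
        assert ranked.loc["a", "significant"]
        assert not ranked.loc["b", "significant"]


class TestModelSurface:
    def test_from_tables_joins_and_filters(self):
        adsorption = pd.DataFrame(
            {
                "polymer_id": ["p0", "p1", "p2", "p3"],
                "protein_id": ["insulin"] * 4,
                "log10_geomean": [3.0, 4.0, 5.0, 6.0],
                "snr": [10.0, 0.5, 10.0, 10.0],
                "passed_filter": [True, False, True, True],
            }
        )
        descriptors = pd.DataFrame(
            {"d1": [1.0, 2.0, 3.0, 4.0]}, index=["p0", "p1", "p2", "p3"]
        )
        descriptors.index.name = "polymer_id"
        model = ProteinAdsorptionModel.from_tables(adsorption, descriptors, "insulin")
        assert len(model.y) == 3  # p1 dropped by the SNR filter

    def test_fit_and_summary(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(
            rng.standard_normal((40, 6)), columns=[f"d{i}" for i in range(6)]
        )
        y = 2.0 * X["d2"] + rng.normal(0, 0.1, 40)
        model = ProteinAdsorptionModel(X, y, ModelConfig(seed=2), protein="insulin")
        res = model.fit()
        assert "insulin" in res.summary()
        assert res.rsquared() > 0.95
        assert "d2" in res.params.index

    def test_bootstrap_results_summary_and_frames(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(
            rng.standard_normal((30, 4)), columns=list("abcd")
        )
        y = X["a"].to_numpy() * 3 + rng.normal(0, 0.2, 30)
        model = ProteinAdsorptionModel(X, y, ModelConfig(n_boot=6, seed=4))
        boot = model.fit_bootstrap()
        frame = boot.metrics_frame()
        assert list(frame.columns) == ["bootstrap", "seed", "rmse", "r2"]
        assert len(frame) == 6
        assert "test R^2" in boot.summary()

    def test_plots_return_axes(self):
        import matplotlib

        matplotlib.use("Agg")
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.standard_normal((30, 4)), columns=list("wxyz"))
        y = X["w"].to_numpy() * 2 + rng.normal(0, 0.2, 30)
        boot = ProteinAdsorptionModel(
            X, y, ModelConfig(n_boot=4, seed=1)
        ).fit_bootstrap()
        assert boot.plot_predictions() is not None
        assert boot.plot_coefficients() is not None
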