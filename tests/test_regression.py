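"""The four calibration engines, cross-validation, and persistence."""

import numpy as np
import pytest

from nspec import (
    ConfigurationError,
    CVScheme,
    DEFAULT_SVR_GRID,
    DegenerateDataError,
    FittedModel,
    LOO,
    ShapeError,
    fit_mlr,
    fit_pcr,
    fit_pls,
    fit_svr_rbf,
    rmsecv,
)


def _random_instance(n=40, p=8, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = 1.5 + X @ beta + noise * rng.normal(size=n)
    return X, y


class TestMLR:
    def test_exact_affine_relationship_recovered(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 2))
        y = 0.7 + 2.0 * X[:, 0] - 1.2 * X[:, 1]
        model = fit_mlr(X, y)
        assert np.allclose(model.predict(X), y, atol=1e-10)
        assert model.coef == pytest.approx([2.0, -1.2], abs=1e-10)
        assert model.intercept == pytest.approx(0.7, abs=1e-10)

    def test_duplicated_column_gives_identical_predictions(self):
        X, y = _random_instance(n=30, p=5, seed=2, noise=0.1)
        X_dup = np.hstack([X, X[:, [0]]])
        base = fit_mlr(X, y).predict(X)
        dup = fit_mlr(X_dup, y).predict(X_dup)
        assert np.allclose(base, dup, atol=1e-8)

    def test_wide_matrix_interpolates_training_data(self):
        # p >> n: minimum-norm solution drives training residuals to zero
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 120))
        y = rng.normal(size=30)
        model = fit_mlr(X, y)
        assert np.allclose(model.predict(X), y, atol=1e-8)


class TestPCR:
    def test_single_component_structure_detected(self):
        rng = np.random.default_rng(4)
        direction = rng.normal(size=6)
        direction /= np.linalg.norm(direction)
        scores = rng.normal(size=50)
        X = np.outer(scores, direction)  # exact rank one, noise-free
        y = 2.0 + 3.0 * scores
        model, trace = fit_pcr(X, y, max_components=5)
        assert model.selected_order == 1
        assert trace.rmsecv[0] == pytest.approx(0.0, abs=1e-8)

    def test_trace_minimum_is_the_selected_order(self):
        X, y = _random_instance(n=30, p=6, seed=5, noise=0.5)
        model, trace = fit_pcr(X, y, max_components=6)
        assert trace.candidates[int(np.argmin(trace.rmsecv))] == model.selected_order
        assert (trace.rmsecv >= 0).all()


class TestPLS:
    def test_rank_one_model_recovered_with_single_lv(self):
        rng = np.random.default_rng(6)
        t = rng.normal(size=40)
        p_load = rng.normal(size=10)
        X = np.outer(t, p_load)
        y = 2.5 * t
        model, trace = fit_pls(X, y, max_lv=5)
        assert model.selected_order == 1
        assert trace.rmsecv[0] == pytest.approx(0.0, abs=1e-8)

    def test_weights_unit_norm_and_scores_orthogonal(self):
        X, y = _random_instance(n=30, p=12, seed=7, noise=0.3)
        model, _ = fit_pls(X, y, n_lv=4)
        W, T = model.loading_weights, model.x_scores
        assert np.allclose(np.linalg.norm(W, axis=0), 1.0, atol=1e-10)
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.allclose(off, 0.0, atol=1e-8 * np.abs(gram).max())

    def test_calibration_rmse_non_increasing_in_lv(self):
        X, y = _random_instance(n=35, p=10, seed=8, noise=0.5)
        rmses = []
        for a in range(1, 7):
            model, _ = fit_pls(X, y, n_lv=a)
            rmses.append(np.sqrt(np.mean((model.predict(X) - y) ** 2)))
        assert all(b <= a + 1e-10 for a, b in zip(rmses, rmses[1:]))

    def test_matches_sklearn_pls_regression(self):
        # independent oracle: scikit-learn's PLS (centered, unscaled)
        from sklearn.cross_decomposition import PLSRegression

        X, y = _random_instance(n=45, p=9, seed=9, noise=0.4)
        for a in (1, 3, 5):
            ours, _ = fit_pls(X, y, n_lv=a)
            theirs = PLSRegression(n_components=a, scale=False).fit(X, y)
            assert np.allclose(
                ours.predict(X), theirs.predict(X).ravel(), atol=1e-8
            )

    def test_constant_response_rejected(self):
        X, _ = _random_instance(n=20, p=5, seed=10)
        with pytest.raises(DegenerateDataError):
            fit_pls(X, np.full(20, 3.0))


class TestFullRankEquivalence:
    def test_pcr_pls_mlr_coincide_at_full_rank(self):
        X, y = _random_instance(n=40, p=8, seed=11, noise=0.5)
        mlr = fit_mlr(X, y).predict(X)
        pcr, _ = fit_pcr(X, y, n_components=8)
        pls, _ = fit_pls(X, y, n_lv=8)
        scale = np.abs(mlr).max()
        assert np.allclose(pcr.predict(X), mlr, atol=1e-8 * scale)
        assert np.allclose(pls.predict(X), mlr, atol=1e-8 * scale)


class TestSVR:
    small_grid = {"c": (10.0, 100.0), "g": (0.1, 1.0), "epsilon": (0.01, 0.1)}

    def test_default_grid_contains_study_optimum(self):
        assert any(abs(c - 100.0) < 1e-9 for c in DEFAULT_SVR_GRID["c"])
        assert any(abs(g - 10**0.5) < 1e-9 for g in DEFAULT_SVR_GRID["g"])
        assert any(abs(e - 0.1) < 1e-12 for e in DEFAULT_SVR_GRID["epsilon"])

    def test_constant_response_predicted_exactly(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(25, 4))
        y = np.full(25, 3.3)
        model, _ = fit_svr_rbf(
            X, y, grid=self.small_grid, cv_scheme=CVScheme("kfold", k=5, seed=0)
        )
        assert np.allclose(model.predict(X), 3.3, atol=0.11)

    def test_approximates_noise_free_linear_map(self):
        rng = np.random.default_rng(13)
        X = rng.uniform(-1, 1, size=(60, 3))
        y = 1.0 + X @ np.array([0.5, -0.3, 0.2])
        model, _ = fit_svr_rbf(
            X, y,
            grid={"c": (1000.0,), "g": (0.1,), "epsilon": (0.001,)},
            cv_scheme=CVScheme("kfold", k=5, seed=0),
        )
        rmse = np.sqrt(np.mean((model.predict(X) - y) ** 2))
        assert rmse < 0.05 * y.std(ddof=1)

    def test_nonpositive_hyperparameters_rejected(self):
        X, y = _random_instance(n=20, p=3, seed=14)
        with pytest.raises(ConfigurationError):
            fit_svr_rbf(X, y, grid={"c": (-1.0,), "g": (0.1,), "epsilon": (0.1,)})


class TestCrossValidation:
    def test_loo_matches_hand_enumerated_folds(self):
        # n=3, one predictor: enumerate the three held-out residuals by hand
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array([0.0, 1.0, 4.0])
        expected_errors = []
        for i in range(3):
            train = [j for j in range(3) if j != i]
            slope, intercept = np.polyfit(X[train, 0], y[train], 1)
            expected_errors.append(slope * X[i, 0] + intercept - y[i])
        expected = np.sqrt(np.mean(np.square(expected_errors)))
        got = rmsecv(fit_mlr, X, y, LOO)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_constant_response_scores_zero(self):
        X = np.arange(8.0).reshape(-1, 1)
        y = np.full(8, 2.0)
        assert rmsecv(fit_mlr, X, y, LOO) == pytest.approx(0.0, abs=1e-10)

    def test_seeded_kfold_is_deterministic(self):
        X, y = _random_instance(n=30, p=4, seed=15, noise=0.5)
        scheme = CVScheme("kfold", k=5, seed=123)
        assert rmsecv(fit_mlr, X, y, scheme) == rmsecv(fit_mlr, X, y, scheme)

    def test_fold_count_exceeding_n_rejected(self):
        X, y = _random_instance(n=5, p=2, seed=16)
        with pytest.raises(ConfigurationError):
            rmsecv(fit_mlr, X, y, CVScheme("kfold", k=10))


class TestPredictAndPersistence:
    def test_row_permutation_permutes_predictions(self):
        X, y = _random_instance(n=20, p=4, seed=17, noise=0.2)
        model = fit_mlr(X, y)
        perm = np.random.default_rng(0).permutation(20)
        assert np.allclose(model.predict(X[perm]), model.predict(X)[perm])

    def test_band_count_mismatch_rejected(self):
        X, y = _random_instance(n=20, p=4, seed=18)
        model = fit_mlr(X, y)
        with pytest.raises(ShapeError):
            model.predict(X[:, :3])

    @pytest.mark.parametrize("method", ["pls", "svm"])
    def test_json_round_trip_preserves_predictions(self, tmp_path, method):
        X, y = _random_instance(n=30, p=6, seed=19, noise=0.3)
        if method == "pls":
            model, _ = fit_pls(X, y, n_lv=3)
        else:
            model, _ = fit_svr_rbf(
                X, y, grid=TestSVR.small_grid, cv_scheme=CVScheme("kfold", k=5)
            )
        path = tmp_path / "model.json"
        model.to_json(path)
        back = FittedModel.from_json(path)
        assert np.allclose(back.predict(X), model.predict(X), atol=1e-12)
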