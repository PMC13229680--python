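import numpy as np
import pytest

from leafspec import DataError, LearnerSpec, band_importances, vip_scores
from leafspec import learners as L


def _regression_problem(n=20, p=8, seed=0, noise=0.05):
    rng = np.random.default_rng(seed)
    X = rng.random((n, p))
    beta = rng.normal(size=p)
    y = X @ beta + noise * rng.normal(size=n)
    return X, y


def _small_spec(kind, p):
    """Default-ish spec whose hyperparameters fit a p-band toy problem."""
    if kind == "latent_linear":
        return LearnerSpec(kind, {"n_components": min(4, p)})
    if kind == "boosted_trees":
        return LearnerSpec(kind, {"n_estimators": 50, "max_depth": 3,
                                  "learning_rate": 0.2, "subsample": 1.0,
                                  "colsample": 1.0})
    return L.default_spec(kind)


def _ols(X, y):
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    return np.linalg.lstsq(Xc, yc, rcond=None)[0]


class TestRidge:
    def test_matches_closed_form_on_random_systems(self):
        """(Xc'Xc + aI)^-1 Xc'yc reproduces the fitted coefficients."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            n, p = 20, 8
            X = rng.random((n, p))
            y = rng.random(n)
            alpha = float(rng.uniform(0.01, 10))
            fitted = L.fit(LearnerSpec("ridge_linear", {"alpha": alpha}), X, y)
            Xc = X - X.mean(axis=0)
            yc = y - y.mean()
            closed = np.linalg.solve(Xc.T @ Xc + alpha * np.eye(p), Xc.T @ yc)
            assert np.allclose(fitted.model.coef_, closed, atol=1e-8)

    def test_alpha_to_zero_reproduces_ols(self):
        X, y = _regression_problem(10, 5, seed=2)
        fitted = L.fit(LearnerSpec("ridge_linear", {"alpha": 1e-10}), X, y)
        assert np.allclose(fitted.model.coef_, _ols(X, y), atol=1e-6)

    def test_huge_alpha_shrinks_coefficients(self):
        X, y = _regression_problem(15, 6, seed=3)
        fitted = L.fit(LearnerSpec("ridge_linear", {"alpha": 1e6}), X, y)
        assert np.all(np.abs(fitted.model.coef_) < 1e-3)


class TestLatentLinear:
    def test_full_components_match_ols_predictions(self):
        X, y = _regression_problem(12, 5, seed=4)
        fitted = L.fit(LearnerSpec("latent_linear", {"n_components": 5}), X, y)
        pred = L.predict(fitted, X)
        ols_pred = (X - X.mean(axis=0)) @ _ols(X, y) + y.mean()
        assert np.allclose(pred, ols_pred, atol=1e-6)

    def test_in_sample_r2_nondecreasing_in_components(self):
        X, y = _regression_problem(30, 10, seed=5, noise=0.2)
        from leafspec import r_squared

        scores = []
        for k in range(1, 9):
            fitted = L.fit(LearnerSpec("latent_linear", {"n_components": k}), X, y)
            scores.append(r_squared(y, L.predict(fitted, X)))
        assert all(b >= a - 1e-10 for a, b in zip(scores, scores[1:]))

    def test_too_many_components_rejected(self):
        X, y = _regression_problem(6, 4)
        with pytest.raises(Exception):
            L.fit(LearnerSpec("latent_linear", {"n_components": 6}), X, y)


class TestBoostedTrees:
    def test_overfit_limit_near_zero_training_error(self):
        X, y = _regression_problem(60, 5, seed=6, noise=0.0)
        spec = LearnerSpec(
            "boosted_trees",
            {"n_estimators": 400, "max_depth": 6, "learning_rate": 0.3,
             "subsample": 1.0, "colsample": 1.0},
        )
        fitted = L.fit(spec, X, y)
        from leafspec import rmse

        assert rmse(y, L.predict(fitted, X)) < 0.05 * y.std()

    def test_deterministic_given_seed(self):
        X, y = _regression_problem(40, 6, seed=7)
        spec = LearnerSpec("boosted_trees", {"subsample": 0.7}, seed=3)
        p1 = L.predict(L.fit(spec, X, y), X)
        p2 = L.predict(L.fit(spec, X, y), X)
        assert np.array_equal(p1, p2)


class TestPredictContract:
    @pytest.mark.parametrize("kind", L.KINDS)
    def test_duplicated_rows_duplicated_predictions(self, kind):
        X, y = _regression_problem(20, 6, seed=8)
        fitted = L.fit(_small_spec(kind, 6), X, y)
        X2 = np.vstack([X[:3], X[:3]])
        pred = L.predict(fitted, X2)
        assert np.allclose(pred[:3], pred[3:])

    @pytest.mark.parametrize("kind", L.KINDS)
    def test_column_permutation_with_permuted_axis(self, kind):
        """Permuting columns and axis metadata together leaves output alone."""
        X, y = _regression_problem(25, 6, seed=9)
        axis = np.linspace(400, 1000, 6)
        perm = np.random.default_rng(0).permutation(6)
        f1 = L.fit(_small_spec(kind, 6), X, y, axis)
        f2 = L.fit(_small_spec(kind, 6), X[:, perm], y, axis[perm])
        assert np.allclose(L.predict(f1, X), L.predict(f2, X[:, perm]), atol=1e-8)

    def test_axis_mismatch_rejected(self):
        X, y = _regression_problem(10, 5)
        fitted = L.fit(L.default_spec("ridge_linear"), X, y,
                       np.linspace(400, 1000, 5))
        with pytest.raises(DataError):
            L.predict(fitted, X, axis=np.linspace(401, 1001, 5))
        with pytest.raises(DataError):
            L.predict(fitted, X[:, :4])


class TestVIP:
    def test_normalization_identity(self):
        """Sum of squared VIP scores equals the band count."""
        for seed in range(5):
            X, y = _regression_problem(30, 12, seed=seed, noise=0.3)
            for k in (1, 3, 6):
                fitted = L.fit(LearnerSpec("latent_linear", {"n_components": k}),
                               X, y)
                vip = vip_scores(fitted).vip
                assert np.all(vip >= 0)
                assert np.sum(vip**2) == pytest.approx(12, abs=1e-8)

    def test_single_component_closed_form(self):
        X, y = _regression_problem(25, 7, seed=11)
        fitted = L.fit(LearnerSpec("latent_linear", {"n_components": 1}), X, y)
        w = fitted.model.x_weights_[:, 0]
        expected = np.sqrt(7) * np.abs(w) / np.linalg.norm(w)
        assert np.allclose(vip_scores(fitted).vip, expected, atol=1e-10)

    def test_planted_active_band_wins(self):
        """y built from one band puts the VIP argmax on that band."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 20))
            y = 3.0 * X[:, 12] + 0.1 * rng.normal(size=40)
            fitted = L.fit(LearnerSpec("latent_linear", {"n_components": 2}), X, y)
            if int(np.argmax(vip_scores(fitted).vip)) == 12:
                hits += 1
        assert hits >= 95

    def test_rejects_non_latent_learner(self):
        X, y = _regression_problem(10, 5)
        with pytest.raises(TypeError):
            vip_scores(L.fit(L.default_spec("ridge_linear"), X, y))


class TestSerialization:
    @pytest.mark.parametrize("kind", L.KINDS)
    def test_save_load_roundtrip_preserves_predictions(self, kind, tmp_path):
        X, y = _regression_problem(25, 6, seed=21)
        axis = np.linspace(400, 1000, 6)
        fitted = L.fit(_small_spec(kind, 6), X, y, axis)
        L.save_learner(fitted, tmp_path / kind)
        back = L.load_learner(tmp_path / kind)
        assert back.spec.kind == kind
        assert np.allclose(back.axis, axis)
        assert np.allclose(L.predict(back, X), L.predict(fitted, X), atol=1e-10)


class TestBandImportances:
    def test_planted_signal_tops_ridge_ranking(self):
        rng = np.random.default_rng(12)
        axis = np.linspace(400, 1000, 7)
        X = rng.normal(size=(60, 7))
        band = int(np.argmin(np.abs(axis - 700)))
        y = 3.0 * X[:, band] + 0.05 * rng.normal(size=60)
        fitted = L.fit(LearnerSpec("ridge_linear", {"alpha": 0.1}), X, y, axis)
        top = band_importances(fitted, top_k=1)
        assert top[0][0] == pytest.approx(axis[band])

    @pytest.mark.parametrize("kind", L.KINDS)
    def test_full_ranking_is_permutation_and_nonnegative(self, kind):
        X, y = _regression_problem(30, 6, seed=13)
        axis = np.linspace(400, 1000, 6)
        fitted = L.fit(_small_spec(kind, 6), X, y, axis)
        ranking = band_importances(fitted, top_k=6)
        assert sorted(w for w, _ in ranking) == sorted(axis)
        assert all(np.isfinite(s) and s >= 0 for _, s in ranking)

    def test_oversized_top_k_truncates_with_warning(self):
        X, y = _regression_problem(15, 4, seed=14)
        fitted = L.fit(L.default_spec("ridge_linear"), X, y)
        with pytest.warns(UserWarning):
            out = band_importances(fitted, top_k=10)
        assert len(out) == 4
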