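import itertools

import numpy as np
import pytest
from sklearn.model_selection import KFold

from leafspec import (
    ConfigurationError,
    EnsembleWeights,
    LearnerSpec,
    calibrate_weights,
    cv_mean_r2,
    ensemble_predict,
    r_squared,
    tune_learner,
)
from leafspec import learners as L
from leafspec.ensemble import Dimension, oof_prediction_matrix


def _toy(n=30, p=6, seed=0, noise=0.1):
    rng = np.random.default_rng(seed)
    X = rng.random((n, p))
    y = X @ rng.normal(size=p) + noise * rng.normal(size=n)
    return X, y


class TestCVObjective:
    def test_perfect_model_scores_one(self):
        X, y = _toy(20, 4, noise=0.0)
        spec = LearnerSpec("latent_linear", {"n_components": 4})
        assert cv_mean_r2(spec, X, y, k=5, seed=1) == pytest.approx(1.0, abs=1e-6)

    def test_matches_explicit_fold_loop(self):
        """The objective equals a hand-written k-fold loop to 1e-12."""
        X, y = _toy(30, 6, seed=2)
        spec = LearnerSpec("ridge_linear", {"alpha": 0.5})
        got = cv_mean_r2(spec, X, y, k=5, seed=7)
        scores = []
        for tr, te in KFold(5, shuffle=True, random_state=7).split(np.arange(30)):
            fitted = L.fit(spec, X[tr], y[tr])
            scores.append(r_squared(y[te], L.predict(fitted, X[te])))
        assert got == pytest.approx(np.mean(scores), abs=1e-12)

    def test_mean_predictor_not_positive_in_expectation(self):
        """Models no better than the training-fold mean score <= 0 on average."""
        rng = np.random.default_rng(3)
        vals = []
        for seed in range(20):
            y = rng.normal(size=40)
            X = np.ones((40, 2)) + 1e-9 * rng.normal(size=(40, 2))
            spec = LearnerSpec("ridge_linear", {"alpha": 1e6})
            vals.append(cv_mean_r2(spec, X, y, k=5, seed=seed))
        assert np.mean(vals) <= 0

    def test_too_few_samples_rejected(self):
        X, y = _toy(8, 3)
        with pytest.raises(ConfigurationError):
            cv_mean_r2(LearnerSpec("ridge_linear", {}), X, y, k=5, seed=0)


class TestTuning:
    def test_collapsed_space_returns_that_point(self):
        X, y = _toy(25, 5, seed=4)
        space = {"ridge_linear": {"alpha": Dimension(0.7, 0.7, log=True)}}
        res = tune_learner("ridge_linear", space, X, y, n_trials=5, seed=0)
        assert len(res.trials) == 5
        assert res.best_spec.hyperparams["alpha"] == pytest.approx(0.7)

    def test_best_is_argmax_of_log(self):
        X, y = _toy(30, 6, seed=5)
        res = tune_learner("ridge_linear", None, X, y, n_trials=10, seed=1)
        assert res.best_cv_r2 == pytest.approx(max(o for _, o in res.trials))

    def test_seed_reproducibility(self):
        X, y = _toy(30, 6, seed=6)
        r1 = tune_learner("ridge_linear", None, X, y, n_trials=8, seed=3)
        r2 = tune_learner("ridge_linear", None, X, y, n_trials=8, seed=3)
        assert [t[0].hyperparams for t in r1.trials] == [
            t[0].hyperparams for t in r2.trials
        ]
        assert [t[1] for t in r1.trials] == [t[1] for t in r2.trials]

    def test_near_grid_scan_optimum_on_ridge_alpha(self):
        """30 random trials land within 0.02 of a dense alpha-grid maximum."""
        X, y = _toy(40, 8, seed=7, noise=0.5)
        space = {"ridge_linear": {"alpha": Dimension(1e-3, 1e2, log=True)}}
        res = tune_learner("ridge_linear", space, X, y, n_trials=30, seed=2)
        grid_best = max(
            cv_mean_r2(LearnerSpec("ridge_linear", {"alpha": a}), X, y, 5, 2)
            for a in np.logspace(-3, 2, 60)
        )
        assert res.best_cv_r2 >= grid_best - 0.02


class TestEnsemblePredict:
    def _three_fitted(self, X, y):
        specs = [
            LearnerSpec("boosted_trees", {"n_estimators": 50, "max_depth": 3,
                                          "learning_rate": 0.2, "subsample": 1.0,
                                          "colsample": 1.0}),
            LearnerSpec("latent_linear", {"n_components": 3}),
            LearnerSpec("ridge_linear", {"alpha": 0.5}),
        ]
        return [L.fit(s, X, y) for s in specs]

    def test_vertex_weight_selects_single_learner(self):
        X, y = _toy(25, 5, seed=8)
        fitted = self._three_fitted(X, y)
        w = EnsembleWeights(np.array([1.0, 0.0, 0.0]))
        assert np.array_equal(ensemble_predict(fitted, w, X),
                              L.predict(fitted[0], X))

    def test_identical_learners_any_weights(self):
        X, y = _toy(25, 5, seed=9)
        f = L.fit(L.default_spec("ridge_linear"), X, y)
        w = EnsembleWeights(np.array([0.2, 0.5, 0.3]))
        assert np.allclose(ensemble_predict([f, f, f], w, X), L.predict(f, X))

    def test_hand_arithmetic(self):
        class Fixed:
            def __init__(self, c, p):
                self.spec = L.LearnerSpec("ridge_linear", {})
                self.axis = np.arange(p, dtype=float)
                self.c = c
                self.model = self

            def predict(self, X):
                return np.full(len(X), self.c)

        fitted = [Fixed(2.0, 3), Fixed(4.0, 3), Fixed(6.0, 3)]
        w = EnsembleWeights(np.full(3, 1 / 3))
        out = ensemble_predict(fitted, w, np.zeros((5, 3)))
        assert np.allclose(out, 4.0)

    def test_affine_equivariance(self):
        """Shifting every learner's predictions by c shifts the ensemble by c."""
        X, y = _toy(20, 4, seed=10)
        fitted = self._three_fitted(X, y)
        w = EnsembleWeights(np.array([0.5, 0.25, 0.25]))
        base = ensemble_predict(fitted, w, X)
        preds = np.column_stack([L.predict(f, X) + 7.0 for f in fitted])
        assert np.allclose(preds @ w.w, base + 7.0, atol=1e-10)

    def test_count_mismatch_rejected(self):
        X, y = _toy(20, 4)
        fitted = self._three_fitted(X, y)
        with pytest.raises(ConfigurationError):
            ensemble_predict(fitted[:2], EnsembleWeights(np.full(3, 1 / 3)), X)


class TestWeights:
    def test_simplex_constraints_enforced(self):
        with pytest.raises(ConfigurationError):
            EnsembleWeights(np.array([0.5, 0.6, -0.1]))
        with pytest.raises(ConfigurationError):
            EnsembleWeights(np.array([0.5, 0.4, 0.2]))

    def _specs(self):
        return [
            LearnerSpec("boosted_trees", {"n_estimators": 60, "max_depth": 3,
                                          "learning_rate": 0.2, "subsample": 1.0,
                                          "colsample": 1.0}),
            LearnerSpec("latent_linear", {"n_components": 4}),
            LearnerSpec("ridge_linear", {"alpha": 0.1}),
        ]

    def test_calibrated_weights_valid_and_never_worse_than_best_single(self):
        X, y = _toy(36, 6, seed=11)
        specs = self._specs()
        w, mse = calibrate_weights(specs, X, y, k=3, n_calls=20, seed=4)
        assert np.all(w.w >= 0)
        assert abs(w.w.sum() - 1) <= 1e-9
        oof = oof_prediction_matrix(specs, X, y, k=3, seed=4)
        singles = [
            np.mean([np.mean((y[te] - P[:, m]) ** 2) for te, P in oof])
            for m in range(3)
        ]
        assert mse <= min(singles) + 1e-9

    def test_dominant_learner_takes_the_weight(self):
        """When one learner predicts y and the others noise, it gets >=0.9."""
        rng = np.random.default_rng(12)
        X = rng.random((40, 5))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0, 1.5])
        specs = [
            LearnerSpec("boosted_trees", {"n_estimators": 5, "max_depth": 1,
                                          "learning_rate": 0.01,
                                          "subsample": 1.0, "colsample": 0.3}),
            LearnerSpec("latent_linear", {"n_components": 5}),  # exact model
            LearnerSpec("ridge_linear", {"alpha": 1e6}),  # predicts ~mean
        ]
        w, _ = calibrate_weights(specs, X, y, k=3, n_calls=30, seed=5)
        assert w.w[1] >= 0.9

    def test_matches_dense_simplex_grid_oracle(self):
        """CV-MSE of returned weights is within 2% of a 101^2 grid scan."""
        X, y = _toy(20, 4, seed=13, noise=0.3)
        specs = self._specs()
        w, mse = calibrate_weights(specs, X, y, k=3, n_calls=40, seed=6)
        oof = oof_prediction_matrix(specs, X, y, k=3, seed=6)

        def cv_mse(wv):
            return np.mean([np.mean((y[te] - P @ wv) ** 2) for te, P in oof])

        grid_best = min(
            cv_mse(np.array([a, b, 1 - a - b]))
            for a, b in itertools.product(np.linspace(0, 1, 101), repeat=2)
            if a + b <= 1 + 1e-12
        )
        assert mse <= grid_best * 1.02 + 1e-12

    def test_deterministic_per_seed(self):
        X, y = _toy(24, 5, seed=14)
        specs = self._specs()
        w1, m1 = calibrate_weights(specs, X, y, seed=8, n_calls=10)
        w2, m2 = calibrate_weights(specs, X, y, seed=8, n_calls=10)
        assert np.array_equal(w1.w, w2.w) and m1 == m2

    def test_fold_partition_shared_across_learners(self):
        """OOF rows cover each sample once with the same fold layout."""
        X, y = _toy(21, 4, seed=15)
        oof = oof_prediction_matrix(self._specs(), X, y, k=3, seed=9)
        covered = np.concatenate([te for te, _ in oof])
        assert sorted(covered) == list(range(21))
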