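"""Hyperparameter tuning and convex-weighted ensembling.

The tuning objective for each base learner is the mean coefficient of
determination over k-fold cross-validation on the training set,

    max_theta  (1/k) * sum_k R^2(y_k, yhat_k(theta)),

maximized over a bounded hyperparameter space by a seeded random-search
sampler (any bounded black-box optimizer satisfies this contract; the fold
partition is fixed per seed and shared across all candidate specs, so
objective values are paired comparisons).

The ensemble prediction is the convex combination

    yhat = sum_m w_m yhat_m,   w_m >= 0,  sum_m w_m = 1,

with the weight vector calibrated to minimize the k-fold cross-validated
MSE of the combined out-of-fold predictions on the training set.  The three
simplex vertices and the uniform point are always evaluated as seed
candidates, so the calibrated ensemble's CV MSE never exceeds the best
single learner's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.model_selection import KFold

from . import learners as L
from .exceptions import ConfigurationError
from .metrics import r_squared

# ---------------------------------------------------------------------------
# Hyperparameter space
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Dimension:
    """One bounded search dimension (optionally log-scaled / integer)."""

    low: float
    high: float
    log: bool = False
    integer: bool = False

    def __post_init__(self) -> None:
        if not (math.isfinite(self.low) and math.isfinite(self.high)):
            raise ConfigurationError("bounds must be finite")
        if self.low >= self.high and not (self.low == self.high):
            raise ConfigurationError("lower bound must not exceed upper bound")
        if self.log and self.low <= 0:
            raise ConfigurationError("log-scaled dimension needs positive bounds")

    def sample(self, rng: np.random.Generator) -> float:
        if self.low == self.high:
            val = self.low
        elif self.log:
            val = float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))
        else:
            val = float(rng.uniform(self.low, self.high))
        # integer dimensions: round the continuous proposal
        return int(round(val)) if self.integer else val


def default_space(n_train: int | None = None, n_bands: int | None = None) -> dict:
    """Default per-learner search spaces (artifact choices, overridable).

    The PLS component cap accounts for cross-validation shrinkage: inside a
    k-fold search only about (k-1)/k of the rows are fitted, so the cap is
    min(30, n_bands, floor(2*n_train/3) - 1) when the training shape is
    known (2/3 covers every fold count >= 3 used in this package).
    """
    k_hi = 30
    if n_train is not None and n_bands is not None:
        k_hi = max(1, min(30, (2 * n_train) // 3 - 1, n_bands))
    return {
        "latent_linear": {"n_components": Dimension(1, k_hi, integer=True)},
        "ridge_linear": {"alpha": Dimension(1e-4, 1e3, log=True)},
        "boosted_trees": {
            "n_estimators": Dimension(50, 300, integer=True),
            "max_depth": Dimension(2, 6, integer=True),
            "learning_rate": Dimension(0.02, 0.3, log=True),
            "subsample": Dimension(0.5, 1.0),
            "colsample": Dimension(0.3, 0.9),
        },
    }


# ---------------------------------------------------------------------------
# CV objective
# ---------------------------------------------------------------------------


def _folds(n: int, k: int, seed: int):
    if k < 2:
        raise ConfigurationError("need at least 2 folds")
    if n < 2 * k:
        raise ConfigurationError(f"n={n} too small for k={k} folds (need n >= 2k)")
    return list(KFold(n_splits=k, shuffle=True, random_state=seed).split(np.arange(n)))


def cv_mean_r2(spec: L.LearnerSpec, X, y, k: int = 5, seed: int = 0) -> float:
    """Mean held-out R^2 over a fixed seeded k-fold partition.

    Each fold's R^2 uses that held-out fold's own mean, so the value can be
    negative for models worse than the fold-mean predictor.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    scores = []
    for tr, te in _folds(len(y), k, seed):
        fitted = L.fit(spec, X[tr], y[tr])
        scores.append(r_squared(y[te], L.predict(fitted, X[te])))
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# Random-search tuner
# ---------------------------------------------------------------------------


@dataclass
class SearchResult:
    """Best spec found plus the full trial log."""

    best_spec: L.LearnerSpec
    best_cv_r2: float
    trials: list = field(default_factory=list)  # (LearnerSpec, objective)


def tune_learner(
    kind: str,
    space: dict | None,
    X,
    y,
    n_trials: int = 30,
    k: int = 5,
    seed: int = 0,
) -> SearchResult:
    """Seeded bounded random search over the learner's hyperparameter space.

    All trials share one fold partition (derived from ``seed``) so their
    objectives are directly comparable; the argmax of the trial log is
    returned.  Reproducible: the same seed yields the same trial log.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    dims = (space or default_space(X.shape[0], X.shape[1]))[kind]
    rng = np.random.default_rng(seed)
    trials: list = []
    first_error: Exception | None = None
    for _ in range(n_trials):
        hp = {name: dim.sample(rng) for name, dim in dims.items()}
        spec = L.LearnerSpec(kind, hp, seed)
        try:
            obj = cv_mean_r2(spec, X, y, k=k, seed=seed)
        except ConfigurationError:
            raise
        except Exception as exc:  # log failed trial, keep searching
            if first_error is None:
                first_error = exc
            obj = -np.inf
        trials.append((spec, obj))
    finite = [t for t in trials if np.isfinite(t[1])]
    if not finite:
        raise RuntimeError(f"all {n_trials} tuning trials failed") from first_error
    best_spec, best_obj = max(finite, key=lambda t: t[1])
    return SearchResult(best_spec, best_obj, trials)


# ---------------------------------------------------------------------------
# Convex ensemble
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnsembleWeights:
    """Nonnegative weights over the base learners, summing to one."""

    w: np.ndarray
    kinds: tuple = L.KINDS

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if np.any(w < 0):
            raise ConfigurationError("ensemble weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ConfigurationError("ensemble weights must sum to 1 (within 1e-9)")
        object.__setattr__(self, "w", w)

    def as_dict(self) -> dict:
        return {k: float(v) for k, v in zip(self.kinds, self.w)}


def ensemble_predict(fitted_learners, weights: EnsembleWeights, X) -> np.ndarray:
    """Convex combination of the base learners' predictions."""
    if len(fitted_learners) != len(weights.w):
        raise ConfigurationError(
            f"{len(fitted_learners)} learners but {len(weights.w)} weights"
        )
    preds = np.column_stack([L.predict(f, X) for f in fitted_learners])
    return preds @ weights.w


def _simplex_from_free(a: float, b: float) -> np.ndarray:
    """Map two free coordinates in [0,1]^2 onto the 2-simplex."""
    a = min(max(a, 0.0), 1.0)
    b = min(max(b, 0.0), 1.0)
    w = np.array([a, b * (1.0 - a), (1.0 - a) * (1.0 - b)])
    s = w.sum()
    return w / s if s > 0 else np.full(3, 1.0 / 3.0)


def oof_prediction_matrix(specs, X, y, k: int = 3, seed: int = 0):
    """Per-fold out-of-fold prediction columns for each learner spec.

    Base learners are refit inside each fold (the held-out targets never
    influence the fit).  Returns a list of (test_index, n_test x m matrix).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    folds = _folds(len(y), k, seed)
    out = []
    for tr, te in folds:
        P = np.column_stack(
            [L.predict(L.fit(s, X[tr], y[tr]), X[te]) for s in specs]
        )
        out.append((te, P))
    return out


def calibrate_weights(
    specs,
    X,
    y,
    k: int = 3,
    n_calls: int = 40,
    seed: int = 0,
) -> tuple[EnsembleWeights, float]:
    """Minimize the k-fold CV MSE of the weighted ensemble over the simplex.

    The weight search is parameterized by two free coordinates in [0,1]^2;
    the three vertices and the uniform point are always evaluated, followed
    by ``n_calls`` seeded random candidates and a Nelder–Mead polish of the
    best one.  Returns the weights and their CV MSE.
    """
    y = np.asarray(y, dtype=float)
    oof = oof_prediction_matrix(specs, X, y, k=k, seed=seed)

    def cv_mse(w: np.ndarray) -> float:
        return float(
            np.mean([np.mean((y[te] - P @ w) ** 2) for te, P in oof])
        )

    candidates = [
        np.array([1.0, 0.0, 0.0]),
        np.array([0.0, 1.0, 0.0]),
        np.array([0.0, 0.0, 1.0]),
        np.full(3, 1.0 / 3.0),
    ]
    rng = np.random.default_rng(seed)
    for _ in range(n_calls):
        candidates.append(_simplex_from_free(*rng.uniform(0, 1, size=2)))
    scores = [cv_mse(w) for w in candidates]
    best_idx = int(np.argmin(scores))
    best_w, best_mse = candidates[best_idx], scores[best_idx]

    # local polish in the free-coordinate parameterization
    w0 = best_w
    a0 = w0[0]
    b0 = w0[1] / (1.0 - a0) if a0 < 1.0 else 0.0
    res = minimize(
        lambda ab: cv_mse(_simplex_from_free(*ab)),
        x0=[a0, min(max(b0, 0.0), 1.0)],
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 200},
    )
    if res.fun < best_mse:
        best_w, best_mse = _simplex_from_free(*res.x), float(res.fun)
    kinds = tuple(s.kind for s in specs)
    return EnsembleWeights(best_w, kinds), best_mse
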