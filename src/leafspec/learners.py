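"""The three heterogeneous base regressors behind one fit/predict contract.

* ``latent_linear`` — partial least squares (PLS) regression: bilinear
  components maximizing spectrum–target covariance, suited to thousands of
  collinear reflectance bands (delegates to scikit-learn's NIPALS PLS).
* ``ridge_linear`` — L2-penalized linear regression on centered data,
  stable under multicollinearity (scikit-learn Ridge).
* ``boosted_trees`` — stagewise additive regression trees on squared-error
  loss, capturing band interactions and nonlinearity (XGBoost).

Interpretability outputs: PLS variable-importance-in-projection (VIP)
scores, ridge coefficient magnitudes, and gain-based tree importances, all
mapped back to physical wavelengths by :func:`band_importances`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import Ridge
from xgboost import XGBRegressor

from .exceptions import ConfigurationError, DataError

KINDS = ("boosted_trees", "latent_linear", "ridge_linear")


@dataclass(frozen=True)
class LearnerSpec:
    """A learner kind plus its hyperparameters."""

    kind: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConfigurationError(f"unknown learner kind {self.kind!r}")


DEFAULT_HYPERPARAMS = {
    "latent_linear": {"n_components": 10},
    "ridge_linear": {"alpha": 1.0},
    "boosted_trees": {
        "n_estimators": 200,
        "max_depth": 4,
        "learning_rate": 0.1,
        "subsample": 0.9,
        "colsample": 0.9,
        # 64 histogram bins are ample for smooth reflectance in [0, 1]
        "max_bin": 64,
    },
}


def default_spec(kind: str, seed: int = 0) -> LearnerSpec:
    return LearnerSpec(kind, dict(DEFAULT_HYPERPARAMS[kind]), seed)


@dataclass
class FittedLearner:
    """Opaque fitted state tied to the wavelength axis it was trained on."""

    spec: LearnerSpec
    axis: np.ndarray
    model: object

    def predict(self, X, axis=None) -> np.ndarray:
        return predict(self, X, axis)


def _build_estimator(spec: LearnerSpec, n: int, p: int):
    hp = {**DEFAULT_HYPERPARAMS[spec.kind], **spec.hyperparams}
    if spec.kind == "latent_linear":
        k = int(hp["n_components"])
        if k < 1:
            raise ConfigurationError("n_components must be >= 1")
        if k > min(n - 1, p):
            raise ConfigurationError(
                f"n_components={k} exceeds min(n-1, p)={min(n - 1, p)}"
            )
        # scale=False: bands share reflectance units; center only
        return PLSRegression(n_components=k, scale=False)
    if spec.kind == "ridge_linear":
        alpha = float(hp["alpha"])
        if alpha <= 0:
            raise ConfigurationError("ridge alpha must be > 0")
        return Ridge(alpha=alpha, fit_intercept=True)
    return XGBRegressor(
        n_estimators=int(hp["n_estimators"]),
        max_depth=int(hp["max_depth"]),
        learning_rate=float(hp["learning_rate"]),
        subsample=float(hp["subsample"]),
        colsample_bytree=float(hp["colsample"]),
        max_bin=int(hp.get("max_bin", 64)),
        objective="reg:squarederror",
        tree_method="hist",
        random_state=spec.seed,
        n_jobs=1,
        verbosity=0,
    )


def fit(spec: LearnerSpec, X, y, axis=None) -> FittedLearner:
    """Fit one base learner; deterministic given (spec, data, seed)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise DataError("X must be n x p with matching y")
    if X.shape[0] < 2:
        raise DataError("need at least 2 samples to fit")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise DataError("inputs contain missing or non-finite values")
    axis = (
        np.asarray(axis, dtype=float)
        if axis is not None
        else np.arange(X.shape[1], dtype=float)
    )
    if len(axis) != X.shape[1]:
        raise DataError("wavelength axis length must match X columns")
    est = _build_estimator(spec, *X.shape)
    try:
        est.fit(X, y)
    except np.linalg.LinAlgError as exc:
        raise DataError(
            f"degenerate training data for {spec.kind}: {exc}; "
            "reduce n_components or add samples"
        ) from exc
    return FittedLearner(spec, axis, est)


def predict(fitted: FittedLearner, X, axis=None) -> np.ndarray:
    """Predict on new spectra; the wavelength axis must match training."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(fitted.axis):
        raise DataError("prediction input does not match the training band count")
    if axis is not None and not np.allclose(np.asarray(axis, float), fitted.axis):
        raise DataError("prediction wavelength axis differs from training axis")
    out = np.asarray(fitted.model.predict(X), dtype=float).ravel()
    if not np.all(np.isfinite(out)):
        raise DataError("model produced non-finite predictions")
    return out


def save_learner(fitted: FittedLearner, out_dir) -> None:
    """Serialize a fitted learner to a versioned directory.

    Layout: ``spec.yaml`` (kind, hyperparameters, seed, format version),
    ``axis.csv`` (training wavelength axis) and ``state.bin`` (the pickled
    fitted estimator).
    """
    import pickle

    from pathlib import Path

    import pandas as pd
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "spec.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "format_version": 1,
                "kind": fitted.spec.kind,
                "hyperparams": {
                    k: (float(v) if isinstance(v, float) else int(v))
                    for k, v in fitted.spec.hyperparams.items()
                },
                "seed": fitted.spec.seed,
            },
            fh,
        )
    pd.DataFrame({"wavelength_nm": fitted.axis}).to_csv(
        out / "axis.csv", index=False
    )
    with open(out / "state.bin", "wb") as fh:
        pickle.dump(fitted.model, fh)


def load_learner(in_dir) -> FittedLearner:
    """Load a learner serialized by :func:`save_learner`."""
    import pickle

    from pathlib import Path

    import pandas as pd
    import yaml

    in_dir = Path(in_dir)
    with open(in_dir / "spec.yaml") as fh:
        meta = yaml.safe_load(fh)
    if meta.get("format_version") != 1:
        raise DataError(f"unsupported learner format version {meta.get('format_version')!r}")
    spec = LearnerSpec(meta["kind"], dict(meta["hyperparams"]), meta.get("seed", 0))
    axis = pd.read_csv(in_dir / "axis.csv")["wavelength_nm"].to_numpy(dtype=float)
    with open(in_dir / "state.bin", "rb") as fh:
        model = pickle.load(fh)
    return FittedLearner(spec, axis, model)


@dataclass(frozen=True)
class VIPProfile:
    """Per-band VIP scores; their squares average to 1 across bands."""

    wavelengths_nm: np.ndarray
    vip: np.ndarray


def vip_scores(fitted: FittedLearner) -> VIPProfile:
    """Variable importance in projection for a fitted PLS model.

    VIP_j = sqrt( p * sum_a SSY_a (w_aj / ||w_a||)^2 / sum_a SSY_a ) where
    w_a are the component weight vectors and SSY_a the y-variance explained
    by component a (from the regression of y on the component scores).
    """
    if fitted.spec.kind != "latent_linear":
        raise TypeError("VIP is defined for the latent_linear (PLS) learner only")
    pls: PLSRegression = fitted.model  # type: ignore[assignment]
    W = pls.x_weights_  # p x A
    T = pls.x_scores_  # n x A
    q = pls.y_loadings_.ravel()  # A
    p, n_comp = W.shape
    ssy = (q**2) * np.sum(T**2, axis=0)  # y-SS explained per component
    Wn2 = (W / np.linalg.norm(W, axis=0, keepdims=True)) ** 2
    vip = np.sqrt(p * (Wn2 @ ssy) / ssy.sum())
    return VIPProfile(fitted.axis.copy(), vip)


def band_importances(fitted: FittedLearner, top_k: int = 20) -> list[tuple[float, float]]:
    """Top-k (wavelength_nm, importance) pairs, sorted by importance.

    Importance is |coefficient| for ridge, gain for boosted trees and VIP
    for the latent-linear learner.  Ties are broken toward the shorter
    wavelength so the ranking is total and deterministic.
    """
    p = len(fitted.axis)
    if top_k > p:
        warnings.warn(f"top_k={top_k} exceeds the {p} available bands; truncating")
        top_k = p
    kind = fitted.spec.kind
    if kind == "ridge_linear":
        scores = np.abs(fitted.model.coef_.ravel())
    elif kind == "latent_linear":
        scores = vip_scores(fitted).vip
    else:
        booster = fitted.model.get_booster()
        gain = booster.get_score(importance_type="gain")
        scores = np.zeros(p)
        for key, val in gain.items():
            scores[int(key.lstrip("f"))] = val
    order = np.lexsort((fitted.axis, -scores))
    return [(float(fitted.axis[i]), float(scores[i])) for i in order[:top_k]]
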