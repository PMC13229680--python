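"""Model/Results front end for the augmented, tuned, weighted ensemble.

:class:`EnsembleRegression` bundles the full training recipe — optional
leakage-safe augmentation of the training set, per-learner cross-validated
hyperparameter search, convex ensemble-weight calibration and final fits —
behind a statsmodels-style ``model.fit() -> results`` interface.
:class:`EnsembleResults` carries the tuned specifications, calibrated
weights, diagnostics and prediction/evaluation methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ensemble as E
from . import learners as L
from .augment import AugmentConfig, build_augmented_training_set
from .dataio import SpectralDataset
from .exceptions import ConfigurationError
from .metrics import MetricReport

MODEL_NAMES = L.KINDS + ("ensemble",)


class EnsembleRegression:
    """Chlorophyll regression on reflectance spectra via a tuned ensemble.

    Parameters
    ----------
    train : training dataset (original-provenance rows).
    augment : optional :class:`AugmentConfig`; when given, the training set
        is doubled with one perturbed variant per original before tuning.
        ``None`` trains on the originals only (the baseline condition).
    n_trials : tuning trials per base learner (paired 5-fold CV objective).
    space : per-learner search-space override (see ``ensemble.default_space``).
    seed : master seed for folds, samplers and learner internals.
    """

    def __init__(
        self,
        train: SpectralDataset,
        augment: AugmentConfig | None = None,
        n_trials: int = 30,
        cv_folds: int = 5,
        weight_folds: int = 3,
        weight_calls: int = 40,
        space: dict | None = None,
        seed: int = 42,
    ):
        self.train = train
        self.augment = augment
        self.n_trials = n_trials
        self.cv_folds = cv_folds
        self.weight_folds = weight_folds
        self.weight_calls = weight_calls
        self.space = space
        self.seed = int(seed)

    @classmethod
    def from_dataframe(
        cls,
        spectra: pd.DataFrame,
        labels: pd.Series | np.ndarray,
        ids=None,
        **kwargs,
    ) -> "EnsembleRegression":
        """Build from a wide spectra frame (numeric-nm columns) and labels."""
        wavelengths = np.array([float(c) for c in spectra.columns])
        if ids is None:
            ids = np.array([str(i) for i in spectra.index], dtype=object)
        ds = SpectralDataset(
            wavelengths, spectra.to_numpy(dtype=float), np.asarray(labels, float), ids
        )
        return cls(ds, **kwargs)

    def fit(self, reuse_specs: dict | None = None) -> "EnsembleResults":
        """Run augmentation, tuning, weight calibration and final fits.

        ``reuse_specs`` (kind -> :class:`~leafspec.learners.LearnerSpec`)
        skips the per-learner search, e.g. to reuse one tuning pass across
        an augmentation grid.
        """
        train_eff = (
            build_augmented_training_set(self.train, self.augment)
            if self.augment is not None
            else self.train
        )
        X, y, axis = train_eff.X, train_eff.y, train_eff.wavelengths_nm
        space = self.space or E.default_space(X.shape[0], X.shape[1])

        searches: dict[str, E.SearchResult] = {}
        specs = []
        for i, kind in enumerate(L.KINDS):
            if reuse_specs is not None:
                if kind not in reuse_specs:
                    raise ConfigurationError(f"reuse_specs missing kind {kind!r}")
                specs.append(reuse_specs[kind])
            else:
                sr = E.tune_learner(
                    kind, space, X, y,
                    n_trials=self.n_trials, k=self.cv_folds, seed=self.seed,
                )
                searches[kind] = sr
                specs.append(sr.best_spec)

        weights, cv_mse = E.calibrate_weights(
            specs, X, y, k=self.weight_folds, n_calls=self.weight_calls, seed=self.seed
        )
        fitted = [L.fit(s, X, y, axis) for s in specs]
        return EnsembleResults(
            model=self,
            train_effective=train_eff,
            specs={s.kind: s for s in specs},
            searches=searches,
            weights=weights,
            weight_cv_mse=cv_mse,
            fitted={f.spec.kind: f for f in fitted},
        )


@dataclass
class EnsembleResults:
    """Fitted ensemble: tuned specs, calibrated weights and diagnostics."""

    model: EnsembleRegression
    train_effective: SpectralDataset
    specs: dict
    searches: dict
    weights: E.EnsembleWeights
    weight_cv_mse: float
    fitted: dict
    _evaluations: dict = field(default_factory=dict)

    # -- prediction -------------------------------------------------------
    def predict(self, X, model: str = "ensemble") -> np.ndarray:
        """Predict chlorophyll for spectra on the training axis."""
        if isinstance(X, SpectralDataset):
            X = X.X
        if model == "ensemble":
            ordered = [self.fitted[k] for k in self.weights.kinds]
            return E.ensemble_predict(ordered, self.weights, X)
        if model not in self.fitted:
            raise ConfigurationError(f"unknown model {model!r}")
        return L.predict(self.fitted[model], X)

    def evaluate(self, dataset: SpectralDataset, split_name: str = "val") -> dict:
        """R^2/RMSE of every base learner and the ensemble on one split."""
        out = {}
        for name in MODEL_NAMES:
            y_hat = self.predict(dataset, model=name)
            out[name] = MetricReport.evaluate(dataset.y, y_hat, split_name)
        self._evaluations[split_name] = out
        return out

    # -- interpretability -------------------------------------------------
    def band_importances(self, model: str, top_k: int = 20):
        if model not in self.fitted:
            raise ConfigurationError(f"unknown model {model!r}")
        return L.band_importances(self.fitted[model], top_k)

    def vip(self):
        return L.vip_scores(self.fitted["latent_linear"])

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        """Human-readable fit summary (weights, tuned specs, metrics)."""
        lines = [
            "Convex-weighted ensemble regression",
            "=" * 60,
            f"training rows: {self.train_effective.n_samples} "
            f"(augmentation: {self._augment_desc()})",
            f"bands: {self.train_effective.n_bands} "
            f"({self.train_effective.wavelengths_nm[0]:g}-"
            f"{self.train_effective.wavelengths_nm[-1]:g} nm)",
            "",
            "Ensemble weights (3-fold CV-MSE calibrated, "
            f"cv_mse={self.weight_cv_mse:.4f}):",
        ]
        for kind, w in self.weights.as_dict().items():
            lines.append(f"  {kind:<15s} w = {w:.4f}")
        lines.append("")
        lines.append("Tuned base learners:")
        for kind, spec in self.specs.items():
            hp = ", ".join(f"{k}={_fmt(v)}" for k, v in spec.hyperparams.items())
            obj = (
                f"  (cv R^2 = {self.searches[kind].best_cv_r2:.4f})"
                if kind in self.searches
                else ""
            )
            lines.append(f"  {kind:<15s} {hp}{obj}")
        for split, reports in self._evaluations.items():
            lines.append("")
            lines.append(f"Metrics on '{split}':")
            lines.append(f"  {'model':<15s} {'R^2':>8s} {'RMSE':>10s}")
            for name, rep in reports.items():
                lines.append(f"  {name:<15s} {rep.r2:>8.4f} {rep.rmse:>10.4f}")
        return "\n".join(lines)

    def _augment_desc(self) -> str:
        a = self.model.augment
        if a is None:
            return "none"
        return f"{a.mode}, sigma={a.noise_sigma}, warp={a.warp_magnitude}"

    # -- plotting ---------------------------------------------------------
    def plot_predictions(self, dataset: SpectralDataset, ax=None, model="ensemble"):
        """Predicted-vs-measured parity scatter."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        y_hat = self.predict(dataset, model=model)
        ax.scatter(dataset.y, y_hat, s=12, alpha=0.6)
        lims = [min(dataset.y.min(), y_hat.min()), max(dataset.y.max(), y_hat.max())]
        ax.plot(lims, lims, "k--", lw=1)
        ax.set_xlabel("measured chlorophyll")
        ax.set_ylabel("predicted chlorophyll")
        ax.set_title(f"{model} parity")
        return ax

    def plot_residuals(self, dataset: SpectralDataset, ax=None, model="ensemble"):
        """Residuals against measured values."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        y_hat = self.predict(dataset, model=model)
        ax.scatter(dataset.y, dataset.y - y_hat, s=12, alpha=0.6)
        ax.axhline(0.0, color="k", lw=1, ls="--")
        ax.set_xlabel("measured chlorophyll")
        ax.set_ylabel("residual (measured - predicted)")
        return ax


def _fmt(v):
    return f"{v:.4g}" if isinstance(v, float) else str(v)
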