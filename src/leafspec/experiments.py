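"""Experiment harness: baseline, augmentation grids, residuals, sample-size.

The grid harness is the machine twin of a benchmark table: every row is one
(augmentation setting, model) pair with train and validation R^2/RMSE under
a shared seed.  Validation data are never augmented, and the zero-
perturbation setting runs the identical no-augmentation code path as the
baseline so the two agree bitwise under a shared seed.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .augment import AugmentConfig
from .dataio import SpectralDataset
from .exceptions import ConfigurationError
from .metrics import r_squared, rmse  # noqa: F401  (re-exported metric surface)
from .model import MODEL_NAMES, EnsembleRegression

GRID_COLUMNS = [
    "mode", "noise_sigma", "warp_magnitude", "model",
    "train_r2", "train_rmse", "val_r2", "val_rmse", "seed",
]

#: default single-factor and composite grids
NOISE_GRID = tuple(round(0.001 * i, 3) for i in range(1, 9))  # 0.001 .. 0.008
WARP_GRID = tuple(round(0.01 * i, 2) for i in range(1, 8))  # 0.01 .. 0.07
COMPOSITE_GRID = tuple(
    itertools.product((0.001, 0.002, 0.003, 0.004), (0.01, 0.015, 0.02, 0.025))
)


def _run_setting(
    train: SpectralDataset,
    val: SpectralDataset,
    augment: AugmentConfig | None,
    seed: int,
    n_trials: int,
    reuse_specs: dict | None,
    mode_label: str,
) -> list[dict]:
    model = EnsembleRegression(train, augment=augment, n_trials=n_trials, seed=seed)
    res = model.fit(reuse_specs=reuse_specs)
    tr_rep = res.evaluate(train, "train")
    va_rep = res.evaluate(val, "val")
    rows = []
    for name in MODEL_NAMES:
        rows.append(
            {
                "mode": mode_label,
                "noise_sigma": augment.noise_sigma if augment else 0.0,
                "warp_magnitude": augment.warp_magnitude if augment else 0.0,
                "model": name,
                "train_r2": tr_rep[name].r2,
                "train_rmse": tr_rep[name].rmse,
                "val_r2": va_rep[name].r2,
                "val_rmse": va_rep[name].rmse,
                "seed": seed,
            }
        )
    return rows


def run_baseline(
    train: SpectralDataset,
    val: SpectralDataset,
    seed: int = 42,
    n_trials: int = 30,
    reuse_specs: dict | None = None,
) -> pd.DataFrame:
    """Tune/fit/evaluate the three learners + ensemble without augmentation."""
    _check_disjoint(train, val)
    rows = _run_setting(train, val, None, seed, n_trials, reuse_specs, "baseline")
    return pd.DataFrame(rows, columns=GRID_COLUMNS)


def run_augmentation_grid(
    train: SpectralDataset,
    val: SpectralDataset,
    mode: str = "composite",
    settings=None,
    seed: int = 42,
    n_trials: int = 30,
    reuse_tuning: bool = False,
    reuse_specs: dict | None = None,
) -> pd.DataFrame:
    """Evaluate the full tune-fit-ensemble chain across augmentation settings.

    ``settings`` is a sequence of (noise_sigma, warp_magnitude) pairs; the
    default follows ``mode`` (8 noise levels, 7 warp levels, or the 16
    composite noise x warp combinations).  Each setting rebuilds the
    augmented training set from the same originals under the shared seed.
    With ``reuse_tuning`` the hyperparameter search runs once on the
    un-augmented originals and its specs are reused for every setting
    (weight calibration still runs per setting); ``reuse_specs`` supplies
    already-tuned specs directly.
    """
    _check_disjoint(train, val)
    if settings is None:
        if mode == "noise":
            settings = [(s, 0.0) for s in NOISE_GRID]
        elif mode == "warp":
            settings = [(0.0, m) for m in WARP_GRID]
        elif mode == "composite":
            settings = list(COMPOSITE_GRID)
        else:
            raise ConfigurationError(f"unknown augmentation mode {mode!r}")
    settings = list(settings)
    if not settings:
        raise ConfigurationError("settings must be nonempty")

    if reuse_specs is None and reuse_tuning:
        base = EnsembleRegression(train, augment=None, n_trials=n_trials, seed=seed)
        reuse_specs = {k: sr.best_spec for k, sr in base.fit().searches.items()}

    rows: list[dict] = []
    for sigma, magnitude in settings:
        if sigma == 0 and magnitude == 0:
            aug = None  # identity augmentation == the baseline condition
        else:
            aug = AugmentConfig(
                mode=mode, noise_sigma=sigma, warp_magnitude=magnitude, seed=seed
            )
        rows.extend(
            _run_setting(train, val, aug, seed, n_trials, reuse_specs, mode)
        )
    return pd.DataFrame(rows, columns=GRID_COLUMNS)


def _check_disjoint(train: SpectralDataset, val: SpectralDataset) -> None:
    overlap = set(train.ids.tolist()) & set(val.ids.tolist())
    if overlap:
        raise ConfigurationError(
            f"train and validation sets share identifiers, e.g. {sorted(overlap)[0]!r}"
        )


# ---------------------------------------------------------------------------
# Residual analysis
# ---------------------------------------------------------------------------

def residual_analysis(y, y_hat, n_grid: int = 256):
    """Residuals, their kernel-density summary and per-tertile mean residual.

    Residuals are ``y - y_hat`` (positive = underestimation).  The density
    uses a Gaussian kernel with Silverman bandwidth on a fixed grid padded
    10% beyond the residual range; for degenerate (constant) residuals the
    density is reported as a unit spike at that value.  Tertiles are cut on
    the observed labels, so a positive high-tertile mean exposes high-range
    underestimation.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if len(y) != len(y_hat):
        raise ConfigurationError("y and y_hat must have equal length")
    r = y - y_hat
    table = pd.DataFrame({"observed": y, "predicted": y_hat, "residual": r})

    if np.ptp(r) == 0:
        density = pd.DataFrame({"residual": [r[0]], "density": [1.0]})
    else:
        pad = 0.1 * np.ptp(r)
        grid = np.linspace(r.min() - pad, r.max() + pad, n_grid)
        kde = gaussian_kde(r, bw_method="silverman")
        density = pd.DataFrame({"residual": grid, "density": kde(grid)})

    order = np.argsort(y, kind="stable")
    names = ("low", "medium", "high")
    rows = []
    for name, grp in zip(names, np.array_split(order, 3)):
        rows.append(
            {"tertile": name, "mean_residual": float(r[grp].mean()), "n": len(grp)}
        )
    tertiles = pd.DataFrame(rows)
    return table, density, tertiles


# ---------------------------------------------------------------------------
# Sample-size response
# ---------------------------------------------------------------------------

def sample_size_curve(
    dataset: SpectralDataset,
    fractions=(0.2, 0.4, 0.6, 0.8, 1.0),
    n_repeats: int = 5,
    seed: int = 42,
    n_trials: int = 30,
    train_fraction: float = 0.7,
) -> pd.DataFrame:
    """Validation RMSE of every model as the training subset grows.

    Each repeat draws its own train/validation split (seed + repeat index)
    and evaluates nested training subsets: the subset at a smaller fraction
    is contained in every larger one, so rows differ only by training size.
    Returns (fraction, model, mean_val_rmse, sd_val_rmse, n_train).
    """
    from .dataio import split_dataset

    fractions = sorted(fractions)
    if not fractions or fractions[0] <= 0 or fractions[-1] > 1:
        raise ConfigurationError("fractions must lie in (0, 1]")
    records: dict[tuple, list] = {}
    n_train_at: dict[float, int] = {}
    for rep in range(n_repeats):
        rep_seed = seed + rep
        train, val = split_dataset(dataset, train_fraction, rep_seed)
        perm = np.random.default_rng(rep_seed).permutation(train.n_samples)
        for frac in fractions:
            n_sub = max(2, int(np.ceil(frac * train.n_samples)))
            n_train_at[frac] = n_sub
            sub = train.subset(np.sort(perm[:n_sub]))
            df = run_baseline(sub, val, seed=rep_seed, n_trials=n_trials)
            for _, row in df.iterrows():
                records.setdefault((frac, row["model"]), []).append(row["val_rmse"])
    rows = []
    for frac in fractions:
        for name in MODEL_NAMES:
            vals = np.array(records[(frac, name)])
            rows.append(
                {
                    "fraction": frac,
                    "model": name,
                    "mean_val_rmse": float(vals.mean()),
                    "sd_val_rmse": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    "n_train": n_train_at[frac],
                }
            )
    return pd.DataFrame(rows)
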