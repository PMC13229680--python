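"""Spectral smoothing, label stratification and split diagnostics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .dataio import SpectralDataset, Spectrum
from .exceptions import ConfigurationError, DataError

#: default moving-average window, in bands
DEFAULT_WINDOW = 63


def moving_average(values, window: int = DEFAULT_WINDOW):
    """Centered moving-average smoothing with a shrinking window at the edges.

    ``window`` counts bands (odd, positive).  Near the spectrum ends the
    window is truncated to the available bands, so the output has the same
    length as the input and no reflectance outside the measured range is
    fabricated.  Accepts a 1-D spectrum or an ``n x p`` matrix (smoothed
    along bands).
    """
    if window <= 0 or window % 2 == 0:
        raise ConfigurationError(f"window must be an odd positive integer, got {window}")
    arr = np.asarray(values, dtype=float)
    one_d = arr.ndim == 1
    mat = arr[None, :] if one_d else arr
    if window > mat.shape[1]:
        raise ConfigurationError(
            f"window {window} exceeds the number of bands {mat.shape[1]}"
        )
    half = window // 2
    n_bands = mat.shape[1]
    # clipped-window mean via cumulative sums
    csum = np.cumsum(np.concatenate([np.zeros((mat.shape[0], 1)), mat], axis=1), axis=1)
    lo = np.clip(np.arange(n_bands) - half, 0, None)
    hi = np.clip(np.arange(n_bands) + half + 1, None, n_bands)
    out = (csum[:, hi] - csum[:, lo]) / (hi - lo)
    return out[0] if one_d else out


def smooth_dataset(dataset: SpectralDataset, window: int = DEFAULT_WINDOW) -> SpectralDataset:
    """Return a copy of the dataset with every spectrum smoothed."""
    smoothed = dataset.replace(X=moving_average(dataset.X, window))
    smoothed.meta = {**dataset.meta, "smoothing_window": window}
    return smoothed


@dataclass(frozen=True)
class CorrelationProfile:
    """Per-band Pearson correlation between reflectance and the label.

    ``r`` is NaN at flagged zero-variance bands rather than silently zero.
    """

    wavelengths_nm: np.ndarray
    r: np.ndarray
    zero_variance: np.ndarray  # boolean flags

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wavelength_nm": self.wavelengths_nm,
                "r": self.r,
                "zero_variance": self.zero_variance,
            }
        )


def correlation_profile(dataset: SpectralDataset) -> CorrelationProfile:
    """Pearson correlation of each band with the chlorophyll label."""
    if dataset.n_samples < 3:
        raise DataError("correlation profile needs at least 3 samples")
    y = dataset.y
    yc = y - y.mean()
    sy = np.sqrt((yc**2).sum())
    if sy == 0:
        raise DataError("label has zero variance; correlation undefined")
    Xc = dataset.X - dataset.X.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    zero_var = sx == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * yc[:, None]).sum(axis=0) / (sx * sy)
    r[zero_var] = np.nan
    return CorrelationProfile(dataset.wavelengths_nm.copy(), r, zero_var)


@dataclass(frozen=True)
class LevelAssignment:
    """Quantile-based label levels (low/medium/high by default)."""

    ids: np.ndarray
    level: np.ndarray  # level name per sample
    cut_points: np.ndarray  # label thresholds between consecutive levels
    level_names: tuple

    def members(self, name: str) -> np.ndarray:
        return self.ids[self.level == name]


_LEVEL_NAMES3 = ("low", "medium", "high")


def stratify_levels(dataset: SpectralDataset, n_levels: int = 3) -> LevelAssignment:
    """Rank samples by label and cut into near-equal quantile groups.

    Ties are broken by identifier order; group sizes differ by at most one.
    With three levels the groups are the familiar low/medium/high tertiles.
    """
    n = dataset.n_samples
    if n < n_levels:
        raise ConfigurationError(f"need at least {n_levels} samples for {n_levels} levels")
    if n_levels == 3:
        names = _LEVEL_NAMES3
    else:
        names = tuple(f"level_{i + 1}" for i in range(n_levels))
    if np.ptp(dataset.y) == 0:
        warnings.warn("all labels equal; every sample assigned to one level")
        level = np.array([names[0]] * n, dtype=object)
        return LevelAssignment(
            dataset.ids.copy(), level, np.array([]), (names[0],)
        )
    order = np.lexsort((dataset.ids.astype(str), dataset.y))
    groups = np.array_split(order, n_levels)
    level = np.empty(n, dtype=object)
    cuts = []
    for name, grp in zip(names, groups):
        level[grp] = name
    for a, b in zip(groups[:-1], groups[1:]):
        cuts.append(0.5 * (dataset.y[a[-1]] + dataset.y[b[0]]))
    return LevelAssignment(dataset.ids.copy(), level, np.array(cuts), names)


def mean_spectrum(dataset: SpectralDataset, subset_ids) -> Spectrum:
    """Bandwise arithmetic mean spectrum over a subset of sample ids."""
    subset_ids = list(subset_ids)
    if not subset_ids:
        raise DataError("subset is empty")
    index = {sid: i for i, sid in enumerate(dataset.ids)}
    try:
        rows = [index[s] for s in subset_ids]
    except KeyError as exc:
        raise DataError(f"unknown sample id {exc.args[0]!r}") from None
    return Spectrum(
        f"mean({len(rows)} samples)",
        dataset.wavelengths_nm,
        dataset.X[rows].mean(axis=0),
    )


def pca_scores(
    train: SpectralDataset, val: SpectralDataset, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Descriptive PCA split check: basis fit on train only, val projected.

    Returns a tidy per-sample score table (id, split, pc1..pcK) and the
    explained-variance fractions of the train-fitted basis.  This is a
    coverage diagnostic, not evidence of an unbiased partition.
    """
    if train.n_samples < 2:
        raise DataError("PCA needs at least 2 training samples")
    k = min(n_components, train.n_samples - 1, train.n_bands)
    if k < n_components:
        raise ConfigurationError(
            f"n_components={n_components} exceeds min(n_train-1, p)={k}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    t_scores = pca.fit_transform(train.X)
    v_scores = pca.transform(val.X)
    cols = [f"pc{i + 1}" for i in range(n_components)]
    frames = []
    for split, ds, scores in (("train", train, t_scores), ("val", val, v_scores)):
        df = pd.DataFrame(scores, columns=cols)
        df.insert(0, "split", split)
        df.insert(0, "id", ds.ids)
        frames.append(df)
    return pd.concat(frames, ignore_index=True), pca.explained_variance_ratio_.copy()
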