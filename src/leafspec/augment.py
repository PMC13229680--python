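"""Physically constrained spectral augmentation.

Two perturbation operators expand a small training set while keeping the
spectra physiologically plausible:

* **additive Gaussian noise** — i.i.d. per-band noise emulating random
  measurement noise (sigma in reflectance units, searched in 0.001–0.008);
* **smooth wavelength warping** — a smooth, endpoint-pinned, monotone
  displacement field ``d(lambda)`` remaps the wavelength axis, emulating
  calibration drift and sample-state shape changes (magnitude expressed as
  the maximum displacement as a fraction of the modeled span, searched in
  0.01–0.07).

The composite operator applies warping first (shape drift happens before
the sensor), then noise.  :func:`build_augmented_training_set` doubles a
training set with one perturbed variant per original, copying labels and
recording lineage; validation data are never augmented, which keeps every
variant's parent strictly inside the training partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .dataio import ORIGINAL, SpectralDataset
from .exceptions import ConfigurationError, DataError

#: default search bounds used by the grid harness
NOISE_BOUNDS = (0.001, 0.008)
WARP_BOUNDS = (0.01, 0.07)


@dataclass(frozen=True)
class AugmentConfig:
    """One augmentation setting (operator, magnitudes, seed)."""

    mode: str = "composite"  # noise | warp | composite
    noise_sigma: float = 0.002
    warp_magnitude: float = 0.02
    n_control_points: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("noise", "warp", "composite"):
            raise ConfigurationError(f"unknown augmentation mode {self.mode!r}")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be nonnegative")
        if self.warp_magnitude < 0:
            raise ConfigurationError("warp_magnitude must be nonnegative")
        if self.n_control_points < 2:
            raise ConfigurationError("n_control_points must be >= 2")


def add_gaussian_noise(X, sigma: float, rng: np.random.Generator):
    """Add i.i.d. Normal(0, sigma^2) noise to every entry."""
    if sigma < 0:
        raise ConfigurationError("sigma must be nonnegative")
    X = np.asarray(X, dtype=float)
    if sigma == 0:
        return X.copy()
    return X + rng.normal(0.0, sigma, size=X.shape)


@dataclass(frozen=True)
class WarpField:
    """A smooth displacement field over one wavelength axis.

    Invariants: displacements vanish at both endpoints, ``|d| <=
    magnitude * span`` everywhere, and the remap ``lambda + d(lambda)`` is
    strictly increasing on the axis (no fold-over).
    """

    axis: np.ndarray
    control_wavelengths: np.ndarray
    displacements_nm: np.ndarray  # at control points
    d: np.ndarray  # interpolated displacement on the full axis

    @property
    def remap(self) -> np.ndarray:
        return self.axis + self.d


def make_warp_field(
    axis,
    magnitude: float,
    n_control: int = 4,
    rng: np.random.Generator | None = None,
) -> WarpField:
    """Draw a random smooth warp field of bounded magnitude.

    Interior control displacements are Uniform(-m*span, +m*span) at evenly
    spaced anchors, endpoints pinned at zero, interpolated by a natural
    cubic spline.  If the interpolant overshoots the bound or breaks remap
    monotonicity, the whole field is rescaled by the largest admissible
    factor (computed from the per-interval remap differences).
    """
    if magnitude < 0:
        raise ConfigurationError("magnitude must be nonnegative")
    if n_control < 2:
        raise ConfigurationError("n_control must be >= 2")
    axis = np.asarray(axis, dtype=float)
    rng = rng if rng is not None else np.random.default_rng()
    span = axis[-1] - axis[0]
    control = np.linspace(axis[0], axis[-1], n_control + 2)
    disp = np.zeros(n_control + 2)
    # draw interior displacements even when magnitude == 0 so the rng stream
    # does not depend on the magnitude value
    disp[1:-1] = rng.uniform(-1.0, 1.0, size=n_control) * magnitude * span
    if magnitude == 0:
        return WarpField(axis, control, disp, np.zeros_like(axis))
    d = CubicSpline(control, disp, bc_type="natural")(axis)
    scale = 1.0
    max_abs = np.max(np.abs(d))
    if max_abs > magnitude * span:
        scale = min(scale, magnitude * span / max_abs)
    # remap monotone: diff(axis) + s*diff(d) > 0 for every interval
    da, dd = np.diff(axis), np.diff(d)
    neg = dd < 0
    if np.any(neg):
        scale = min(scale, 0.999 * np.min(da[neg] / (-dd[neg])))
    d = d * scale
    disp = disp * scale
    return WarpField(axis, control, disp, d)


def smooth_warp(X, axis, field: WarpField):
    """Resample spectra at the warped wavelengths ``lambda + d(lambda)``.

    Linear interpolation of each spectrum, clamped to the measured range at
    the boundaries; output shape equals input shape.
    """
    axis = np.asarray(axis, dtype=float)
    if len(axis) != len(field.axis) or not np.allclose(axis, field.axis):
        raise DataError("warp field was built for a different wavelength axis")
    arr = np.asarray(X, dtype=float)
    one_d = arr.ndim == 1
    mat = np.atleast_2d(arr)
    target = np.clip(field.remap, axis[0], axis[-1])
    out = np.empty_like(mat)
    for i in range(mat.shape[0]):
        out[i] = np.interp(target, axis, mat[i])
    return out[0] if one_d else out


def composite_perturb(
    X,
    axis,
    sigma: float,
    magnitude: float,
    rng: np.random.Generator,
    n_control: int = 4,
):
    """Warp each spectrum with its own fresh field, then add fresh noise."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.empty_like(X)
    for i in range(X.shape[0]):
        field = make_warp_field(np.asarray(axis, float), magnitude, n_control, rng)
        out[i] = smooth_warp(X[i], axis, field)
    return add_gaussian_noise(out, sigma, rng)


#: reflectance below this after perturbation is flagged as implausible
_NEGATIVE_FLAG = -0.05


def build_augmented_training_set(
    train: SpectralDataset, config: AugmentConfig
) -> SpectralDataset:
    """Originals plus one perturbed variant each: a 2n-row training set.

    Variant labels are copied from their parents; provenance records the
    operator and parent id.  Augmenting an already-augmented set is refused
    to prevent perturbations from compounding across experiments.
    """
    if not np.all(train.provenance == ORIGINAL):
        raise DataError(
            "training set already contains augmented rows; augment originals only"
        )
    rng = np.random.default_rng(config.seed)
    axis = train.wavelengths_nm
    if config.mode == "noise":
        X_aug = add_gaussian_noise(train.X, config.noise_sigma, rng)
    elif config.mode == "warp":
        X_aug = composite_perturb(
            train.X, axis, 0.0, config.warp_magnitude, rng, config.n_control_points
        )
    else:
        X_aug = composite_perturb(
            train.X,
            axis,
            config.noise_sigma,
            config.warp_magnitude,
            rng,
            config.n_control_points,
        )
    if np.any(X_aug < _NEGATIVE_FLAG):
        warnings.warn(
            "augmentation produced reflectance below -0.05; "
            "perturbation magnitudes may be implausibly large"
        )
    aug_ids = np.array([f"{sid}-aug" for sid in train.ids], dtype=object)
    new = SpectralDataset(
        axis.copy(),
        np.vstack([train.X, X_aug]),
        np.concatenate([train.y, train.y]),
        np.concatenate([train.ids, aug_ids]),
        np.concatenate(
            [train.provenance, np.array([config.mode] * train.n_samples, dtype=object)]
        ),
        np.concatenate([train.parent_ids, train.ids.copy()]),
        {
            **train.meta,
            "augmentation": {
                "mode": config.mode,
                "noise_sigma": config.noise_sigma,
                "warp_magnitude": config.warp_magnitude,
                "seed": config.seed,
            },
        },
    )
    return new
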