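"""Synthetic leaf-reflectance generator.

A phenomenological model of a green-leaf reflectance spectrum over
400–1000 nm with the structure chlorophyll estimation relies on:

* strong visible absorption whose green peak (~550 nm) shrinks as
  chlorophyll increases,
* a logistic red edge whose inflection moves longward with chlorophyll
  (``lambda_re = 690 + 0.5 * chl`` nm),
* a flat near-infrared plateau,
* a leaf-water absorption dip near 975 nm,
* multiplicative brightness variation and additive measurement noise.

It is deliberately *not* a radiative-transfer model (PROSPECT-class
fidelity is out of scope); it provides monotone, localized, physiologically
ordered structure so every pipeline stage can be exercised and verified
without external data.  The ground truth (chlorophyll, brightness,
noiseless spectrum, true red-edge position) is returned alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import Spectrum, SpectralDataset
from .exceptions import ConfigurationError


def _default_axis() -> np.ndarray:
    return np.arange(400.0, 1001.0, 1.0)  # 601 bands


@dataclass
class SyntheticConfig:
    """Generator settings; defaults define the package's study conditions."""

    n_samples: int = 1000
    axis: np.ndarray = field(default_factory=_default_axis)
    chl_range: tuple[float, float] = (10.0, 70.0)
    measurement_noise_sd: float = 0.003
    brightness_sd: float = 0.05
    label_noise_sd: float = 0.0
    seed: int = 0
    # spectral shape constants (overridable)
    base_reflectance: float = 0.05
    nir_amplitude: float = 0.45
    red_edge_width_nm: float = 15.0
    red_edge_offset_nm: float = 690.0
    red_edge_slope_nm_per_chl: float = 0.5
    green_peak_nm: float = 550.0
    green_width_nm: float = 30.0
    green_amplitude: float = 0.15
    green_decay_chl: float = 40.0
    water_dip_nm: float = 975.0
    water_width_nm: float = 25.0
    water_depth: float = 0.06

    def __post_init__(self) -> None:
        lo, hi = self.chl_range
        if not (0 < lo < hi):
            raise ConfigurationError("chl_range must be positive and increasing")
        axis = np.asarray(self.axis, dtype=float)
        if axis.min() < 400 - 1e-9 or axis.max() > 1000 + 1e-9:
            raise ConfigurationError("axis must lie within [400, 1000] nm")
        self.axis = axis


def red_edge_inflection(chl: float, config: SyntheticConfig | None = None) -> float:
    """True red-edge inflection wavelength (nm) for a chlorophyll value."""
    c = config or SyntheticConfig()
    return c.red_edge_offset_nm + c.red_edge_slope_nm_per_chl * chl


def noiseless_reflectance(
    chl: float, config: SyntheticConfig, brightness: float = 1.0
) -> np.ndarray:
    """Deterministic spectral model before noise and clipping."""
    lam = config.axis
    lam_re = red_edge_inflection(chl, config)
    sigmoid = 1.0 / (1.0 + np.exp(-(lam - lam_re) / config.red_edge_width_nm))
    green = (
        config.green_amplitude
        * np.exp(-chl / config.green_decay_chl)
        * np.exp(-((lam - config.green_peak_nm) ** 2) / (2 * config.green_width_nm**2))
    )
    water = config.water_depth * np.exp(
        -((lam - config.water_dip_nm) ** 2) / (2 * config.water_width_nm**2)
    )
    return brightness * (
        config.base_reflectance + config.nir_amplitude * sigmoid + green - water
    )


def generate_spectrum(
    chl: float,
    config: SyntheticConfig | None = None,
    rng: np.random.Generator | None = None,
    sample_id: str = "SYN-000001",
) -> tuple[Spectrum, dict]:
    """Draw one spectrum; returns it with its ground-truth record."""
    config = config or SyntheticConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = config.chl_range
    if not (lo <= chl <= hi):
        raise ConfigurationError(f"chl={chl} outside configured range {config.chl_range}")
    brightness = (
        float(rng.lognormal(0.0, config.brightness_sd))
        if config.brightness_sd > 0
        else 1.0
    )
    clean = noiseless_reflectance(chl, config, brightness)
    noisy = clean + rng.normal(0.0, config.measurement_noise_sd, size=clean.shape)
    refl = np.clip(noisy, 0.0, 1.0)
    truth = {
        "sample_id": sample_id,
        "chl": float(chl),
        "brightness": brightness,
        "red_edge_nm": red_edge_inflection(chl, config),
        "noiseless": clean,
    }
    return Spectrum(sample_id, config.axis, refl), truth


def generate_dataset(
    config: SyntheticConfig | None = None,
) -> tuple[SpectralDataset, pd.DataFrame]:
    """Generate a labelled synthetic dataset plus its ground-truth table.

    Chlorophyll is uniform over ``config.chl_range``; the label equals the
    true chlorophyll unless ``label_noise_sd > 0``.  Identifiers are
    ``SYN-000001`` ... and the draw is deterministic per seed.
    """
    config = config or SyntheticConfig()
    if config.n_samples < 1:
        raise ConfigurationError("n_samples must be >= 1")
    rng = np.random.default_rng(config.seed)
    lo, hi = config.chl_range
    chls = rng.uniform(lo, hi, size=config.n_samples)
    X = np.empty((config.n_samples, len(config.axis)))
    truths = []
    for i, chl in enumerate(chls):
        sid = f"SYN-{i + 1:06d}"
        spec, truth = generate_spectrum(chl, config, rng, sid)
        X[i] = spec.reflectance
        truths.append(truth)
    y = chls.copy()
    if config.label_noise_sd > 0:
        y = y + rng.normal(0.0, config.label_noise_sd, size=y.shape)
    ids = np.array([t["sample_id"] for t in truths], dtype=object)
    dataset = SpectralDataset(
        config.axis.copy(), X, y, ids, meta={"source": "synthetic", "seed": config.seed}
    )
    truth_table = pd.DataFrame(
        {
            "id": ids,
            "chl": [t["chl"] for t in truths],
            "brightness": [t["brightness"] for t in truths],
            "red_edge_nm": [t["red_edge_nm"] for t in truths],
        }
    )
    return dataset, truth_table
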