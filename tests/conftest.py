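import numpy as np
import pytest

from leafspec import SpectralDataset, SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """200 synthetic leaf spectra on the default 601-band axis."""
    ds, truth = generate_dataset(SyntheticConfig(n_samples=200, seed=11))
    return ds, truth


@pytest.fixture(scope="session")
def tiny_dataset():
    """30 noiseless, brightness-free spectra (clean signal, fast fits)."""
    cfg = SyntheticConfig(
        n_samples=30, seed=5, measurement_noise_sd=0.0, brightness_sd=0.0
    )
    ds, truth = generate_dataset(cfg)
    return ds, truth


@pytest.fixture()
def toy_dataset():
    """Hand-built 6-sample, 5-band dataset for exact-value checks."""
    wl = np.array([400.0, 500.0, 600.0, 700.0, 800.0])
    rng = np.random.default_rng(3)
    X = rng.random((6, 5))
    y = np.arange(1.0, 7.0)
    ids = np.array([f"S{i}" for i in range(6)], dtype=object)
    return SpectralDataset(wl, X, y, ids)
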