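"""Spectral physiology diagnostics: first derivative and red-edge position.

The red edge — the steep reflectance rise between roughly 680 and 760 nm —
moves toward longer wavelengths as chlorophyll increases, so its position
is the classic physiological sanity check for a chlorophyll pipeline.  The
position is estimated as the wavelength of maximum first derivative inside
the red-edge window (the standard max-slope estimator; recorded as such in
the output metadata).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import SpectralDataset, Spectrum
from .exceptions import ConfigurationError
from .preprocess import LevelAssignment

ESTIMATOR = "max-first-derivative"
DEFAULT_WINDOW_NM = (680.0, 760.0)


def first_derivative(spectrum: Spectrum) -> Spectrum:
    """Central-difference derivative on the (possibly nonuniform) nm axis.

    Interior: d_j = (R_{j+1} - R_{j-1}) / (lambda_{j+1} - lambda_{j-1});
    one-sided differences at the endpoints.  Exact for affine spectra and
    for quadratics at interior points.
    """
    lam = spectrum.wavelengths_nm
    r = spectrum.reflectance
    if len(lam) < 3:
        raise ConfigurationError("derivative needs at least 3 bands")
    d = np.empty_like(r)
    d[1:-1] = (r[2:] - r[:-2]) / (lam[2:] - lam[:-2])
    d[0] = (r[1] - r[0]) / (lam[1] - lam[0])
    d[-1] = (r[-1] - r[-2]) / (lam[-1] - lam[-2])
    return Spectrum(spectrum.sample_id, lam, d)


@dataclass(frozen=True)
class RedEdgeResult:
    """Estimated red-edge position for one sample."""

    sample_id: str
    red_edge_nm: float
    window: tuple
    at_boundary: bool  # argmax fell on a window edge (degenerate shape)
    estimator: str = ESTIMATOR


def red_edge_position(
    spectrum: Spectrum, window_nm: tuple = DEFAULT_WINDOW_NM
) -> RedEdgeResult:
    """Wavelength of maximum first derivative inside the red-edge window.

    Ties are broken toward the longer wavelength.  If the maximum slope sits
    on a window boundary (e.g. a monotone-decreasing spectrum with no red
    edge) the result is flagged via ``at_boundary``.
    """
    lo, hi = window_nm
    if lo >= hi:
        raise ConfigurationError(f"red-edge window invalid: ({lo}, {hi})")
    deriv = first_derivative(spectrum)
    mask = (deriv.wavelengths_nm >= lo) & (deriv.wavelengths_nm <= hi)
    if mask.sum() < 3:
        raise ConfigurationError(
            f"red-edge window ({lo}, {hi}) nm covers fewer than 3 bands"
        )
    wl = deriv.wavelengths_nm[mask]
    d = deriv.reflectance[mask]
    # argmax with ties broken toward the longer wavelength
    best = len(d) - 1 - int(np.argmax(d[::-1]))
    return RedEdgeResult(
        spectrum.sample_id,
        float(wl[best]),
        (float(lo), float(hi)),
        at_boundary=best in (0, len(d) - 1),
    )


def dataset_red_edges(
    dataset: SpectralDataset, window_nm: tuple = DEFAULT_WINDOW_NM
) -> pd.DataFrame:
    """Per-sample red-edge positions for a whole dataset."""
    rows = []
    for i, sid in enumerate(dataset.ids):
        res = red_edge_position(
            Spectrum(sid, dataset.wavelengths_nm, dataset.X[i]), window_nm
        )
        rows.append(
            {
                "id": sid,
                "red_edge_nm": res.red_edge_nm,
                "at_boundary": res.at_boundary,
                "estimator": res.estimator,
            }
        )
    return pd.DataFrame(rows)


def stratified_red_edge(
    dataset: SpectralDataset,
    levels: LevelAssignment,
    window_nm: tuple = DEFAULT_WINDOW_NM,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Red-edge position distributions per chlorophyll level.

    Returns the per-sample table (with its level) and a per-level summary
    (mean, sd, n), ordered low-to-high.
    """
    per_sample = dataset_red_edges(dataset, window_nm)
    level_of = dict(zip(levels.ids, levels.level))
    per_sample["level"] = [level_of[i] for i in per_sample["id"]]
    rows = []
    for name in levels.level_names:
        vals = per_sample.loc[per_sample["level"] == name, "red_edge_nm"].to_numpy()
        if len(vals) == 0:
            continue
        rows.append(
            {
                "level": name,
                "mean_nm": float(vals.mean()),
                "sd_nm": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "n": len(vals),
            }
        )
    return per_sample, pd.DataFrame(rows)
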