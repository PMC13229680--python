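"""Spectral dataset containers, CSV matching, band trimming and splitting.

A :class:`SpectralDataset` couples an ``n x p`` reflectance matrix with a
shared wavelength axis (nm), continuous chlorophyll reference labels and
per-row provenance (original measurement vs. augmented variant).  Datasets
are built either from a pair of delimited label/spectra tables
(:func:`load_matched_dataset`) or by the synthetic generator
(:mod:`leafspec.synthgen`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, DataError

ORIGINAL = "original"
#: provenance tags an augmented row may carry
AUGMENT_MODES = ("noise", "warp", "composite")


@dataclass(frozen=True)
class Spectrum:
    """A single sample's reflectance over a strictly increasing nm axis."""

    sample_id: str
    wavelengths_nm: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        refl = np.asarray(self.reflectance, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "reflectance", refl)
        if wl.ndim != 1 or refl.ndim != 1 or len(wl) != len(refl):
            raise DataError("wavelengths and reflectance must be 1-D and equal length")
        if len(wl) < 2:
            raise DataError("a spectrum needs at least 2 bands")
        if not np.all(np.diff(wl) > 0):
            raise DataError("wavelength axis must be strictly increasing")
        if np.any(wl <= 0):
            raise DataError("wavelengths must be positive (nm)")
        if not np.all(np.isfinite(refl)):
            raise DataError("reflectance values must be finite")


@dataclass(frozen=True)
class MatchReport:
    """Bookkeeping for identifier matching between a label and a spectra table."""

    n_labels_read: int
    n_spectra_read: int
    n_matched: int
    n_dropped_labels: int
    n_dropped_spectra: int

    def __post_init__(self) -> None:
        if self.n_matched > min(self.n_labels_read, self.n_spectra_read):
            raise DataError("matched count exceeds an input table's row count")


@dataclass
class SpectralDataset:
    """Reflectance matrix + labels + ids + provenance on one wavelength axis.

    Parameters
    ----------
    wavelengths_nm : (p,) strictly increasing wavelength axis in nm.
    X : (n, p) reflectance matrix.
    y : (n,) continuous chlorophyll reference values (unit-agnostic).
    ids : (n,) unique sample identifiers.
    provenance : (n,) tags, ``"original"`` or an augmentation mode.
    parent_ids : (n,) parent identifier for augmented rows, ``None`` otherwise.
    """

    wavelengths_nm: np.ndarray
    X: np.ndarray
    y: np.ndarray
    ids: np.ndarray
    provenance: np.ndarray = None  # type: ignore[assignment]
    parent_ids: np.ndarray = None  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.ids = np.asarray(self.ids, dtype=object)
        n = len(self.ids)
        if self.provenance is None:
            self.provenance = np.array([ORIGINAL] * n, dtype=object)
        else:
            self.provenance = np.asarray(self.provenance, dtype=object)
        if self.parent_ids is None:
            self.parent_ids = np.array([None] * n, dtype=object)
        else:
            self.parent_ids = np.asarray(self.parent_ids, dtype=object)
        self._validate()

    def _validate(self) -> None:
        if self.X.ndim != 2:
            raise DataError("X must be 2-D (samples x bands)")
        n, p = self.X.shape
        if len(self.wavelengths_nm) != p:
            raise DataError("wavelength axis length must match X columns")
        if not np.all(np.diff(self.wavelengths_nm) > 0):
            raise DataError("wavelength axis must be strictly increasing")
        if len(self.y) != n or len(self.ids) != n:
            raise DataError("y and ids must match the number of rows of X")
        if len(self.provenance) != n or len(self.parent_ids) != n:
            raise DataError("provenance arrays must match the number of rows")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise DataError("X and y must not contain missing/non-finite values")
        if len(set(self.ids.tolist())) != n:
            raise DataError("sample identifiers must be unique within a dataset")
        id_set = set(self.ids.tolist())
        lineage = set(self.meta.get("lineage_ids", [])) | id_set
        for tag, pid in zip(self.provenance, self.parent_ids):
            if tag == ORIGINAL:
                continue
            if tag not in AUGMENT_MODES:
                raise DataError(f"unknown provenance tag {tag!r}")
            if pid is None or pid not in lineage:
                raise DataError(
                    f"augmented row has parent_id {pid!r} outside the dataset lineage"
                )

    # -- conveniences -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    def spectrum(self, sample_id: str) -> Spectrum:
        """Return one sample as a :class:`Spectrum`."""
        idx = np.flatnonzero(self.ids == sample_id)
        if len(idx) == 0:
            raise DataError(f"unknown sample id {sample_id!r}")
        return Spectrum(sample_id, self.wavelengths_nm, self.X[idx[0]])

    def subset(self, indices: np.ndarray) -> "SpectralDataset":
        """Row-subset, preserving axis and metadata."""
        indices = np.asarray(indices)
        return SpectralDataset(
            self.wavelengths_nm.copy(),
            self.X[indices].copy(),
            self.y[indices].copy(),
            self.ids[indices].copy(),
            self.provenance[indices].copy(),
            self.parent_ids[indices].copy(),
            dict(self.meta),
        )

    def replace(self, **kwargs) -> "SpectralDataset":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# CSV matching
# ---------------------------------------------------------------------------

def _read_table(path, id_column: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"file not found: {path}")
    df = pd.read_csv(path)
    if id_column not in df.columns:
        raise ConfigurationError(f"column {id_column!r} not present in {path}")
    df[id_column] = df[id_column].astype(str).str.strip()
    dup = df[id_column][df[id_column].duplicated()]
    if len(dup):
        raise DataError(f"duplicate identifier {dup.iloc[0]!r} in {path}")
    return df


def load_matched_dataset(
    label_path,
    spectra_path,
    id_column: str = "id",
    target_column: str = "chl",
) -> tuple[SpectralDataset, MatchReport]:
    """Read a label table and a spectra table and join them on identifiers.

    Only samples present in *both* tables are kept (exact string match after
    whitespace stripping); rows are ordered by sorted identifier so the
    result is independent of file row order.  Spectra-table headers other
    than the id column must parse as wavelengths in nm.

    Returns the matched dataset and a :class:`MatchReport` with drop counts.
    """
    labels = _read_table(label_path, id_column)
    if target_column not in labels.columns:
        raise ConfigurationError(
            f"target column {target_column!r} not present in {label_path}"
        )
    spectra = _read_table(spectra_path, id_column)

    wl_cols = [c for c in spectra.columns if c != id_column]
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise ConfigurationError(
            f"spectra headers must be numeric wavelengths (nm): {exc}"
        ) from None
    order = np.argsort(wavelengths)
    wavelengths = wavelengths[order]
    wl_cols = [wl_cols[i] for i in order]

    matched_ids = sorted(set(labels[id_column]) & set(spectra[id_column]))
    if not matched_ids:
        raise DataError("no identifiers are common to the label and spectra tables")

    labels_m = labels.set_index(id_column).loc[matched_ids]
    spectra_m = spectra.set_index(id_column).loc[matched_ids]

    X = spectra_m[wl_cols].to_numpy(dtype=float)
    y = labels_m[target_column].to_numpy(dtype=float)
    if np.any(~np.isfinite(X)) or np.any(~np.isfinite(y)):
        raise DataError("matched tables contain missing or non-finite values")

    dataset = SpectralDataset(wavelengths, X, y, np.array(matched_ids, dtype=object))
    report = MatchReport(
        n_labels_read=len(labels),
        n_spectra_read=len(spectra),
        n_matched=len(matched_ids),
        n_dropped_labels=len(labels) - len(matched_ids),
        n_dropped_spectra=len(spectra) - len(matched_ids),
    )
    return dataset, report


# ---------------------------------------------------------------------------
# Trimming and splitting
# ---------------------------------------------------------------------------

def trim_bands(dataset: SpectralDataset, lo_nm: float, hi_nm: float) -> SpectralDataset:
    """Restrict the dataset to wavelengths in the closed interval [lo, hi] nm."""
    if lo_nm >= hi_nm:
        raise ConfigurationError(f"trim interval invalid: lo={lo_nm} >= hi={hi_nm}")
    mask = (dataset.wavelengths_nm >= lo_nm) & (dataset.wavelengths_nm <= hi_nm)
    if mask.sum() < 2:
        raise DataError(
            f"fewer than 2 bands inside [{lo_nm}, {hi_nm}] nm — nothing to model"
        )
    return dataset.replace(
        wavelengths_nm=dataset.wavelengths_nm[mask], X=dataset.X[:, mask]
    )


def split_dataset(
    dataset: SpectralDataset, train_fraction: float = 0.7, seed: int = 42
) -> tuple[SpectralDataset, SpectralDataset]:
    """Seeded disjoint train/validation partition.

    Rows are sorted by identifier before the seeded permutation so membership
    depends only on (ids, seed), not on file row order.  The training size is
    ``floor(n * train_fraction + 0.5)`` (779/334 for n=1113 at 0.7).
    """
    if not 0 < train_fraction < 1:
        raise ConfigurationError("train_fraction must lie strictly between 0 and 1")
    n = dataset.n_samples
    if n < 2:
        raise ConfigurationError("need at least 2 samples to split")
    n_train = int(np.floor(n * train_fraction + 0.5))
    if n_train == 0 or n_train == n:
        raise ConfigurationError(
            f"train_fraction={train_fraction} leaves an empty partition for n={n}"
        )
    order = np.argsort(dataset.ids.astype(str))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    ordered = order[perm]
    return dataset.subset(np.sort(ordered[:n_train])), dataset.subset(
        np.sort(ordered[n_train:])
    )


# ---------------------------------------------------------------------------
# Directory serialization ({spectra,labels,provenance}.csv + meta.yaml)
# ---------------------------------------------------------------------------

def save_dataset(dataset: SpectralDataset, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = pd.DataFrame(dataset.X, columns=[f"{w:g}" for w in dataset.wavelengths_nm])
    spec.insert(0, "id", dataset.ids)
    spec.to_csv(out / "spectra.csv", index=False)
    pd.DataFrame({"id": dataset.ids, "chl": dataset.y}).to_csv(
        out / "labels.csv", index=False
    )
    pd.DataFrame(
        {
            "id": dataset.ids,
            "provenance": dataset.provenance,
            "parent_id": [p if p is not None else "" for p in dataset.parent_ids],
        }
    ).to_csv(out / "provenance.csv", index=False)
    with open(out / "meta.yaml", "w") as fh:
        yaml.safe_dump({k: v for k, v in dataset.meta.items()}, fh)
    return out


def load_dataset(in_dir) -> SpectralDataset:
    in_dir = Path(in_dir)
    dataset, _ = load_matched_dataset(
        in_dir / "labels.csv", in_dir / "spectra.csv", "id", "chl"
    )
    prov_path = in_dir / "provenance.csv"
    meta = {}
    meta_path = in_dir / "meta.yaml"
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh) or {}
    if prov_path.exists():
        prov = pd.read_csv(prov_path, dtype=str).fillna("")
        prov["id"] = prov["id"].str.strip()
        prov = prov.set_index("id").loc[[str(i) for i in dataset.ids]]
        dataset = dataset.replace(
            provenance=prov["provenance"].to_numpy(dtype=object),
            parent_ids=np.array(
                [p if p else None for p in prov["parent_id"]], dtype=object
            ),
            meta=meta,
        )
    else:
        dataset = dataset.replace(meta=meta)
    return dataset
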