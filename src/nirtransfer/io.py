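"""Reading, writing and validation of spectral datasets.

The on-disk format is a plain CSV with a fixed three-metadata-column
layout::

    sample_id,brand,target,<w1>,<w2>,...,<wd>
    s001,#1,72.5,0.5312,0.5298,...

where ``w1..wd`` are wavenumbers in cm^-1 and each data row carries one
sample's absorbance spectrum.  The internal convention is a strictly
*descending* wavenumber grid (FT-NIR instruments scan 10,000 -> 4,000
cm^-1); ascending files are accepted and reordered on read.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpectralDataset",
    "SpectralFormatError",
    "read_dataset",
    "write_dataset",
    "default_grid",
]

logger = logging.getLogger(__name__)


class SpectralFormatError(ValueError):
    """A spectral CSV file or dataset violates the format contract."""


def default_grid(start: float = 10_000.0, end: float = 4_000.0, step: float = 4.0) -> np.ndarray:
    """Descending inclusive wavenumber grid from ``start`` down to ``end``.

    The default (10,000 -> 4,000 cm^-1 at 4 cm^-1 spacing, 1501 points) is
    a typical FT-NIR digitization of an 8 cm^-1-resolution scan; resolution
    does not fix the export spacing, so the spacing is explicit here.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    if not (start >= end > 0):
        raise ValueError(
            f"need start >= end > 0 for a descending grid, got start={start}, end={end}"
        )
    n = int(np.floor((start - end) / step + 1e-9)) + 1
    return start - step * np.arange(n, dtype=float)


@dataclass
class SpectralDataset:
    """A wavenumber grid plus per-sample spectra, targets and brand tags.

    Attributes
    ----------
    wavenumbers : (d,) array, strictly descending, cm^-1
    absorbance : (n, d) array, unitless absorbance
    target : (n,) array, blend proportion of the analyte component in
        percent of total mass, each value in [0, 100]
    brand : (n,) array of categorical labels
    sample_id : (n,) array of unique strings
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    target: np.ndarray
    brand: np.ndarray
    sample_id: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.target = np.asarray(self.target, dtype=float)
        self.brand = np.asarray(self.brand, dtype=object)
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        if self.absorbance.size == 0:
            self.absorbance = self.absorbance.reshape(0, self.wavenumbers.size)
        self.validate()

    # -- container basics -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.wavenumbers.size

    def __len__(self) -> int:
        return self.n_samples

    def validate(self) -> None:
        d = self.wavenumbers.size
        if self.absorbance.ndim != 2 or self.absorbance.shape[1] != d:
            raise SpectralFormatError(
                f"absorbance has {self.absorbance.shape[1] if self.absorbance.ndim == 2 else '?'}"
                f" columns but the grid has {d} points"
            )
        if d > 1 and not np.all(np.diff(self.wavenumbers) < 0):
            raise SpectralFormatError("wavenumber grid must be strictly descending")
        if not np.all(np.isfinite(self.absorbance)):
            raise SpectralFormatError("absorbance contains non-finite values")
        n = self.n_samples
        for name, arr in (("target", self.target), ("brand", self.brand), ("sample_id", self.sample_id)):
            if arr.shape != (n,):
                raise SpectralFormatError(f"{name} has shape {arr.shape}, expected ({n},)")
        if n and (np.min(self.target) < 0 or np.max(self.target) > 100):
            raise SpectralFormatError("target values must lie in [0, 100]")
        if len(set(self.sample_id.tolist())) != n:
            raise SpectralFormatError("sample_id values must be unique")

    def equals(self, other: "SpectralDataset") -> bool:
        return (
            np.array_equal(self.wavenumbers, other.wavenumbers)
            and np.array_equal(self.absorbance, other.absorbance)
            and np.array_equal(self.target, other.target)
            and self.brand.tolist() == other.brand.tolist()
            and self.sample_id.tolist() == other.sample_id.tolist()
        )

    def take(self, indices) -> "SpectralDataset":
        """Row subset (copy), preserving order of ``indices``."""
        idx = np.asarray(indices, dtype=int)
        return SpectralDataset(
            wavenumbers=self.wavenumbers.copy(),
            absorbance=self.absorbance[idx].copy(),
            target=self.target[idx].copy(),
            brand=self.brand[idx].copy(),
            sample_id=self.sample_id[idx].copy(),
        )


def concat_datasets(datasets) -> SpectralDataset:
    """Stack datasets sharing a common grid into one."""
    datasets = list(datasets)
    if not datasets:
        raise ValueError("need at least one dataset")
    grid = datasets[0].wavenumbers
    for ds in datasets[1:]:
        if not np.array_equal(ds.wavenumbers, grid):
            raise SpectralFormatError("datasets are not on a common wavenumber grid")
    return SpectralDataset(
        wavenumbers=grid.copy(),
        absorbance=np.vstack([ds.absorbance for ds in datasets]),
        target=np.concatenate([ds.target for ds in datasets]),
        brand=np.concatenate([ds.brand for ds in datasets]),
        sample_id=np.concatenate([ds.sample_id for ds in datasets]),
    )


_META_COLS = 3


def read_dataset(path, dialect: str = "csv") -> SpectralDataset:
    """Read a spectral CSV file into a validated :class:`SpectralDataset`.

    Ascending-grid files are accepted: columns are permuted to the internal
    descending convention (with a logged notice).  Row order is preserved.
    """
    if dialect != "csv":
        raise ValueError(f"unknown dialect {dialect!r}; only 'csv' is supported")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SpectralFormatError(f"{path}: empty file") from None
        if len(header) < _META_COLS or header[:_META_COLS] != ["sample_id", "brand", "target"]:
            raise SpectralFormatError(
                f"{path}: header must start with 'sample_id,brand,target', got {header[:_META_COLS]}"
            )
        try:
            grid = np.array([float(w) for w in header[_META_COLS:]], dtype=float)
        except ValueError as exc:
            raise SpectralFormatError(f"{path}: non-numeric wavenumber in header: {exc}") from None
        d = grid.size
        ids, brands, targets, rows = [], [], [], []
        for i, row in enumerate(reader, start=2):  # header is line 1
            if not row:
                continue
            if len(row) != _META_COLS + d:
                raise SpectralFormatError(
                    f"{path}: row {i} has {len(row)} fields, expected {_META_COLS + d}"
                )
            ids.append(row[0])
            brands.append(row[1])
            try:
                targets.append(float(row[2]))
                rows.append(np.array(row[_META_COLS:], dtype=float))
            except ValueError as exc:
                raise SpectralFormatError(f"{path}: non-numeric value in row {i}: {exc}") from None
    X = np.vstack(rows) if rows else np.empty((0, d))
    if d > 1:
        diffs = np.diff(grid)
        if np.all(diffs > 0):
            logger.info("%s: ascending wavenumber grid; reordering to descending convention", path)
            order = np.arange(d)[::-1]
            grid = grid[order]
            X = X[:, order]
        elif not np.all(diffs < 0):
            raise SpectralFormatError(f"{path}: wavenumber grid is not strictly monotone")
    return SpectralDataset(
        wavenumbers=grid,
        absorbance=X,
        target=np.array(targets, dtype=float),
        brand=np.array(brands, dtype=object),
        sample_id=np.array(ids, dtype=object),
    )


def write_dataset(ds: SpectralDataset, path) -> None:
    """Write ``ds`` as spectral CSV, re-readable to an equal dataset.

    Floats are written with :func:`repr`, which round-trips IEEE doubles
    exactly (>= 17 significant digits when needed).
    """
    ds.validate()
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "brand", "target"] + [repr(w) for w in ds.wavenumbers.tolist()])
        for i in range(ds.n_samples):
            writer.writerow(
                [str(ds.sample_id[i]), str(ds.brand[i]), repr(float(ds.target[i]))]
                + [repr(v) for v in ds.absorbance[i].tolist()]
            )
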