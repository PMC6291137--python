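"""Dataset container and file I/O: imzML, metabolite tables, peak tables.

The in-memory container is :class:`MSIDataset` — one profile spectrum
per pixel on a rectangular grid, either sharing one mass axis
(imzML *continuous* mode) or carrying per-pixel axes (*processed*
mode, e.g. when each pixel has its own residual mass drift).

imzML 1.1 reading/writing is delegated to :mod:`pyimzml`. Coordinates
are 0-based internally and converted to imzML's 1-based convention at
this boundary only; pixel order is canonicalized row-major on read.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem import FormulaError, ElementalComposition, parse_formula

__all__ = [
    "MSIDataset",
    "MetaboliteRecord",
    "MSIDataError",
    "read_imzml",
    "write_imzml",
    "read_metabolite_db",
    "write_peak_matrix",
    "read_peak_matrix",
    "write_annotations",
]


class MSIDataError(ValueError):
    """Raised for structurally invalid MSI datasets or files."""


@dataclass
class MSIDataset:
    """A rectangular-grid MSI dataset of profile spectra.

    Parameters
    ----------
    coordinates : (N, 2) int array of 0-based (x, y) pixel positions.
    mzs : list of N strictly increasing m/z arrays. With
        ``shared_axis=True`` all entries must be identical (they may be
        the same object).
    intensities : list of N nonnegative intensity arrays, one per pixel.
    pixel_pitch : pixel spacing in micrometres.
    metadata : free-form key/value pairs.
    """

    coordinates: np.ndarray
    mzs: list[np.ndarray]
    intensities: list[np.ndarray]
    shared_axis: bool
    pixel_pitch: float = 100.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=int)
        n = len(self.coordinates)
        if n == 0:
            raise MSIDataError("no pixels")
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 2:
            raise MSIDataError("coordinates must be an (N, 2) array")
        if len(self.mzs) != n or len(self.intensities) != n:
            raise MSIDataError("mzs/intensities length must match pixel count")
        if len({tuple(c) for c in self.coordinates}) != n:
            raise MSIDataError("duplicate pixel coordinates")
        if self.shared_axis:
            ax0 = self.mzs[0]
            for ax in self.mzs[1:]:
                if ax is not ax0 and not np.array_equal(ax, ax0):
                    raise MSIDataError("shared_axis=True but axes differ")

    # -- basic views ----------------------------------------------------

    @property
    def n_pixels(self) -> int:
        return len(self.coordinates)

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(rows, cols) of the bounding grid."""
        xs, ys = self.coordinates[:, 0], self.coordinates[:, 1]
        return int(ys.max()) + 1, int(xs.max()) + 1

    @property
    def mz_axis(self) -> np.ndarray:
        if not self.shared_axis:
            raise MSIDataError("dataset has per-pixel axes; align first")
        return self.mzs[0]

    def intensity_matrix(self) -> np.ndarray:
        """(N, P) intensity matrix; requires a shared axis."""
        if not self.shared_axis:
            raise MSIDataError("dataset has per-pixel axes; align first")
        return np.vstack(self.intensities)

    def tic(self) -> np.ndarray:
        """Per-pixel total (summed) profile intensity."""
        return np.array([float(np.sum(v)) for v in self.intensities])

    def sort_row_major(self) -> "MSIDataset":
        """Return a copy with pixels ordered row-major (y, then x)."""
        order = np.lexsort((self.coordinates[:, 0], self.coordinates[:, 1]))
        return MSIDataset(
            self.coordinates[order],
            [self.mzs[i] for i in order],
            [self.intensities[i] for i in order],
            self.shared_axis,
            self.pixel_pitch,
            dict(self.metadata),
        )


# -- imzML -------------------------------------------------------------


def write_imzml(
    dataset: MSIDataset,
    path: str | os.PathLike,
    mode: str = "auto",
    intensity_dtype=np.float32,
) -> None:
    """Write a dataset as an imzML/ibd pair.

    ``mode`` is ``"continuous"`` (requires a shared axis),
    ``"processed"``, or ``"auto"`` (continuous iff the axis is shared).
    Intensities are stored as 32-bit floats by default; pass
    ``numpy.float64`` for bit-exact round-trips.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    if mode == "auto":
        mode = "continuous" if dataset.shared_axis else "processed"
    if mode not in ("continuous", "processed"):
        raise MSIDataError(f"unknown imzML mode {mode!r}")
    if mode == "continuous" and not dataset.shared_axis:
        raise MSIDataError("continuous-mode write requires a shared mass axis")
    ds = dataset.sort_row_major()
    with ImzMLWriter(
        str(path),
        mode=mode,
        mz_dtype=np.float64,
        intensity_dtype=intensity_dtype,
        spec_type="profile",
        polarity="positive",
    ) as w:
        for (x, y), mz, inten in zip(ds.coordinates, ds.mzs, ds.intensities):
            # imzML coordinates are 1-based
            w.addSpectrum(np.asarray(mz, float), np.asarray(inten, float), (int(x) + 1, int(y) + 1))


def read_imzml(path: str | os.PathLike, pixel_pitch: float = 100.0) -> MSIDataset:
    """Read an imzML/ibd pair into an :class:`MSIDataset` (row-major order)."""
    from pyimzml.ImzMLParser import ImzMLParser

    path = str(path)
    ibd = os.path.splitext(path)[0] + ".ibd"
    if not os.path.exists(path):
        raise MSIDataError(f"imzML file not found: {path}")
    if not os.path.exists(ibd):
        raise MSIDataError(f"ibd binary file not found next to imzML: {ibd}")
    parser = ImzMLParser(path)
    try:
        coords = []
        mzs: list[np.ndarray] = []
        intens: list[np.ndarray] = []
        for i, (x, y, _z) in enumerate(parser.coordinates):
            mz, inten = parser.getspectrum(i)
            coords.append((int(x) - 1, int(y) - 1))
            mzs.append(np.asarray(mz, float))
            intens.append(np.asarray(inten, float))
    finally:
        parser.m.close()
    if not coords:
        raise MSIDataError("no pixels in imzML file")
    shared = all(len(a) == len(mzs[0]) and np.array_equal(a, mzs[0]) for a in mzs[1:])
    if shared:
        mzs = [mzs[0]] * len(mzs)
    ds = MSIDataset(np.array(coords), mzs, intens, shared, pixel_pitch)
    return ds.sort_row_major()


# -- metabolite database -----------------------------------------------


@dataclass(frozen=True)
class MetaboliteRecord:
    """One neutral metabolite: name, formula, optional tissue occurrences."""

    name: str
    neutral_formula: ElementalComposition
    reported_in_tissue: frozenset[str] = frozenset()


def read_metabolite_db(path) -> tuple[list[MetaboliteRecord], list[tuple[str, str]]]:
    """Read a delimited metabolite table (HMDB-like records).

    Requires columns ``name`` and ``formula``; an optional ``tissue``
    column holds a comma-separated list of tissue labels. Returns
    ``(records, rejects)`` where rejects is a list of
    ``(name, reason)`` for rows whose formula failed to parse —
    malformed rows are reported, never silently dropped.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in ("name", "formula") if c not in df.columns]
    if missing:
        raise MSIDataError(f"metabolite table missing required columns: {missing}")
    if len(df) == 0:
        warnings.warn(f"metabolite table {path} has a header but no rows")
        return [], []
    records: list[MetaboliteRecord] = []
    rejects: list[tuple[str, str]] = []
    for _, row in df.iterrows():
        name = str(row["name"]).strip()
        try:
            comp = parse_formula(str(row["formula"]))
        except FormulaError as e:
            rejects.append((name, str(e)))
            continue
        tissues: frozenset[str] = frozenset()
        if "tissue" in df.columns and pd.notna(row.get("tissue")):
            tissues = frozenset(
                t.strip().lower() for t in str(row["tissue"]).split(",") if t.strip()
            )
        records.append(MetaboliteRecord(name, comp, tissues))
    return records, rejects


# -- tabular outputs ---------------------------------------------------


def write_peak_matrix(matrix, path) -> None:
    """Write a PeakMatrix as TSV: pixel x/y columns then one column per bin m/z."""
    df = matrix.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_peak_matrix(path) -> pd.DataFrame:
    """Read a peak-matrix TSV back as a DataFrame (x, y, then bin columns)."""
    return pd.read_csv(path, sep="\t")


def write_annotations(hits: Iterable, path) -> None:
    """Write annotation hits as TSV mirroring the putative-ID table schema.

    Columns: name, ion_formula, adduct, mz_experimental, mz_theoretical,
    ppm_error, tissue_reported.
    """
    from .annotate import hits_to_frame

    hits_to_frame(list(hits)).to_csv(path, sep="\t", index=False, float_format="%.6f")
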