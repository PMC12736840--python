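"""Labelled regions of interest and per-class reflectance spectra.

ROIs are axis-aligned, half-open pixel rectangles tagged ``peel`` or
``flesh``.  Each ROI contributes one row to the spectra matrix: the mean
reflectance over its pixels at every band (the per-pixel alternative is
available via ``per_pixel=True``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cube_io import HyperspectralCube
from .exceptions import CalibrationError, DegenerateDataError, RoiError

__all__ = [
    "ROI",
    "SpectraMatrix",
    "VALID_LABELS",
    "parse_roi_table",
    "extract_spectra",
    "class_mean_spectrum",
    "spectra_to_csv",
]

VALID_LABELS = ("peel", "flesh")


@dataclass(frozen=True)
class ROI:
    """Half-open rectangle ``[row0, row1) x [col0, col1)`` with a tissue label."""

    label: str
    row0: int
    col0: int
    row1: int
    col1: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise RoiError(f"unknown ROI label {self.label!r}; expected one of {VALID_LABELS}")
        if self.row0 >= self.row1 or self.col0 >= self.col1:
            raise RoiError(
                f"empty ROI rect ({self.row0},{self.col0},{self.row1},{self.col1}) "
                f"for sample {self.sample_id!r}"
            )
        if self.row0 < 0 or self.col0 < 0:
            raise RoiError(f"negative ROI coordinates for sample {self.sample_id!r}")

    @property
    def n_pixels(self) -> int:
        return (self.row1 - self.row0) * (self.col1 - self.col0)


@dataclass
class SpectraMatrix:
    """Sample-by-band reflectance table with class labels.

    ``values[i, b]`` is the reflectance of sample ``i`` at band ``b``;
    ``labels[i]`` its tissue class; ``ids[i]`` the originating sample key.
    """

    values: np.ndarray
    labels: np.ndarray
    wavelengths_nm: np.ndarray
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.values.ndim != 2:
            raise RoiError("spectra values must be 2-D (samples x bands)")
        if self.values.shape[1] != self.wavelengths_nm.size:
            raise RoiError(
                f"n_bands {self.values.shape[1]} != wavelength axis "
                f"length {self.wavelengths_nm.size}"
            )
        if self.labels.shape != (self.values.shape[0],):
            raise RoiError("one label per spectra row required")
        if not np.all(np.isfinite(self.values)):
            raise RoiError("spectra contain non-finite values")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise RoiError("spectra must be reflectance in [0, 1]")
        if self.ids is not None:
            self.ids = np.asarray(self.ids)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]


def parse_roi_table(path: str | Path) -> list[ROI]:
    """Read an ROI CSV with columns sample_id, label, row0, col0, row1, col1."""
    path = Path(path)
    try:
        table = pd.read_csv(path, dtype={"sample_id": str})
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise RoiError(f"cannot read ROI table {path}: {exc}") from exc
    required = ["sample_id", "label", "row0", "col0", "row1", "col1"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise RoiError(f"{path}: ROI table missing columns {missing}")
    rois = []
    for rec in table.itertuples(index=False):
        rois.append(
            ROI(
                label=str(rec.label).strip(),
                row0=int(rec.row0),
                col0=int(rec.col0),
                row1=int(rec.row1),
                col1=int(rec.col1),
                sample_id=str(rec.sample_id),
            )
        )
    return rois


def _check_bounds(roi: ROI, cube: HyperspectralCube) -> None:
    if roi.row1 > cube.height or roi.col1 > cube.width:
        raise RoiError(
            f"ROI {roi.label}@({roi.row0},{roi.col0},{roi.row1},{roi.col1}) "
            f"of sample {roi.sample_id!r} exceeds cube extent "
            f"{cube.height}x{cube.width}"
        )


def extract_spectra(
    cube: HyperspectralCube,
    rois: Sequence[ROI],
    *,
    per_pixel: bool = False,
) -> SpectraMatrix:
    """Extract labelled reflectance spectra from ROIs on a calibrated cube.

    By default each ROI yields one row, the per-band mean over its pixels.
    With ``per_pixel=True`` every ROI pixel yields its own row (same label).
    """
    if not cube.is_calibrated:
        raise CalibrationError("spectra extraction requires a calibrated cube")
    if not rois:
        raise RoiError("no ROIs supplied")
    rows: list[np.ndarray] = []
    labels: list[str] = []
    ids: list[str] = []
    for roi in rois:
        _check_bounds(roi, cube)
        block = cube.data[roi.row0 : roi.row1, roi.col0 : roi.col1, :]
        if per_pixel:
            flat = block.reshape(-1, cube.n_bands)
            rows.extend(flat)
            labels.extend([roi.label] * flat.shape[0])
            ids.extend([roi.sample_id] * flat.shape[0])
        else:
            rows.append(block.mean(axis=(0, 1)))
            labels.append(roi.label)
            ids.append(roi.sample_id)
    return SpectraMatrix(
        values=np.array(rows),
        labels=np.array(labels),
        wavelengths_nm=cube.wavelengths_nm.copy(),
        ids=np.array(ids),
    )


def class_mean_spectrum(matrix: SpectraMatrix, label: str) -> np.ndarray:
    """Per-band arithmetic mean over all rows carrying ``label``."""
    mask = matrix.labels == label
    if not mask.any():
        raise DegenerateDataError(f"no spectra with label {label!r}")
    return matrix.values[mask].mean(axis=0)


def spectra_to_csv(matrix: SpectraMatrix, path: str | Path) -> None:
    """Write a wavelength_nm column plus one column per spectrum.

    Column headers carry ``<sample_id>/<label>/<index>`` so class and origin
    survive the round trip.
    """
    ids: Iterable[str] = (
        matrix.ids if matrix.ids is not None else [""] * matrix.n_samples
    )
    cols = {
        f"{sid}/{lab}/{i}": matrix.values[i]
        for i, (sid, lab) in enumerate(zip(ids, matrix.labels))
    }
    frame = pd.DataFrame({"wavelength_nm": matrix.wavelengths_nm, **cols})
    frame.to_csv(path, index=False, float_format="%.8g")
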