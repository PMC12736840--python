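"""Hyperspectral cube container, ENVI I/O, and black/white reflectance calibration.

A cube is a 3-D array indexed ``(row, col, band)`` with an ascending
wavelength axis in nanometres.  Raw sensor counts are converted to
normalized reflectance with a whiteboard/blackboard reference pair:

    R = (R0 - B) / (W - B)

where ``R0`` is the recorded scene, ``W`` the whiteboard capture and ``B``
the blackboard (dark current) capture.  Results are clipped to [0, 1];
sensor sites where ``W - B <= 0`` are undefined, set to 0 and tallied.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .exceptions import (
    CalibrationError,
    CubeIntegrityError,
    EnviFormatError,
    GeometryMismatchError,
    ParameterError,
)

__all__ = [
    "HyperspectralCube",
    "ReferencePair",
    "read_envi_cube",
    "write_envi_cube",
    "calibrate_reflectance",
    "wavelength_to_band",
]

# ENVI numeric data-type codes <-> numpy dtypes (little-endian on disk).
_ENVI_DTYPES: dict[int, str] = {
    1: "u1",
    2: "<i2",
    3: "<i4",
    4: "<f4",
    5: "<f8",
    12: "<u2",
    13: "<u4",
    14: "<i8",
    15: "<u8",
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}

_INTERLEAVES = ("bsq", "bil", "bip")


@dataclass
class HyperspectralCube:
    """Reflectance or raw-count cube with its wavelength axis.

    Parameters
    ----------
    data:
        3-D array laid out ``(row, col, band)``.
    wavelengths_nm:
        Strictly increasing band-centre wavelengths, one per band.
    is_calibrated:
        ``True`` once the cube holds normalized reflectance in [0, 1],
        ``False`` for raw sensor counts.
    meta:
        Free-form provenance (e.g. invalid-pixel tally after calibration).
    """

    data: np.ndarray
    wavelengths_nm: np.ndarray
    is_calibrated: bool = False
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.data.ndim != 3:
            raise ParameterError(
                f"cube data must be 3-D (row, col, band); got {self.data.ndim}-D"
            )
        h, w, b = self.data.shape
        if h < 1 or w < 1 or b < 1:
            raise ParameterError(f"cube dimensions must be positive; got {self.data.shape}")
        if self.wavelengths_nm.ndim != 1 or len(self.wavelengths_nm) != b:
            raise ParameterError(
                f"wavelength axis length {self.wavelengths_nm.size} != n_bands {b}"
            )
        if b > 1 and not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ParameterError("wavelengths_nm must be strictly increasing")
        if self.is_calibrated:
            finite = self.data[np.isfinite(self.data)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ParameterError(
                    "calibrated cube must lie in [0, 1]; "
                    f"found range [{finite.min():g}, {finite.max():g}]"
                )

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HyperspectralCube):
            return NotImplemented
        return (
            self.data.shape == other.data.shape
            and np.array_equal(self.data, other.data)
            and np.array_equal(self.wavelengths_nm, other.wavelengths_nm)
            and self.is_calibrated == other.is_calibrated
        )


@dataclass
class ReferencePair:
    """Whiteboard and blackboard reference captures for calibration.

    Both cubes must share geometry and wavelength axis with each other.
    Height-1 references (line-scan whiteboards) broadcast along scene rows
    at calibration time.  Sites where white < dark are physically
    implausible and produce a warning; they are zeroed and tallied during
    calibration.
    """

    white: HyperspectralCube
    dark: HyperspectralCube

    def __post_init__(self) -> None:
        if self.white.data.shape != self.dark.data.shape:
            raise GeometryMismatchError(
                f"white {self.white.data.shape} and dark {self.dark.data.shape} "
                "references must share geometry"
            )
        if not np.allclose(self.white.wavelengths_nm, self.dark.wavelengths_nm):
            raise GeometryMismatchError("white and dark wavelength axes differ")
        n_bad = int(np.sum(self.white.data < self.dark.data))
        if n_bad:
            warnings.warn(
                f"{n_bad} reference positions have white < dark (dead/saturated "
                "sensor sites); they will calibrate to 0",
                stacklevel=2,
            )


# ---------------------------------------------------------------------------
# ENVI header parsing / writing
# ---------------------------------------------------------------------------

def _parse_envi_header(text: str, path: Path) -> dict[str, str]:
    if not text.lstrip().lower().startswith("envi"):
        raise EnviFormatError(f"{path}: missing 'ENVI' magic on first line")
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    # key = value, where value may be a {...} block spanning lines
    pattern = re.compile(r"^\s*([\w ]+?)\s*=\s*(\{.*?\}|[^\n]*)\s*$", re.M | re.S)
    pos = 0
    while pos < len(body):
        m = pattern.search(body, pos)
        if m is None:
            break
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        if val.startswith("{") and not val.endswith("}"):
            end = body.find("}", m.start(2))
            if end < 0:
                raise EnviFormatError(f"{path}: unterminated '{{' in field '{key}'")
            val = body[m.start(2) : end + 1]
            pos = end + 1
        else:
            pos = m.end()
        fields[key] = val
    return fields


def _require_int(fields: dict[str, str], key: str, path: Path) -> int:
    if key not in fields:
        raise EnviFormatError(f"{path}: header missing required field '{key}'")
    try:
        return int(fields[key])
    except ValueError as exc:
        raise EnviFormatError(f"{path}: field '{key}' is not an integer: {fields[key]!r}") from exc


def _find_binary(header_path: Path) -> Path:
    stem = header_path.with_suffix("")
    for cand in (stem.with_suffix(".img"), stem, stem.with_suffix(".dat"),
                 stem.with_suffix(".raw"), stem.with_suffix(".bsq")):
        if cand.exists() and cand != header_path:
            return cand
    raise EnviFormatError(f"no binary companion found for header {header_path}")


def read_envi_cube(header_path: str | Path) -> HyperspectralCube:
    """Read an ENVI header + binary cube into ``(row, col, band)`` layout.

    Supports BSQ, BIL and BIP interleaves and the numeric data types in the
    ENVI standard (little-endian).  The returned cube is marked calibrated
    only if the header carries the non-standard ``calibrated = 1`` key this
    package writes.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise EnviFormatError(f"header file not found: {header_path}")
    fields = _parse_envi_header(header_path.read_text(), header_path)

    samples = _require_int(fields, "samples", header_path)
    lines = _require_int(fields, "lines", header_path)
    bands = _require_int(fields, "bands", header_path)
    dtype_code = _require_int(fields, "data type", header_path)
    offset = int(fields.get("header offset", "0"))
    if dtype_code not in _ENVI_DTYPES:
        raise EnviFormatError(f"{header_path}: unsupported data type code {dtype_code}")
    interleave = fields.get("interleave", "bsq").strip().lower()
    if interleave not in _INTERLEAVES:
        raise EnviFormatError(f"{header_path}: unknown interleave {interleave!r}")
    if fields.get("byte order", "0").strip() not in ("0", ""):
        raise EnviFormatError(f"{header_path}: only little-endian (byte order = 0) supported")

    if "wavelength" not in fields:
        raise EnviFormatError(f"{header_path}: header missing required field 'wavelength'")
    wl_text = fields["wavelength"].strip().lstrip("{").rstrip("}")
    try:
        wavelengths = np.array(
            [float(tok) for tok in wl_text.replace("\n", " ").split(",") if tok.strip()]
        )
    except ValueError as exc:
        raise EnviFormatError(f"{header_path}: unparseable wavelength list") from exc
    units = fields.get("wavelength units", "nanometers").strip().lower()
    if units.startswith("microm") or units == "um":
        wavelengths = wavelengths * 1000.0
    elif units and not units.startswith("nanom") and units != "unknown":
        raise EnviFormatError(f"{header_path}: unsupported wavelength units {units!r}")
    if wavelengths.size != bands:
        raise EnviFormatError(
            f"{header_path}: header declares {bands} bands but lists "
            f"{wavelengths.size} wavelengths"
        )

    binary = _find_binary(header_path)
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    expected = samples * lines * bands * dtype.itemsize
    payload = binary.stat().st_size - offset
    if payload != expected:
        raise CubeIntegrityError(
            f"{binary}: payload is {payload} bytes, but header geometry "
            f"{lines}x{samples}x{bands} ({dtype}) requires {expected}"
        )
    flat = np.fromfile(binary, dtype=dtype, offset=offset)
    if interleave == "bsq":
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        data = flat.reshape(lines, samples, bands)

    calibrated = fields.get("calibrated", "0").strip() == "1"
    return HyperspectralCube(
        data=np.ascontiguousarray(data),
        wavelengths_nm=wavelengths,
        is_calibrated=calibrated,
        meta={"source": str(header_path)},
    )


def write_envi_cube(cube: HyperspectralCube, header_path: str | Path) -> Path:
    """Write ``cube`` as an ENVI header plus little-endian BSQ binary.

    The binary goes to ``<stem>.img`` next to the header.  Returns the
    binary path.  Data type is preserved when it maps onto an ENVI code.
    """
    header_path = Path(header_path)
    dtype = np.dtype(cube.data.dtype).newbyteorder("<")
    if dtype not in _DTYPE_CODES:
        raise ParameterError(f"dtype {cube.data.dtype} has no ENVI data type code")
    binary_path = header_path.with_suffix(".img")

    wl = ", ".join(f"{w:.6g}" for w in cube.wavelengths_nm)
    lines = [
        "ENVI",
        "description = {peelscan hyperspectral cube}",
        f"samples = {cube.width}",
        f"lines = {cube.height}",
        f"bands = {cube.n_bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_CODES[dtype]}",
        "interleave = bsq",
        "byte order = 0",
        f"calibrated = {1 if cube.is_calibrated else 0}",
        "wavelength units = Nanometers",
        f"wavelength = {{{wl}}}",
        "",
    ]
    header_path.write_text("\n".join(lines))
    cube.data.transpose(2, 0, 1).astype(dtype, copy=False).tofile(binary_path)
    return binary_path


# ---------------------------------------------------------------------------
# Calibration and wavelength lookup
# ---------------------------------------------------------------------------

def _check_reference_geometry(raw: HyperspectralCube, ref: HyperspectralCube, name: str) -> None:
    if ref.n_bands != raw.n_bands or not np.allclose(ref.wavelengths_nm, raw.wavelengths_nm):
        raise GeometryMismatchError(f"{name} reference wavelength axis differs from scene")
    if ref.width != raw.width or ref.height not in (1, raw.height):
        raise GeometryMismatchError(
            f"{name} reference geometry {ref.data.shape[:2]} incompatible with "
            f"scene {raw.data.shape[:2]} (height must match or be 1)"
        )


def calibrate_reflectance(raw: HyperspectralCube, refs: ReferencePair) -> HyperspectralCube:
    """Black/white correction: ``R = (R0 - B) / (W - B)``, clipped to [0, 1].

    Height-1 references broadcast along scene rows.  Positions where
    ``W - B <= 0`` are undefined, set to 0 and counted in the returned
    cube's ``meta['n_invalid']``.
    """
    if raw.is_calibrated:
        raise CalibrationError("cube is already calibrated")
    _check_reference_geometry(raw, refs.white, "white")
    _check_reference_geometry(raw, refs.dark, "dark")

    white = refs.white.data.astype(np.float64)
    dark = refs.dark.data.astype(np.float64)
    denom = white - dark
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (raw.data.astype(np.float64) - dark) / denom
    invalid = np.broadcast_to(denom <= 0, raw.data.shape)
    r = np.where(invalid, 0.0, np.broadcast_to(r, raw.data.shape))
    r = np.clip(r, 0.0, 1.0)
    return HyperspectralCube(
        data=r,
        wavelengths_nm=raw.wavelengths_nm.copy(),
        is_calibrated=True,
        meta={**raw.meta, "n_invalid": int(invalid.sum())},
    )


def wavelength_to_band(cube: HyperspectralCube, lambda_nm: float) -> int:
    """Index of the band whose centre is nearest ``lambda_nm``.

    Exact midpoints resolve to the lower index.  Queries more than half a
    local band spacing beyond either end of the axis are out of range.
    """
    wl = cube.wavelengths_nm
    if wl.size == 1:
        lo_margin = hi_margin = 0.0
    else:
        lo_margin = (wl[1] - wl[0]) / 2.0
        hi_margin = (wl[-1] - wl[-2]) / 2.0
    if lambda_nm < wl[0] - lo_margin or lambda_nm > wl[-1] + hi_margin:
        raise ParameterError(
            f"wavelength {lambda_nm} nm outside axis range "
            f"[{wl[0] - lo_margin:g}, {wl[-1] + hi_margin:g}] nm"
        )
    # argmin returns the first minimum, i.e. the lower index on exact ties
    return int(np.argmin(np.abs(wl - lambda_nm)))
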