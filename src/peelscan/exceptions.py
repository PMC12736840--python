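"""Exception hierarchy.

All package errors derive from :class:`PeelscanError` so callers can catch
one base class; most also derive from ``ValueError`` because they signal
invalid inputs rather than environmental failures.
"""


class PeelscanError(Exception):
    """Base class for all peelscan errors."""


class EnviFormatError(PeelscanError, ValueError):
    """ENVI header is missing, malformed, or self-contradictory."""


class CubeIntegrityError(PeelscanError, ValueError):
    """Binary payload does not match the geometry the header declares."""


class GeometryMismatchError(PeelscanError, ValueError):
    """Two cubes that must share geometry/wavelength axis do not."""


class CalibrationError(PeelscanError, ValueError):
    """Calibration requested on data in the wrong state."""


class RoiError(PeelscanError, ValueError):
    """ROI table is malformed or an ROI falls outside the cube."""


class ParameterError(PeelscanError, ValueError):
    """A numeric parameter is outside its valid range."""


class DegenerateDataError(PeelscanError, ValueError):
    """Input carries no usable signal (zero variance, zero potato pixels)."""
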