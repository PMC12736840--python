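"""PCA of class spectra, weight-coefficient curve, and key-band selection.

The two tissue classes (peel, flesh) differ most strongly in a narrow
wavelength window; covariance PCA of labelled ROI spectra finds it.  The
first principal component captures the between-class contrast, its
per-band weight coefficients (loadings) peak where the classes separate
best, and a window of ``center +/- half_width`` (default 20 nm, i.e. the
592 +/- 20 nm key band on potato data) around that peak is used to render
the grayscale image that segmentation operates on.

Centering only, no per-band standardization: all bands share reflectance
units.  Contribution rates are percentages of total variance over the full
eigen-spectrum, not just the retained components.  Eigenvector sign is
fixed so each component's largest-magnitude coefficient is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from sklearn.decomposition import PCA as _SKPCA

from .cube_io import HyperspectralCube
from .exceptions import CalibrationError, DegenerateDataError, ParameterError
from .roi_spectra import SpectraMatrix

__all__ = [
    "PCAResult",
    "BandWindow",
    "WeightCurve",
    "fit_pca",
    "pc1_weight_curve",
    "select_key_window",
    "resolve_band_window",
    "band_window_grayscale",
]


@dataclass
class PCAResult:
    """Retained principal components of a spectra matrix.

    ``loadings`` rows are orthonormal eigenvectors of the band covariance
    matrix (sign-fixed), ``contribution_rates`` their share of *total*
    variance in percent (descending), ``scores`` the centred projections,
    and ``band_mean`` the centering vector.
    """

    loadings: np.ndarray
    contribution_rates: np.ndarray
    scores: np.ndarray
    band_mean: np.ndarray

    def __post_init__(self) -> None:
        gram = self.loadings @ self.loadings.T
        if not np.allclose(gram, np.eye(self.loadings.shape[0]), atol=1e-8):
            raise ParameterError("loadings rows must be orthonormal")
        rates = self.contribution_rates
        if np.any(np.diff(rates) > 1e-9) or rates.sum() > 100 + 1e-6:
            raise ParameterError("contribution rates must be non-increasing, sum <= 100")


class WeightCurve(NamedTuple):
    """Per-band PC1 weight coefficients paired with the wavelength axis."""

    wavelengths_nm: np.ndarray
    weights: np.ndarray


@dataclass
class BandWindow:
    """Contiguous band window ``center_nm +/- half_width_nm`` on a cube axis."""

    center_nm: float
    half_width_nm: float
    band_indices: np.ndarray
    mean_weight: float | None = field(default=None)

    def __post_init__(self) -> None:
        idx = np.asarray(self.band_indices, dtype=int)
        if idx.size == 0:
            raise ParameterError(
                f"no bands fall within {self.center_nm} +/- {self.half_width_nm} nm"
            )
        if idx.size > 1 and not np.all(np.diff(idx) == 1):
            raise ParameterError("band window indices must be contiguous")
        self.band_indices = idx


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    """Flip each component so its largest-magnitude coefficient is positive."""
    for i, row in enumerate(loadings):
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            loadings[i] = -row
            scores[:, i] = -scores[:, i]


def fit_pca(matrix: SpectraMatrix, k: int) -> PCAResult:
    """Covariance PCA of the spectra matrix, retaining ``k`` components.

    Requires ``2 <= n_samples`` and ``k <= min(n_samples - 1, n_bands)``.
    """
    x = matrix.values
    n, b = x.shape
    if n < 2:
        raise ParameterError(f"PCA needs at least 2 samples; got {n}")
    if not 1 <= k <= min(n - 1, b):
        raise ParameterError(
            f"k={k} outside valid range [1, {min(n - 1, b)}] for a {n}x{b} matrix"
        )
    if np.allclose(x, x.mean(axis=0), atol=1e-15):
        raise DegenerateDataError("spectra matrix has zero variance")

    model = _SKPCA(n_components=min(n, b), svd_solver="full")
    scores_full = model.fit_transform(x)
    rates_full = model.explained_variance_ratio_ * 100.0

    loadings = model.components_[:k].copy()
    scores = scores_full[:, :k].copy()
    _fix_signs(loadings, scores)
    return PCAResult(
        loadings=loadings,
        contribution_rates=rates_full[:k].copy(),
        scores=scores,
        band_mean=model.mean_.copy(),
    )


def pc1_weight_curve(pca: PCAResult, wavelengths_nm: np.ndarray) -> WeightCurve:
    """First-component weight coefficients over wavelength, peak-positive.

    The sign is fixed so the maximum-magnitude coefficient is positive
    (idempotent after :func:`fit_pca`'s own convention).
    """
    if pca.loadings.shape[0] < 1:
        raise ParameterError("PCA result has no components")
    wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
    if wavelengths_nm.size != pca.loadings.shape[1]:
        raise ParameterError("wavelength axis length != number of bands in loadings")
    weights = pca.loadings[0].copy()
    if weights[int(np.argmax(np.abs(weights)))] < 0:
        weights = -weights
    return WeightCurve(wavelengths_nm=wavelengths_nm, weights=weights)


def select_key_window(curve: WeightCurve, half_width_nm: float = 20.0) -> BandWindow:
    """Window centred on the weight-curve maximum (ties -> lowest wavelength).

    The window is clipped to the spectral range; ``mean_weight`` reports the
    average weight coefficient inside it.
    """
    if curve.weights.size == 0:
        raise ParameterError("empty weight curve")
    peak = int(np.argmax(curve.weights))  # first max = lowest wavelength on ties
    center = float(curve.wavelengths_nm[peak])
    window = resolve_band_window(curve.wavelengths_nm, center, half_width_nm)
    window.mean_weight = float(curve.weights[window.band_indices].mean())
    return window


def resolve_band_window(
    wavelengths_nm: np.ndarray, center_nm: float, half_width_nm: float = 20.0
) -> BandWindow:
    """All band indices whose centres lie within ``center_nm +/- half_width_nm``."""
    if half_width_nm < 0:
        raise ParameterError("half_width_nm must be non-negative")
    wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
    inside = np.abs(wavelengths_nm - center_nm) <= half_width_nm + 1e-9
    idx = np.flatnonzero(inside)
    if idx.size == 0:
        raise ParameterError(
            f"window {center_nm} +/- {half_width_nm} nm contains no band centres "
            f"of axis [{wavelengths_nm[0]:g}, {wavelengths_nm[-1]:g}] nm"
        )
    return BandWindow(center_nm=center_nm, half_width_nm=half_width_nm, band_indices=idx)


def band_window_grayscale(
    cube: HyperspectralCube,
    window: BandWindow,
    *,
    mode: str = "window-mean",
) -> np.ndarray:
    """8-bit grayscale of a calibrated cube over a band window.

    ``window-mean`` (default) averages reflectance over all window bands;
    ``center-band`` uses only the band nearest the window centre.  The
    [0, 1] reflectance maps linearly to [0, 255] with round-half-up.
    """
    if not cube.is_calibrated:
        raise CalibrationError("grayscale rendering requires a calibrated cube")
    idx = window.band_indices
    if idx.min() < 0 or idx.max() >= cube.n_bands:
        raise ParameterError(
            f"window bands {idx.min()}..{idx.max()} outside cube with {cube.n_bands} bands"
        )
    if mode == "window-mean":
        mean = cube.data[:, :, idx].mean(axis=2)
    elif mode == "center-band":
        nearest = idx[int(np.argmin(np.abs(cube.wavelengths_nm[idx] - window.center_nm)))]
        mean = cube.data[:, :, nearest].astype(float)
    else:
        raise ParameterError(f"unknown grayscale mode {mode!r}")
    gray = np.floor(mean * 255.0 + 0.5)  # round half up
    return np.clip(gray, 0, 255).astype(np.uint8)
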