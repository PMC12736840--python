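"""Median denoising and dual-threshold three-class segmentation.

The 8-bit grayscale of the key band is denoised with a 5x5 median filter
(each pixel replaced by the median of its 5x5 neighbourhood, reflect
padding at borders), then partitioned with two cut points:

    background : I < T_low
    peel       : T_low <= I < T_high
    flesh      : I >= T_high

Defaults T_low = 35, T_high = 125.  Pixel counts N_peel, N_flesh and
Q = N_peel + N_flesh feed the peeling-rate calculation.  No morphological
cleanup is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import ParameterError

__all__ = [
    "Thresholds",
    "MaskPair",
    "SegmentationCounts",
    "median_filter_5x5",
    "dual_threshold_masks",
    "count_regions",
    "label_image",
]


@dataclass(frozen=True)
class Thresholds:
    """Dual cut points on 8-bit gray values: ``0 <= t_low < t_high <= 255``."""

    t_low: int = 35
    t_high: int = 125

    def __post_init__(self) -> None:
        if not (0 <= self.t_low < self.t_high <= 255):
            raise ParameterError(
                f"need 0 <= t_low < t_high <= 255; got ({self.t_low}, {self.t_high})"
            )


@dataclass
class MaskPair:
    """Disjoint binary masks for the peel and flesh classes."""

    peel_mask: np.ndarray
    flesh_mask: np.ndarray

    def __post_init__(self) -> None:
        self.peel_mask = np.asarray(self.peel_mask, dtype=bool)
        self.flesh_mask = np.asarray(self.flesh_mask, dtype=bool)
        if self.peel_mask.shape != self.flesh_mask.shape:
            raise ParameterError("peel and flesh masks must share shape")
        if np.any(self.peel_mask & self.flesh_mask):
            raise ParameterError("peel and flesh masks overlap")


@dataclass(frozen=True)
class SegmentationCounts:
    """Pixel tallies: ``q`` is always ``n_peel + n_flesh``."""

    n_peel: int
    n_flesh: int

    @property
    def q(self) -> int:
        return self.n_peel + self.n_flesh


def _as_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 2 or img.size == 0:
        raise ParameterError("grayscale image must be non-empty and 2-D")
    if img.dtype != np.uint8:
        if np.any((img < 0) | (img > 255)):
            raise ParameterError("gray values must lie in [0, 255]")
        img = img.astype(np.uint8)
    return img


def median_filter_5x5(image: np.ndarray) -> np.ndarray:
    """5x5 median filter with reflect padding; output values come from the input set."""
    return ndimage.median_filter(_as_gray(image), size=5, mode="reflect")


def dual_threshold_masks(image: np.ndarray, thr: Thresholds = Thresholds()) -> MaskPair:
    """Peel mask ``t_low <= I < t_high`` and flesh mask ``I >= t_high``."""
    img = _as_gray(image)
    peel = (img >= thr.t_low) & (img < thr.t_high)
    flesh = img >= thr.t_high
    return MaskPair(peel_mask=peel, flesh_mask=flesh)


def count_regions(masks: MaskPair) -> SegmentationCounts:
    """Sum the masks into N_peel, N_flesh (Q follows as their sum)."""
    return SegmentationCounts(
        n_peel=int(masks.peel_mask.sum()),
        n_flesh=int(masks.flesh_mask.sum()),
    )


def label_image(masks: MaskPair) -> np.ndarray:
    """Three-class label image: 0 = background, 1 = peel, 2 = flesh."""
    out = np.zeros(masks.peel_mask.shape, dtype=np.uint8)
    out[masks.peel_mask] = 1
    out[masks.flesh_mask] = 2
    return out
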