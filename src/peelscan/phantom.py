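"""Seed-controlled phantom hyperspectral scenes of peeled potato tubers.

A phantom scene is an elliptical tuber on a dark background, with residual
peel drawn as blob-shaped patches (a level set of a union-of-disks distance
field, adjusted so the peel pixel count hits the requested area fraction
exactly).  Per-class reflectance follows smooth spectral profiles shaped
like real potato tissue: both classes rise from 485 nm with flesh rising
faster on 485-523 nm, flesh exceeds peel everywhere with the separation
maximal at 592 nm, and both decline past 823 nm.  Raw sensor counts are
synthesised by inverting the black/white correction,

    raw = dark + R * (white - dark),

so calibration recovers the class profiles exactly when noise is off.
Gaussian noise (reflectance units) and salt-and-pepper impulses (dead or
saturated sensor sites affecting a whole pixel spectrum, in raw-count
space) emulate the disturbances the median filter exists to remove.
Ground-truth labels are recorded before noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.interpolate import PchipInterpolator

from .cube_io import HyperspectralCube, ReferencePair
from .exceptions import ParameterError, RoiError
from .roi_spectra import ROI

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "profile_library",
    "generate_phantom",
    "generate_sample_pair",
    "auto_rois",
    "manual_rates_from_truth",
]

#: full-scale scene geometry of the imaging system being emulated
FULL_SCALE = (696, 700, 256)
#: spectral range of the emulated imager, nm
WAVELENGTH_RANGE_NM = (386.7, 1016.7)
#: wavelength of maximal flesh-peel separation, nm
KEY_WAVELENGTH_NM = 592.0

# Peel reflectance knots: flat blue end, rise from 485 nm, plateau, decline
# past 823 nm.  Flesh adds a constant offset plus a Gaussian separation bump
# centred at the key wavelength.
_PEEL_KNOTS_NM = np.array([386.7, 450.0, 485.0, 523.0, 592.0, 700.0, 823.0, 920.0, 1016.7])
_PEEL_KNOTS_R = np.array([0.16, 0.17, 0.18, 0.21, 0.285, 0.36, 0.40, 0.37, 0.33])
_SEP_BASE = 0.06
_SEP_AMPLITUDE = 0.27
_SEP_SIGMA_NM = 80.0
_BACKGROUND_R = 0.02


def profile_library() -> dict[str, Callable[[np.ndarray], np.ndarray]]:
    """Named reflectance profiles: ``peel``, ``flesh``, ``background``.

    Each maps wavelength (nm, scalar or array) to reflectance in [0, 1].
    """
    peel_interp = PchipInterpolator(_PEEL_KNOTS_NM, _PEEL_KNOTS_R)

    def peel(lam: np.ndarray) -> np.ndarray:
        return np.asarray(peel_interp(lam), dtype=float)

    def separation(lam: np.ndarray) -> np.ndarray:
        lam = np.asarray(lam, dtype=float)
        return _SEP_BASE + _SEP_AMPLITUDE * np.exp(
            -(((lam - KEY_WAVELENGTH_NM) / _SEP_SIGMA_NM) ** 2)
        )

    def flesh(lam: np.ndarray) -> np.ndarray:
        return np.clip(peel(lam) + separation(lam), 0.0, 1.0)

    def background(lam: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(lam, dtype=float), _BACKGROUND_R)

    return {"peel": peel, "flesh": flesh, "background": background}


@dataclass
class PhantomSpec:
    """Parameters of one phantom scene.

    Defaults are a quarter-scale analogue of the emulated imager
    (174 x 175 pixels, 64 bands over 386.7-1016.7 nm) with the noise
    levels used throughout the noisy test conditions: Gaussian SD 0.01 in
    reflectance units and 2 % salt-and-pepper pixel density.  Pass zeros
    for a noiseless scene, or ``full_scale=True`` for 696 x 700 x 256.
    """

    height: int = 174
    width: int = 175
    n_bands: int = 64
    wavelength_range_nm: tuple[float, float] = WAVELENGTH_RANGE_NM
    flesh_fraction: float = 0.75
    semi_axes_frac: tuple[float, float] = (0.32, 0.34)
    blob_radius_range: tuple[float, float] = (9.0, 15.0)
    n_blobs: int | None = None
    gaussian_sd: float = 0.01
    salt_pepper_density: float = 0.02
    flesh_shift: float = 0.0  # uniform post-peeling discoloration drift
    reference_rows: str = "full"  # "full" frame or "single" line-scan row
    seed: int = 0
    full_scale: bool = False

    def __post_init__(self) -> None:
        if self.full_scale:
            self.height, self.width, self.n_bands = FULL_SCALE
        if not 0.0 <= self.flesh_fraction <= 1.0:
            raise ParameterError("flesh_fraction must lie in [0, 1]")
        if self.gaussian_sd < 0 or not 0 <= self.salt_pepper_density < 1:
            raise ParameterError("invalid noise levels")
        if self.reference_rows not in ("full", "single"):
            raise ParameterError("reference_rows must be 'full' or 'single'")
        if min(self.height, self.width, self.n_bands) < 1:
            raise ParameterError("scene dimensions must be positive")


@dataclass
class PhantomTruth:
    """Ground-truth labels (0 background, 1 peel, 2 flesh) and class counts."""

    label_image: np.ndarray
    n_background: int = field(init=False)
    n_peel: int = field(init=False)
    n_flesh: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_background = int(np.sum(self.label_image == 0))
        self.n_peel = int(np.sum(self.label_image == 1))
        self.n_flesh = int(np.sum(self.label_image == 2))

    @property
    def true_flesh_fraction(self) -> float:
        total = self.n_peel + self.n_flesh
        if total == 0:
            raise ParameterError("phantom contains no tuber pixels")
        return self.n_flesh / total


def _white_counts(lam: np.ndarray) -> np.ndarray:
    """Halogen-lamp-like white reference counts per band."""
    return 3200.0 * (0.55 + 0.45 * np.exp(-(((lam - 760.0) / 300.0) ** 2)))


_DARK_COUNTS = 96.0


def _tuber_and_labels(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    rows = np.arange(spec.height)[:, None]
    cols = np.arange(spec.width)[None, :]
    cr, cc = (spec.height - 1) / 2.0, (spec.width - 1) / 2.0
    a = spec.semi_axes_frac[0] * spec.height
    b = spec.semi_axes_frac[1] * spec.width
    tuber = ((rows - cr) / a) ** 2 + ((cols - cc) / b) ** 2 <= 1.0
    n_tuber = int(tuber.sum())
    if n_tuber == 0:
        raise ParameterError("tuber ellipse contains no pixels")

    m_peel = int(round((1.0 - spec.flesh_fraction) * n_tuber))
    labels = np.where(tuber, 2, 0).astype(np.uint8)
    if m_peel == 0:
        return labels

    r_lo, r_hi = spec.blob_radius_range
    mean_area = np.pi * ((r_lo + r_hi) / 2.0) ** 2
    n_blobs = spec.n_blobs or max(2, min(20, int(round(m_peel / mean_area))))

    # blob centres uniform in a shrunken ellipse, radii uniform in range
    u = rng.random(n_blobs)
    theta = rng.uniform(0, 2 * np.pi, n_blobs)
    centres_r = cr + 0.8 * a * np.sqrt(u) * np.cos(theta)
    centres_c = cc + 0.8 * b * np.sqrt(u) * np.sin(theta)
    radii = rng.uniform(r_lo, r_hi, n_blobs)

    # signed distance to the union of disks; its level set with the count
    # m_peel gives blob-shaped peel with an exact area fraction
    phi = np.full((spec.height, spec.width), np.inf)
    for pr, pc, rad in zip(centres_r, centres_c, radii):
        d = np.hypot(rows - pr, cols - pc) - rad
        np.minimum(phi, d, out=phi)

    tuber_flat = np.flatnonzero(tuber.ravel())
    order = np.argsort(phi.ravel()[tuber_flat], kind="stable")
    peel_flat = tuber_flat[order[:m_peel]]
    labels.ravel()[peel_flat] = 1
    return labels


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[HyperspectralCube, ReferencePair, PhantomTruth]:
    """Render one phantom scene: raw-count cube, references, ground truth."""
    rng = np.random.default_rng(spec.seed)
    lam = np.linspace(*spec.wavelength_range_nm, spec.n_bands)
    profiles = profile_library()

    labels = _tuber_and_labels(spec, rng)
    truth = PhantomTruth(label_image=labels)

    class_spectra = np.stack(
        [
            profiles["background"](lam),
            profiles["peel"](lam),
            np.clip(profiles["flesh"](lam) + spec.flesh_shift, 0.0, 1.0),
        ]
    )
    reflectance = class_spectra[labels]  # (H, W, B)
    if spec.gaussian_sd > 0:
        reflectance = reflectance + rng.normal(0.0, spec.gaussian_sd, reflectance.shape)
        reflectance = np.clip(reflectance, 0.0, 1.0)

    white_band = _white_counts(lam)
    dark_band = np.full_like(white_band, _DARK_COUNTS)
    raw = dark_band + reflectance * (white_band - dark_band)

    if spec.salt_pepper_density > 0:
        n_pix = spec.height * spec.width
        n_hit = int(round(spec.salt_pepper_density * n_pix))
        hits = rng.choice(n_pix, size=n_hit, replace=False)
        n_salt = (n_hit + 1) // 2
        flat = raw.reshape(n_pix, spec.n_bands)
        flat[hits[:n_salt]] = white_band  # saturated sites -> reflectance 1
        flat[hits[n_salt:]] = dark_band  # dead sites -> reflectance 0

    ref_shape = (spec.height if spec.reference_rows == "full" else 1, spec.width, spec.n_bands)
    white_cube = HyperspectralCube(
        data=np.broadcast_to(white_band, ref_shape).astype(np.float32).copy(),
        wavelengths_nm=lam,
    )
    dark_cube = HyperspectralCube(
        data=np.broadcast_to(dark_band, ref_shape).astype(np.float32).copy(),
        wavelengths_nm=lam,
    )
    raw_cube = HyperspectralCube(data=raw.astype(np.float32), wavelengths_nm=lam)
    return raw_cube, ReferencePair(white=white_cube, dark=dark_cube), truth


def generate_sample_pair(
    seed: int, flesh_fraction: float, **overrides
) -> tuple[
    tuple[HyperspectralCube, ReferencePair, PhantomTruth],
    tuple[HyperspectralCube, ReferencePair, PhantomTruth],
]:
    """Front and back phantom captures of one tuber (independent peel layouts)."""
    faces = []
    for offset in (0, 1):
        spec = PhantomSpec(
            seed=(2 * seed + offset) % 2**31,
            flesh_fraction=flesh_fraction,
            **overrides,
        )
        faces.append(generate_phantom(spec))
    return faces[0], faces[1]


def auto_rois(
    truth: PhantomTruth,
    n_per_class: int = 10,
    size: int = 8,
    seed: int = 0,
    sample_id: str = "phantom",
) -> list[ROI]:
    """Place ``n_per_class`` square ROIs fully inside each tissue class.

    Positions are drawn without overlap when possible (falling back to
    overlapping placements if a class region is too small), deterministically
    for a given seed.
    """
    rng = np.random.default_rng(seed)
    rois: list[ROI] = []
    for label_name, code in (("peel", 1), ("flesh", 2)):
        mask = truth.label_image == code
        window = np.lib.stride_tricks.sliding_window_view(mask, (size, size))
        valid = np.argwhere(window.all(axis=(2, 3)))
        if valid.shape[0] < n_per_class:
            raise RoiError(
                f"cannot place {n_per_class} {size}x{size} ROIs in class "
                f"{label_name!r}; only {valid.shape[0]} positions exist"
            )
        perm = valid[rng.permutation(valid.shape[0])]
        chosen: list[tuple[int, int]] = []
        for r, c in perm:
            if all(abs(r - r2) >= size or abs(c - c2) >= size for r2, c2 in chosen):
                chosen.append((int(r), int(c)))
            if len(chosen) == n_per_class:
                break
        i = 0
        while len(chosen) < n_per_class:  # fallback: allow overlap
            chosen.append((int(perm[i][0]), int(perm[i][1])))
            i += 1
        for r, c in chosen:
            rois.append(
                ROI(label=label_name, row0=r, col0=c, row1=r + size, col1=c + size,
                    sample_id=sample_id)
            )
    return rois


def manual_rates_from_truth(
    truths: dict[str, float], sd: float = 2.0, seed: int = 0
) -> dict[str, float]:
    """Synthesise manual-measurement rates: truth (percent) + N(0, sd) noise.

    Results are clipped to [0, 100].  ``sd`` is in percentage points and
    emulates the scatter of the manual surface-area protocol.
    """
    rng = np.random.default_rng(seed)
    return {
        sid: float(np.clip(rate + rng.normal(0.0, sd), 0.0, 100.0))
        for sid, rate in truths.items()
    }
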