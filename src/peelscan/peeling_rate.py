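"""Peeling rate from front/back segmentation counts, validation statistics,
and the end-to-end pipeline.

The peeling rate of one tuber pools the two captures:

    C = 100 * (N_flesh_front + N_flesh_back) / (Q_front + Q_back)

where Q is the total potato pixel count (peel + flesh) of a face.  Against
manually measured rates, validation reports the mean absolute error of
``rate_calc - rate_manual`` and the sample standard deviation (n - 1
denominator) of the signed errors.

``run_pipeline`` executes the full workflow per sample: reflectance
calibration, optional PCA-driven key-band selection from an ROI table
(fixed 592 +/- 20 nm window otherwise), band-window grayscale, 5x5 median
filtering, dual-threshold segmentation, pixel counting and rate
computation, writing per-face images and deterministic CSV outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import band_selection, roi_spectra, segmentation
from .band_selection import BandWindow, band_window_grayscale, resolve_band_window
from .cube_io import HyperspectralCube, ReferencePair, calibrate_reflectance, read_envi_cube
from .exceptions import DegenerateDataError, ParameterError, PeelscanError
from .segmentation import SegmentationCounts, Thresholds

__all__ = [
    "SampleFaces",
    "PeelingRateRecord",
    "ValidationSummary",
    "compute_peeling_rate",
    "validation_stats",
    "segment_face",
    "rate_from_cubes",
    "PipelineConfig",
    "run_pipeline",
    "PipelineResult",
]


@dataclass(frozen=True)
class SampleFaces:
    """Front and back segmentation counts of one tuber."""

    sample_id: str
    front: SegmentationCounts
    back: SegmentationCounts


@dataclass
class PeelingRateRecord:
    """Computed (and optionally manual) peeling rate of one sample, in percent."""

    sample_id: str
    n_flesh_front: int
    q_front: int
    n_flesh_back: int
    q_back: int
    rate_calc: float
    rate_manual: float | None = None

    @property
    def error(self) -> float | None:
        """Signed error ``rate_calc - rate_manual``, if a manual rate exists."""
        if self.rate_manual is None:
            return None
        return self.rate_calc - self.rate_manual


@dataclass(frozen=True)
class ValidationSummary:
    """Aggregate agreement between computed and manual peeling rates (percent)."""

    n_samples: int
    mean_rate_calc: float
    mean_rate_manual: float
    mean_abs_error: float
    sd_error: float
    sd_abs_error: float


def compute_peeling_rate(faces: SampleFaces) -> PeelingRateRecord:
    """Pool front/back counts into the peeling rate C (percent)."""
    q_total = faces.front.q + faces.back.q
    if q_total <= 0:
        raise DegenerateDataError(
            f"sample {faces.sample_id!r} has zero potato pixels; "
            "check thresholds/segmentation"
        )
    flesh_total = faces.front.n_flesh + faces.back.n_flesh
    return PeelingRateRecord(
        sample_id=faces.sample_id,
        n_flesh_front=faces.front.n_flesh,
        q_front=faces.front.q,
        n_flesh_back=faces.back.n_flesh,
        q_back=faces.back.q,
        rate_calc=100.0 * flesh_total / q_total,
    )


def validation_stats(records: Sequence[PeelingRateRecord]) -> ValidationSummary:
    """Mean rates, mean |error| and sample SD of signed errors over samples."""
    if len(records) < 2:
        raise ParameterError("validation statistics need at least 2 samples")
    for rec in records:
        if rec.rate_manual is None:
            raise ParameterError(f"sample {rec.sample_id!r} lacks a manual rate")
    calc = np.array([r.rate_calc for r in records])
    manual = np.array([r.rate_manual for r in records])
    err = calc - manual
    return ValidationSummary(
        n_samples=len(records),
        mean_rate_calc=float(calc.mean()),
        mean_rate_manual=float(manual.mean()),
        mean_abs_error=float(np.abs(err).mean()),
        sd_error=float(err.std(ddof=1)),
        sd_abs_error=float(np.abs(err).std(ddof=1)),
    )


# ---------------------------------------------------------------------------
# Face-level processing
# ---------------------------------------------------------------------------

def segment_face(
    cube: HyperspectralCube,
    window: BandWindow,
    thresholds: Thresholds = Thresholds(),
    *,
    median_filter: bool = True,
    grayscale_mode: str = "window-mean",
) -> tuple[SegmentationCounts, np.ndarray, np.ndarray]:
    """Grayscale -> (optional) median filter -> dual-threshold -> counts.

    Returns ``(counts, denoised_gray, label_image)``.
    """
    gray = band_window_grayscale(cube, window, mode=grayscale_mode)
    denoised = segmentation.median_filter_5x5(gray) if median_filter else gray
    masks = segmentation.dual_threshold_masks(denoised, thresholds)
    return segmentation.count_regions(masks), denoised, segmentation.label_image(masks)


def rate_from_cubes(
    sample_id: str,
    front: HyperspectralCube,
    back: HyperspectralCube,
    window: BandWindow,
    thresholds: Thresholds = Thresholds(),
    *,
    median_filter: bool = True,
    grayscale_mode: str = "window-mean",
) -> PeelingRateRecord:
    """Peeling rate of one sample directly from two calibrated cubes."""
    counts_f, _, _ = segment_face(
        front, window, thresholds, median_filter=median_filter, grayscale_mode=grayscale_mode
    )
    counts_b, _, _ = segment_face(
        back, window, thresholds, median_filter=median_filter, grayscale_mode=grayscale_mode
    )
    return compute_peeling_rate(SampleFaces(sample_id, counts_f, counts_b))


# ---------------------------------------------------------------------------
# Config schema and pipeline
# ---------------------------------------------------------------------------

class FaceConfig(BaseModel):
    """One capture: a cube path plus optional white/dark reference paths.

    If references are given the cube is treated as raw counts and
    calibrated; otherwise it must already be reflectance.
    """

    cube: Path
    white: Optional[Path] = None
    dark: Optional[Path] = None

    @model_validator(mode="after")
    def _refs_paired(self) -> "FaceConfig":
        if (self.white is None) != (self.dark is None):
            raise ValueError("white and dark references must be given together")
        return self


class SampleConfig(BaseModel):
    sample_id: str
    front: FaceConfig
    back: FaceConfig


class WindowConfig(BaseModel):
    center_nm: float = 592.0
    half_width_nm: float = Field(default=20.0, ge=0)
    grayscale_mode: Literal["window-mean", "center-band"] = "window-mean"


class PipelineConfig(BaseModel):
    """Validated schema for the end-to-end run (JSON or YAML on disk)."""

    samples: list[SampleConfig] = Field(min_length=1)
    t_low: int = Field(default=35, ge=0, le=255)
    t_high: int = Field(default=125, ge=0, le=255)
    window: WindowConfig = WindowConfig()
    median_filter: bool = True
    roi_table: Optional[Path] = None
    roi_cube: Optional[Path] = None  # defaults to first sample's front face
    pca_components: int = Field(default=5, ge=1)
    manual_rates: Optional[Path] = None
    output_dir: Path = Path("peelscan_out")
    seed: Optional[int] = None

    @model_validator(mode="after")
    def _thresholds_ordered(self) -> "PipelineConfig":
        if self.t_low >= self.t_high:
            raise ValueError(f"t_low ({self.t_low}) must be < t_high ({self.t_high})")
        return self


@dataclass
class PipelineResult:
    records: list[PeelingRateRecord]
    summary: ValidationSummary | None
    window: BandWindow
    params: dict


def load_config(path: str | Path) -> PipelineConfig:
    """Load a JSON or YAML pipeline config with schema validation."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yml", ".yaml"):
        import yaml

        payload = yaml.safe_load(text)
    else:
        payload = json.loads(text)
    return PipelineConfig.model_validate(payload)


def _load_face(face: FaceConfig) -> HyperspectralCube:
    cube = read_envi_cube(face.cube)
    if face.white is not None:
        refs = ReferencePair(white=read_envi_cube(face.white), dark=read_envi_cube(face.dark))
        return calibrate_reflectance(cube, refs)
    if not cube.is_calibrated:
        finite = cube.data[np.isfinite(cube.data)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ParameterError(
                f"{face.cube}: no references given but values are outside [0, 1]"
            )
        cube = HyperspectralCube(
            data=cube.data, wavelengths_nm=cube.wavelengths_nm,
            is_calibrated=True, meta=cube.meta,
        )
    return cube


def _write_png(image: np.ndarray, path: Path) -> None:
    from PIL import Image

    Image.fromarray(image).save(path)


def _select_window(config: PipelineConfig) -> tuple[BandWindow, dict]:
    """Fixed window, or PCA-selected window when an ROI table is configured."""
    first = config.samples[0].front
    axis_cube = read_envi_cube(config.roi_cube) if config.roi_cube else None
    if config.roi_table is None:
        cube = axis_cube or read_envi_cube(first.cube)
        window = resolve_band_window(
            cube.wavelengths_nm, config.window.center_nm, config.window.half_width_nm
        )
        return window, {"band_selection": "fixed"}
    if axis_cube is not None:
        cube = _load_face(FaceConfig(cube=config.roi_cube, white=first.white, dark=first.dark))
    else:
        cube = _load_face(first)
    rois = roi_spectra.parse_roi_table(config.roi_table)
    matrix = roi_spectra.extract_spectra(cube, rois)
    pca = band_selection.fit_pca(matrix, k=min(config.pca_components, matrix.n_samples - 1))
    curve = band_selection.pc1_weight_curve(pca, matrix.wavelengths_nm)
    window = band_selection.select_key_window(curve, config.window.half_width_nm)
    info = {
        "band_selection": "pca",
        "contribution_rates_percent": [round(float(r), 4) for r in pca.contribution_rates],
        "window_mean_weight": window.mean_weight,
    }
    return window, info


def run_pipeline(config: PipelineConfig | dict | str | Path) -> PipelineResult:
    """Execute calibration, band selection, segmentation and rating end to end.

    Writes per-face grayscale and label images (PNG), a per-sample results
    CSV, a validation summary CSV when manual rates are supplied, and a
    parameter log.  Outputs are deterministic: re-running with an identical
    config produces byte-identical CSVs.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    elif isinstance(config, dict):
        config = PipelineConfig.model_validate(config)

    thresholds = Thresholds(t_low=config.t_low, t_high=config.t_high)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    window, band_info = _select_window(config)

    manual: dict[str, float] = {}
    if config.manual_rates is not None:
        table = pd.read_csv(config.manual_rates, dtype={"sample_id": str})
        if not {"sample_id", "rate_manual_percent"} <= set(table.columns):
            raise ParameterError(
                f"{config.manual_rates}: need columns sample_id, rate_manual_percent"
            )
        manual = dict(zip(table["sample_id"], table["rate_manual_percent"].astype(float)))

    records: list[PeelingRateRecord] = []
    for sample in config.samples:
        counts = {}
        for face_name in ("front", "back"):
            face = getattr(sample, face_name)
            try:
                cube = _load_face(face)
                face_counts, denoised, labels = segment_face(
                    cube, window, thresholds,
                    median_filter=config.median_filter,
                    grayscale_mode=config.window.grayscale_mode,
                )
            except PeelscanError as exc:
                raise type(exc)(
                    f"sample {sample.sample_id!r}, {face_name} face: {exc}"
                ) from exc
            counts[face_name] = face_counts
            stem = f"{sample.sample_id}_{face_name}"
            _write_png(denoised, out / f"{stem}_gray.png")
            _write_png((labels * 127).astype(np.uint8), out / f"{stem}_labels.png")
        record = compute_peeling_rate(
            SampleFaces(sample.sample_id, counts["front"], counts["back"])
        )
        record.rate_manual = manual.get(sample.sample_id)
        records.append(record)

    frame = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "n_flesh_front": [r.n_flesh_front for r in records],
            "q_front": [r.q_front for r in records],
            "n_flesh_back": [r.n_flesh_back for r in records],
            "q_back": [r.q_back for r in records],
            "rate_calc": [f"{r.rate_calc:.2f}" for r in records],
            "rate_manual": ["" if r.rate_manual is None else f"{r.rate_manual:.2f}" for r in records],
            "error": ["" if r.error is None else f"{r.error:.2f}" for r in records],
        }
    )
    frame.to_csv(out / "results.csv", index=False)

    summary = None
    with_manual = [r for r in records if r.rate_manual is not None]
    if len(with_manual) >= 2:
        summary = validation_stats(with_manual)
        pd.DataFrame(
            [
                {
                    "n_samples": summary.n_samples,
                    "mean_rate_calc": f"{summary.mean_rate_calc:.2f}",
                    "mean_rate_manual": f"{summary.mean_rate_manual:.2f}",
                    "mean_abs_error": f"{summary.mean_abs_error:.2f}",
                    "sd_error": f"{summary.sd_error:.2f}",
                    "sd_abs_error": f"{summary.sd_abs_error:.2f}",
                }
            ]
        ).to_csv(out / "summary.csv", index=False)

    params = {
        "t_low": config.t_low,
        "t_high": config.t_high,
        "median_filter": config.median_filter,
        "window_center_nm": window.center_nm,
        "window_half_width_nm": window.half_width_nm,
        "window_band_indices": [int(i) for i in window.band_indices],
        "grayscale_mode": config.window.grayscale_mode,
        "seed": config.seed,
        **band_info,
    }
    (out / "params.json").write_text(json.dumps(params, indent=2, sort_keys=True) + "\n")
    return PipelineResult(records=records, summary=summary, window=window, params=params)
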