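# Methods

## Model and assumptions

The package estimates the peeled fraction (peeling rate) of a potato tuber
from two hyperspectral captures (front and back faces) under four
assumptions:

1. **Reflectance separability.** After black/white correction, flesh
   reflectance exceeds peel reflectance across the visible–NIR range, with
   the contrast largest in a narrow key band (592 nm region on potato
   tissue). One grayscale image from that band therefore carries enough
   contrast for a three-way intensity partition.
2. **Intensity-only segmentation.** Background, peel and flesh are
   separable by two fixed gray-level cut points; no spatial model, shape
   prior or morphological cleanup is used.
3. **Area ≈ pixel count.** The peeled surface fraction is approximated by
   the exposed-flesh pixel fraction of the two 2-D projections,
   `C = 100·(N_flesh,front + N_flesh,back)/(Q_front + Q_back)`. Front and
   back faces are independent captures linked only by sample id — no
   spatial registration, and curvature foreshortening is ignored.
4. **Impulse-dominated noise.** The disturbance that threatens the counts
   is isolated dead/saturated pixels; a 5×5 median filter removes it while
   preserving region boundaries.

## Pipeline stages and numerical choices

**Calibration** `R = (R0 − B)/(W − B)` is computed in float64 and clipped
to [0, 1] (specular highlights would otherwise exceed 1; downstream 8-bit
rendering assumes the unit interval). Sites with `W − B ≤ 0` (dead or
saturated sensor columns) are undefined; they are set to 0 and tallied in
the result's `meta["n_invalid"]`. Height-1 references broadcast along
scene rows, the common line-scan whiteboard case. Calibrating an
already-calibrated cube is refused.

**ROI spectra.** ROIs are axis-aligned half-open rectangles with 0-based
pixel coordinates — the simplest reproducible stand-in for freehand ROI
drawing. Each ROI contributes one spectra-matrix row, its per-band mean:
per-ROI means match the sampling structure of manual ROI selection
(20 ROIs → 20 samples) and damp pixel noise before PCA. A per-pixel mode
(`extract_spectra(..., per_pixel=True)`) is provided for users who prefer
pixel-level samples; the default is the per-ROI mean.

**PCA band selection** uses covariance PCA (centering only — all bands
share reflectance units, so per-band standardization would only amplify
noisy low-variance bands). Contribution rates are percentages of *total*
variance (full eigenvalue spectrum), not of the retained components.
Eigenvector sign is arbitrary; it is fixed so each component's
largest-magnitude coefficient is positive, making the PC1 weight curve
peak positive and reproducible. Ties in the weight-curve maximum resolve
to the lowest wavelength. The selected window is `center ± half_width`
(default half-width 20 nm), clipped to the spectral axis.

**Grayscale rendering** averages reflectance over all window bands by
default ("window-mean"): the 40 nm window contains several bands, and
averaging uses all of them and reduces per-band noise. A "center-band"
mode using only the band nearest the window centre is available.
Quantization maps [0, 1] linearly to [0, 255] with round-half-up, chosen
for cross-platform determinism.

**Median filter**: 5×5 window, reflect padding at borders (reflection
avoids inventing background values where the tuber touches the frame).
Output values are always drawn from the input value set.

**Dual thresholds**: peel is `T_low ≤ I < T_high`, flesh `I ≥ T_high`,
background `I < T_low`, with defaults `T_low = 35`, `T_high = 125` on the
8-bit window-mean grayscale. The flesh boundary is inclusive (`≥`). The
three classes always partition the image. A sample whose pooled potato
pixel count is zero raises a degenerate-sample error (almost always a
threshold misconfiguration) rather than returning NaN.

**Validation statistics**: "error" is `rate_calc − rate_manual` per
sample; the summary reports the mean of |error| and the sample standard
deviation (n − 1) of the *signed* errors. The SD of absolute errors is
also reported (`sd_abs_error`) since either reading can be wanted.
Rates are written to CSV at 2 decimal places; full precision is kept
internally.

## Tunable parameters

| parameter | default | units | notes |
|---|---|---|---|
| window centre | 592 | nm | key band on potato tissue; re-derived when an ROI table is supplied |
| window half-width | 20 | nm | bands with centres within ±20 nm are averaged |
| T_low / T_high | 35 / 125 | 8-bit gray | calibrated for this imaging geometry; not universal constants |
| median filter | on | — | 5×5; disable only on noise-free data |
| PCA components | 5 | — | retained for reporting; selection only uses PC1 |

## The phantom generator

`peelscan.phantom` renders what the pipeline needs to be testable without
real data: an elliptical tuber (semi-axes ≈ 0.32/0.34 of the frame) on a
dark background (reflectance 0.02), residual peel drawn as blob shapes —
a level set of a union-of-disks distance field, thresholded at exactly the
pixel count matching the requested peel fraction, so ground truth hits the
target to within one pixel. Class reflectance follows smooth profiles with
the structure of real potato tissue: both classes rise from 485 nm with
flesh rising faster over 485–523 nm, flesh above peel everywhere, the
separation maximal at 592 nm (Gaussian bump, σ = 80 nm, amplitude 0.27
over a 0.06 floor), and both declining beyond 823 nm. Raw counts invert
the calibration equation against a halogen-like white reference (~3200
counts, peaking near 760 nm) and a flat dark level (96 counts), so
noiseless phantoms calibrate back to the class profiles exactly.

Noise defaults model the acquisition conditions used throughout the noisy
tests: Gaussian reflectance noise SD 0.01 (1 % of full scale) per
pixel/band, plus salt-and-pepper impulses at 2 % spatial density applied
across a pixel's whole spectrum in raw-count space (dead/hot sensor
sites). Ground-truth labels are recorded before noise.

Default scenes are 174 × 175 pixels × 64 bands over 386.7–1016.7 nm — a
quarter-scale analogue of the emulated imager (696 × 700 × 256), chosen so
the 30-sample study suites run in seconds on a laptop; full-scale scenes
are available via `full_scale=True`.

**What the phantom does not emulate** — and hence what passing tests do
not establish about real data: realistic peel morphology and texture
(blobs only encode area fraction), within-class spectral variability
beyond iid noise (cultivar differences, moisture, bruising), post-peeling
discoloration drift (only a uniform `flesh_shift` offset is offered),
shadows, specular highlights, stem scars, and curvature foreshortening of
surface area. The fixed 35/125 thresholds are correct for the phantom's
gray levels by construction; on a real system they must be re-derived.

## Test-suite design notes

The exact-recovery suite (30 noiseless sample pairs, flesh fractions
uniform over 50–95 %) runs with the median filter disabled: with nothing
to denoise this isolates the calibration → grayscale → threshold → count
path, which must be *exact*, since each class renders to a single gray
level strictly between the thresholds. A median filter, by contrast,
necessarily erodes convex corners of any rasterized region (a boundary
pixel whose 5×5 window holds fewer than 13 same-class pixels flips), so
demanding pixel-exact counts through the filter would test rasterization
geometry, not the method. The noisy suite runs the full default pipeline
(filter on) and bounds the error at 1 percentage point per sample, and
also demonstrates the filter's necessity: without it, impulse noise on the
large background area inflates the flesh count enough to break the same
bound for low-flesh-fraction samples.

PCA is checked against an independent brute-force oracle
(eigendecomposition of the explicitly formed covariance matrix) on random
matrices up to 20 × 30, to 1e-8.

## Known limitations

- Thresholds and the key band are instrument- and cultivar-specific;
  adaptive threshold selection is out of scope.
- Two projections under-sample a 3-D surface; strongly non-convex tubers
  bias C.
- Ambiguous tissue (discolored flesh, thin residual membrane) is forced
  into one of three classes by gray level alone.
- The ENVI reader supports little-endian files only, and the standard
  numeric data types; BSQ is the only write interleave.
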