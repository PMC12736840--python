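# peelscan

Non-destructive quantification of the **peeling rate** of potato tubers from
hyperspectral images, for researchers and process engineers evaluating
peeling machinery (e.g. waterjet peelers). The conventional alternative —
manual surface-area measurement, or iodine staining of residual starch — is
slow, subjective or destructive; peel and flesh differ strongly in spectral
reflectance, so a calibrated hyperspectral cube plus simple thresholding
can count exposed-flesh pixels directly.

## Method

For each tuber, front and back reflectance cubes are processed as:

1. **Black/white correction.** Raw counts become normalized reflectance via
   whiteboard/blackboard references:
   `R = (R0 − B) / (W − B)`, clipped to [0, 1].
2. **Key-band selection.** Labelled ROI spectra (peel vs flesh) are reduced
   by covariance PCA. The first principal component captures the
   between-class contrast; its weight-coefficient curve over wavelength
   peaks where the tissues separate best, and a window of
   `center ± 20 nm` is selected (on potato tissue: **592 ± 20 nm**, used as
   the fixed default when no ROI table is given).
3. **Grayscale + denoising.** Mean reflectance over the window bands maps
   linearly to 8-bit gray, then a **5 × 5 median filter** removes impulse
   noise.
4. **Dual-threshold segmentation.** Two cut points partition the image:
   background (`I < T_low`), peel (`T_low ≤ I < T_high`), flesh
   (`I ≥ T_high`); defaults `T_low = 35`, `T_high = 125`. Pixel counts
   N_peel, N_flesh and Q = N_peel + N_flesh follow.
5. **Peeling rate.** Pooling both faces,

   `C = 100 · (N_flesh,front + N_flesh,back) / (Q_front + Q_back)  [%]`

   Against manual measurements the package reports the mean absolute error
   and the sample standard deviation of the signed errors.

Because no raw potato imagery ships with the package, a **phantom
generator** renders seed-controlled synthetic scenes (elliptical tuber,
blob-shaped residual peel with an exact area fraction, class-specific
spectral profiles with maximal peel/flesh separation at 592 nm, Gaussian +
salt-and-pepper noise, matching white/dark references) with exact ground
truth, so every stage is testable end to end.

## Worked example

Simulate a small phantom dataset (ENVI cubes + references + ROI, truth and
manual-rate CSVs + a ready config), then run the full pipeline:

```bash
peelscan simulate --out demo --n-samples 3 --seed 1 \
    --height 96 --width 96 --bands 32
peelscan run --config demo/config.json
```

prints

```
s000: C = 49.54 %
s001: C = 72.41 %
s002: C = 95.39 %
mean calc 72.45 % vs manual 73.49 %; MAE 1.05 %, SD of error 0.74 %
```

`C` is each sample's computed peeling rate; the three samples were
generated with true flesh fractions of 50 %, 72.5 % and 95 %, so the
computed rates recover the ground truth to well under one percentage point
even with 2 % impulse noise, while the residual MAE against the *manual*
column reflects the simulated scatter of manual measurement.
`demo/results/` then contains `results.csv` (per-sample counts, rates,
errors), `summary.csv`, per-face grayscale/label PNGs and `params.json`.

The same stages are available individually (`peelscan calibrate`,
`spectra`, `select-band`, `segment`, `rate`) and as a Python API:

```python
import peelscan as ps

cube = ps.calibrate_reflectance(raw, ps.ReferencePair(white=w, dark=d))
window = ps.resolve_band_window(cube.wavelengths_nm, 592.0, 20.0)
counts, gray, labels = ps.segment_face(cube, window)  # Thresholds(35, 125)
```

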