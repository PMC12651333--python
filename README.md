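# lfaquant

A desk-scale reader for smartphone-photographed lateral-flow immunoassay
(LFIA) strips, built around the semi-quantitative 25-hydroxyvitamin D
[25(OH)D] cassette format: a control line (C), an analyte-dependent test
line (T), and five printed reference lines of known nominal signal used
for per-image multi-point calibration. It is written for people who build
or validate strip readers — assay developers, image-analysis engineers,
and statisticians reviewing analytical-validation claims — and runs
entirely on synthetic strip photographs with exhaustively known ground
truth, so every stage is testable without a wet lab or a phone.

## What it computes

**Readout chain.** A photograph is reduced to a clinical call in six
steps:

1. **Detection** — the strip quadrilateral is found by edge detection
   (Sobel magnitude at the Otsu level) combined with brightness
   thresholding, contour tracing, polygonal simplification and line-fit
   corner refinement.
2. **Rectification** — a 4-point direct linear transform maps the
   quadrilateral onto the canonical 600x120 frame; pixels are
   gamma-decoded so all downstream math is in linear light.
3. **Line measurement** — the strip becomes a longitudinal green-channel
   absorbance profile (−log10 of a 20%-trimmed transverse mean); each
   line's intensity *I* is its window mean minus a local flanking-median
   background, which cancels global illumination exactly.
4. **Per-image calibration** — the five reference lines give points
   (I_k, R_k); least squares yields S = g(I) = a0 + a1 I (+ a2 I^2), with
   robust outlier masking (3x median absolute residual about a Theil–Sen
   provisional line).
5. **Concentration** — standardized signals S_T = g(I_T), S_C = g(I_C)
   feed a pre-calibrated regression
   `25(OH)D (ng/mL) = alpha * S_T/S_C + beta` (or alpha S_T + beta),
   censored to the 5–100 ng/mL measurement range.
6. **Classification** — deficient (< 20), insufficient (20–30),
   sufficient (> 30 ng/mL).

**Cross-device alignment.** A source device is mapped onto a reference
device's linear RGB space by (i) sRGB linearization, (ii) neutral-zone
white balance, (iii) polynomial shading correction and (iv) a 3x3 color
correction matrix with intensity scaling, learned from paired captures of
the same strips (`PhotometricAligner`).

**Validation statistics.** CLSI EP17-style detection limits
(LoB = mean_blank + 1.645 SD_blank, LoD = LoB + 1.645 SD_low), percent
agreement with Wilson score intervals, unweighted and ordinal-weighted
Cohen's kappa, Pearson r/R², and Welch confidence intervals. Bundled
contingency tables from a published serum method comparison (n = 100) and
a capillary–serum equivalence study (n = 22) serve as ready inputs.

The calibration, concentration and alignment models are scikit-learn
style estimators (`fit`/`transform`/`predict`, `get_params`, fitted
attributes with trailing underscores) and compose with sklearn tooling.

## Worked example

```python
from lfaquant import (DeviceModel, DoseResponse, Pose, StripLayout,
                      analyze_image, fit_concentration_model, render_strip,
                      agreement_report)
from lfaquant.datasets import serum_comparison_table

layout, dr = StripLayout(), DoseResponse()

# calibrate the concentration regression on a synthetic reference panel
model = fit_concentration_model(seed=1, layout=layout, dr=dr, photographed=True)
print(f"concentration model: c = {model.alpha_:.1f} * S_T/C {model.beta_:+.1f}")

# photograph a 25 ng/mL strip at a tilted pose with a noisy sRGB camera
pose = Pose.framed(layout, rotation_deg=7, perspective=0.02, scale=0.85)
img, truth = render_strip(layout, 25.0, dr, DeviceModel(), pose, seed=8)
rec = analyze_image(img, model, layout=layout)
print(f"S_T/C={rec.signals.s_tc:.4f} est={rec.result.display} "
      f"level {rec.result.level} ({rec.result.label})")

# agreement statistics for the bundled serum method-comparison table
print(agreement_report(serum_comparison_table()).summary())
```

prints

```
concentration model: c = 170.9 * S_T/C -4.5
S_T/C=0.1976 est=29.3 level 2 (insufficient)
overall agreement: 97.0% (95% CI 91.5-99.0%)
  level 1: 93.3% (95% CI 70.2-98.8%)
  level 2: 97.4% (95% CI 86.8-99.5%)
  level 3: 97.8% (95% CI 88.7-99.6%)
kappa (unweighted): 0.951
kappa (linear weights): 0.960
```

The strip was rendered at a true 25 ng/mL; the pipeline detects and
rectifies the tilted photograph, recalibrates against the strip's own
reference ladder, and reads back 29.3 ng/mL — inside the insufficient
(20–30 ng/mL) band. The agreement summary reproduces the serum study's
published figures: 97/100 concordant calls and an unweighted kappa of
0.951 against the laboratory analyzer.

A command-line interface mirrors the library
(`lfaquant simulate|analyze|fit-calibration|fit-align|apply-align|lod-study|compare|report`).

## Layout

```
src/lfaquant/
  layout.py      strip geometry, dose-response, device models, poses
  synthetic.py   ground-truth strip renderer and validation panels
  geometry.py    detection, rectification, QC flags
  signals.py     absorbance profiles, line intensities, reference ladder
  calibration.py ReferenceCalibrator, ConcentrationRegressor, 3-level call
  photometric.py sRGB, white balance, shading, CCM, PhotometricAligner
  stats.py       LoB/LoD, agreement, Wilson, kappa, Pearson, Welch
  studies.py     synthetic validation studies (shared by tests/acceptance)
  datasets.py    bundled clinical contingency tables and blank-study stats
  pipeline.py    photograph -> record orchestration, method comparison
  cli.py         typer CLI
docs/methods.md  model assumptions, defaults, numerical choices, limits
```
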