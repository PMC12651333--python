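# Methods

## The measurement model

The reader treats a lateral-flow strip as a set of transverse colored
bands on an off-white nitrocellulose substrate. The test line's color is
produced by gold-nanoparticle immunocomplexes, so its optical density
rises with analyte concentration and saturates as binding sites fill. We
model this with the simplest monotone saturating (Langmuir-form) curve

    d(c) = floor + d_max * c / (k_half + c)

with defaults `d_max = 1.2`, `k_half = 250 ng/mL`, `floor = 0.0024`
(trace nonspecific binding at zero analyte). The half-saturation point is
deliberately placed well above the 5–100 ng/mL measurement range: readers
of this class report near-unity linear correlation between signal and
concentration in range (R² ≈ 0.99), which requires the response to be
close to linear there, while saturation only bends the curve above the
top of the range. With these defaults the best linear readout has at most
~8% concentration error at the range ends and R² ≈ 0.992 across an
8-level panel — consistent with the behavior the format is validated to.

Band color is implemented as green-channel absorbance on the substrate:
gold-nanoparticle bands are red, so green is the complementary, maximally
absorbed channel (per-channel absorption ratios R:G:B = 0.15:1:0.55).
Line densities: control line fixed at 0.6 (strongest band), reference
line k at `0.006 * R_k` for nominal signals R_k = (10, 20, 40, 60, 80) —
the true signal-to-density map of printed ladders is not public, so a
linear map is used as a stand-in — and the test line from d(c).

The substrate renders at linear reflectance 0.75, not 1.0. This is a
deliberate exposure choice: it leaves headroom so a global illumination
gain up to 1.3x never clips pixels. Clipping would destroy the exact
cancellation that makes the readout illumination-invariant (below).

## Synthetic captures

A capture is the canonical 600x120 strip warped by homography into a
photograph (darker background, optional rotation/perspective), then
passed through a device model in a fixed order: multiplicative shading
field (degree-2 2-D polynomial), 3x3 channel mixing, global intensity
scale, white-balance tint, sRGB gamma encoding, additive Gaussian pixel
noise (default sd 0.004 in encoded units, clipped to [0, 1]). Every
generator is a pure function of its inputs and a seed; paired captures of
the same strip share densities and differ only in device pipelines and
noise draws.

Replicate chemistry variability is modeled as Gaussian jitter on the
test-line density (default sd 0.001, truncated at zero). This is the
dominant replicate-to-replicate variance source in the detection-limit
study, as it is in real assays, where plate-to-plate chemistry beats
shot noise by an order of magnitude.

What the generator does *not* emulate: membrane texture, flow fronts and
drying artifacts, hook effects at extreme analyte, specular glare,
autofocus blur, JPEG compression. Tests passing on synthetic strips
therefore demonstrate the *algorithmic* correctness and invariances of
the pipeline, not field robustness to those physical effects.

## Geometry

Detection thresholds the luminance image and the Sobel gradient magnitude
at their Otsu levels, unions the masks, closes with a 5x41 footprint
(wider than a line band, which would otherwise split the strip region),
fills holes, and takes the largest region covering at least 5% of the
image. Its contour is simplified to a quadrilateral (tolerance is scanned
geometrically until exactly four vertices remain) and each corner is
refined by intersecting total-least-squares lines fitted to the contour
runs along the four edges. Corners are ordered clockwise from top-left;
coordinates are 0-based (row, col). Accuracy on synthetic poses is
~1.5–2.5 px up to ±25° rotation with moderate perspective.

Rectification estimates the source-to-canonical homography from the four
corners (DLT), resamples bilinearly, and gamma-decodes, so everything
downstream operates in linear light. The homography is stored acting on
homogeneous (x, y, 1) = (col, row, 1) coordinates.

## Line signal

The absorbance profile is `-log10(max(1e-4, m(col)))` where m is the
20%-trimmed mean of the green channel over the transverse central 60% of
the strip — trimming resists dust and glare specks. Because a global
illumination gain multiplies transmittance, it adds a constant to the
whole absorbance profile; line intensity is the window mean minus the
median of two flanking background windows, so that constant cancels
exactly. This is the mechanism behind the illumination-invariance
property, and it holds only while no pixels clip.

Line localization returns the center of the near-maximum plateau (within
5% of the peak height above the window minimum) rather than the raw
argmax: band tops are flat, so the argmax wanders across the plateau
under pixel noise (empirically ±6 px, enough to corrupt window
placement). The plateau-center rule degrades to the exact argmax for a
sharp peak and to the window center for a flat window (the tie-break).
All seven lines are then measured on the nominal window grid translated
by one common registration shift (the median peak displacement), which
absorbs residual rectification offset while keeping the configured
relative window geometry — and hence the validity of the
flank-vs-other-window disjointness check — intact.

Ladder outlier masking uses residuals about a provisional *robust* line:
Theil–Sen slope with a median pointwise intercept, cutoff at 3x the
median absolute residual (with a tiny absolute floor so an exactly linear
ladder never self-flags). A provisional least-squares line was tried
first and rejected: a single gross outlier drags the LSQ fit enough to
inflate the good points' residuals and hide itself from the 3x-MAD rule,
and scipy's default Theil–Sen intercept `median(y) − m·median(x)` is
corrupted the same way through `median(x)`. At least two points must
survive or the ladder is unusable.

## Calibration and classification

`ReferenceCalibrator` fits R on a degree-1 (optionally degree-2)
polynomial in I by ordinary least squares over the surviving ladder
points and rejects any fit that is not strictly increasing over the
observed intensity range (an inverted ladder is a failed strip, not a
calibration). Degree 1 is the default: the quadratic term helps only when
intensity nonlinearity lies *inside* the ladder's span, and extrapolating
a quadratic to the control line's higher density is less stable than the
affine extrapolation.

`ConcentrationRegressor` defaults to the control-normalized predictor
S_T/S_C, which cancels residual device and run effects that scale T and C
together. Predictions below 5 or above 100 ng/mL are reported as censored
markers ("<5", ">100") with the level implied — never silently clamped.
The middle class is the closed interval [20, 30] ng/mL; the boundary
values 20 and 30 belong to "insufficient".

Calibration panels can be measured either as canonical ROI captures
(`photographed=False`, the reference path for bench-top studies) or as
framed photographs pushed through detection and rectification
(`photographed=True`). The photographed path shares the optical path —
including resampling blur — with the images the model will be applied to,
and is used wherever the analysis target is a photograph.

## Photometric alignment

The source-to-reference transform is fitted sequentially, keeping each
sub-fit linear: white-balance gains from pooled neutral-zone channel
medians; a degree-2 shading field by least squares on background
luminance (correction divides by the field normalized to mean 1); then a
3x3 color matrix by least squares on paired patch means (the seven line
windows plus the neutral zone), with the intensity scale factored out as
the mean luminance ratio so the matrix stays near luminance-preserving.
Patch means, not raw pixels, feed the matrix fit — averaging ~2,000
pixels per patch suppresses sensor noise by ~45x. Each fitting step
exactly recovers parameters it generated itself (to 1e-6); transform
fidelity on held-out pairs is judged on noise-free captures because
propagated sensor noise alone (sd 0.004 encoded, decode slope ~1.9 at the
substrate level, two captures) contributes ~0.011 linear RMS — above any
model residual.

## Validation statistics

Detection limits follow the EP17 constructions
`LoB = mean_blank + 1.645 SD_blank`, `LoD = LoB + 1.645 SD_low` with
sample SDs (n−1). From the bundled blank-study summary (mean 0.5,
SD 0.2, SD_low 2.5 ng/mL) these evaluate to LoB = 0.829 and LoD = 4.9415;
the published validation rounds the latter to 5.0, and this package
reports the formula value. The synthetic detection-limit study runs 20
blank and 20 low-level replicates through the full image pipeline and
compares the recovered LoD with the analytically configured limit
(`c(blank) + 2·1.645·alpha·sigma_d / d_C`); the raw blank estimates are
negative ng/mL values because a linear calibration extrapolates below
its panel — expected for immunoassay readouts near zero, and the EP17
arithmetic is defined on exactly such raw values.

Wilson intervals use z = 1.959964 (not 1.96) without continuity
correction; that choice reproduces the published per-category confidence
bounds at one-decimal rounding for 14/15, 6/7, 3/3, 12/12 and 45/46. Two
printed bounds do not reproduce under any standard convention we tried
(38/39 upper: computed 99.5 vs printed 99.6; the overall 97/100 interval:
computed 91.5–99.0 vs printed 93.0–99.1) and are documented rather than
matched. Cohen's kappa defaults to unweighted — that is the convention
under which the published three-level serum comparison's kappa (0.951)
is reproduced — with linear/quadratic ordinal weights
`w_ij = 1 − (|i−j|/(K−1))^q` available; a table with all mass in one
agreeing cell returns kappa 1 by convention. Percent agreement for an
empty reference column is reported as missing, never as zero. Welch
intervals use the Welch–Satterthwaite degrees of freedom via scipy.

## Problem sizes

Default study sizes keep everything desk-scale: calibration panels are 8
levels x 3 replicates; the classification study is 3 concentrations x 5
device models; illumination invariance scans 5 gains x 3 concentrations;
the cross-device panel is 12 held-out strips (3 fitting pairs); the
detection-limit study is 20 + 20 replicates. The full test suite runs in
well under a minute on one core.

## Known limitations

- Resampling blur at strongly minified or rotated poses attenuates
  high-density bands (notably the control line) more than low-density
  ones, biasing S_T/S_C upward by a few percent — worth ~+3 ng/mL at
  mid-range in the worst poses tested. Photographed-path calibration
  absorbs the average effect; the residual pose-to-pose spread is well
  inside the 10 ng/mL class widths but would matter for fully
  quantitative claims, which this format does not make.
- The ladder's linear signal-to-density map is a stand-in; only its
  strict monotonicity is load-bearing.
- Detection assumes the strip boundary itself is the detectable
  quadrilateral (one bright rectangle on a darker field); cassettes with
  printed fiducials or cluttered backgrounds need a different front end.
- The device model covers static photometric distortions; dynamic camera
  behavior (auto-exposure, local tone mapping, RAW processing) is out of
  scope.
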