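# Methods

This note documents the model behind `tlcquant`, the numerical choices
made where the procedure left room, what the synthetic data generator does
and does not emulate, and the known limitations.

## Physical model

A developed TLC plate carries a fluorescence indicator that glows under
254 nm UV light.  Analyte spots absorb the UV and appear dark; to first
order the *integrated darkening* of a spot is proportional to the amount of
analyte in the lane.  A photograph of the plate measures this darkening
multiplied by a smooth, uneven illumination field (the UV hand lamp is
small and close to the plate).  Quantification therefore needs three
things: geometric rectification of the photo, removal of the illumination
field, and a calibration mapping integrated darkening to content, anchored
by reference lanes of known concentration.

Because the relationship between integration value and content is assumed
(and empirically found) to be linear but with an unknown gain *and* offset,
the calibration line is fitted with an intercept, and two references of any
two distinct percentages suffice.

## Pipeline stages and numerical choices

**Colour handling.**  Photos are decoded as 8-bit sRGB and linearized with
the standard electro-optical transfer inverse before any densitometry;
luminance uses the Rec. 709 weights (0.2126, 0.7152, 0.0722).  A colorspace
tag on the image container makes double linearization a hard error.  A
config switch (`assume_srgb=False`) admits images already in linear
intensity.

**Plate detection.**  On a 4× block-mean downsampled luminance image:
Otsu binarization, boundary extraction, (ρ, θ) Hough transform with 1°
angular resolution, best line per side (left/right/top/bottom relative to
the foreground centroid), corner intersection, and scaling back to full
resolution at block centres.  Accuracy is limited by the ×4 quantization to
about ±2 px.  A nearly uniform bright image is treated as "the photo is
entirely plate"; a nearly uniform dark one raises a plate-not-found error
directing the user to manual corner entry.  Manual corners always override
detection.

**Rectification.**  Homography from the corner quad to an upright
rectangle whose width/height are the rounded means of opposite edge spans
(+1 px so a full-frame quad is the identity), bilinear interpolation.
Corner ordering (TL, TR, BR, BL) fixes the output orientation.

**Illumination model.**  The 15-term bivariate quartic is fitted by
ordinary least squares in coordinates normalised to [−1, 1]² (conditioning
of the quartic basis).  The fit runs on every 4th pixel in each direction.
Stride subsampling — rather than block averaging — is used deliberately:
the mean of a quartic over a block is a *different* quartic of the block
centre, so block averaging would bias the recovered surface by terms
proportional to the block's second moment, while subsampling keeps the fit
exact (to rounding) on any surface inside the model family.

By default the fit is two-pass: after the first pass, pixels whose residual
lies at or above the residual mean (i.e. candidate spot and pencil pixels)
are excluded and the surface is refitted.  This removes most of the spots'
leverage on the background estimate; sub-threshold Gaussian tails keep it
from being exact, but the remaining bias is far below the spot amplitudes.
Without the refit, the projection of the spots onto the quartic basis rings
across the background, and at very low noise the mean-threshold rule then
marks large spurious background regions.  A `background_model="constant"`
option replaces the surface with the plate mean, for studying what the
correction buys (see the off-centre-lamp analysis below).

**Residual sign.**  The residual is defined as *background minus image*,
so fluorescence-quenching (dark) spots have positive residual and the
threshold rule `t(v) = 1 iff v ≥ μ_I` (μ_I = residual mean) selects them
directly.  The literal opposite subtraction order would make spots negative
and the same threshold rule would select everything *but* the spots.  The
boundary comparison carries a few-ulp tolerance so a constant residual is
fully selected.

**Component filtering.**  8-connected components; removed are components
with bounding-box aspect ratio above 3 (or below 1/3 — pencil lines),
area below a minimum of 25 px specified at a 12-megapixel reference
resolution and scaled proportionally with plate area (floored at 4 px),
and area above a quarter of the plate.  Survivors are ordered by reading
order of their centroids.  All thresholds live in `AnalysisConfig`.

**Spot geometry and integration.**  Centre = residual-weighted centroid of
the component; radius = distance to the farthest member pixel + 1 px, so
the disk covers the whole spot.  Integration = sum of the top
`max(1, ceil(0.15·N))` residual values among the N pixels whose centres
fall in the disk (clipped to the image); ties are broken by row-major
pixel index so results are deterministic.  The "top 15%" rule makes the
value robust against the exact disk size to first order, but the
max-distance radius is still an extreme statistic of a noisy component
boundary — see Limitations.  Manually placed disks are integrated by the
identical code path.

**Calibration and reporting.**  OLS with intercept, percentage on
integration value; extrapolation beyond the reference range is allowed and
negative results only warn.  On-screen/CLI display rounds half away from
zero to integers and clamps negatives to zero; the JSON record always
keeps full precision.  `capture.json` keeps the five per-spot keys of the
bundle schema (`x`, `y`, `radius`, `integrationValue`, `percentage`)
verbatim and adds `role`, `referencePercentage`, `detection` and a
provenance block; unknown keys on read produce a warning, not an error.

## Synthetic plates

`synthetic.render_plate` composes scenes as

    plate = illumination(x, y) · base − Σ spots − pencil marks

with anisotropic Gaussian spots whose peak is `content ×
amplitude_per_percent`.  Integrated darkening is therefore *exactly* linear
in content by construction — linearity is the assumption the method rests
on, so the generator enforces it and the pipeline is judged on recovering
it.  Illumination presets (`central-lamp`, `off-center-lamp`,
`low-battery`) are quartic coefficient fields, matching the background
model family; one deliberately non-quartic `cosine4-vignette` preset
exists for model-mismatch studies.  Sensor noise is multiplicative
Gaussian per pixel, applied after composition; a per-spot multiplicative
amplitude jitter emulates manual 2 µl capillary spotting, which in
practice dominates measurement variability.  Optional perspective warp
embeds the plate in a dark canvas; optional JPEG re-encoding exercises
compression robustness.  All randomness flows from one explicit seed.

Default study conditions, chosen once: 450×330 px plates, base brightness
0.8, spot σ = 9 px, amplitude 0.0035 per percent.  These put the spot
coverage (~5% of plate area) and quenching depth (~30% of background at
100% content) in the range of real plates, which matters because the
mean-threshold detection rule only works when the residual mean (set by
total spot mass) exceeds the per-pixel noise floor, including 8-bit
quantization (~0.004 in linear units).  The repeatability noise profile
(`REPEATABILITY_NOISE`: sensor σ = 0.001, spot amplitude RSD = 0.0204) was
calibrated so that the *full pipeline's* pooled single-measurement RSD over
the standard repeatability design is ≈ 2.8%, the regime of the physical
method; pixel noise alone cannot reach that level without flooding the
threshold rule, which is the modelling reason for the spotting-jitter term.

What the generator does **not** emulate: spot tailing and crescent shapes,
Rf migration, chamber-saturation artefacts, lens distortion, camera PSF,
chromatic illumination gradients, or saturation/clipping.  Passing tests
therefore demonstrate the correctness and stability of the *algorithm*
under controlled conditions, not the field performance of the assay.

## Validation statistics

Sample statistics use the n−1 denominator throughout.  Recovery =
100·mean/true; RSD = 100·SD/mean; pooling across content levels uses
recoveries (measured/true), the convention under which measurements at
different contents are commensurable.  Linearity reports intercept, slope,
R, R², RSS from OLS of measured on true content (≥3 distinct levels).  The
intermediate-precision layout draws, per day, 6 of the 9 photo ×
investigator combinations without replacement (12 rows per analyte).

The one-sided OOS detection limit treats a single measurement of a sample
with true content p as N(p, ((RSD/100)·T)²) with T the specification
threshold (90% of declared):

    limit = T − z_c · (RSD/100) · T,  z_0.95 = 1.6449.

The SD is anchored at the threshold rather than at p because the decision
of interest is made at the threshold; this model reproduces both published
limit values for this method (85.9 at RSD 2.79; 83.4 at RSD 4.46), which
is the built-in correctness gate for the interpretation.

## Test problem sizes

The statistical-regime tests run the full image pipeline on rendered
plates: 14 analytes × 3 contents × 8 replicates (168 plates) for the
repeatability regime, ≥100 plates for the mean-recovery check, and 5
content levels × 3 replicates for linearity.  These sizes put the standard
error of the pooled RSD near 0.1 percentage points, small enough to test
the calibration of the noise model rather than sampling luck.

## Known limitations

* The max-distance spot radius is an extreme statistic; under blocky
  compression artefacts (JPEG quality ≤ 85 applied at plate resolution)
  automatically detected radii can shift by several pixels and move
  single-lane results by a few percentage points.  The robust workflow in
  that regime — also the one used for weak or oversized spots in practice —
  is manual spot placement, which integrates over fixed disks and is stable
  to <1 point under re-encoding.
* Plate detection assumes one bright plate on a dark surround and four
  dominant boundary lines; glare bridging plate and surround defeats it
  (manual corners are the fallback).
* The mean-threshold rule intentionally follows the original procedure; on
  very clean images it admits faint spurious components (they carry
  near-zero integration values and do not perturb calibrated results, and
  the annotation file supports deleting them).
* Quantification inherits a mild, smooth nonlinearity (≲0.5 points across
  the 60–100% range) from the content-dependence of the detected spot
  radius; it is part of the method, visible in the generator where ground
  truth is exactly linear, and small compared with single-measurement
  noise.
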