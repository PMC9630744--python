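# Methods

## Scope and model

`urolab` is a software re-creation of a bench instrument that grades an
athlete's hydration from the color of a urine sample in a 10 mm quartz
cuvette, photographed under a uniform LED light source. The package
covers everything downstream of the optics: color-space conversion,
grading, measurement from images, synthetic image generation, and
records/CLI. Hardware control, cloud upload and validation against
refractometry/osmometry (which require real urine and reference
instruments) are out of scope.

## Color conversion

RGB→XYZ uses the fixed 3×3 matrix given in the README applied to
channel fractions in [0, 1], multiplied by 100. The ×100 scaling is
forced by consistency: the Lab stage references the D65 white point on
the 0–100 scale (Xn = 95.047, Yn = 100.0, Zn = 108.883), and only with
the scaling does an all-white pixel give X/Xn ≈ 1 and hence L\* ≈ 100.

The companding function `f(t)` is the standard CIE piecewise form with
breakpoint (6/29)³; the branch condition is the strict inequality
`t > (6/29)³`. Both branches agree at the breakpoint to 1e−12, so the
choice is benign but fixed for determinism.

Gamma: by default the matrix is applied to raw channel fractions with
no sRGB decoding, reproducing the instrument's calibration path — its
grading scale was established on raw camera output under fixed
illumination. `srgb_gamma=True` enables standard sRGB decoding (and
re-encoding on the inverse path) for images from ordinary sources. The
two paths agree at black and white and differ in between.

The inverse (`lab_to_rgb`) is the exact algebraic inverse — inverse
companding, inverse matrix, ×255 — with rounding half away from zero
and clipping to [0, 255]. A triple is flagged out-of-gamut when any
pre-rounding channel leaves (−0.5, 255.5), i.e. when clipping changes
more than ordinary quantization would. All math is double precision;
the vectorized implementation is verified against an independent scalar
re-implementation to 1e−9.

Numerical note: the matrix's row sums (95.03, 99.98, 108.86) differ
slightly from the nominal white point, so pure white maps to
L\* = 99.992, not 100 exactly; pure black maps to (0, 0, 0) exactly
because the linear branch of `f` makes 116·(4/29) − 16 vanish.

## Grading

The table is derived at run time, never hard-coded: the regression
`b* = intercept + slope·Usg` (defaults −1220 and 1220) is evaluated at
the eight Usg thresholds 1.000 … 1.035, and the last grade is capped at
b\* = 127, the top of the axis. Grade intervals are half-open
`[b_low, b_high)` so the printed overlapping endpoints (6.1 belongs to
level 2, etc.) resolve to a partition; b\* = 127 itself still grades as
level 8. A Usg printed exactly on a threshold therefore belongs to the
upper level — an arbitrary but fixed tie-break.

Negative b\* (blue-shifted urine, e.g. dye interference) is clamped to
level 1 rather than rejected; the clamp is surfaced as a quality flag
by the measurement layer and via `classify_b_ex`. Physiologically a
negative b\* means the sample is not behaving like urine, so the level
should be read alongside the flag, not trusted alone.

Rehydration volumes read the guidance fractions literally: "up to
0.25%" is (0%, 0.25%), "drinking enough" is (0%, 0%). Fluid density is
taken as 1 g/ml, so frac% of body weight is `frac × weight_kg × 10` ml,
computed in that factor order so the printed examples (800–1200 ml at
80 kg, 900–1200 ml at 60 kg) are exact in floating point. Volumes are
not rounded. Weight is accepted on (20, 250) kg and height on
(80, 250) cm — generous sanity bounds, not physiological claims.

## Measurement from images

Pipeline: crop ROI → denoise → per-channel 10% trimmed mean (10% from
each tail) → optional affine calibration → round to 8-bit RGB → convert
to Lab. Aggregation happens in RGB and conversion happens once, in that
order, matching the instrument's recognize-then-convert sequence.

* **ROI.** The key-area geometry is not specified by the instrument's
  description; the default is the central 50%×50% window, which is also
  exactly where the synthetic generator places the cuvette. Configurable
  as fractional center/extent; a crop that leaves the frame is a
  geometry error, not a silent clamp.
* **Denoising.** Gaussian → bilateral → morphological opening/closing,
  mirroring the instrument's listed processing stages; each stage is
  individually disableable and zeros disable. Defaults enable only the
  bilateral stage (σ_color = 12 counts, σ_spatial = 2.5 px): it
  suppresses Gaussian sensor noise while leaving impulse outliers
  (specular highlights, debris) as outliers, which the trimmed mean
  then rejects. Gaussian pre-smoothing is off by default because it
  smears impulses into the background *before* robust aggregation —
  with it on, 5% salt-and-pepper contamination biases the measured b\*;
  with the default chain the shift is below 0.3. Morphology (radius 0 =
  off) is available for structured speckle.
* **Quality flags.** `clipped` when ≥10% of raw ROI pixels saturate at
  0 or 255; `low-pixel-count` below 100 px; `high-variance` when any
  denoised channel's std exceeds 20 counts; `negative-b-clamped` as
  above. Thresholds live in the config.
* **Calibration.** The "standard curve" is modelled as the simplest
  correction consistent with its purpose: a per-channel affine map in
  RGB space, least-squares fitted from ≥2 paired standard samples, with
  an exact identity short-circuit when measured equals reference.
  Degenerate (constant-channel) standards are a fit error.

The pipeline is fully deterministic: the same file and config give
bit-identical results, which is what lets the repeat-detection
stability of the instrument (Pearson r = 1 between two runs over a
100-sample panel) be reproduced exactly in software.

## Synthetic images

The generator inverse-renders a target b\* through `lab_to_rgb` into
the cuvette window of an image (default 160×120 px, window = default
ROI), surrounded by a dark border (60, 60, 60). Ground truth is defined
on b\* only; lightness and redness follow the plausible concentration
trajectory L\* = 90 − 0.55·b\*, a\* = 0.08·b\* (urine darkens and
reddens as it concentrates). These trajectory constants are arbitrary
by design and carry no meaning; only b\* is graded.

Noise is additive Gaussian in 8-bit RGB space (default σ = 2 counts),
clipped to [0, 255] — the simplest model that exercises denoising and
trimming. Radial vignetting is available but defaults to 0, since the
instrument lights samples with a uniform LED surface source. One
integer seed drives a single named stream; panels derive per-image
seeds as `seed + index`, so identical specs give byte-identical PNGs.

What the generator does *not* emulate: the cuvette meniscus and wall
refractions, illumination spectra, camera PSF and demosaicing, and the
biological scatter of real urine around the Usg↔b\* regression
(R² = 0.657 means individual samples deviate substantially). A green
recovery test therefore establishes that the software chain is exact
and stable, not that the instrument's biological validity claims hold.

Because the window fill must be quantized to 8-bit RGB, a rendered
sample's true b\* differs from the target by up to ≈0.4 near the yellow
end of the range (the blue channel is small there and b\* is steep in
it). The ±0.5 recovery tolerance covers exactly this quantization
floor; sub-quantization recovery is not achievable from 8-bit images.

Out-of-gamut targets: under the default trajectory, targets beyond
b\* ≈ 60 leave the RGB cube. The generator refuses them by default
(naming the offending channel); `allow_clip=True` clips the fill to the
cube and records the clip in the ground truth. This exists for
exercising the top grade: clipping moves b\* (e.g. a b\* = 84.85 target
renders at b\* ≈ 51) but stays well inside level 8's wide interval
[42.7, 127), so classification tests remain meaningful.

## Records and CLI

Storage is a single append-only JSON-lines file — durable, diffable,
and trivially concatenable — standing in for the instrument's host
database; CSV/JSON export (lossless round trip) stands in for cloud
upload. Reports render the level's guidance with computed volumes;
levels 7–8 append the sip-slowly caution (100–200 ml every 10–20 min).
The CLI (`simulate`, `analyze`, `grade`, `calibrate`, `review`,
`export`, `table`) is a thin layer over the library and adds no logic.

## Known limitations

* Grading inherits the regression's scatter: the mapping from b\* to
  Usg-defined levels is a population-level calibration, not a per-sample
  measurement of specific gravity.
* No automatic cuvette detection: the ROI is fixed geometry, valid for
  the fixed camera/cuvette layout it models.
* The sRGB flag covers gamma only; no ICC profiles or chromatic
  adaptation, and only the D65 white point.
* Synthetic fidelity as above — results on synthetic panels bound the
  software's error, not the instrument's.
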