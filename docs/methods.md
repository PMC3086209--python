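# Methods

## The measurement problem

Contact x-ray microradiography places a thin (~100 µm) tooth section
directly on fine-grain film; transmitted x-ray intensity, and hence film
grayscale after digitization, encodes the line integral of mineral density
through the section.  Comparing a *before* and an *after* radiograph of
the same specimen distinguishes two modes of acid damage:

* **erosion** — bulk surface loss: the density edge translates inward with
  its gradient preserved;
* **demineralization** — subsurface mineral loss: density is depressed
  over a depth but the surface does not recede, and by definition the
  lesion retains more than 20 % of sound density (deeper loss is counted
  as erosion).

`tmrquant` implements the full quantification chain on digitized films and
provides a phantom generator so that every step can be validated against
known ground truth.

## Film response model

The digitized negative responds to x-ray attenuation fraction *a* as

    G(a) = intercept + slope · r(a)

with `r` the identity on the linear band `[linear_lo, linear_hi]`
(defaults 0.10–0.90) and, outside it, a tanh roll-off
`bound ± c·tanh(|gap|/c)` matched in value and first derivative at the
band edges (`c = clip_softness`, default 0.05).  This is a stand-in: the
real film's characteristic curve is not quantified, only its linearity in
the working band and its saturation at the extremes.  The roll-off is
monotone and bounded, which is all the measurement chain relies on:
everything quantitative happens inside the linear band, which is exactly
why calibration restricts itself to the 10–90 % range.

`intercept` is brightness and `slope` is contrast; both vary between
radiographs (developer freshness, digitization lamp).  Because they enter
affinely, the two-point normalizations remove them *exactly* — this is an
algebraic identity, and the package tests it as one (invariance of
normalized outputs under `a·G + b`, `a > 0`, to 1e-9).

Grain is modeled as additive i.i.d. Gaussian noise (default sd 41
grayscale units ≈ 1 % of the 12-bit scale) applied before rounding and
clamping to the bit depth.  No spatial correlation (film MTF/grain size)
is modeled.

## Phantom geometry

Density varies only along the depth axis (image columns); column `c` sits
at depth `c · pixel_pitch_um`.  Ground truth:

    d_before(x) = clamp((x − s)/w, 0, 1)
    d_after(x)  = clamp((x − s − e)/w, 0, 1) ·
                  (1 − δ · clamp(1 − (x − s − e)/L, 0, 1))

with `s` the surface position (default 150 µm), `w` the edge width
(default 8 µm), `e` erosion, `L` demineralization depth and `δ ≤ 0.8` the
maximum fractional loss.  Attenuation is
`background + (sound − background)·d(x)` with `sound = 0.8` (inside the
linear band) and `background = 0`.  A metal grid fiducial (127 µm pitch,
24 µm bars, attenuation 10 ≈ opaque) is rendered as vertical stripes; its
bars are the raster maxima and serve as registration landmarks.  The
*after* exposure can be shifted by a whole number of pixels to emulate
film repositioning; the shift is applied in pixel units before scaling to
micrometers so a shifted scene is bit-identical to the translated
unshifted one.

The default `w = 8 µm` is the smallest edge width whose 25–75 % band spans
at least three samples at the coarser calibration (1.11 µm/px), the
minimum for the gradient fit.  Physically it represents a slightly
rounded/beveled polished edge; perfectly sharp edges are not resolvable by
this estimator at that pixel pitch.

What the phantom does **not** emulate: 2-D lesion shapes, beam hardening,
film MTF, development gradients across a film, specimen tilt.  Passing the
recovery experiments therefore demonstrates correctness of the *analysis
chain* under the stated noise/jitter model, not robustness to every
artifact of real films.

## Step-wedge linearity

Each radiograph's per-step ROI means are normalized by an affine map
sending two user-chosen anchor steps to 20 % and 80 % (anchors are
explicit; `choose_anchor_steps` only proposes the steps nearest those
fractions of the observed range).  Repeats of a wedge are averaged per
step; the pooled averaged values are fitted against step index over the
points lying within 10–90 %, and r² is the squared Pearson correlation.
The pass flag defaults to r² ≥ 0.9959 (configurable).  Conventions:
population sd for pixel ROIs (the ROI is the entire region of interest),
sample sd (n−1) for across-wedge spread (an estimate of process
variability).  The wedge abscissa is step index, not thickness: the folded
aluminum wedge has uniform thickness increments, and the step thicknesses
themselves are not part of the record.

## Measurement chain

1. **Extract** — ROI averaged across its width (arithmetic mean, 64+ px
   wide in practice) into grayscale vs depth, exterior → interior.
2. **Register** — grid-bar maxima detected (prominence ≥ 8 % of profile
   range, separation ≥ half the grid pitch; positions refined to the
   centroid of the half-prominence plateau).  The integer offset
   minimizing matched-peak squared distance (more matches first, then
   cost, then smaller |offset|) is applied to the after profile.
   Registration is integer-pixel by design; sub-pixel precision enters
   later through interpolated crossings.  A matched-peak rms residual
   above 1 px is a hard alignment error.
3. **Normalize** — background window → 0 %, sound-enamel window → 100 %
   (windows are user-specified index ranges; for phantoms they are derived
   from the known geometry, avoiding grid bars).  Grid peaks may exceed
   100 %: metal out-attenuates enamel.
4. **Gradient fit** — least squares through the outermost contiguous run
   of before-profile samples in the 25–75 % band (a margin inside the
   film's 10–90 % trusted range).
5. **Erosion** — closed form: `x_after(20 %) − x_line(20 %)`, the
   depth-axis distance between the before-gradient line and the parallel
   line through the after profile's 20 % crossing.
6. **Demineralization** — deficit `before(x − e_reported) − after(x)`
   scanned from the interior; depth = lesion front − surface reference.

## Zero-calls and front estimation (design choices)

Three estimator details matter near the noise floor and are deliberate
design choices of this package:

* **Foot-coincidence zero-call for erosion.**  A surface-touching lesion
  of severity δ drags the after profile's 20 % crossing inward by about
  `0.2·w·δ/(1−δ)` even with zero true erosion, because the lesion flattens
  the rising edge.  The surface *foot* (first 5 % crossing) is far less
  sensitive to δ.  If the two feet coincide within 2.5 px the erosion is
  called zero; otherwise the closed-form distance is reported.  Negative
  apparent erosion clamps to zero within `max(ε/slope, 1 px)` and raises
  beyond it (apparent surface gain = registration/polarity fault;
  remineralization is out of scope).
* **Front extrapolation.**  The deficit tail decays roughly linearly
  (slope ≈ δ/L per µm in density units), so its first excursion above the
  tolerance ε undershoots the true front by `ε·L/δ`.  The ε-crossing is
  therefore interpolated sub-pixel and extended to the zero-deficit
  position using the local deficit slope (least squares over the 4–5
  samples on the lesion side of the crossing, extension capped at
  `max(5 px, 5 µm)`).
* **Surface reference.**  Depth is referenced to the before-gradient
  line's zero-density position advanced by the reported erosion — an
  estimate of the true (possibly receded) surface that is independent of
  lesion severity, unlike the after profile's 20 % crossing.

The noise tolerance ε defaults to `max(3 × sd of the normalized
sound-window, 2 percentage points)`.  The floor keeps zero-calls
well-defined even on noise-free inputs, where the discrete pixel grid
alone produces sub-percent residuals.  The classification tolerance
`eps_distance_um` (default 1 µm) decides when a distance counts as
present; measurements below roughly one pixel pitch are not meaningful —
the original system's precision was pixel-limited as well.

## Numerical conventions

* 0-based pixel indices; ROIs and windows half-open `[start, end)`;
  positions at pixel centers, `x = index · µm/px`.
* Interpolation: linear everywhere (threshold crossings, deficit
  compensation shift).
* Alignment candidates: all rounded pairwise peak differences; ties by
  smaller |offset|.
* 12-bit data live unscaled in uint16 containers, 0–4095.
* All randomness flows from one integer seed per run
  (`numpy.random.default_rng`; experiments spawn per-case sub-seeds via
  `SeedSequence`).

## Validation experiments and problem sizes

The replication experiments (`tmrquant.experiments`) use deliberately
compact rasters — 96 × 1600 px at 0.305 µm/px, 96 × 512 px at 1.11 µm/px,
100 × 100 px wedge ROIs — sized so the profile noise after width-averaging
(≈ 0.15 % of the density scale) matches the regime where the estimator
tolerances were designed; larger rasters only reduce noise further.

* Wedge linearity: 6 wedges × 6 radiographs, 6 steps evenly spaced in
  attenuation 0.15–0.85, ±5 % brightness/contrast jitter, noise 0.5 % of
  full scale; pooled r² ≈ 0.99999.
* Erosion recovery: 50 phantoms, e ~ U[0, 50] µm at 0.305 µm/px, noise 1 %
  of full scale: 98 % within one pixel pitch.
* Demineralization recovery: 50 phantoms, L ~ U[5, 30] µm, δ ~ U[0.2, 0.8]
  at 1.11 µm/px: 98 % within two pixel pitches, erosion zero-called in
  all.
* Registration: 100 noiseless pairs, shifts U{−200, …, 200} px: all exact.

The residual ~2 % failures are structural, not noise: true erosion inside
the foot-coincidence window (≲ 0.76 µm) is zero-called, and very shallow
small lesions (δ ≈ 0.2, L ≈ 5 µm) can overshoot the front extrapolation by
slightly more than two pixels.

## Known limitations

* No conversion to absolute mineral density units (g/cm³); the step wedge
  verifies linearity only.
* No integrated mineral-loss area (ΔZ-style) parameter; depth at a density
  percentage is the reported lesion descriptor.
* No remineralization metric: apparent surface gain raises an error.
* Integer-pixel registration; profiles with fewer than one grid peak per
  exposure cannot be registered.
* The film model is phenomenological; quantitative claims about real films
  are limited to the linear band.
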