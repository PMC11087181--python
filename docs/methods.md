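# Methods

This note documents the models, conventions, parameter choices and known
limitations of scintshot's star-shot analysis. It states how each quantity
is defined and computed; all empirical numbers it refers to are the ones
computed by the test suite and `scripts/acceptance.py`.

## Coordinate conventions

All raster modules share one frame: pixel (0, 0) is the *center* of the
top-left pixel, x grows rightward along columns, y grows downward along
rows, and millimetre coordinates are `pixel × pixel_pitch_mm` on the same
axes. Report vectors (the deviations written to summaries) are mapped to
conventional y-up axes by negating the raster y difference; this happens
only in `scintshot.report.deviation` and is the single place the flip can
be configured.

A beam at gantry angle θ appears as a stripe along the raster direction
(cos θ, sin θ): θ = 0 is horizontal, θ = 90° vertical, and angles 180°
apart give the same line, as they must for opposed beams. The signed
per-beam offset displaces the stripe along the left normal (−sin θ, cos θ).
Since line orientations only matter mod 180°, the choice of which of the
two possible screen orientations corresponds to θ = 0 is a convention; it
is applied consistently by the renderer and checked (mod 180°, tolerance
3°) by the extractor.

## Star-line extraction

The composite star-shot image is the per-pixel **maximum** of the per-angle
frames. The maximum is idempotent and saturation-safe: merging a frame
with itself or with a blank frame changes nothing, and frame order is
irrelevant. (A sum-based composite would be equivalent for line *positions*
but can clip at the bit depth where stripes overlap.)

Lines are extracted from a ring profile:

* The ring radius is `ring_radius_frac × min(image dims)` (default 0.35,
  large enough that beam crossings are well separated and the cross-fire
  region near the center is avoided, small enough to fit any tentative
  center reasonably off-middle).
* The profile is bilinearly sampled at ~2 samples per pixel of arc,
  averaged over a ±3 px radial band, and smoothed with a circular Gaussian
  of 2 samples. To first order the angular position of a stripe crossing
  is independent of ring radius, and both the band average and the
  smoothing are symmetric about each peak, so they suppress sensor noise
  without biasing the FWHM midpoints. Empirically (acceptance ensemble)
  this brings the isocenter error at noise σ = 3 on an 8-bit image from
  ≈ 0.1 mm down to ≈ 0.01–0.03 mm.
* Peaks need a prominence of a quarter of the profile span above the
  median background and a minimum separation of 8°; each peak's angular
  FWHM midpoint is computed by linear interpolation of the two
  half-maximum crossings (the peak's own half-maximum, above the median
  background).
* Midpoints are paired greedily by smallest deviation from 180° apart
  (tolerance 10°, deterministic ordering by angle); each pair of ring
  points defines one infinite line. Any unpairable peak aborts the
  extraction — a clean star pattern has none.
* The whole pass runs twice: the preliminary lines give a preliminary
  minimum circle, and the ring is re-centered on it once. This removes the
  second-order asymmetry that an off-center ring induces in the angular
  profile.

The pair quality reported per line is `1 − mismatch/tolerance` of its
180°-pairing mismatch, in (0, 1].

## Radiation isocenter

The point-based definition is primary: every pair of
star-lines with mutual angle ≥ 5° is intersected (15 points for six
beams), and the **minimum enclosing circle** of the intersection points is
computed with Welzl's move-to-front algorithm, exact up to floating point,
deterministic via a fixed internal shuffle seed. The circle's center is the
radiation isocenter, its radius the wobble measure. The support set (2 or
3 points on the boundary) is returned and checked by tests.

A known alternative used by some star-shot tools — the Chebyshev center
minimizing the maximum point-to-*line* distance, a 3-variable linear
program — is provided behind `line_distance_variant` and reported
alongside, never silently substituted. For concurrent lines the two
definitions agree.

## Fiducial detection

**Steel ball.** The image is lightly smoothed (Gaussian, σ = 2 px) before
Otsu thresholding: the ball occupies ~10⁻⁴ of the frame, and on the raw
noisy image the threshold collapses into the background mode (Otsu's
criterion is unreliable under extreme class imbalance). Dark regions are
labelled; candidates are filtered by equivalent radius √(A/π) within the
configured window and scored by circularity 4πA/P²; the winner must beat
the runner-up by ≥ 1% circularity, otherwise the detection is ambiguous.
The reported center is the darkness-weighted centroid (weights
`background − I` clipped at 0, over the region padded by 2 px): it is
invariant to affine intensity rescaling, coincides with the geometric
center on symmetric renders, and is unbiased under zero-mean noise.

**Laser cross.** Profiles are sampled every `sample_interval_px`
(default 100; the phase defaults to centered, i.e. offset interval/2, and
is configurable). Each profile's strip center is the midpoint of the two
half-maximum crossings around the global peak, with the profile median as
background — the same FWHM primitive used on the ring profile. A peak
below 3× background is rejected as low contrast (profiles inside the
perpendicular strip's glare reject themselves this way). Samples whose
measured strip width exceeds twice the median width are discarded: a
profile that grazes a near-parallel strip sees a very wide blob, not the
8–10 px laser. Each strip's centers get a total-least-squares line fit
(principal direction of the centered points), the two lines must cross at
≥ 45°, and after a preliminary intersection all samples within two strip
widths of the cross (where the strips overlap and profiles are bimodal)
are excluded and the lines refitted once.

## Camera model

Brown–Conrady distortion with two radial (k1, k2) and two tangential
(p1, p2) terms acting on normalized coordinates about the principal point.
The forward map is closed-form; undistortion is a fixed-point iteration
converging below 10⁻⁶ px (cap 100 iterations, divergence raises an error).
Rectification is applied to *extracted point coordinates* (ring points,
fiducial centers), never by resampling images, avoiding interpolation
artifacts in sub-pixel estimates; for point estimates the two are
mathematically equivalent. A model comes from config or from
`fit_distortion`, a linear least-squares fit of the four coefficients from
matched ideal/observed point pairs (e.g. checkerboard corners from any
corner locator) — the distortion equations are linear in the coefficients,
so no iterative bundle adjustment is needed. Because the star-lines cross
near the principal point, where the distortion field vanishes, enabling or
disabling a realistic mild model moves the recovered isocenter by well
under 0.1 mm (asserted in tests at ≤ 0.07 mm).

The pixel pitch comes from config, from a scanner's dpi (25.4/dpi — 300 dpi
film scans give 0.0847 mm/px), or from a fiducial of known length. The
camera operating scale used throughout the synthetic studies is
0.16 mm/px.

## Synthetic phantom

The renderer emulates what the analysis needs to be true of real images:

* **Beam frames** — one stripe per gantry angle with a Gaussian
  perpendicular intensity profile (σ default 2 mm, a typical proton-spot
  scale on a scintillator sheet; exposed as a parameter since it is a
  machine property), spanning the field of view, peak 200 on a background
  of 6 (8-bit scale, ×257 for 16-bit).
* **Ball image** — dark disk (level 25) on a bright ambient field (180)
  with area-coverage anti-aliased edges.
* **Laser image** — two perpendicular strips of configurable width
  (8–10 px, i.e. 1–1.5 mm at the camera scale), optionally rotated, on a
  dark background (room lights off). Strip edges are top-hat profiles seen
  through a Gaussian camera PSF (σ default 0.7 px, erf edges): a perfectly
  sharp 1-px ramp is both unphysical and under-resolved, and would alias
  the FWHM midpoint by up to ±0.08 px depending on the sub-pixel phase.
  The erf edge keeps the FWHM exactly at the nominal width.
* **Noise** — additive Gaussian (σ in intensity units) applied before
  clipping to the bit depth, with independent seeded streams per image
  type so a whole phantom set is reproducible bit-for-bit from one seed.
  Optional salt-and-pepper flecks emulate stray sensor hits.
* **Distortion** — when a camera model is attached, each raw pixel is
  assigned the scene value at its undistorted position, i.e. the image is
  warped exactly as the model describes.

Not emulated: scintillator light-yield physics and aging, optical
vignetting, beam divergence/scattering along the stripe, secondary-particle
CCD spikes beyond the salt-and-pepper option, and camera perspective tilt.
Passing tests therefore demonstrate the *analysis chain's* correctness and
noise robustness under a faithful geometric model, not the physics of any
particular scintillator or camera.

## Study conditions and problem sizes

The synthetic studies use a 960×960 px field at 0.16 mm/px (a ~154 mm
square, comfortably containing the star pattern), six beams at gantry
angles 240/300/0/30/90/150°, per-beam offsets drawn uniformly from
±0.5 mm (producing sub-millimetre minimum-circle radii, the regime of
interest for QA), and 8-bit noise σ = 3 for beams and lasers, σ = 5 for
the ball. Fiducial ensembles run on a 640×640 px field, which the
detections do not depend on. The recovery ensemble is 20 seeded sessions;
the fiducial ensemble 200 seeded renders. The independent oracle for
end-to-end recovery is the minimum circle of the *analytically*
intersected true beam lines; for the minimum circle itself, an exhaustive
O(n⁴) enumeration over all pair-diameter and triple-circumscribed circles.

## Numerical choices

* Half-maximum crossings: linear interpolation between the two bracketing
  samples, walking outward from the peak; profile edges are treated as
  crossings if reached (degenerate, flagged by contrast checks upstream).
* Collinear triples in the circle solver fall back to the widest
  two-point circle; the containment test uses a relative epsilon of 1e-12.
* Parallel-line intersection tolerance 0.1°; line orientations are
  canonicalized to the upper half-plane so every line has one
  representation.
* Summary statistics use the population SD (divisor n). Rendered report
  values are rounded half-away-from-zero at 2 decimals via decimal
  arithmetic, locale-independent; full precision is kept internally and in
  CSV round-trips.
* Session CSVs are parsed row by row so a malformed value is reported
  with its row number.

## Known limitations

* The analysis is strictly 2-D: it measures the isocenter in the
  star-shot plane and cannot resolve the component along the beam-axis
  normal, the same limitation as film star-shots.
* Ring extraction assumes every beam crosses the sampling ring twice;
  beams masked to a small central region (supported by the renderer)
  need a correspondingly smaller ring fraction.
* Otsu-based ball detection assumes the ball is the darkest compact
  object; heavy vignetting or debris of ball-like size would need the
  radius window tightened.
* The camera is assumed rectified in mounting (no perspective
  homography); only lens distortion is modelled.
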