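# Methods

This note documents the models behind `fgskit`: what the simulator assumes,
which parameters matter, how the measurements are computed, and where the
approximations end. Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate and unit conventions

Image coordinates are 0-based and real-valued, origin at the top-left pixel
center, x rightward along columns, y downward along rows. All lengths are
millimetres internally; irradiance is mW/cm²; intensities live in [0, 1].
Homographies are normalized to h₃₃ = 1 when that entry is non-negligible
(above 1e-8 of the largest entry), otherwise to unit Frobenius norm, and are
serialized as a row-major 9-entry JSON list plus the convention tag.

## Camera model

An ideal pinhole: focal length f, pixel pitch p, resolution, principal point,
pose, and bit depth. The default sensor preset uses f = 3.04 mm with an
effective pitch/f ratio of 3.0e-4 per pixel, i.e. 0.15 mm of scene per pixel
at a 50 cm working distance at full resolution (3280 × 2464). That ratio is
chosen so the documented pixel↔scene conversion of the device class (20 px ≈
3 mm at 50 cm) holds exactly; it does not match the physical 1.12 µm pitch of
the underlying sensor die at full resolution, because the capture mode
(crop/binning) behind the reported conversion is not uniquely determined. The
ratio, not the die geometry, is what every scene-space statement depends on,
so the discrepancy is documented rather than resolved. `CameraModel.rpi_v2(binning=k)`
divides the pixel count and multiplies the pitch by k, leaving the field of
view and all scene-space geometry unchanged; tests run at binning 4–8 for
speed, the acceptance script at binning 2. No lens distortion, rolling
shutter, or chromatic aberration is modeled.

## Homography estimation

Direct linear transform with Hartley pre-normalization (translate centroids to
the origin, scale mean radius to √2), solved by SVD; the smallest right
singular vector gives the solution, and a collapsing eighth singular value
flags a degenerate configuration. The fit is exact (residual < 1e-9) on
noiseless minimal 4-point and consistent over-determined input. Minimal
4-point sets are rejected when any three points are collinear within 1e-6 of
the bounding-box diagonal. Warping uses inverse mapping with bilinear
(default) or nearest interpolation; out-of-source samples are zero-filled.

## Scene simulator

**Targets** are fronto-parallel planes: resolution targets (bright square
fiducials plus line-pair bar groups on a dark background), uniform cards, and
black well plates. Patterns are rendered with analytic anti-aliasing — every
edge gets a linear coverage ramp one sample-footprint wide — which is what
makes sub-pixel centroid and bar-peak localization meaningful.

**Illumination** is a circular array of three Gaussian beams starting on a
circle of radius d = 30 mm, aimed to cross the optical axis at L = 400 mm
(inclination θ = arctan(d/L) ≈ 4.3°). At plane z each beam center sits at
radius d·(1 − z/L); the 1/e² radius grows linearly, w(z) = w₀ + 0.05·z with
w₀ = 12 mm, and the per-beam peak falls as (w₀/w)². The per-beam source peak
(47 mW/cm²) was set once so the array delivers roughly 20 mW/cm² on-axis at
40 cm, decays toward 5–10 at 60 cm, and exceeds 5 mW/cm² over ≈ 5 cm diameter
at 50 cm — the operating regime of this instrument class. Beam parameters are
config-exposed and not asserted by tests. No diffraction or speckle. A
`UniformIllumination` variant (default 20 mW/cm²) emulates the motorized-stage
protocol that repositions each well to a constant irradiance.

**Channels.** The visible channel sees reflectance times a white-light level
(default 0.85). The NIR channel folds the excitation filter into a single
scalar leak fraction ℓ and the fluorophore response into an emission gain k:

    I = min(1, k·C·E + ℓ·E·ρ + ambient·ρ)

with C the local concentration (molar), E the excitation irradiance (zero
when the laser is off), ρ the surface reflectance. The four filter presets
set ℓ so that a white card (ρ = 1) at the 20 mW/cm² reference irradiance
reproduces the measured maximum leak intensities 0.53 (single 830 nm LP),
0.082 (double 830 nm LP), 0.106 (832 nm BP), and 0.090 (808 nm LP) — the
filters are characterized by exactly this number, so the calibration is by
construction. The default emission gain k = 8.2e4 intensity/(M·mW/cm²) places
the sensitivity knee (k·C = ℓ·ρ) at 1 nM on a 2%-reflectance black plate
behind the double-830 filter: sub-nanomolar wells sit near the plateau and
the 1–100 nM range rises log-log linearly, the qualitative behavior of the
physical phantom. The scalar-leak model has no wavelength axis; spectral
effects (laser NIR tail, filter edge shapes) are outside it, which is the
main reason sub-nanomolar behavior of real filters is only qualitatively
reproduced.

**Noise** is applied in physical order: Poisson shot noise at a full-scale
photoelectron count (default 5000), additive Gaussian read noise (default
1/255, one 8-bit step), then round-to-nearest quantization to the camera bit
depth (default 8, matching the device class) and clipping. `noise=None`
yields the exact continuous forward model, used wherever a test needs
algebraic identities. All noise flows through `numpy` Generators seeded from
explicit integers; per-frame generators are spawned from the stream seed, so
streams are bit-reproducible and frames are mutually independent.

**Streams.** Frame period is round(1000/fps) ms (33 ms at 30 fps); the laser
trigger period is twice that (66 ms). The laser-on window lasts `duty` frame
periods (default 0.70). Exposure is modeled as ending 70% of the way through
the nominal period with the next readout starting immediately, so a frame's
excitation term scales by min(duty, 0.7) and any excess duty − 0.7 bleeds
into the following frame — the mechanism by which longer excitation windows
contaminate consecutive frames. By default the second frame (index 1) is
laser-on; the phase is configurable.

## Stream processing

Background subtraction is sliding — ΔFₙ = |Fₙ − Fₙ₋₁| for every n ≥ 1 — so
the output runs at the full input rate (one frame fewer in total), matching a
real-time display pipeline; half-rate non-overlapping pairing is available
separately for SBR work (`pair_on_off`). Differences are computed in float,
so integer wraparound cannot occur at any source bit depth. When laser-state
metadata is absent, parity is recovered from mean intensities with a
configurable relative-margin threshold (default 1%); below it the decision is
refused rather than guessed.

## Quantification

The leak threshold is max(ON − OFF) on a uniform non-fluorescent card.
Per-pixel SBR is (ON − OFF)/leak with negatives clipped to zero before the
ratio (8-bit noise drives differences negative; clipping keeps the map
non-negative without biasing bright regions). Well SBR uses the ROI mean by
default (median by flag); duplicate wells are averaged after per-well SBR so
per-well variance stays estimable. Well ROIs are the projected well discs
shrunk to 80% radius to keep soft edges out of the statistic. Only ON−OFF
subtraction is performed; no additional dark or off-plate region is
subtracted. The sensitivity fit splits points at SBR 1.5 (the same threshold
used for overlay masking; config-exposed): below is the plateau (reported as
a mean), the rest is fitted by OLS on (log₁₀C, log₁₀SBR). With the knee at
1 nM and the fixed dilution grid, several grid points fall in the knee
transition where log(1 + x) is not yet linear, so the quantitative
slope/plateau recovery test uses plates spanning the deep plateau
(k·C/(ℓ·ρ) ≈ 0.01) and the clean linear regime (10–500); the standard
dilution plate is checked for the qualitative shape (monotone rise, plateau
at the sub-nanomolar end, local slope ≈ 1 at the top).

## Alignment audits

Fiducials are detected by mid-intensity thresholding, connected components,
an aspect-ratio filter that rejects elongated bar groups, and an
intensity-weighted centroid over a 2-px-expanded window with
background-subtracted weights (thresholded weights cut the anti-aliased edge
ramp asymmetrically and bias the centroid by ~0.1 px; background-subtracted
weights keep it near 0.01 px). Centroid sets from the two views are matched
by their arrangement after centering (Hungarian assignment). Bar-group
offsets use profile extraction across the projected group ROI, coarse maxima,
and a windowed-centroid sub-sample refinement; flat-topped bars defeat
three-point parabolic interpolation, which is why the centroid window is used.
Errors are reported as the mean over fiducials (or bar peaks) per axis, in
pixels and in scene mm via the eye camera's mm-per-pixel at the target plane.

Mount presets encode the raw overlay offsets of the three head-mount
positions as baselines with parallel optical axes: forehead (26.5, 69.5) mm,
between-eyes (23.0, 36.9) mm, and coaxial — shared optical center with the
residual mounting offset (3.4, 17.3) mm at 50 cm expressed as a sensor shift.
Parallel axes make raw offset equal baseline exactly; the physical
between-eyes mount evidently included a tilt (its reported corrected vertical
error is smaller than pure-translation parallax allows), which is documented
here rather than reproduced by tuning a hidden tilt parameter. The distance
sweep calibrates once at d_cal, holds the homography fixed, and records raw
and corrected errors per distance; residuals default to the fiducial-centroid
method, with the line-pair method available and cross-validated against it.
The closed-form parallax oracle B·|d/d_cal − 1| is verified against the
rendered pipeline to 2%.

## Illumination analysis

The thermal power estimator is the linear rescaling
P = max(0, ΔT)/ΔT_max · P_max — heating proportional to absorbed power,
uniform absorptivity, no diffusion correction, exactly invariant to constant
offsets. Coverage above a threshold reports the pixel-count area and the
area-equivalent circle diameter, since a multi-beam footprint is not exactly
circular.

## Reproducibility and problem sizes

Every randomized path consumes randomness only through explicit seeds; the
experiment layer forks one top-level seed into per-module substreams keyed by
a stable CRC-32 of the module name, so adding an experiment never perturbs
another's draws. The test suite renders at binning 4–8 (410×308 to 820×616
pixels) and the acceptance script at binning 2 (1640×1232); binned and full
modes share identical scene-space geometry, and the chosen sizes keep the
whole suite under a minute while leaving sub-pixel localization comfortably
below the tolerances being tested. The parameter-recovery check uses 20
seeded replicate plates of 8 ON/OFF pairs each.

## What passing tests do and do not show

The simulator demonstrates internal consistency: the processing chain
recovers exactly the quantities the forward model encodes (parallax law,
leak-normalized SBR algebra, background-removal identities) and does so
through the full rendered-image path, not just symbolically. It does not
model tissue scattering or depth attenuation, motion, autofocus, spectral
filter edges, sensor fixed-pattern noise, or geometric lens distortion;
agreement of the real instrument with these predictions depends on those
effects being small or calibrated out, which the simulation cannot certify.
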