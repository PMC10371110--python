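# fgskit

A simulation and image-processing toolkit for wearable fluorescence-guided-surgery
(FGS) optics. It reproduces, entirely in software, the computational pipeline of a
head-mounted near-infrared (NIR) imaging system: frame-synchronized excitation with
background subtraction, projective-transform coalignment of camera pairs,
signal-to-background-ratio (SBR) quantification of fluorescence phantoms, and
laser-array illumination analysis. A built-in optical simulator stands in for the
hardware, so every experiment runs at desk scale from a seed and a config.

**Who it is for.** People building or evaluating low-cost FGS instrumentation
(augmented-reality goggle systems, dual visible/NIR camera heads, pulsed laser-diode
excitation) who want a quantitative, reproducible software model of the processing
chain before — or instead of — touching hardware.

## The core models

**Synchronized background subtraction.** With the excitation laser triggered on
every other camera frame (66 ms trigger period at 30 fps), the absolute difference
of consecutive frames

&nbsp;&nbsp;&nbsp;&nbsp;ΔF<sub>n</sub> = |F<sub>n</sub> − F<sub>n−1</sub>|

removes every static contribution (ambient NIR room light, dark level) and
preserves the excitation-driven fluorescence, at the full input frame rate.

**Projective coalignment and parallax.** Two views of a planar scene are related by
a 3×3 homography **H**, estimated here by a Hartley-normalized direct linear
transform on ≥ 4 fiducial correspondences. For a camera pair *sharing an optical
center* (beamsplitter design) one calibration is valid at **every** working
distance. For a camera displaced from the eye by a baseline *B* parallel to the
image plane, a homography calibrated at distance *d*<sub>cal</sub> leaves a
scene-space residual

&nbsp;&nbsp;&nbsp;&nbsp;e(d) = B · |d / d<sub>cal</sub> − 1|,

the parallax penalty of every non-coaxial see-through mount.

**SBR.** Per-pixel SBR divides the background-subtracted intensity by the
excitation-leak threshold (the maximum ON−OFF intensity on a non-fluorescent white
card), so SBR = 1 marks signal indistinguishable from leaked excitation light.
Well-plate SBR divides each well's mean background-subtracted intensity by the
zero-concentration control well. Under the simulator's forward model
I = k·C·E + ℓ·E·ρ + ambient, the well SBR is 1 + k·C/(ℓ·ρ): flat near 1 at low
concentration, log-log linear with slope 1 at high concentration.

## Worked example

Audit a forehead-mounted imaging camera (69.5 mm vertical / 26.5 mm horizontal
offset from the eye) calibrated once at 50 cm:

```python
from fgskit import MountGeometry, distance_sweep, parallax_error_closed_form

rep = distance_sweep(MountGeometry.forehead(), d_cal=500.0,
                     distances=[400.0, 500.0, 600.0])
print(rep.to_frame()[["distance_mm", "raw_v_mm", "raw_h_mm",
                      "corr_v_mm", "corr_h_mm"]].round(3).to_string(index=False))
print("closed form at 400 mm:", parallax_error_closed_form(69.5, 400.0, 500.0))
```

Output:

```
 distance_mm  raw_v_mm  raw_h_mm  corr_v_mm  corr_h_mm
       400.0    69.500      26.5     13.899        5.3
       500.0    69.501      26.5      0.000        0.0
       600.0    69.500      26.5     13.901        5.3
closed form at 400 mm: 13.899999999999997
```

The raw overlay offset equals the mount baseline at every distance; the 4-point
calibration zeroes the error at 50 cm but leaves ≈ 13.9 mm vertical / 5.3 mm
horizontal residual at ±10 cm — the measured pipeline agrees with the closed-form
parallax model to 0.1%. Swapping in `MountGeometry.coaxial_preset()` (beamsplitter,
shared optical center) drops the residual below 2 µm at every distance, which is
why the coaxial design is the one worth building.

The same audits are available from the shell:

```bash
fgskit audit --preset coaxial --dcal 500 --dmin 400 --dmax 600 --step 10
fgskit run sensitivity --seed 1 --out out/
```

## Layout

| module | contents |
| --- | --- |
| `fgskit.optics` | pinhole cameras, homography fit/apply/warp, fiducial detection |
| `fgskit.scene` | targets, phantoms, illumination, channels, noise, frame rendering |
| `fgskit.stream` | laser schedules, parity detection, background subtraction |
| `fgskit.quantify` | leak thresholds, well/per-pixel SBR, sensitivity fits, overlays |
| `fgskit.align` | mount geometries, calibration, distance sweeps, parallax oracle |
| `fgskit.illum` | thermal-pair power maps, beam inclination, irradiance coverage |
| `fgskit.io` / `fgskit.experiments` / `fgskit.cli` | streams on disk, experiment bundles, CLI |

See `docs/methods.md` for the underlying models, parameter defaults, and known
limitations.
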