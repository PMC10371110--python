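"""Synthetic optical scenes: planar targets, phantoms, illumination, frames.

The simulator renders what the imaging head sees: a planar target
(resolution target, uniform card, or fluorescent well plate) placed
fronto-parallel at a working distance, illuminated by a converging
laser-diode array, viewed through either a visible channel or an NIR
channel whose excitation filter leaks a small fraction of the laser
light.  Everything is deterministic under a fixed seed.

Forward model for the NIR channel (pre-noise, clipped to [0, 1]):

    I = k * C * E + l * E * rho + ambient

where ``C`` is the local fluorophore concentration (molar), ``E`` the
local excitation irradiance (mW/cm^2, zero when the laser is off),
``k`` the emission gain, ``l`` the scalar leak fraction of the
excitation filter, ``rho`` the local surface reflectance, and
``ambient`` the static room-light NIR level.  The visible channel sees
``rho`` times the white-light level.  Patterns are rendered with
analytic anti-aliasing: every edge gets a linear coverage ramp one
sample-footprint wide, so rendered centroids land on the geometric
truth to well below a tenth of a pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import BehindCameraError, ConfigError, DataError
from .optics import CameraModel

# Measured maximum leaked-excitation intensity (out of 1) on a white card
# for the four excitation-filter assemblies, at the reference irradiance.
FILTER_LEAK_INTENSITY = {
    "830lp": 0.53,
    "dbl_830lp": 0.082,
    "832bp": 0.106,
    "808lp": 0.090,
}
REFERENCE_IRRADIANCE = 20.0  # mW/cm^2 delivered at the characterization plane

# Emission gain chosen so that at the reference irradiance, on a 2%-reflectance
# black well plate behind the double-830 nm-longpass filter, the fluorescence
# term equals the leak term at 1 nM: the knee of the sensitivity curve sits
# just below the nanomolar range.
DEFAULT_EMISSION_GAIN = 8.2e4  # intensity per molar per (mW/cm^2)
DEFAULT_PLATE_REFLECTANCE = 0.02


def _soft_box(u, center, half_width, edge):
    """Coverage of a 1-D box with a linear anti-aliasing ramp of width ``edge``."""
    return np.clip((half_width - np.abs(u - center)) / edge + 0.5, 0.0, 1.0)


def _soft_disc(x, y, center, radius, edge):
    r = np.hypot(x - center[0], y - center[1])
    return np.clip((radius - r) / edge + 0.5, 0.0, 1.0)


@dataclass(frozen=True)
class FiducialSquare:
    center: tuple[float, float]  # mm in plane coordinates
    side: float  # mm

    def coverage(self, x, y, edge):
        return _soft_box(x, self.center[0], self.side / 2, edge) * _soft_box(
            y, self.center[1], self.side / 2, edge
        )


@dataclass(frozen=True)
class LinePairGroup:
    """A bar group of a resolution target.

    ``orientation`` follows the bar direction: "vertical" bars vary along
    x (they localize horizontal offsets), "horizontal" bars vary along y.
    """

    label: str
    frequency: float  # line pairs per mm
    bar_count: int = 5
    orientation: str = "vertical"
    position: tuple[float, float] = (0.0, 0.0)
    bar_length: float | None = None  # mm; default 2.5 periods

    def __post_init__(self):
        if self.frequency <= 0 or self.bar_count < 1:
            raise ConfigError("line-pair group needs positive frequency and bars")
        if self.orientation not in ("vertical", "horizontal"):
            raise ConfigError("orientation must be 'vertical' or 'horizontal'")

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    @property
    def length(self) -> float:
        return self.bar_length if self.bar_length is not None else 2.5 * self.period

    def bar_centers(self) -> np.ndarray:
        """Positions of bright-bar centers along the varying axis (mm)."""
        offsets = (np.arange(self.bar_count) - (self.bar_count - 1) / 2) * self.period
        along = self.position[0] if self.orientation == "vertical" else self.position[1]
        return along + offsets

    def bbox(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in plane mm."""
        span = (self.bar_count - 1) * self.period + self.period / 2
        if self.orientation == "vertical":
            w, h = span, self.length
        else:
            w, h = self.length, span
        return (
            self.position[0] - w / 2,
            self.position[1] - h / 2,
            self.position[0] + w / 2,
            self.position[1] + h / 2,
        )

    def coverage(self, x, y, edge):
        half_bar = self.period / 4  # bright bar fills half a period
        out = np.zeros(np.broadcast(x, y).shape)
        u = x if self.orientation == "vertical" else y
        v = y if self.orientation == "vertical" else x
        across = self.position[1] if self.orientation == "vertical" else self.position[0]
        envelope = _soft_box(v, across, self.length / 2, edge)
        for c in self.bar_centers():
            out += _soft_box(u, c, half_bar, edge)
        return np.clip(out, 0, 1) * envelope


def _bboxes_overlap(a, b) -> bool:
    return not (a[2] <= b[0] or b[2] <= a[0] or a[3] <= b[1] or b[3] <= a[1])


@dataclass
class ResolutionTargetSpec:
    """Planar resolution target: bar groups plus bright square fiducials."""

    groups: list[LinePairGroup] = field(default_factory=list)
    fiducials: list[FiducialSquare] = field(default_factory=list)
    background_reflectance: float = 0.08
    feature_reflectance: float = 0.95

    def __post_init__(self):
        boxes = [g.bbox() for g in self.groups]
        for i in range(len(boxes)):
            for j in range(i + 1, len(boxes)):
                if _bboxes_overlap(boxes[i], boxes[j]):
                    raise ConfigError(
                        f"line-pair groups {self.groups[i].label!r} and "
                        f"{self.groups[j].label!r} overlap"
                    )
        if len(self.fiducials) >= 3:
            pts = np.array([f.center for f in self.fiducials])
            # all fiducials on one line would make a projective fit degenerate
            centered = pts - pts.mean(axis=0)
            if np.linalg.svd(centered, compute_uv=False)[-1] < 1e-9:
                raise ConfigError("fiducial centers are collinear")

    def fiducial_centers(self) -> np.ndarray:
        pts = np.array([f.center for f in self.fiducials], dtype=float).reshape(-1, 2)
        order = np.lexsort((pts[:, 0], pts[:, 1]))
        return pts[order]

    def reflectance(self, x, y, edge):
        cov = np.zeros(np.broadcast(x, y).shape)
        for f in self.fiducials:
            cov = np.maximum(cov, f.coverage(x, y, edge))
        for g in self.groups:
            cov = np.maximum(cov, g.coverage(x, y, edge))
        return self.background_reflectance + (self.feature_reflectance - self.background_reflectance) * cov


def default_resolution_target() -> ResolutionTargetSpec:
    """Four corner fiducials plus one vertical and one horizontal bar group."""
    side = 10.0
    fids = [FiducialSquare((sx * 80.0, sy * 60.0), side) for sx in (-1, 1) for sy in (-1, 1)]
    groups = [
        LinePairGroup("v-0.2", frequency=0.2, bar_count=5, orientation="vertical", position=(0.0, -25.0)),
        LinePairGroup("h-0.2", frequency=0.2, bar_count=5, orientation="horizontal", position=(0.0, 25.0)),
    ]
    return ResolutionTargetSpec(groups=groups, fiducials=fids)


def group_one_target() -> ResolutionTargetSpec:
    """Target carrying 1.0 lp/mm groups (needs a fine pixel scale to resolve)."""
    side = 10.0
    fids = [FiducialSquare((sx * 80.0, sy * 60.0), side) for sx in (-1, 1) for sy in (-1, 1)]
    groups = [
        LinePairGroup("v-1.0", frequency=1.0, bar_count=5, orientation="vertical", position=(0.0, -10.0)),
        LinePairGroup("h-1.0", frequency=1.0, bar_count=5, orientation="horizontal", position=(0.0, 10.0)),
    ]
    return ResolutionTargetSpec(groups=groups, fiducials=fids)


# Standard dilution series of the IR-125 phantom plate (molar).
IR125_CONCENTRATIONS = (
    0.0,
    250e-12,
    500e-12,
    1e-9,
    5e-9,
    7.5e-9,
    10e-9,
    25e-9,
    50e-9,
    75e-9,
    100e-9,
)


@dataclass
class WellPlatePhantom:
    """Black well plate with fluorophore-loaded wells.

    ``concentrations`` is a (rows, cols) molar array; ``control`` names the
    single designated zero-concentration reference well.
    """

    rows: int
    cols: int
    pitch: float  # mm center-to-center
    well_diameter: float  # mm
    concentrations: np.ndarray
    control: tuple[int, int]
    plate_reflectance: float = DEFAULT_PLATE_REFLECTANCE

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.concentrations.shape != (self.rows, self.cols):
            raise ConfigError("concentrations must be a (rows, cols) array")
        if np.any(self.concentrations < 0):
            raise ConfigError("concentrations must be non-negative")
        r, c = self.control
        if not (0 <= r < self.rows and 0 <= c < self.cols):
            raise ConfigError("control well outside the plate")
        if self.concentrations[r, c] != 0:
            raise ConfigError("designated control well must have zero concentration")

    @classmethod
    def ir125_duplicate_plate(cls) -> "WellPlatePhantom":
        """Two duplicate rows of the standard dilution series, control at (0, 0)."""
        conc = np.tile(np.asarray(IR125_CONCENTRATIONS), (2, 1))
        return cls(
            rows=2,
            cols=len(IR125_CONCENTRATIONS),
            pitch=9.0,
            well_diameter=6.0,
            concentrations=conc,
            control=(0, 0),
        )

    def well_center(self, row: int, col: int) -> tuple[float, float]:
        x = (col - (self.cols - 1) / 2) * self.pitch
        y = (row - (self.rows - 1) / 2) * self.pitch
        return (x, y)

    def concentration(self, x, y, edge):
        out = np.zeros(np.broadcast(x, y).shape)
        for r in range(self.rows):
            for c in range(self.cols):
                conc = self.concentrations[r, c]
                if conc == 0:
                    continue
                out += conc * _soft_disc(x, y, self.well_center(r, c), self.well_diameter / 2, edge)
        return out

    def reflectance(self, x, y, edge):
        return np.full(np.broadcast(x, y).shape, self.plate_reflectance)


@dataclass
class PlanarTarget:
    """A fronto-parallel planar scene at ``distance`` mm along the viewing axis."""

    kind: str  # resolution_target | uniform_card | well_plate
    reflectance_fn: Callable
    concentration_fn: Callable
    distance: float
    extent: tuple[float, float]  # mm x mm

    def __post_init__(self):
        if self.extent[0] <= 0 or self.extent[1] <= 0:
            raise ConfigError("target extent must be positive")
        if self.distance <= 0:
            raise ConfigError("target distance must be positive")

    @classmethod
    def from_resolution_target(
        cls, spec: ResolutionTargetSpec, distance: float, extent=(500.0, 400.0)
    ) -> "PlanarTarget":
        zero = lambda x, y, edge: np.zeros(np.broadcast(x, y).shape)
        return cls("resolution_target", spec.reflectance, zero, distance, extent)

    @classmethod
    def uniform_card(
        cls, distance: float, reflectance: float = 1.0, extent=(500.0, 400.0)
    ) -> "PlanarTarget":
        refl = lambda x, y, edge: np.full(np.broadcast(x, y).shape, reflectance)
        zero = lambda x, y, edge: np.zeros(np.broadcast(x, y).shape)
        return cls("uniform_card", refl, zero, distance, extent)

    @classmethod
    def from_well_plate(
        cls, phantom: WellPlatePhantom, distance: float, extent=(500.0, 400.0)
    ) -> "PlanarTarget":
        return cls("well_plate", phantom.reflectance, phantom.concentration, distance, extent)

    @classmethod
    def fluorescent_spot_card(
        cls,
        distance: float,
        concentration: float = 50e-9,
        spot_center=(0.0, 0.0),
        spot_radius: float = 15.0,
        reflectance: float = 1.0,
        extent=(500.0, 400.0),
    ) -> "PlanarTarget":
        """White card carrying one fluorescent disc (a dye-vial stand-in)."""
        refl = lambda x, y, edge: np.full(np.broadcast(x, y).shape, reflectance)
        conc = lambda x, y, edge: concentration * _soft_disc(x, y, spot_center, spot_radius, edge)
        return cls("uniform_card", refl, conc, distance, extent)


@dataclass
class IlluminationModel:
    """Converging laser-diode array plus ambient terms.

    ``n_beams`` Gaussian beams start on a circle of radius ``beam_distance_d``
    around the optical axis and are aimed to intersect the axis at the
    working distance ``working_distance_L``; at plane ``z`` each beam center
    sits at radius ``d * (1 - z / L)`` and the 1/e^2 radius grows linearly,
    ``w(z) = w0 + radius_growth * z``, with the peak falling as ``(w0/w)^2``.
    """

    beam_peak: float = 47.0  # mW/cm^2 at the source, per beam
    beam_radius0: float = 12.0  # mm, 1/e^2 at the source
    radius_growth: float = 0.05  # mm of radius per mm of propagation
    beam_distance_d: float = 30.0  # mm, array circle radius
    working_distance_L: float = 400.0  # mm, beam-crossing distance
    n_beams: int = 3
    white_level: float = 0.85  # visible-channel illumination (dimensionless)
    nir_ambient: float = 0.0  # static room-light NIR level

    def __post_init__(self):
        if self.working_distance_L <= 0:
            raise ConfigError("working distance L must be positive")
        if self.beam_distance_d < 0 or self.beam_peak < 0:
            raise ConfigError("beam geometry parameters must be non-negative")

    def beam_positions(self) -> np.ndarray:
        ang = np.pi / 2 + 2 * np.pi * np.arange(self.n_beams) / self.n_beams
        return self.beam_distance_d * np.column_stack([np.cos(ang), np.sin(ang)])

    def inclination_deg(self) -> float:
        return float(np.degrees(np.arctan2(self.beam_distance_d, self.working_distance_L)))

    def irradiance(self, distance: float, x, y) -> np.ndarray:
        """Total irradiance (mW/cm^2) on the plane z = distance."""
        if distance <= 0:
            raise ConfigError("distance must be positive")
        w = self.beam_radius0 + self.radius_growth * distance
        shrink = 1.0 - distance / self.working_distance_L
        peak = self.beam_peak * (self.beam_radius0 / w) ** 2
        out = np.zeros(np.broadcast(x, y).shape)
        for px, py in self.beam_positions():
            r2 = (x - px * shrink) ** 2 + (y - py * shrink) ** 2
            out = out + peak * np.exp(-2.0 * r2 / w**2)
        return out

    @classmethod
    def uniform(cls, irradiance: float = REFERENCE_IRRADIANCE, **kw) -> "UniformIllumination":
        return UniformIllumination(level=irradiance, **kw)


@dataclass
class UniformIllumination(IlluminationModel):
    """Spatially flat excitation, emulating per-well stage repositioning."""

    level: float = REFERENCE_IRRADIANCE

    def irradiance(self, distance: float, x, y) -> np.ndarray:
        if distance <= 0:
            raise ConfigError("distance must be positive")
        return np.full(np.broadcast(x, y).shape, self.level)


def irradiance_map(ill: IlluminationModel, distance: float, grid_spec) -> np.ndarray:
    """Irradiance grid for a plane at ``distance``.

    ``grid_spec`` is ``(x_mm, y_mm)`` 1-D coordinate vectors; the result has
    shape ``(len(y), len(x))``.
    """
    x, y = grid_spec
    X, Y = np.meshgrid(np.asarray(x, float), np.asarray(y, float))
    return ill.irradiance(distance, X, Y)


@dataclass(frozen=True)
class OpticalChannel:
    """Spectral channel of the imaging head.

    ``leak_fraction`` is the fraction of excitation irradiance registered by
    the NIR sensor through the excitation filter (the filter's effective
    optical density collapsed to one scalar); ``emission_gain`` converts
    concentration x irradiance into detected intensity.
    """

    kind: str  # visible | nir
    leak_fraction: float = 0.0
    emission_gain: float = 0.0
    filter_name: str | None = None

    def __post_init__(self):
        if self.kind not in ("visible", "nir"):
            raise ConfigError("channel kind must be 'visible' or 'nir'")
        if not (0 <= self.leak_fraction <= 1) or self.emission_gain < 0:
            raise ConfigError("leak in [0,1] and non-negative emission gain required")
        if self.kind == "visible" and (self.leak_fraction != 0 or self.emission_gain != 0):
            raise ConfigError("visible channel must have zero leak and gain")

    @classmethod
    def visible(cls) -> "OpticalChannel":
        return cls("visible")

    @classmethod
    def nir(
        cls,
        filter_preset: str = "dbl_830lp",
        emission_gain: float = DEFAULT_EMISSION_GAIN,
        reference_irradiance: float = REFERENCE_IRRADIANCE,
    ) -> "OpticalChannel":
        """NIR channel with the leak fraction calibrated to a filter preset.

        The presets reproduce the measured white-card leak intensities when
        the card is illuminated at ``reference_irradiance``.
        """
        try:
            leak_intensity = FILTER_LEAK_INTENSITY[filter_preset]
        except KeyError:
            raise ConfigError(f"unknown filter preset {filter_preset!r}") from None
        return cls(
            "nir",
            leak_fraction=leak_intensity / reference_irradiance,
            emission_gain=emission_gain,
            filter_name=filter_preset,
        )


def detected_intensity(concentration, irradiance, ch: OpticalChannel, ambient=0.0, reflectance=1.0):
    """Pre-noise detected intensity, clipped at full scale.

    ``I = min(1, k*C*E + l*E*rho + ambient)`` — monotone non-decreasing in
    every argument.
    """
    C = np.asarray(concentration, dtype=float)
    E = np.asarray(irradiance, dtype=float)
    if np.any(C < 0) or np.any(E < 0):
        raise DataError("concentration and irradiance must be non-negative")
    I = ch.emission_gain * C * E + ch.leak_fraction * E * np.asarray(reflectance, float) + ambient
    return np.minimum(I, 1.0)


@dataclass(frozen=True)
class NoiseModel:
    """Sensor noise: Poisson shot noise, Gaussian read noise, quantization.

    ``shot_scale`` is the photoelectron count at full scale (0 disables shot
    noise); ``read_sigma`` is in intensity units.  Identical seeds reproduce
    identical frames bit for bit.
    """

    shot_scale: float = 5000.0
    read_sigma: float = 1.0 / 255.0
    seed: int = 0

    def __post_init__(self):
        if self.shot_scale < 0 or self.read_sigma < 0:
            raise ConfigError("noise parameters must be non-negative")

    def apply(self, image: np.ndarray, bit_depth: int, rng: np.random.Generator) -> np.ndarray:
        out = np.asarray(image, dtype=float)
        if self.shot_scale > 0:
            out = rng.poisson(np.clip(out, 0, None) * self.shot_scale) / self.shot_scale
        if self.read_sigma > 0:
            out = out + rng.normal(0.0, self.read_sigma, size=out.shape)
        return quantize(out, bit_depth)


def quantize(image: np.ndarray, bit_depth: int) -> np.ndarray:
    """Round-to-nearest quantization to 2**bit_depth levels, clipped to [0, 1]."""
    levels = 2**bit_depth - 1
    return np.clip(np.round(np.asarray(image, float) * levels) / levels, 0.0, 1.0)


@dataclass
class Frame:
    """One grayscale frame with acquisition metadata."""

    data: np.ndarray
    timestamp_ms: float
    laser_state: str | None  # "on" | "off" | None (unknown)
    channel: str = "nir"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.min() < 0 or self.data.max() > 1:
            raise DataError("frame intensities must lie in [0, 1]")
        if self.laser_state not in ("on", "off", None):
            raise DataError("laser_state must be 'on', 'off', or None")


@dataclass
class FrameStream:
    """Ordered frames at a fixed period."""

    frames: list[Frame]
    period_ms: float
    fps: float

    def __post_init__(self):
        if self.period_ms <= 0:
            raise DataError("frame period must be positive")
        ts = np.array([f.timestamp_ms for f in self.frames])
        if len(ts) > 1:
            dt = np.diff(ts)
            if np.any(dt <= 0) or np.max(np.abs(dt - self.period_ms)) > 1e-6 * self.period_ms:
                raise DataError("timestamps must increase by exactly the frame period")
        if abs(self.fps - 1000.0 / self.period_ms) > 0.01 * self.fps:
            raise DataError("declared rate inconsistent with frame period (>1%)")

    def __len__(self) -> int:
        return len(self.frames)

    def intensities(self) -> np.ndarray:
        return np.stack([f.data for f in self.frames])

    def laser_states(self) -> list[str | None]:
        return [f.laser_state for f in self.frames]


@dataclass(frozen=True)
class PatternRender:
    """Planar-space rasterization of a target pattern with ground truth."""

    reflectance: np.ndarray
    concentration: np.ndarray
    px_per_mm: float
    origin_mm: tuple[float, float]  # plane mm of pixel (0, 0) center
    fiducial_centers_mm: np.ndarray
    fiducial_centers_px: np.ndarray
    line_positions_mm: dict

    def mm_to_px(self, pts_mm) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts_mm, float))
        return (pts - np.asarray(self.origin_mm)) * self.px_per_mm


def render_pattern(
    spec, px_per_mm: float, extent: tuple[float, float] = (200.0, 150.0)
) -> PatternRender:
    """Rasterize a target spec in plane space at ``px_per_mm``.

    Accepts a :class:`ResolutionTargetSpec` or :class:`WellPlatePhantom`.
    Anti-aliasing uses a one-pixel linear edge ramp, so the centroid of a
    rendered fiducial matches the ground truth to a few hundredths of a
    pixel at 10 px/mm and beyond.
    """
    if px_per_mm <= 0:
        raise ConfigError("px_per_mm must be positive")
    w_px = int(round(extent[0] * px_per_mm))
    h_px = int(round(extent[1] * px_per_mm))
    origin = (-(w_px - 1) / 2 / px_per_mm, -(h_px - 1) / 2 / px_per_mm)
    xs = origin[0] + np.arange(w_px) / px_per_mm
    ys = origin[1] + np.arange(h_px) / px_per_mm
    X, Y = np.meshgrid(xs, ys)
    edge = 1.0 / px_per_mm
    lines: dict = {}
    if isinstance(spec, WellPlatePhantom):
        refl = spec.reflectance(X, Y, edge)
        conc = spec.concentration(X, Y, edge)
        fid_mm = np.empty((0, 2))
    elif isinstance(spec, ResolutionTargetSpec):
        refl = spec.reflectance(X, Y, edge)
        conc = np.zeros_like(refl)
        fid_mm = spec.fiducial_centers()
        for g in spec.groups:
            lines[g.label] = g.bar_centers()
    else:
        raise ConfigError(f"cannot render pattern of type {type(spec).__name__}")
    fid_px = (fid_mm - np.asarray(origin)) * px_per_mm if len(fid_mm) else np.empty((0, 2))
    return PatternRender(refl, conc, px_per_mm, origin, fid_mm, fid_px, lines)


def excitation_overlap(duty: float, exposure_phase: float = 0.7) -> tuple[float, float]:
    """Overlap of the laser-on window with the exposure windows.

    The exposure of frame ``n`` ends ``exposure_phase`` of the way through
    its nominal period and the next frame's exposure begins immediately
    (rolling readout).  A laser pulse of length ``duty`` periods starting at
    the frame boundary therefore contributes a fraction
    ``min(duty, exposure_phase)`` to the pulsed frame and spills
    ``max(0, duty - exposure_phase)`` into the following frame
    ("bleed-through" for duty beyond the exposure phase).
    """
    if not (0 < duty <= 1):
        raise ConfigError("duty must lie in (0, 1]")
    if not (0 < exposure_phase <= 1):
        raise ConfigError("exposure_phase must lie in (0, 1]")
    return min(duty, exposure_phase), max(0.0, duty - exposure_phase)


def render_frame(
    target: PlanarTarget,
    camera: CameraModel,
    ill: IlluminationModel,
    ch: OpticalChannel,
    laser_state: str = "off",
    noise: NoiseModel | None = None,
    t_ms: float = 0.0,
    excitation_scale: float = 1.0,
    rng: np.random.Generator | None = None,
) -> Frame:
    """Render one frame of ``target`` as seen by ``camera``.

    With ``noise=None`` the frame is the exact continuous forward model
    (no quantization); pass a :class:`NoiseModel` for the full pipeline of
    shot noise, read noise, and bit-depth quantization.
    """
    if laser_state not in ("on", "off"):
        raise DataError("laser_state must be 'on' or 'off'")
    if target.distance - camera.position[2] <= 0:
        raise BehindCameraError("target plane is behind the camera")
    px_x, px_y = camera.pixel_grid()
    X, Y = camera.back_project_to_plane(px_x, px_y, target.distance)
    edge = camera.mm_per_px(target.distance - camera.position[2])
    rho = target.reflectance_fn(X, Y, edge)
    if ch.kind == "visible":
        I = rho * ill.white_level
    else:
        C = target.concentration_fn(X, Y, edge)
        if laser_state == "on" and excitation_scale > 0:
            E = ill.irradiance(target.distance, X, Y) * excitation_scale
        else:
            E = np.zeros_like(rho)
        I = detected_intensity(C, E, ch, ambient=ill.nir_ambient * rho, reflectance=rho)
    I = np.clip(I, 0.0, 1.0)
    if noise is not None:
        if rng is None:
            rng = np.random.default_rng(np.random.SeedSequence([noise.seed]))
        I = noise.apply(I, camera.bit_depth, rng)
    return Frame(I, t_ms, laser_state, ch.kind)


def generate_stream(
    target: PlanarTarget,
    camera: CameraModel,
    ill: IlluminationModel,
    ch: OpticalChannel,
    n_frames: int,
    fps: float = 30.0,
    duty: float = 0.7,
    noise: NoiseModel | None = None,
    phase: int = 1,
    exposure_phase: float = 0.7,
) -> FrameStream:
    """Laser-toggled frame stream: frames whose index parity equals ``phase``
    are laser-on; the trigger period is twice the frame period.

    The excitation contribution of each frame is scaled by the overlap of
    the laser-on window with that frame's exposure window, so duty factors
    beyond the exposure phase bleed excitation into the following frame.
    """
    if n_frames < 2:
        raise ConfigError("a stream needs at least 2 frames")
    if phase not in (0, 1):
        raise ConfigError("phase must be 0 or 1")
    on_scale, bleed_scale = excitation_overlap(duty, exposure_phase)
    period = round(1000.0 / fps)
    frames = []
    if noise is not None:
        seeds = np.random.SeedSequence([noise.seed]).spawn(n_frames)
    for n in range(n_frames):
        is_on = n % 2 == phase
        prev_on = n >= 1 and (n - 1) % 2 == phase
        if is_on:
            state, scale = "on", on_scale
        elif prev_on and bleed_scale > 0:
            state, scale = "off", bleed_scale
        else:
            state, scale = "off", 0.0
        rng = np.random.default_rng(seeds[n]) if noise is not None else None
        fr = render_frame(
            target,
            camera,
            ill,
            ch,
            laser_state="on" if scale > 0 else "off",
            noise=noise,
            t_ms=n * period,
            excitation_scale=scale if scale > 0 else 1.0,
            rng=rng,
        )
        fr.laser_state = state  # metadata reflects the trigger, not the bleed
        frames.append(fr)
    return FrameStream(frames, period_ms=period, fps=1000.0 / period)
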