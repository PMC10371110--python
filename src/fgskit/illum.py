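"""Illumination-side analysis: thermal power mapping, beam geometry, coverage.

The thermal estimator assumes surface heating proportional to absorbed
power with uniform absorptivity: the temperature rise map, rescaled so
its maximum equals the measured peak laser power, is the irradiance
estimate.  No diffusion correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError


@dataclass
class ThermalMap:
    """Surface-temperature grid (deg C) at a labelled acquisition time."""

    temperature: np.ndarray
    time_label: str
    pixel_scale_mm: float

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        if not np.all(np.isfinite(self.temperature)):
            raise DataError("thermal map contains non-finite values")
        if self.pixel_scale_mm <= 0:
            raise DataError("pixel scale must be positive")


@dataclass
class PowerMap:
    """Irradiance grid (mW/cm^2) with its pixel scale and scaling peak."""

    irradiance: np.ndarray
    pixel_scale_mm: float
    peak_power: float

    def __post_init__(self):
        self.irradiance = np.asarray(self.irradiance, dtype=float)
        if np.any(self.irradiance < 0):
            raise DataError("irradiance must be non-negative")
        if self.irradiance.max() > 0 and abs(self.irradiance.max() - self.peak_power) > 1e-9:
            raise DataError("power map maximum must equal the supplied peak power")


def power_from_thermal(t0: ThermalMap, t5: ThermalMap, p_max: float) -> PowerMap:
    """Estimate the surface power distribution from before/after thermal maps.

    ``P(x, y) = max(0, dT) / max(dT) * p_max`` where ``dT = T_after - T_before``;
    invariant to any constant offset present in both maps.
    """
    if p_max <= 0:
        raise ConfigError("p_max must be positive")
    if t0.temperature.shape != t5.temperature.shape:
        raise DataError("thermal maps must share one shape")
    if abs(t0.pixel_scale_mm - t5.pixel_scale_mm) > 1e-12:
        raise DataError("thermal maps must share one pixel scale")
    dt = t5.temperature - t0.temperature
    dt_max = float(dt.max())
    if dt_max <= 0:
        raise DataError("no heating detected (max temperature rise <= 0)")
    return PowerMap(np.clip(dt, 0.0, None) / dt_max * p_max, t0.pixel_scale_mm, p_max)


def inclination_angle(L_mm: float, d_mm: float) -> float:
    """Beam inclination theta = arctan(d / L) in degrees.

    ``L`` is the distance at which the angled beams intersect the optical
    axis and ``d`` the radius of the source circle.
    """
    if L_mm <= 0:
        raise ConfigError("working distance L must be positive")
    if d_mm < 0:
        raise ConfigError("source-circle radius d must be non-negative")
    return float(np.degrees(np.arctan2(d_mm, L_mm)))


def coverage_above(power: PowerMap, threshold: float) -> tuple[float, float]:
    """Area (cm^2) with irradiance >= threshold, and the equivalent diameter (cm).

    The diameter is that of the circle of equal area (the footprint of a
    multi-beam superposition is not exactly circular).
    """
    if threshold <= 0:
        raise ConfigError("threshold must be positive")
    px_area_cm2 = (power.pixel_scale_mm / 10.0) ** 2
    area = float(np.count_nonzero(power.irradiance >= threshold) * px_area_cm2)
    diameter = float(2.0 * np.sqrt(area / np.pi))
    return area, diameter
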