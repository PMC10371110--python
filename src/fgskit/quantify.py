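"""Signal-to-background quantification.

Two SBR conventions are implemented, mirroring how phantom plates and
per-pixel maps are analyzed in practice:

* well SBR — background-subtracted mean intensity of a fluorophore well
  divided by that of the zero-concentration control well;
* per-pixel SBR — background-subtracted intensity divided by the
  excitation-leak threshold measured on a non-fluorescent white card, so
  SBR = 1 marks signal indistinguishable from leaked excitation light.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib
import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .optics import CameraModel, Homography, warp_image
from .scene import WellPlatePhantom


def leak_threshold(on_image: np.ndarray, off_image: np.ndarray) -> float:
    """Maximum pixel intensity of (laser-ON minus laser-OFF), floored at 0.

    Measured on a uniform non-fluorescent target, this is the worst-case
    leaked-excitation intensity of the filter assembly.  Raises
    ``DataError`` when no positive difference exists (the per-pixel SBR
    map would divide by zero).
    """
    on = np.asarray(on_image, float)
    off = np.asarray(off_image, float)
    if on.shape != off.shape:
        raise DataError("on and off images must share one shape")
    peak = float(np.max(on - off))
    if peak <= 0:
        raise DataError("no detectable excitation leak (max ON-OFF <= 0)")
    return peak


@dataclass(frozen=True)
class WellROI:
    """Disc region of interest over one well."""

    row: int
    col: int
    center_px: tuple[float, float]  # (x, y)
    radius_px: float
    concentration: float  # molar
    is_control: bool = False

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        return (xx - self.center_px[0]) ** 2 + (yy - self.center_px[1]) ** 2 <= self.radius_px**2


def rois_from_phantom(
    phantom: WellPlatePhantom,
    camera: CameraModel,
    distance: float,
    shrink: float = 0.8,
) -> list[WellROI]:
    """Project well centers into the camera and build disc ROIs.

    ``shrink`` scales the ROI radius inside the physical well so soft well
    edges stay out of the statistic.
    """
    rois = []
    r_px = shrink * (phantom.well_diameter / 2) / camera.mm_per_px(distance - camera.position[2])
    for r in range(phantom.rows):
        for c in range(phantom.cols):
            cx, cy = phantom.well_center(r, c)
            px = camera.project(np.array([cx, cy, distance]))
            rois.append(
                WellROI(
                    r,
                    c,
                    (float(px[0]), float(px[1])),
                    r_px,
                    float(phantom.concentrations[r, c]),
                    is_control=(r, c) == phantom.control,
                )
            )
    w, h = camera.resolution
    for roi in rois:
        x, y = roi.center_px
        if not (roi.radius_px <= x <= w - 1 - roi.radius_px and roi.radius_px <= y <= h - 1 - roi.radius_px):
            raise DataError(f"well ROI ({roi.row}, {roi.col}) extends outside the image")
    return rois


def well_sbr(
    on: np.ndarray,
    off: np.ndarray,
    wells: list[WellROI],
    control: WellROI | None = None,
    stat: str = "mean",
) -> pd.DataFrame:
    """Per-well SBR table: well statistic of (on - off) over control statistic.

    Negative background-subtracted pixels are clipped to 0 before the
    ratio.  ``stat`` selects mean (default) or median.  Returns a
    DataFrame with one row per well (row, col, concentration, sbr,
    is_control).
    """
    if stat not in ("mean", "median"):
        raise ConfigError("stat must be 'mean' or 'median'")
    reduce = np.mean if stat == "mean" else np.median
    on = np.asarray(on, float)
    off = np.asarray(off, float)
    if on.shape != off.shape:
        raise DataError("on and off images must share one shape")
    if control is None:
        controls = [w for w in wells if w.is_control]
        if len(controls) != 1:
            raise DataError("exactly one control ROI is required")
        control = controls[0]
    diff = np.clip(on - off, 0.0, None)
    ctrl_val = float(reduce(diff[control.mask(diff.shape)]))
    if ctrl_val <= 0:
        raise DataError("control-well background-subtracted intensity is not positive")
    rows = []
    for w in wells:
        val = float(reduce(diff[w.mask(diff.shape)]))
        rows.append(
            dict(
                row=w.row,
                col=w.col,
                concentration=w.concentration,
                sbr=val / ctrl_val,
                is_control=w.is_control,
            )
        )
    return pd.DataFrame(rows)


def aggregate_duplicates(table: pd.DataFrame) -> pd.DataFrame:
    """Average duplicate wells after per-well SBR (keeps per-well variance visible)."""
    grouped = (
        table.groupby("concentration", as_index=False)
        .agg(sbr=("sbr", "mean"), sbr_sd=("sbr", "std"), n=("sbr", "size"))
        .sort_values("concentration", ignore_index=True)
    )
    return grouped


@dataclass
class SBRMap:
    """Per-pixel signal-to-background map normalized by the leak threshold."""

    values: np.ndarray
    leak: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise DataError("SBR map contains non-finite values")
        if self.leak <= 0:
            raise DataError("leak threshold must be positive")


def sbr_map(on: np.ndarray, off: np.ndarray, leak: float, provenance: dict | None = None) -> SBRMap:
    """Per-pixel (on - off) / leak with negatives clipped to 0.

    A region whose background-subtracted intensity equals the leak
    threshold gets SBR exactly 1.
    """
    if leak <= 0:
        raise DataError("leak threshold must be positive")
    on = np.asarray(on, float)
    off = np.asarray(off, float)
    if on.shape != off.shape:
        raise DataError("on and off images must share one shape")
    vals = np.clip(on - off, 0.0, None) / leak
    return SBRMap(vals, leak, provenance or {})


def peak_sbr(map_: SBRMap, roi: np.ndarray | None = None) -> float:
    """Maximum SBR over all pixels (or over a boolean ROI)."""
    vals = map_.values if roi is None else map_.values[np.asarray(roi, bool)]
    if vals.size == 0:
        raise DataError("empty region for peak SBR")
    return float(np.max(vals))


def overlay(
    map_: SBRMap,
    visible_image: np.ndarray,
    H: Homography | None = None,
    threshold: float = 1.5,
    alpha: float = 0.6,
    colormap: str = "inferno",
    interpolation: str = "bilinear",
    vmax: float | None = None,
) -> np.ndarray:
    """False-color SBR overlay on the coaligned visible image.

    The map is warped into visible-image coordinates by ``H`` (NIR ->
    visible; identity if None), pixels below ``threshold`` are fully
    transparent, and the rest are alpha-blended in ``colormap``.  Returns
    a float RGB image in [0, 1].
    """
    vis = np.asarray(visible_image, float)
    if H is None:
        warped = map_.values if map_.values.shape == vis.shape else None
        if warped is None:
            raise DataError("shapes differ; an NIR->visible homography is required")
    else:
        warped = warp_image(H, map_.values, output_shape=vis.shape, interpolation=interpolation)
    mask = warped >= threshold
    rgb = np.repeat(vis[..., None], 3, axis=-1)
    if not np.any(mask):
        return rgb
    top = vmax if vmax is not None else float(warped.max())
    denom = max(top - threshold, 1e-12)
    norm = np.clip((warped - threshold) / denom, 0.0, 1.0)
    cmap = matplotlib.colormaps[colormap]
    colors = cmap(norm)[..., :3]
    rgb[mask] = (1.0 - alpha) * rgb[mask] + alpha * colors[mask]
    return rgb


@dataclass
class SensitivityCurve:
    """Log-log sensitivity fit of SBR against concentration.

    The plateau is the mean SBR of points below ``1 + plateau_factor``;
    the remaining points form the linear region fitted by ordinary least
    squares on (log10 C, log10 SBR).
    """

    concentrations: np.ndarray
    sbr: np.ndarray
    slope: float
    intercept: float
    plateau: float
    linear_mask: np.ndarray
    fit_available: bool
    plateau_factor: float

    def predict(self, concentrations) -> np.ndarray:
        if not self.fit_available:
            raise DataError("no linear-region fit available")
        return 10 ** (self.intercept + self.slope * np.log10(np.asarray(concentrations, float)))


def fit_sensitivity(
    concentrations, sbr, plateau_factor: float = 0.5
) -> SensitivityCurve:
    """Split a dilution series into plateau and linear regions and fit the latter.

    Requires at least 3 distinct positive concentrations.  If fewer than
    2 points fall in the linear region the fit is marked unavailable and
    only the plateau level is reported.
    """
    conc = np.asarray(concentrations, dtype=float)
    s = np.asarray(sbr, dtype=float)
    keep = conc > 0
    conc, s = conc[keep], s[keep]
    if len(np.unique(conc)) < 3:
        raise DataError("need at least 3 distinct positive concentrations")
    plateau_mask = s < 1.0 + plateau_factor
    linear_mask = ~plateau_mask
    plateau = float(np.mean(s[plateau_mask])) if np.any(plateau_mask) else float("nan")
    if linear_mask.sum() >= 2:
        slope, intercept = np.polyfit(np.log10(conc[linear_mask]), np.log10(s[linear_mask]), 1)
        available = True
    else:
        slope, intercept, available = float("nan"), float("nan"), False
    return SensitivityCurve(
        conc, s, float(slope), float(intercept), plateau, linear_mask, available, plateau_factor
    )
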