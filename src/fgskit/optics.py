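"""Pinhole-camera geometry and planar projective transforms.

All image coordinates are 0-based, real-valued, with the origin at the
top-left pixel *center*, x increasing rightward along columns and y
increasing downward along rows.  Lengths are millimetres throughout.

The projective-transform (homography) estimator is a direct linear
transform with Hartley pre-normalization; it is exact on noiseless
minimal (4-point) input and least-squares on over-determined input.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .errors import BehindCameraError, ConfigError, DataError, DegenerateGeometryError, MappingError

_MIN_DEPTH = 1e-9
_ORTHO_TOL = 1e-9

# Sensor-mode note: the sensor's full-resolution geometry is taken as
# 3280 x 2464 with an effective pitch/focal ratio of 3.0e-4 per pixel,
# i.e. 0.15 mm per pixel of scene at a 50 cm working distance (the crop
# or binning mode behind that figure is not uniquely determined by the
# camera datasheet; the ratio is what every scene-space conversion uses).
RPI_V2_FULL_RESOLUTION = (3280, 2464)
RPI_V2_FOCAL_LENGTH_MM = 3.04
RPI_V2_PITCH_MM = 9.12e-4


def rotation_from_axis_angle(axis, angle_rad: float) -> np.ndarray:
    """3x3 world->camera rotation from an axis (3-vector) and angle in radians."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        if angle_rad != 0:
            raise ConfigError("rotation axis must be non-zero for a non-zero angle")
        return np.eye(3)
    return Rotation.from_rotvec(axis / norm * angle_rad).as_matrix()


@dataclass
class CameraModel:
    """Ideal pinhole camera.

    Parameters
    ----------
    focal_length : float
        Lens focal length in mm.
    pixel_pitch : float
        Sensor pixel pitch in mm per pixel.
    resolution : (int, int)
        Sensor size as (width, height) in pixels.
    principal_point : (float, float), optional
        (x, y) pixel coordinate where the optical axis meets the sensor;
        defaults to the geometric image center.
    position : 3-vector, optional
        Optical-center position in the world frame (mm).
    orientation : (3, 3) array, optional
        Proper rotation taking world coordinates to camera coordinates.
    bit_depth : int
        Quantization depth of the sensor output (2**bit_depth levels).
    """

    focal_length: float
    pixel_pitch: float
    resolution: tuple[int, int]
    principal_point: tuple[float, float] | None = None
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    bit_depth: int = 8

    def __post_init__(self):
        if self.focal_length <= 0:
            raise ConfigError("focal_length must be positive")
        if self.pixel_pitch <= 0:
            raise ConfigError("pixel_pitch must be positive")
        w, h = self.resolution
        if w < 1 or h < 1:
            raise ConfigError("resolution components must be >= 1")
        self.resolution = (int(w), int(h))
        if self.principal_point is None:
            self.principal_point = ((w - 1) / 2.0, (h - 1) / 2.0)
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        R = np.asarray(self.orientation, dtype=float).reshape(3, 3)
        if abs(np.linalg.det(R) - 1.0) > 1e-6 or np.max(np.abs(R @ R.T - np.eye(3))) > _ORTHO_TOL:
            raise ConfigError("orientation must be a proper rotation (orthonormal, det +1)")
        self.orientation = R
        if self.bit_depth < 1:
            raise ConfigError("bit_depth must be >= 1")

    @classmethod
    def rpi_v2(cls, binning: int = 2, **overrides) -> "CameraModel":
        """Camera-sensor preset at an integer binning factor.

        ``binning=1`` is the full-resolution mode; larger factors reduce
        the pixel count and enlarge the effective pitch by the same
        factor, leaving the field of view and all scene-space geometry
        unchanged.
        """
        w = RPI_V2_FULL_RESOLUTION[0] // binning
        h = RPI_V2_FULL_RESOLUTION[1] // binning
        params = dict(
            focal_length=RPI_V2_FOCAL_LENGTH_MM,
            pixel_pitch=RPI_V2_PITCH_MM * binning,
            resolution=(w, h),
        )
        params.update(overrides)
        return cls(**params)

    def mm_per_px(self, distance_mm: float) -> float:
        """Scene millimetres spanned by one pixel at the given depth."""
        return self.pixel_pitch * distance_mm / self.focal_length

    def with_principal_shift(self, shift_px) -> "CameraModel":
        """Copy of this camera with the sensor shifted in-plane by (dx, dy) px."""
        cx, cy = self.principal_point
        return replace(self, principal_point=(cx + shift_px[0], cy + shift_px[1]))

    def project(self, world_points) -> np.ndarray:
        """Perspective-project world points (mm) to pixel coordinates.

        Raises ``BehindCameraError`` for any point at non-positive depth.
        """
        pts = np.atleast_2d(np.asarray(world_points, dtype=float))
        cam = (self.orientation @ (pts - self.position).T).T
        depth = cam[:, 2]
        if np.any(depth <= _MIN_DEPTH):
            raise BehindCameraError("point at non-positive depth in camera frame")
        scale = self.focal_length / (depth * self.pixel_pitch)
        uv = np.empty((len(pts), 2))
        uv[:, 0] = self.principal_point[0] + cam[:, 0] * scale
        uv[:, 1] = self.principal_point[1] + cam[:, 1] * scale
        return uv if np.asarray(world_points).ndim == 2 else uv[0]

    def pixel_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) pixel-center coordinate grids of shape (height, width)."""
        w, h = self.resolution
        y, x = np.mgrid[0:h, 0:w].astype(float)
        return x, y

    def back_project_to_plane(self, px_x, px_y, plane_z: float):
        """Intersect pixel rays with the fronto-parallel world plane z = plane_z.

        Returns world (x, y) coordinates on the plane, same shape as input.
        """
        dir_cam = np.stack(
            [
                (np.asarray(px_x, float) - self.principal_point[0]) * self.pixel_pitch,
                (np.asarray(px_y, float) - self.principal_point[1]) * self.pixel_pitch,
                np.full(np.shape(px_x), self.focal_length),
            ],
            axis=-1,
        )
        dir_world = dir_cam @ self.orientation  # R^T applied to each row
        dz = dir_world[..., 2]
        depth = plane_z - self.position[2]
        if depth <= _MIN_DEPTH or np.any(dz <= _MIN_DEPTH):
            raise BehindCameraError("target plane not in front of camera")
        s = depth / dz
        return (
            self.position[0] + s * dir_world[..., 0],
            self.position[1] + s * dir_world[..., 1],
        )


def project_point(camera: CameraModel, world_point) -> np.ndarray:
    """Functional wrapper over :meth:`CameraModel.project`."""
    return camera.project(world_point)


@dataclass(frozen=True)
class Homography:
    """3x3 planar projective transform.

    Normalized so the lower-right entry equals 1 whenever its magnitude
    exceeds 1e-8 of the largest entry ("h33" convention), otherwise to
    unit Frobenius norm ("frobenius").
    """

    matrix: np.ndarray
    convention: str = "h33"

    @classmethod
    def from_matrix(cls, m) -> "Homography":
        m = np.asarray(m, dtype=float).reshape(3, 3)
        if abs(np.linalg.det(m)) < 1e-300:
            raise DegenerateGeometryError("homography matrix is singular")
        peak = np.max(np.abs(m))
        if abs(m[2, 2]) > 1e-8 * peak:
            return cls(m / m[2, 2], "h33")
        return cls(m / np.linalg.norm(m), "frobenius")

    @classmethod
    def identity(cls) -> "Homography":
        return cls.from_matrix(np.eye(3))

    @classmethod
    def translation(cls, dx: float, dy: float) -> "Homography":
        m = np.eye(3)
        m[0, 2] = dx
        m[1, 2] = dy
        return cls.from_matrix(m)

    def inverse(self) -> "Homography":
        return Homography.from_matrix(np.linalg.inv(self.matrix))

    def to_json(self) -> str:
        return json.dumps(
            {"entries": [float(v) for v in self.matrix.ravel()], "convention": self.convention}
        )

    @classmethod
    def from_json(cls, payload: str) -> "Homography":
        d = json.loads(payload)
        h = cls.from_matrix(np.asarray(d["entries"], dtype=float).reshape(3, 3))
        if h.convention != d.get("convention", h.convention):
            raise DataError("serialized homography convention does not match entries")
        return h


def _collinearity_ok(points: np.ndarray, tol_frac: float = 1e-6) -> bool:
    """True if no triple of the 4 points is collinear within tolerance."""
    lo, hi = points.min(axis=0), points.max(axis=0)
    diag = float(np.hypot(*(hi - lo)))
    if diag == 0:
        return False
    for i, j, k in itertools.combinations(range(len(points)), 3):
        a, b, c = points[i], points[j], points[k]
        area2 = abs((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))
        longest = max(np.linalg.norm(b - a), np.linalg.norm(c - a), np.linalg.norm(c - b))
        if longest == 0 or area2 / longest < tol_frac * diag:
            return False
    return True


@dataclass
class PointCorrespondences:
    """Ordered sub-pixel point pairs (source -> target) for a projective fit."""

    src: np.ndarray
    dst: np.ndarray

    def __post_init__(self):
        self.src = np.atleast_2d(np.asarray(self.src, dtype=float))
        self.dst = np.atleast_2d(np.asarray(self.dst, dtype=float))
        if self.src.shape != self.dst.shape or self.src.shape[1] != 2:
            raise DataError("src and dst must be matching (N, 2) arrays")
        if len(self.src) < 4:
            raise DegenerateGeometryError("at least 4 point correspondences are required")
        if len(self.src) == 4:
            if not _collinearity_ok(self.src) or not _collinearity_ok(self.dst):
                raise DegenerateGeometryError(
                    "three of the four correspondence points are collinear"
                )

    def __len__(self) -> int:
        return len(self.src)


def _hartley_normalization(points: np.ndarray) -> np.ndarray:
    """Similarity transform sending the centroid to 0 and mean radius to sqrt(2)."""
    centroid = points.mean(axis=0)
    mean_dist = np.mean(np.linalg.norm(points - centroid, axis=1))
    s = np.sqrt(2.0) / mean_dist if mean_dist > 0 else 1.0
    T = np.array([[s, 0, -s * centroid[0]], [0, s, -s * centroid[1]], [0, 0, 1.0]])
    return T


def fit_projective_transform(corr: PointCorrespondences) -> Homography:
    """Least-squares DLT homography mapping ``corr.src`` onto ``corr.dst``.

    Exact (residual below 1e-9 of the coordinate scale) for noiseless
    minimal and consistent over-determined inputs.
    """
    if not isinstance(corr, PointCorrespondences):
        corr = PointCorrespondences(*corr)
    Ts = _hartley_normalization(corr.src)
    Td = _hartley_normalization(corr.dst)
    sh = (Ts @ np.column_stack([corr.src, np.ones(len(corr))]).T).T
    dh = (Td @ np.column_stack([corr.dst, np.ones(len(corr))]).T).T
    n = len(corr)
    A = np.zeros((2 * n, 9))
    x, y = sh[:, 0], sh[:, 1]
    u, v = dh[:, 0], dh[:, 1]
    A[0::2, 0] = x
    A[0::2, 1] = y
    A[0::2, 2] = 1
    A[0::2, 6] = -u * x
    A[0::2, 7] = -u * y
    A[0::2, 8] = -u
    A[1::2, 3] = x
    A[1::2, 4] = y
    A[1::2, 5] = 1
    A[1::2, 6] = -v * x
    A[1::2, 7] = -v * y
    A[1::2, 8] = -v
    _, sv, Vt = np.linalg.svd(A)
    # sv[7] collapsing means the system is rank-deficient beyond the single
    # homography null vector, i.e. the configuration is degenerate.
    if sv[7] < 1e-10 * sv[0]:
        raise DegenerateGeometryError("degenerate point configuration for projective fit")
    Hn = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ Hn @ Ts
    return Homography.from_matrix(H)


def transform_points(H: Homography, points) -> np.ndarray:
    """Apply a homography to (N, 2) pixel coordinates with perspective division."""
    m = H.matrix if isinstance(H, Homography) else np.asarray(H, dtype=float)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ph = (m @ np.column_stack([pts, np.ones(len(pts))]).T).T
    w = ph[:, 2]
    if np.any(np.abs(w) < 1e-12):
        raise MappingError("point maps to the plane at infinity")
    out = ph[:, :2] / w[:, None]
    return out if np.asarray(points).ndim == 2 else out[0]


def warp_image(
    H: Homography,
    image: np.ndarray,
    output_shape: tuple[int, int] | None = None,
    interpolation: str = "bilinear",
) -> np.ndarray:
    """Inverse-mapping warp of ``image`` by homography ``H`` (src -> dst).

    Pixels that sample outside the source are filled with 0.
    ``output_shape`` is (height, width); defaults to the input shape.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise DataError("cannot warp an empty image")
    if interpolation not in ("bilinear", "nearest"):
        raise ConfigError(f"unknown interpolation {interpolation!r}")
    m = H.matrix if isinstance(H, Homography) else np.asarray(H, dtype=float)
    try:
        Hinv = np.linalg.inv(m)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - from_matrix guards this
        raise DegenerateGeometryError("homography is not invertible") from exc
    h, w = output_shape if output_shape is not None else image.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    denom = Hinv[2, 0] * xx + Hinv[2, 1] * yy + Hinv[2, 2]
    sx = (Hinv[0, 0] * xx + Hinv[0, 1] * yy + Hinv[0, 2]) / denom
    sy = (Hinv[1, 0] * xx + Hinv[1, 1] * yy + Hinv[1, 2]) / denom
    order = 1 if interpolation == "bilinear" else 0
    return ndimage.map_coordinates(image, [sy, sx], order=order, mode="constant", cval=0.0)


def find_fiducial_centroids(
    image: np.ndarray,
    expected: int | None = None,
    min_area_px: int = 9,
    aspect_range: tuple[float, float] = (0.45, 2.2),
) -> np.ndarray:
    """Detect bright square fiducials and return sub-pixel centroids.

    Thresholds at mid-intensity, labels connected components, rejects
    elongated components (line-pair bars) by bounding-box aspect ratio,
    and returns intensity-weighted centroids as (N, 2) ``(x, y)`` sorted
    by (y, x).  Raises ``DataError`` on a count mismatch or if any kept
    fiducial touches the image border.
    """
    img = np.asarray(image, dtype=float)
    bg = float(img.min())
    thr = 0.5 * (bg + img.max())
    labels, n = ndimage.label(img > thr)
    if n == 0:
        raise DataError("no fiducial candidates found above mid-intensity")
    slices = ndimage.find_objects(labels)
    cents = []
    for lab, sl in enumerate(slices, start=1):
        mask = labels[sl] == lab
        area = int(mask.sum())
        if area < min_area_px:
            continue
        hh = sl[0].stop - sl[0].start
        ww = sl[1].stop - sl[1].start
        aspect = ww / hh
        if not (aspect_range[0] <= aspect <= aspect_range[1]):
            continue
        if (
            sl[0].start == 0
            or sl[1].start == 0
            or sl[0].stop == img.shape[0]
            or sl[1].stop == img.shape[1]
        ):
            raise DataError("fiducial touches the image border")
        # widen the window by 2 px so the anti-aliased edge ramp is fully
        # included; background-subtracted weights keep the centroid unbiased
        # at sub-pixel phases (thresholded weights cut the ramp asymmetrically)
        r0 = max(sl[0].start - 2, 0)
        r1 = min(sl[0].stop + 2, img.shape[0])
        c0 = max(sl[1].start - 2, 0)
        c1 = min(sl[1].stop + 2, img.shape[1])
        win = img[r0:r1, c0:c1] - bg
        weights = np.clip(win, 0.0, None)
        total = weights.sum()
        ys, xs = np.mgrid[r0:r1, c0:c1]
        cy = float((weights * ys).sum() / total)
        cx = float((weights * xs).sum() / total)
        cents.append((cx, cy))
    if expected is not None and len(cents) != expected:
        raise DataError(f"expected {expected} fiducials, found {len(cents)}")
    if not cents:
        raise DataError("no fiducials of plausible size/shape found")
    cents = np.asarray(cents)
    order = np.lexsort((cents[:, 0], cents[:, 1]))
    return cents[order]
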