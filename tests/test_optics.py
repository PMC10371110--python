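"""Pinhole projection and homography estimation."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fgskit.errors import BehindCameraError, ConfigError, DataError, DegenerateGeometryError, MappingError
from fgskit.optics import (
    CameraModel,
    Homography,
    PointCorrespondences,
    find_fiducial_centroids,
    fit_projective_transform,
    project_point,
    rotation_from_axis_angle,
    transform_points,
    warp_image,
)

UNIT_SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


class TestProjection:
    def test_optical_axis_maps_to_principal_point(self):
        cam = CameraModel(3.04, 0.00112, (640, 480))
        for depth in (10.0, 500.0, 5000.0):
            uv = project_point(cam, np.array([0.0, 0.0, depth]))
            assert np.allclose(uv, cam.principal_point)

    def test_offaxis_point_matches_closed_form(self):
        # f * X / (Z * pitch): 3.04 * 69.5 / 500 / 0.00112 = 377.29 px
        cam = CameraModel(3.04, 0.00112, (3280, 2464))
        uv = project_point(cam, np.array([69.5, 0.0, 500.0]))
        assert uv[0] - cam.principal_point[0] == pytest.approx(377.2857142857, abs=1e-6)
        assert uv[1] == pytest.approx(cam.principal_point[1])

    def test_zero_or_negative_depth_raises(self):
        cam = CameraModel(3.04, 0.00112, (640, 480))
        with pytest.raises(BehindCameraError):
            project_point(cam, np.array([1.0, 1.0, 0.0]))
        with pytest.raises(BehindCameraError):
            project_point(cam, np.array([0.0, 0.0, -5.0]))

    def test_mm_per_px_scales_linearly_with_distance(self):
        cam = CameraModel.rpi_v2(binning=1)
        assert cam.mm_per_px(500.0) == pytest.approx(0.15)
        assert cam.mm_per_px(1000.0) == pytest.approx(0.30)

    def test_binning_preserves_field_of_view(self):
        full = CameraModel.rpi_v2(binning=1)
        binned = CameraModel.rpi_v2(binning=4)
        fov = lambda c: c.resolution[0] * c.mm_per_px(500.0)
        assert fov(binned) == pytest.approx(fov(full), rel=1e-3)

    def test_rotation_validation(self):
        with pytest.raises(ConfigError):
            CameraModel(3.04, 0.00112, (64, 48), orientation=np.eye(3) * 2)
        R = rotation_from_axis_angle([0, 0, 1], 0.3)
        CameraModel(3.04, 0.00112, (64, 48), orientation=R)  # does not raise


class TestHomographyFit:
    def test_identity_on_fixed_square(self):
        H = fit_projective_transform(PointCorrespondences(UNIT_SQUARE, UNIT_SQUARE))
        assert np.allclose(H.matrix, np.eye(3), atol=1e-9)

    def test_pure_translation(self):
        H = fit_projective_transform(
            PointCorrespondences(UNIT_SQUARE, UNIT_SQUARE + [5.0, -3.0])
        )
        assert np.allclose(H.matrix, Homography.translation(5.0, -3.0).matrix, atol=1e-9)

    @pytest.mark.parametrize("n_points", [4, 8, 20])
    def test_generate_and_recover(self, n_points, rng):
        truth = Homography.from_matrix(
            np.array([[1.2, 0.1, 8.0], [-0.05, 0.9, -4.0], [2e-4, -1e-4, 1.0]])
        )
        src = rng.uniform(0, 200, (n_points, 2))
        dst = transform_points(truth, src)
        fitted = fit_projective_transform(PointCorrespondences(src, dst))
        assert np.max(np.abs(fitted.matrix - truth.matrix)) < 1e-9

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_recovery_property_random_homographies(self, seed):
        """Noiseless DLT recovers a random well-conditioned homography exactly."""
        r = np.random.default_rng(seed)
        m = np.eye(3) + r.uniform(-0.2, 0.2, (3, 3)) * np.array(
            [[1, 1, 50], [1, 1, 50], [2e-3, 2e-3, 1]]
        )
        if abs(np.linalg.det(m)) < 1e-3:
            return
        truth = Homography.from_matrix(m)
        src = r.uniform(0, 300, (6, 2))
        dst = transform_points(truth, src)
        fitted = fit_projective_transform(PointCorrespondences(src, dst))
        assert np.max(np.abs(fitted.matrix - truth.matrix)) < 1e-8

    def test_agrees_with_independent_estimator(self, rng):
        from skimage.transform import ProjectiveTransform, estimate_transform

        src = rng.uniform(0, 100, (10, 2))
        truth = Homography.from_matrix(np.array([[1.05, 0.02, 3], [0.01, 0.97, -2], [1e-4, 0, 1]]))
        dst = transform_points(truth, src) + rng.normal(0, 0.05, (10, 2))
        ours = fit_projective_transform(PointCorrespondences(src, dst)).matrix
        ref = estimate_transform("projective", src, dst).params
        assert np.allclose(ours, ref / ref[2, 2], atol=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            PointCorrespondences(UNIT_SQUARE[:3], UNIT_SQUARE[:3])

    def test_collinear_minimal_points_rejected(self):
        src = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [0.0, 1.0]])
        with pytest.raises(DegenerateGeometryError):
            PointCorrespondences(src, src)


class TestTransformAndNormalization:
    def test_identity_and_roundtrip(self, rng):
        H = Homography.from_matrix(np.array([[1.1, 0.05, 3], [0.02, 0.94, -7], [1e-4, 2e-4, 1]]))
        pts = rng.uniform(0, 400, (50, 2))
        assert np.allclose(transform_points(Homography.identity(), pts), pts)
        back = transform_points(H.inverse(), transform_points(H, pts))
        assert np.max(np.abs(back - pts)) < 1e-9

    def test_translation_moves_all_points_equally(self, rng):
        H = Homography.translation(12.5, -8.25)
        pts = rng.uniform(-100, 100, (100, 2))
        assert np.allclose(transform_points(H, pts) - pts, [12.5, -8.25])

    def test_point_at_infinity_raises(self):
        H = Homography.from_matrix(np.array([[1.0, 0, 0], [0, 1.0, 0], [-1.0, 0, 1.0]]))
        with pytest.raises(MappingError):
            transform_points(H, np.array([[1.0, 0.5]]))

    def test_h33_normalization_and_frobenius_fallback(self):
        h = Homography.from_matrix(2.0 * np.eye(3))
        assert h.convention == "h33" and h.matrix[2, 2] == 1.0
        # lower-right entry vanishes relative to the other entries
        m = np.array([[0, 1e8, 0], [1e8, 0, 0], [0, 0, 1e-12]])
        h2 = Homography.from_matrix(m)
        assert h2.convention == "frobenius"
        assert np.linalg.norm(h2.matrix) == pytest.approx(1.0)

    def test_json_roundtrip(self):
        h = Homography.from_matrix(np.array([[1.2, 0, 5], [0, 0.8, -2], [1e-4, 0, 1]]))
        h2 = Homography.from_json(h.to_json())
        assert np.allclose(h.matrix, h2.matrix)
        assert h.convention == h2.convention
        assert len(json.loads(h.to_json())["entries"]) == 9


class TestWarp:
    def _smooth_image(self, rng, shape=(96, 96)):
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        img = np.zeros(shape)
        for _ in range(5):
            cx, cy = rng.uniform(15, 80, 2)
            s = rng.uniform(6, 14)
            img += 0.18 * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * s * s))
        return np.clip(img, 0, 1)

    def test_identity_warp_reproduces_input(self, rng):
        img = self._smooth_image(rng)
        assert np.allclose(warp_image(Homography.identity(), img), img)

    def test_integer_translation_nearest_is_exact(self, rng):
        img = rng.uniform(0, 1, (40, 50))
        out = warp_image(Homography.translation(3, 5), img, interpolation="nearest")
        assert np.array_equal(out[5:, 3:], img[:-5, :-3])
        assert np.all(out[:5, :] == 0) and np.all(out[:, :3] == 0)

    def test_roundtrip_error_below_two_quantization_steps(self, rng):
        img = self._smooth_image(rng)
        H = Homography.from_matrix(
            np.array([[1.03, 0.01, 2.0], [0.008, 0.98, -1.5], [2e-5, -1e-5, 1.0]])
        )
        back = warp_image(H.inverse(), warp_image(H, img))
        interior = (slice(12, -12), slice(12, -12))
        assert np.abs(back - img)[interior].mean() < 2.0 / 256.0

    def test_empty_image_rejected(self):
        with pytest.raises(DataError):
            warp_image(Homography.identity(), np.empty((0, 0)))


class TestSharedCenterGeometry:
    def test_single_homography_valid_at_every_depth(self):
        """Cameras sharing an optical center are related by one homography
        regardless of scene depth (pure sensor shift or pure rotation)."""
        cam_a = CameraModel.rpi_v2(binning=4)
        for cam_b in (
            cam_a.with_principal_shift((1.25, 20.5)),
            CameraModel.rpi_v2(binning=4, orientation=rotation_from_axis_angle([0, 1, 0], 0.01)),
        ):
            pts = np.array([[x, y, 500.0] for x in (-80, 80) for y in (-60, 60)])
            H = fit_projective_transform(
                PointCorrespondences(cam_a.project(pts), cam_b.project(pts))
            )
            for depth in (300.0, 450.0, 700.0):
                world = np.array([[x, y, depth] for x in (-70, 0, 70) for y in (-50, 50)])
                mapped = transform_points(H, cam_a.project(world))
                assert np.max(np.abs(mapped - cam_b.project(world))) < 1e-6

    def test_translated_camera_offset_equals_baseline_at_all_depths(self):
        """Scene-space overlay offset for a translated camera pair equals the
        in-plane baseline at every distance (parallax ground truth)."""
        cam_a = CameraModel.rpi_v2(binning=4)
        B = np.array([26.5, 69.5, 0.0])
        cam_b = CameraModel.rpi_v2(binning=4, position=B)
        for depth in (300.0, 500.0, 700.0):
            world = np.array([[0.0, 0.0, depth], [40.0, -30.0, depth]])
            d_px = cam_b.project(world) - cam_a.project(world)
            d_mm = d_px * cam_a.mm_per_px(depth)
            assert np.allclose(d_mm, -B[:2], atol=1e-9)


class TestFiducialDetection:
    def test_contrast_invariance(self, rng):
        from fgskit.scene import FiducialSquare, ResolutionTargetSpec, render_pattern

        spec = ResolutionTargetSpec(
            fiducials=[
                FiducialSquare((-20.0, -15.0), 8.0),
                FiducialSquare((20.0, -15.0), 8.0),
                FiducialSquare((-20.0, 15.0), 8.0),
                FiducialSquare((21.3, 15.7), 8.0),
            ]
        )
        img = render_pattern(spec, px_per_mm=6, extent=(70, 55)).reflectance
        c_full = find_fiducial_centroids(img, expected=4)
        c_half = find_fiducial_centroids(0.5 * img, expected=4)
        assert np.max(np.abs(c_full - c_half)) < 0.05
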