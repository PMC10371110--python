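"""Synthetic-scene generator: illumination, forward model, rendering, streams."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fgskit.errors import BehindCameraError, ConfigError, DataError
from fgskit.optics import find_fiducial_centroids
from fgskit.scene import (
    FILTER_LEAK_INTENSITY,
    FiducialSquare,
    IlluminationModel,
    LinePairGroup,
    NoiseModel,
    OpticalChannel,
    PlanarTarget,
    ResolutionTargetSpec,
    UniformIllumination,
    WellPlatePhantom,
    detected_intensity,
    excitation_overlap,
    generate_stream,
    irradiance_map,
    quantize,
    render_frame,
    render_pattern,
)

GRID = (np.linspace(-60, 60, 241), np.linspace(-60, 60, 241))


class TestIrradiance:
    def test_beams_converge_at_working_distance(self):
        ill = IlluminationModel()
        m = irradiance_map(ill, ill.working_distance_L, GRID)
        w = ill.beam_radius0 + ill.radius_growth * ill.working_distance_L
        expected_peak = ill.n_beams * ill.beam_peak * (ill.beam_radius0 / w) ** 2
        # all beam centers coincide on-axis: the map peaks there at the sum
        center = m[120, 120]
        assert center == pytest.approx(expected_peak, rel=1e-6)
        assert m.max() == pytest.approx(center)

    def test_single_onaxis_beam_is_radially_symmetric(self):
        ill = IlluminationModel(n_beams=1, beam_distance_d=0.0)
        m = irradiance_map(ill, 500.0, GRID)
        assert np.max(np.abs(m - m.T)) < 1e-9
        assert np.max(np.abs(m - m[::-1, ::-1])) < 1e-9

    def test_area_above_threshold_maximal_at_convergence(self):
        # beams narrow relative to their separation, so defocusing in either
        # direction disperses the superposition below the threshold
        ill = IlluminationModel(
            beam_peak=26.7, beam_radius0=5.0, radius_growth=0.0125, beam_distance_d=30.0,
            working_distance_L=400.0,
        )
        areas = [
            int((irradiance_map(ill, d, GRID) >= 10.0).sum())
            for d in (0.8 * 400, 400.0, 1.2 * 400)
        ]
        assert np.argmax(areas) == 1

    def test_distance_must_be_positive(self):
        with pytest.raises(ConfigError):
            irradiance_map(IlluminationModel(), -10.0, GRID)


class TestForwardModel:
    def test_leak_only_when_no_fluorophore(self, nir_channel):
        E = np.array([0.0, 5.0, 20.0])
        I = detected_intensity(0.0, E, nir_channel)
        assert np.allclose(I, nir_channel.leak_fraction * E)

    def test_linear_in_concentration_without_leak(self):
        ch = OpticalChannel("nir", leak_fraction=0.0, emission_gain=8.2e4)
        C = np.array([0.0, 1e-9, 2e-9, 3e-9])
        I = detected_intensity(C, 20.0, ch)
        assert np.allclose(I, 8.2e4 * C * 20.0)
        assert np.allclose(np.diff(I, 2), 0.0)  # exactly linear on a uniform grid

    def test_sbr_algebra_loglog_slope_and_plateau(self, nir_channel):
        """(kCE + lE)/(lE) = 1 + kC/l: slope 1 in log-log where kC >> l,
        plateau at 1 where kC << l."""
        k, leak = nir_channel.emission_gain, nir_channel.leak_fraction
        C_hi = np.logspace(-5.0, -4.0, 5)  # kC/l in the hundreds
        sbr_hi = 1 + k * C_hi / leak
        slope = np.polyfit(np.log10(C_hi), np.log10(sbr_hi), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.01)
        C_lo = np.logspace(-13, -12, 5)
        assert np.allclose(1 + k * C_lo / leak, 1.0, atol=0.01)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        st.floats(0, 1e-7), st.floats(0, 30.0), st.floats(0, 0.2),
        st.floats(min_value=1.0, max_value=1.5),
    )
    def test_monotone_in_every_argument(self, C, E, amb, factor):
        ch = OpticalChannel.nir("dbl_830lp")
        base = detected_intensity(C, E, ch, amb)
        assert detected_intensity(C * factor, E, ch, amb) >= base
        assert detected_intensity(C, E * factor, ch, amb) >= base
        assert detected_intensity(C, E, ch, amb * factor) >= base

    def test_saturates_at_full_scale(self, nir_channel):
        assert detected_intensity(1e-3, 20.0, nir_channel) == 1.0

    def test_leak_presets_reproduce_measured_card_intensities(self):
        for name, level in FILTER_LEAK_INTENSITY.items():
            ch = OpticalChannel.nir(name)
            assert detected_intensity(0.0, 20.0, ch, reflectance=1.0) == pytest.approx(level)

    def test_visible_channel_must_be_inert(self):
        with pytest.raises(ConfigError):
            OpticalChannel("visible", leak_fraction=0.1)


class TestPatternRendering:
    def test_empty_spec_is_uniform_background(self):
        pr = render_pattern(ResolutionTargetSpec(), px_per_mm=4, extent=(30, 30))
        assert np.allclose(pr.reflectance, 0.08)

    def test_fiducial_centroid_matches_ground_truth(self):
        spec = ResolutionTargetSpec(
            fiducials=[
                FiducialSquare((3.3, -2.7), 8.0),
                FiducialSquare((-20.0, -20.0), 8.0),
                FiducialSquare((20.0, -20.0), 8.0),
                FiducialSquare((-20.0, 20.0), 8.0),
            ]
        )
        pr = render_pattern(spec, px_per_mm=10, extent=(80, 80))
        detected = find_fiducial_centroids(pr.reflectance, expected=4)
        gt = pr.mm_to_px(pr.fiducial_centers_mm)
        gt = gt[np.lexsort((gt[:, 0], gt[:, 1]))]
        assert np.max(np.abs(detected - gt)) < 0.05

    def test_bar_spacing_equals_inverse_frequency(self):
        g = LinePairGroup("g", frequency=0.25, bar_count=5)
        centers = g.bar_centers()
        assert np.allclose(np.diff(centers), 4.0)  # 1/f mm

    def test_overlapping_groups_rejected(self):
        g1 = LinePairGroup("a", 0.2, position=(0, 0))
        g2 = LinePairGroup("b", 0.2, position=(1.0, 1.0))
        with pytest.raises(ConfigError):
            ResolutionTargetSpec(groups=[g1, g2])


class TestFrameRendering:
    def test_ambient_only_frame_is_uniform(self, cam_small, nir_channel):
        card = PlanarTarget.uniform_card(450.0)
        ill = UniformIllumination(level=20.0, nir_ambient=0.12)
        fr = render_frame(card, cam_small, ill, nir_channel, laser_state="off")
        assert np.allclose(fr.data, 0.12)

    def test_seeded_rendering_is_bit_identical(self, cam_small, flat_ill, nir_channel):
        card = PlanarTarget.fluorescent_spot_card(450.0)
        noise = NoiseModel(seed=7)
        a = render_frame(card, cam_small, flat_ill, nir_channel, "on", noise=noise)
        b = render_frame(card, cam_small, flat_ill, nir_channel, "on", noise=noise)
        assert np.array_equal(a.data, b.data)

    def test_on_minus_off_equals_leak_times_irradiance(self, cam_small, nir_channel):
        card = PlanarTarget.uniform_card(450.0)
        ill = IlluminationModel(nir_ambient=0.03)
        on = render_frame(card, cam_small, ill, nir_channel, "on").data
        off = render_frame(card, cam_small, ill, nir_channel, "off").data
        x, y = cam_small.pixel_grid()
        X, Y = cam_small.back_project_to_plane(x, y, 450.0)
        expected = nir_channel.leak_fraction * ill.irradiance(450.0, X, Y)
        assert np.max(np.abs((on - off) - expected)) < 1e-12

    def test_identical_poses_render_identical_frames(self, cam_small, flat_ill, visible_channel):
        from dataclasses import replace

        target = PlanarTarget.from_resolution_target(
            ResolutionTargetSpec(fiducials=[FiducialSquare((0, 0), 20.0)] ), 500.0
        )
        a = render_frame(target, cam_small, flat_ill, visible_channel).data
        b = render_frame(target, replace(cam_small), flat_ill, visible_channel).data
        assert np.array_equal(a, b)

    def test_plane_behind_camera_rejected(self, cam_small, flat_ill, nir_channel):
        card = PlanarTarget.uniform_card(100.0)
        from dataclasses import replace

        cam = replace(cam_small, position=np.array([0.0, 0.0, 200.0]))
        with pytest.raises(BehindCameraError):
            render_frame(card, cam, flat_ill, nir_channel)

    def test_quantization_grid(self):
        q = quantize(np.array([0.0, 0.5, 1.0, 1.2, -0.1]), 8)
        assert set(np.round(q * 255).astype(int)) <= set(range(256))
        assert q[3] == 1.0 and q[4] == 0.0


class TestStreams:
    def test_laser_state_alternates_with_parity(self, cam_small, flat_ill, nir_channel):
        card = PlanarTarget.uniform_card(450.0)
        s = generate_stream(card, cam_small, flat_ill, nir_channel, n_frames=4)
        assert s.laser_states() == ["off", "on", "off", "on"]
        s0 = generate_stream(card, cam_small, flat_ill, nir_channel, n_frames=4, phase=0)
        assert s0.laser_states() == ["on", "off", "on", "off"]

    def test_trigger_period_doubles_frame_period(self, cam_small, flat_ill, nir_channel):
        card = PlanarTarget.uniform_card(450.0)
        s = generate_stream(card, cam_small, flat_ill, nir_channel, n_frames=6, fps=30.0)
        assert s.period_ms == 33
        on_times = [f.timestamp_ms for f in s.frames if f.laser_state == "on"]
        assert np.allclose(np.diff(on_times), 66.0)

    def test_excitation_scales_with_exposure_overlap(self, cam_small, nir_channel):
        card = PlanarTarget.uniform_card(450.0)
        ill = UniformIllumination(level=20.0)
        leak = nir_channel.leak_fraction * 20.0

        def on_off_levels(duty):
            s = generate_stream(card, cam_small, ill, nir_channel, n_frames=4, duty=duty)
            return float(s.frames[1].data.mean()), float(s.frames[2].data.mean())

        on7, off7 = on_off_levels(0.7)
        assert on7 == pytest.approx(0.7 * leak)
        assert off7 == 0.0
        on10, off10 = on_off_levels(1.0)
        scale_on, scale_bleed = excitation_overlap(1.0)
        assert on10 == pytest.approx(scale_on * leak)
        assert off10 == pytest.approx(scale_bleed * leak)  # bleed-through

    def test_invalid_duty_rejected(self, cam_small, flat_ill, nir_channel):
        card = PlanarTarget.uniform_card(450.0)
        for duty in (0.0, 1.5, -0.2):
            with pytest.raises(ConfigError):
                generate_stream(card, cam_small, flat_ill, nir_channel, n_frames=4, duty=duty)

    def test_seeded_stream_reproducible(self, cam_small, flat_ill, nir_channel):
        card = PlanarTarget.fluorescent_spot_card(450.0)
        kw = dict(n_frames=6, noise=NoiseModel(seed=11))
        s1 = generate_stream(card, cam_small, flat_ill, nir_channel, **kw)
        s2 = generate_stream(card, cam_small, flat_ill, nir_channel, **kw)
        assert np.array_equal(s1.intensities(), s2.intensities())
        # distinct frames carry distinct noise
        assert not np.array_equal(s1.frames[0].data, s1.frames[2].data)


class TestWellPlate:
    def test_duplicate_plate_layout(self):
        p = WellPlatePhantom.ir125_duplicate_plate()
        assert p.concentrations.shape == (2, 11)
        assert p.concentrations[p.control] == 0.0
        assert p.concentrations.max() == pytest.approx(100e-9)

    def test_control_must_be_zero_concentration(self):
        conc = np.array([[1e-9, 0.0]])
        with pytest.raises(ConfigError):
            WellPlatePhantom(1, 2, 9.0, 6.0, conc, control=(0, 0))
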