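import itertools

import numpy as np
import pytest

from scintshot import (AnalysisConfig, BadInputError, CameraModel, GrayImage,
                       InsufficientDataError, Line2D, PhantomSpec,
                       analyze_starshot, extract_star_lines,
                       line_distance_isocenter, merge_frames,
                       pairwise_intersections, render_beam_frame)

from oracles import brute_force_min_circle, true_intersections


def render_frames(spec):
    return [render_beam_frame(spec, i) for i in range(len(spec.gantry_angles_deg))]


class TestMergeFrames:
    def test_merge_of_identical_frames_is_identity(self, camera_scale_spec):
        f = render_beam_frame(camera_scale_spec, 0)
        merged = merge_frames([f, f, f])
        assert np.array_equal(merged.image.data, f.data)

    def test_all_zero_frame_is_neutral(self, camera_scale_spec):
        f = render_beam_frame(camera_scale_spec, 1)
        zeros = GrayImage(np.zeros_like(f.data), f.pixel_pitch_mm)
        assert np.array_equal(merge_frames([f, zeros]).image.data, f.data)

    def test_order_invariance(self, camera_scale_spec):
        frames = render_frames(camera_scale_spec)
        a = merge_frames(frames)
        b = merge_frames(frames[::-1])
        assert np.array_equal(a.image.data, b.image.data)

    def test_dimension_mismatch_rejected(self, camera_scale_spec):
        f = render_beam_frame(camera_scale_spec, 0)
        other = GrayImage(np.zeros((100, 100)), f.pixel_pitch_mm)
        with pytest.raises(BadInputError):
            merge_frames([f, other])

    def test_single_frame_rejected(self, camera_scale_spec):
        with pytest.raises(BadInputError):
            merge_frames([render_beam_frame(camera_scale_spec, 0)])


class TestExtractStarLines:
    def test_noiseless_six_beams(self, camera_scale_spec, camera_scale_config):
        star = merge_frames(render_frames(camera_scale_spec),
                            source_angles_deg=camera_scale_spec.gantry_angles_deg)
        center_px = camera_scale_spec.mm_to_px(camera_scale_spec.true_isocenter_mm)
        lines = extract_star_lines(star, center_px)
        assert len(lines) == 6
        iso = np.asarray(camera_scale_spec.true_isocenter_mm)
        for sl, nominal in zip(lines, sorted(a % 180 for a in
                                             camera_scale_spec.gantry_angles_deg)):
            mismatch = abs(sl.line.angle_deg - nominal) % 180
            assert min(mismatch, 180 - mismatch) < 0.2
            assert sl.line.distance_to(iso) < 0.02
            assert 0 < sl.peak_pair_quality <= 1

    def test_two_beams_insufficient(self):
        spec = PhantomSpec(gantry_angles_deg=(0.0, 90.0))
        star = merge_frames(render_frames(spec))
        with pytest.raises(InsufficientDataError):
            extract_star_lines(star, spec.mm_to_px(spec.true_isocenter_mm))

    def test_orientation_check_against_nominal_angles(self, camera_scale_spec):
        star = merge_frames(render_frames(camera_scale_spec))
        center = camera_scale_spec.mm_to_px(camera_scale_spec.true_isocenter_mm)
        lines = extract_star_lines(
            star, center, nominal_angles_deg=camera_scale_spec.gantry_angles_deg)
        tags = sorted(sl.gantry_angle_deg for sl in lines)
        assert tags == sorted(camera_scale_spec.gantry_angles_deg)


class TestPairwiseIntersections:
    def test_six_lines_give_fifteen_points(self, camera_scale_spec):
        star = merge_frames(render_frames(camera_scale_spec))
        center = camera_scale_spec.mm_to_px(camera_scale_spec.true_isocenter_mm)
        lines = extract_star_lines(star, center)
        assert len(pairwise_intersections(lines)) == 15

    def test_concurrent_lines_repeat_the_common_point(self):
        lines = [Line2D(point=(2.0, 3.0), direction=(np.cos(t), np.sin(t)))
                 for t in np.deg2rad([0, 60, 120])]
        pts = pairwise_intersections(lines)
        assert len(pts) == 3
        assert np.allclose(pts, (2.0, 3.0), atol=1e-9)

    def test_shallow_angle_pairs_excluded(self):
        lines = [Line2D(point=(0, 0), direction=(1, 0)),
                 Line2D(point=(0, 1), direction=(np.cos(np.deg2rad(1)),
                                                 np.sin(np.deg2rad(1)))),
                 Line2D(point=(0, 0), direction=(0, 1))]
        pts = pairwise_intersections(lines, min_angle_deg=5)
        assert len(pts) == 2  # the 1-degree pair contributes nothing

    def test_fewer_than_three_lines_rejected(self):
        lines = [Line2D(point=(0, 0), direction=(1, 0)),
                 Line2D(point=(0, 0), direction=(0, 1))]
        with pytest.raises(InsufficientDataError):
            pairwise_intersections(lines)


class TestAnalyzeStarshot:
    def test_concurrent_beams_recover_isocenter(self, camera_scale_spec,
                                                camera_scale_config):
        res = analyze_starshot(render_frames(camera_scale_spec),
                               camera_scale_config)
        iso = np.asarray(camera_scale_spec.true_isocenter_mm)
        assert np.hypot(*(res.circle.center - iso)) < 0.2 * camera_scale_spec.pixel_pitch_mm
        assert res.circle.radius_mm < 0.05
        assert len(res.intersections_mm) == 15

    def test_offset_beams_match_analytic_oracle(self):
        rng = np.random.default_rng(42)
        spec = PhantomSpec(beam_offsets_mm=tuple(rng.uniform(-0.5, 0.5, 6)),
                           noise_sigma=0.0)
        cfg = AnalysisConfig(gantry_angles_deg=spec.gantry_angles_deg)
        res = analyze_starshot(render_frames(spec), cfg)
        center, radius = brute_force_min_circle(true_intersections(spec))
        assert np.hypot(*(res.circle.center - center)) < 0.05
        assert abs(res.circle.radius_mm - radius) < 0.1

    def test_offset_doubling_at_least_doubles_radius(self):
        offs = np.array([0.12, -0.3, 0.21, -0.15, 0.26, -0.08])
        radii = []
        for scale in (1.0, 2.0):
            spec = PhantomSpec(beam_offsets_mm=tuple(scale * offs))
            cfg = AnalysisConfig(gantry_angles_deg=spec.gantry_angles_deg,
                                 orientation_tolerance_deg=5.0)
            radii.append(analyze_starshot(render_frames(spec), cfg).circle.radius_mm)
        assert radii[1] >= 2.0 * radii[0] * 0.99

    def test_rotation_equivariance(self, camera_scale_spec):
        rng = np.random.default_rng(17)
        spec = PhantomSpec(beam_offsets_mm=tuple(rng.uniform(-0.4, 0.4, 6)))
        frames = render_frames(spec)
        res = analyze_starshot(frames, AnalysisConfig())
        rotated = [GrayImage(np.rot90(f.data), f.pixel_pitch_mm) for f in frames]
        res_rot = analyze_starshot(rotated, AnalysisConfig())
        h_mm = frames[0].shape[0] * spec.pixel_pitch_mm
        # rot90 (counter-clockwise in array terms): (x, y) -> (y, H - x)
        expect = np.array([res.circle.center_mm[1],
                           h_mm - spec.pixel_pitch_mm - res.circle.center_mm[0]])
        assert np.hypot(*(res_rot.circle.center - expect)) < 0.05
        assert abs(res_rot.circle.radius_mm - res.circle.radius_mm) < 0.05

    def test_calibration_toggle_shifts_isocenter_below_tolerance(self):
        # realistic mild barrel distortion; star-lines cross near the
        # principal point so rectification barely moves the result
        camera = CameraModel(focal_px=(1500.0, 1500.0),
                             principal_point_px=(479.5, 479.5),
                             radial_k1=-0.05)
        rng = np.random.default_rng(3)
        spec = PhantomSpec(beam_offsets_mm=tuple(rng.uniform(-0.4, 0.4, 6)),
                           distortion=camera)
        frames = render_frames(spec)
        cfg_cal = AnalysisConfig(gantry_angles_deg=spec.gantry_angles_deg,
                                 camera=camera)
        res_cal = analyze_starshot(frames, cfg_cal)
        res_raw = analyze_starshot(frames, cfg_cal.without_camera())
        delta = np.abs(res_cal.circle.center - res_raw.circle.center)
        assert np.max(delta) <= 0.07

    def test_stage_tagging_on_failure(self):
        spec = PhantomSpec(gantry_angles_deg=(0.0, 90.0))
        with pytest.raises(InsufficientDataError, match=r"\[extract\]"):
            analyze_starshot(render_frames(spec), AnalysisConfig())


class TestLineDistanceVariant:
    def test_concurrent_lines_give_their_common_point(self):
        lines = [Line2D(point=(4.0, -1.5), direction=(np.cos(t), np.sin(t)))
                 for t in np.deg2rad([10, 70, 130])]
        center, radius = line_distance_isocenter(lines)
        assert np.allclose(center, (4.0, -1.5), atol=1e-6)
        assert radius < 1e-6

    def test_reported_alongside_when_enabled(self, camera_scale_spec):
        cfg = AnalysisConfig(gantry_angles_deg=camera_scale_spec.gantry_angles_deg,
                             line_distance_variant=True)
        res = analyze_starshot(render_frames(camera_scale_spec), cfg)
        assert res.line_distance_center_mm is not None
        assert np.hypot(*(np.asarray(res.line_distance_center_mm)
                          - res.circle.center)) < 0.05
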