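import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazeqc import (
    AmbiguousDetection,
    CameraModel,
    ConfigurationError,
    DegenerateGeometry,
    MarkerDetection,
    MarkersNotFound,
    ScreenGeometry,
    ThresholdConfig,
    compute_scaling_factor,
    detect_markers,
    estimate_viewing_distance,
    eyelink_pixels_to_degrees,
    map_gaze_to_degrees,
    render_scene_frame,
    undistort_detection,
    undistort_points,
)
from helpers import distort_point_oracle


def square_detection(center=(640.0, 360.0), half=300.0, diam=30.0,
                     undistorted=True):
    cx, cy = center
    return MarkerDetection(
        corner_points={
            "TL": (cx - half, cy - half), "TR": (cx + half, cy - half),
            "BL": (cx - half, cy + half), "BR": (cx + half, cy + half),
        },
        target_point=(cx, cy),
        corner_diameters_px={c: diam for c in ("TL", "TR", "BL", "BR")},
        undistorted=undistorted,
    )


class TestDetectMarkers:
    def test_noiseless_frame_centers_within_half_pixel(self, rendered_bright):
        img, truth = rendered_bright
        det = detect_markers(img)
        for cid, ref in truth.marker_pixel_positions.items():
            got = det.target_point if cid == "target" else det.corner_points[cid]
            assert np.hypot(got[0] - ref[0], got[1] - ref[1]) < 0.5

    def test_uniform_frame_raises(self):
        frame = np.full((480, 640, 3), 200, dtype=np.uint8)
        with pytest.raises(MarkersNotFound):
            detect_markers(frame)

    def test_noisy_frame_centers_within_one_pixel(self, distorted_camera, screen):
        img, truth = render_scene_frame(distorted_camera, screen, "bright",
                                        supersample=2, noise_sigma=2.0 / 255.0,
                                        seed=123)
        det = detect_markers(img)
        for cid, ref in truth.marker_pixel_positions.items():
            got = det.target_point if cid == "target" else det.corner_points[cid]
            assert np.hypot(got[0] - ref[0], got[1] - ref[1]) < 1.0

    def test_dark_condition_detects_too(self, distorted_camera, screen):
        img, truth = render_scene_frame(distorted_camera, screen, "dark",
                                        supersample=2)
        det = detect_markers(img)
        ref = truth.marker_pixel_positions["target"]
        assert np.hypot(det.target_point[0] - ref[0],
                        det.target_point[1] - ref[1]) < 0.5

    def test_corner_identities_match_quadrants(self, rendered_bright):
        img, truth = rendered_bright
        det = detect_markers(img)
        assert det.corner_points["TL"][0] < det.corner_points["TR"][0]
        assert det.corner_points["TL"][1] < det.corner_points["BL"][1]
        assert det.corner_points["BR"][0] > det.corner_points["BL"][0]

    def test_missing_corner_identity_rejected(self):
        with pytest.raises(ConfigurationError):
            MarkerDetection(corner_points={"TL": (0, 0)}, target_point=(1, 1),
                            corner_diameters_px={})


class TestUndistortPoints:
    def test_zero_coefficients_identity(self, camera):
        pts = np.array([[100.0, 200.0], [640.0, 360.0], [np.nan, 5.0]])
        out = undistort_points(pts, camera)
        np.testing.assert_array_equal(out, pts)

    def test_round_trip_below_tolerance(self, distorted_camera):
        cam = distorted_camera
        # central 80 % of the image
        u = np.linspace(0.1 * cam.width, 0.9 * cam.width, 15)
        v = np.linspace(0.1 * cam.height, 0.9 * cam.height, 15)
        uu, vv = np.meshgrid(u, v)
        ideal = np.column_stack([uu.ravel(), vv.ravel()])
        xn = (ideal[:, 0] - cam.cx) / cam.fx
        yn = (ideal[:, 1] - cam.cy) / cam.fy
        xd, yd = distort_point_oracle(xn, yn, k1=-0.1)
        observed = np.column_stack([cam.cx + cam.fx * xd, cam.cy + cam.fy * yd])
        recovered = undistort_points(observed, cam)
        assert np.max(np.abs(recovered - ideal)) < 1e-4

    def test_principal_point_is_fixed_point(self, distorted_camera):
        p = np.array([distorted_camera.cx, distorted_camera.cy])
        out = undistort_points(p, distorted_camera)
        assert out == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("k1", [-0.2, -0.05, 0.1, 0.2])
    def test_round_trip_various_k1(self, k1):
        cam = CameraModel(fx=1400.0, fy=1400.0, cx=640.0, cy=360.0,
                          distortion=(k1, 0, 0, 0, 0), width=1280, height=720)
        u = np.linspace(0.1 * cam.width, 0.9 * cam.width, 9)
        v = np.linspace(0.1 * cam.height, 0.9 * cam.height, 9)
        uu, vv = np.meshgrid(u, v)
        ideal = np.column_stack([uu.ravel(), vv.ravel()])
        xn, yn = (ideal[:, 0] - cam.cx) / cam.fx, (ideal[:, 1] - cam.cy) / cam.fy
        xd, yd = distort_point_oracle(xn, yn, k1=k1)
        observed = np.column_stack([cam.cx + cam.fx * xd, cam.cy + cam.fy * yd])
        assert np.max(np.abs(undistort_points(observed, cam) - ideal)) < 1e-4


class TestScalingFactor:
    def test_fronto_parallel_ratio(self, screen):
        # consistent square layout: apparent = physical / 0.5 -> 0.5 mm/px
        layout = screen.marker_layout
        det = MarkerDetection(
            corner_points={c: (640 + layout[c][0] / 0.5, 360 - layout[c][1] / 0.5)
                           for c in ("TL", "TR", "BL", "BR")},
            target_point=(640.0, 360.0),
            corner_diameters_px={c: 30.0 for c in ("TL", "TR", "BL", "BR")},
            undistorted=True,
        )
        assert compute_scaling_factor(det, screen) == pytest.approx(0.5, rel=1e-12)

    def test_rendered_frame_matches_pinhole(self, rendered_bright, distorted_camera,
                                            screen):
        img, truth = rendered_bright
        det = undistort_detection(detect_markers(img), distorted_camera)
        scale = compute_scaling_factor(det, screen)
        assert scale == pytest.approx(930.0 / 1400.0, rel=0.01)

    def test_homogeneity(self, screen):
        det = square_detection()
        scale1 = compute_scaling_factor(det, screen)
        det2 = MarkerDetection(
            corner_points={c: (2 * u, 2 * v) for c, (u, v) in det.corner_points.items()},
            target_point=(0.0, 0.0),
            corner_diameters_px=det.corner_diameters_px,
            undistorted=True,
        )
        assert compute_scaling_factor(det2, screen) == pytest.approx(scale1 / 2)

    def test_translation_invariance(self, screen):
        det = square_detection()
        shifted = MarkerDetection(
            corner_points={c: (u + 37.0, v - 11.0)
                           for c, (u, v) in det.corner_points.items()},
            target_point=(677.0, 349.0),
            corner_diameters_px=det.corner_diameters_px,
            undistorted=True,
        )
        assert compute_scaling_factor(shifted, screen) == pytest.approx(
            compute_scaling_factor(det, screen), rel=1e-12)

    def test_coincident_points_raise(self, screen):
        det = square_detection(half=0.0)
        with pytest.raises(DegenerateGeometry):
            compute_scaling_factor(det, screen)


class TestViewingDistance:
    def test_formula_arithmetic(self, screen):
        cam = CameraModel(fx=1000.0, fy=1000.0, cx=320.0, cy=240.0,
                          width=640, height=480)
        scr = ScreenGeometry(marker_diameter_mm=10.0)
        det = square_detection(center=(320, 240), diam=10.0)
        assert estimate_viewing_distance(det, scr, cam) == pytest.approx(1000.0)

    def test_inverse_proportionality(self, camera, screen):
        d1 = estimate_viewing_distance(square_detection(diam=20.0), screen, camera)
        d2 = estimate_viewing_distance(square_detection(diam=40.0), screen, camera)
        assert d1 == pytest.approx(2.0 * d2)

    def test_rendered_frame_within_one_percent(self, rendered_bright,
                                               distorted_camera, screen):
        img, truth = rendered_bright
        det = undistort_detection(detect_markers(img), distorted_camera)
        dist = estimate_viewing_distance(det, screen, distorted_camera)
        assert abs(dist - truth.true_distance) / truth.true_distance < 0.01

    def test_zero_apparent_size_raises(self, camera, screen):
        det = square_detection(diam=0.0)
        with pytest.raises(DegenerateGeometry):
            estimate_viewing_distance(det, screen, camera)

    def test_translation_invariance(self, camera, screen):
        base = square_detection()
        shifted = MarkerDetection(
            corner_points={c: (u + 50, v + 20) for c, (u, v) in
                           base.corner_points.items()},
            target_point=(690.0, 380.0),
            corner_diameters_px=base.corner_diameters_px,
            undistorted=True,
        )
        assert estimate_viewing_distance(shifted, screen, camera) == pytest.approx(
            estimate_viewing_distance(base, screen, camera))


class TestMapGazeToDegrees:
    def test_target_center_maps_to_zero(self):
        det = square_detection()
        out = map_gaze_to_degrees(np.array([640.0, 360.0]), det, 0.5, 930.0)
        assert out == pytest.approx((0.0, 0.0))

    def test_forty_five_degrees(self):
        det = square_detection(center=(0.0, 0.0))
        # gaze_mm equals distance on x -> 45 deg
        out = map_gaze_to_degrees(np.array([930.0 / 0.5, 0.0]), det, 0.5, 930.0)
        assert out[0] == pytest.approx(45.0)
        assert out[1] == pytest.approx(0.0)

    def test_y_axis_flipped_to_up(self):
        det = square_detection(center=(0.0, 0.0))
        out = map_gaze_to_degrees(np.array([0.0, 100.0]), det, 0.5, 930.0)
        assert out[1] < 0  # image-down offset means looking below center

    def test_nan_propagates_without_exception(self):
        det = square_detection()
        out = map_gaze_to_degrees(np.array([[np.nan, 10.0], [5.0, 5.0]]),
                                  det, 0.5, 930.0)
        assert np.isnan(out[0, 0]) and np.isfinite(out[1]).all()

    def test_invalid_scale_raises(self):
        with pytest.raises(ConfigurationError):
            map_gaze_to_degrees(np.zeros(2), square_detection(), 0.0, 930.0)

    @given(st.floats(-500, 500), st.floats(-500, 500), st.floats(1, 50))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_each_pixel_coordinate(self, u, v, step):
        det = square_detection()
        a = map_gaze_to_degrees(np.array([u, v]), det, 0.5, 930.0)
        b = map_gaze_to_degrees(np.array([u + step, v]), det, 0.5, 930.0)
        c = map_gaze_to_degrees(np.array([u, v + step]), det, 0.5, 930.0)
        assert b[0] > a[0]
        assert c[1] < a[1]  # y flip: larger image v -> lower gaze


class TestEyelinkConversion:
    def test_center_maps_to_zero(self):
        out = eyelink_pixels_to_degrees(np.array([960.0, 540.0]),
                                        (960.0, 540.0), (35.0, 35.0))
        assert out == pytest.approx((0.0, 0.0))

    def test_one_resolution_unit_is_one_degree(self):
        out = eyelink_pixels_to_degrees(np.array([995.0, 540.0]),
                                        (960.0, 540.0), (35.0, 35.0))
        assert out == pytest.approx((1.0, 0.0))

    def test_zero_resolution_raises(self):
        with pytest.raises(ConfigurationError):
            eyelink_pixels_to_degrees(np.zeros(2), (0, 0), (0.0, 35.0))

    @given(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3))
    @settings(max_examples=50, deadline=None)
    def test_linearity_of_centered_map(self, a, b):
        center = (960.0, 540.0)
        res = (35.0, 30.0)
        fa = eyelink_pixels_to_degrees(np.array([a, a]), center, res)
        fb = eyelink_pixels_to_degrees(np.array([b, b]), (0.0, 0.0), res)
        fab = eyelink_pixels_to_degrees(np.array([a + b, a + b]), center, res)
        np.testing.assert_allclose(fa + fb, fab, atol=1e-9)

    def test_nan_propagates(self):
        out = eyelink_pixels_to_degrees(np.array([np.nan, 1.0]), (0, 0), (35, 35))
        assert np.isnan(out[0]) and np.isfinite(out[1])


class TestEndToEnd:
    def test_round_trip_on_rendered_session(self, rendered_bright, distorted_camera,
                                            screen):
        img, truth = rendered_bright  # rendered with true gaze (3, -2) degrees
        det = undistort_detection(detect_markers(img), distorted_camera)
        scale = compute_scaling_factor(det, screen)
        dist = estimate_viewing_distance(det, screen, distorted_camera)
        gaze = undistort_points(np.array([truth.gaze_pixel]), distorted_camera)
        deg = map_gaze_to_degrees(gaze, det, scale, dist)
        assert deg[0, 0] == pytest.approx(3.0, abs=0.1)
        assert deg[0, 1] == pytest.approx(-2.0, abs=0.1)
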