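"""Mask morphometry: shape metrics, hole width, neck radius, tracking."""

import numpy as np
import pytest

from smcluster.config import config_from_dict
from smcluster.morphometry import (
    frame_metrics,
    label_and_track,
    measure_hole,
    measure_neck,
)
from smcluster.synth import _rasterize_ellipse, gen_fusion_track, gen_hole_series


def circ_of(det):
    return 4 * np.pi * det.area_px / det.perimeter_px**2


class TestShapeMetrics:
    def test_disc_circularity_near_one(self):
        mask = _rasterize_ellipse((256, 256), (128, 128), (100, 100))
        det = frame_metrics(mask)[0]
        assert 0.98 <= circ_of(det) <= 1.02

    @pytest.mark.parametrize("R", [30, 50, 100])
    def test_disc_perimeter_converges(self, R):
        mask = _rasterize_ellipse((256, 256), (128, 128), (R, R))
        det = frame_metrics(mask)[0]
        assert abs(det.perimeter_px - 2 * np.pi * R) / (2 * np.pi * R) <= 0.02

    def test_disc_area_within_two_percent(self):
        for R in (20, 50, 100):
            mask = _rasterize_ellipse((256, 256), (128, 128), (R, R))
            det = frame_metrics(mask)[0]
            assert det.area_px == pytest.approx(np.pi * R**2, rel=0.02)

    def test_two_to_one_ellipse_anisotropy(self):
        """Moments of an ideal 2:1 ellipse give axis ratio 2 and
        eps = (c - a)/(c + a) = -1/3."""
        mask = _rasterize_ellipse((300, 300), (150, 150), (120, 60))
        det = frame_metrics(mask)[0]
        assert det.major_px / det.minor_px == pytest.approx(2.0, abs=0.03)
        eps = (det.minor_px - det.major_px) / (det.minor_px + det.major_px)
        assert eps == pytest.approx(-1.0 / 3.0, abs=0.02)

    def test_square_circularity_tends_to_pi_over_4(self):
        mask = np.zeros((300, 300), np.uint8)
        mask[50:250, 50:250] = 255
        det = frame_metrics(mask)[0]
        assert circ_of(det) == pytest.approx(np.pi / 4.0, abs=0.01)

    def test_translation_leaves_area_and_circularity_unchanged(self):
        m1 = _rasterize_ellipse((300, 300), (120, 130), (70, 40))
        m2 = np.roll(np.roll(m1, 17, axis=0), -23, axis=1)
        d1, d2 = frame_metrics(m1)[0], frame_metrics(m2)[0]
        assert d1.area_px == d2.area_px
        assert abs(circ_of(d1) - circ_of(d2)) < 1e-6


class TestTracking:
    def _stack_two_objects(self):
        frames = []
        for i in range(5):
            f = np.zeros((200, 300), np.uint8)
            f |= _rasterize_ellipse((200, 300), (60 + 2 * i, 100), (25, 25))
            f |= _rasterize_ellipse((200, 300), (220 - 2 * i, 100), (35, 20))
            frames.append(f)
        return np.stack(frames)

    def test_two_moving_objects_yield_two_full_tracks(self):
        tracks = label_and_track(self._stack_two_objects(), pixel_size_um=1.0,
                                 frame_interval_s=60.0, min_area_um2=100.0)
        assert len(tracks) == 2
        assert all(len(t) == 5 for t in tracks)

    def test_tracking_is_permutation_invariant(self):
        stack = self._stack_two_objects()
        tracks = label_and_track(stack, 1.0, 60.0)
        flipped = label_and_track(stack[:, :, ::-1].copy(), 1.0, 60.0)
        areas = sorted(tuple(t.area_um2) for t in tracks)
        areas_f = sorted(tuple(t.area_um2) for t in flipped)
        assert areas == areas_f

    def test_small_components_dropped(self):
        f = np.zeros((100, 100), np.uint8)
        f[10:12, 10:12] = 255  # 4 px
        f[40:80, 40:80] = 255
        tracks = label_and_track(f[None], pixel_size_um=1.0,
                                 frame_interval_s=1.0, min_area_um2=100.0)
        assert len(tracks) == 1

    def test_empty_frames_are_not_errors(self):
        stack = np.zeros((3, 50, 50), np.uint8)
        assert label_and_track(stack, 1.0, 1.0) == []


class TestMeasureHole:
    def test_round_trip_against_generator(self):
        cfg = config_from_dict({
            "seed": 2, "scenario": "hole", "a_max_um": 200.0, "C_per_s": 2e-3,
            "n_frames": 8, "frame_interval_s": 300.0, "pixel_size_um": 1.0,
            "image_shape": [512, 512], "render_masks": True})
        series, stack = gen_hole_series(cfg)
        meas = measure_hole(stack, pixel_size_um=1.0, frame_interval_s=300.0)
        assert np.max(np.abs(meas.width_um - series.width_um)) <= 1.0

    def test_full_frame_background_gives_empty_series(self):
        stack = np.zeros((3, 64, 64), np.uint8)
        meas = measure_hole(stack)
        assert len(meas) == 0

    def test_circular_hole_width_equals_diameter(self):
        frame = np.full((256, 256), 255, np.uint8)
        frame[_rasterize_ellipse((256, 256), (128, 128), (40, 40)) > 0] = 0
        meas = measure_hole(frame[None], pixel_size_um=1.0)
        assert meas.width_um[0] == pytest.approx(80.0, abs=1.0)

    def test_hole_touching_border_is_not_a_hole(self):
        frame = np.full((128, 128), 255, np.uint8)
        frame[:20, :] = 0  # open edge, not an enclosed hole
        meas = measure_hole(frame[None], pixel_size_um=1.0)
        assert meas.width_um[0] == 0.0

    def test_tip_profile_parabola_round_trip(self):
        """A rendered parabolic hole edge is recovered well enough to
        re-fit the profile coefficient within 20%."""
        from smcluster.hole import fit_tip_parabola

        A_true = 2.0  # px^(1/2), y = A sqrt(x)
        h, w = 240, 400
        frame = np.full((h, w), 255, np.uint8)
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        xb = np.clip(350.0 - xx, 0.0, None)  # distance back from the tip at x=350
        inside = (xx <= 350) & (xx >= 30) & (np.abs(yy - h / 2) <= A_true * np.sqrt(xb))
        frame[inside] = 0
        meas = measure_hole(frame[None], pixel_size_um=1.0, extract_profile=True,
                            axis_hint=0.0, profile_window_px=200.0)
        keep = meas.profile_x_um > 2.0
        A_fit = fit_tip_parabola(meas.profile_x_um[keep], meas.profile_y_um[keep])
        assert A_fit == pytest.approx(A_true, rel=0.2)


class TestMeasureNeck:
    def test_round_trip_against_generator(self):
        cfg = config_from_dict({
            "seed": 3, "scenario": "fusion", "pixel_size_um": 1.0,
            "image_shape": [320, 520], "render_masks": True, "n_frames": 20})
        series, stack = gen_fusion_track(cfg)
        meas = measure_neck(stack, pixel_size_um=1.0, frame_interval_s=1200.0)
        assert np.max(np.abs(2 * meas.rho_um - 2 * series.rho_um)) <= 2.0

    def test_equal_discs_R0(self):
        cfg = config_from_dict({
            "seed": 3, "scenario": "fusion", "R1_um": 100.0, "R2_um": 100.0,
            "pixel_size_um": 1.0, "image_shape": [320, 520],
            "render_masks": True, "n_frames": 4})
        _, stack = gen_fusion_track(cfg)
        meas = measure_neck(stack, pixel_size_um=1.0)
        assert meas.R0_um == pytest.approx(100.0, rel=0.01)

    def test_separated_lobes_give_zero_rho(self):
        frame = np.zeros((200, 400), np.uint8)
        frame |= _rasterize_ellipse((200, 400), (100, 100), (40, 40))
        frame |= _rasterize_ellipse((200, 400), (300, 100), (40, 40))
        meas = measure_neck(frame[None], pixel_size_um=1.0)
        assert np.all(meas.rho_um == 0.0)

    def test_fully_merged_circle_plateaus_at_radius(self):
        frame = _rasterize_ellipse((300, 300), (150, 150), (80, 80))
        meas = measure_neck(frame[None], pixel_size_um=1.0,
                            centers_px=((110.0, 150.0), (190.0, 150.0)))
        assert meas.rho_um[0] == pytest.approx(80.0, abs=3.0)

    def test_three_lobes_raise(self):
        frame = np.zeros((100, 300), np.uint8)
        for cx in (50, 150, 250):
            frame |= _rasterize_ellipse((100, 300), (cx, 50), (20, 20))
        with pytest.raises(ValueError, match="two lobes"):
            measure_neck(frame[None])
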