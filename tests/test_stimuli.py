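"""Stimulus geometry, trajectories and rasterisation."""

import numpy as np
import pytest

import mantis_stereo as ms
from mantis_stereo.stimuli import Condition, make_condition

GEOM = ms.DEFAULT_GEOMETRY
HALF_GHOST = ms.screen_disparity_from_parallax(2.1) / 2.0  # ~6 deg


def single_disk_spec(diameter=11.25, distance=2.5, **kwargs):
    return ms.StimulusSpec(
        disk_diameter=diameter,
        disparity=ms.DisparitySpec.from_distance(distance),
        **kwargs,
    )


class TestMakeCondition:
    def test_ghost_geometries(self):
        a_l, a_r = make_condition(Condition.GHOST_A, 11.4, GEOM)
        assert a_l == pytest.approx((HALF_GHOST,)) and a_r == pytest.approx((-HALF_GHOST,))
        b_l, b_r = make_condition(Condition.GHOST_B, 11.4, GEOM)
        assert b_l == b_r  # both eyes see the same pair
        assert sorted(b_l) == pytest.approx([-HALF_GHOST, HALF_GHOST])
        c_l, c_r = make_condition(Condition.GHOST_C, 11.4, GEOM)
        assert sorted(c_l) == pytest.approx([-3 * HALF_GHOST, HALF_GHOST])
        assert sorted(c_r) == pytest.approx([-HALF_GHOST, 3 * HALF_GHOST])
        # C separates the disks within each eye further than B does
        assert max(c_l) - min(c_l) > max(b_l) - min(b_l)
        d_l, d_r = make_condition(Condition.GHOST_D, 11.4, GEOM)
        assert d_l == (0.0,) and d_r == (0.0,)

    def test_single_crossed_splits_disparity(self):
        disp = ms.DisparitySpec.from_distance(2.5)
        left, right = make_condition(Condition.SINGLE_CROSSED, 11.25, GEOM, disp)
        assert left[0] == pytest.approx(disp.screen_disparity / 2)
        assert right[0] == pytest.approx(-disp.screen_disparity / 2)

    def test_monocular_leaves_other_eye_empty(self):
        disp = ms.DisparitySpec.zero()
        assert make_condition(Condition.MONOCULAR_LEFT, 11.25, GEOM, disp)[1] == ()
        assert make_condition(Condition.MONOCULAR_RIGHT, 11.25, GEOM, disp)[0] == ()


class TestTrajectory:
    def test_midpoint_is_straight_ahead(self):
        spec = single_disk_spec(distance=10.0)
        t = spec.duration / 2
        x_l, y_l, x_r, y_r = ms.trajectory(spec, t)
        assert 0.5 * (x_l + x_r) == pytest.approx(0.0, abs=1e-9)
        assert y_l == y_r == 0.0

    def test_crossed_disk_splits_six_degrees_at_midline(self):
        spec = single_disk_spec(distance=2.5)
        x_l, _, x_r, _ = ms.trajectory(spec, spec.duration / 2)
        assert x_l == pytest.approx(6.0, abs=0.01)
        assert x_r == pytest.approx(-6.0, abs=0.01)

    def test_vertical_disparity_split_is_constant(self):
        spec = single_disk_spec(vertical_disparity=10.0)
        for t in (0.0, 0.3, spec.duration):
            _, y_l, _, y_r = ms.trajectory(spec, t)
            assert y_l - y_r == pytest.approx(10.0)

    def test_time_outside_traverse_rejected(self):
        spec = single_disk_spec()
        with pytest.raises(ValueError):
            ms.trajectory(spec, spec.duration + 0.1)


class TestRendering:
    def test_per_frame_advance_matches_speed(self):
        seq = ms.render_disk_frames(single_disk_spec(), profile=ms.COARSE_PROFILE)
        dx = np.diff(seq.target_centre_track[:, 0])
        assert dx == pytest.approx(82.0 * seq.frame_period)

    def test_full_profile_frame_count_covers_traverse(self):
        seq = ms.render_disk_frames(single_disk_spec(), profile=ms.FULL_PROFILE)
        assert seq.n_frames == int(np.ceil(60.0 / (82.0 / 60.0)))  # 44

    def test_frames_are_binary_and_area_is_roughly_disk_area(self):
        profile = ms.COARSE_PROFILE
        spec = single_disk_spec(diameter=16.88, distance=10.0)
        seq = ms.render_disk_frames(spec, profile=profile)
        assert set(np.unique(seq.left_frames)) <= {0.0, 1.0}
        mid = seq.n_frames // 2
        area_px = seq.left_frames[mid].sum()
        r_px = 0.5 * spec.disk_diameter / profile.pixel_pitch
        expected = np.pi * r_px**2
        assert abs(area_px - expected) < 2 * np.pi * r_px + 4  # within a perimeter band

    def test_left_right_centroids_differ_by_screen_disparity(self):
        profile = ms.COARSE_PROFILE
        spec = single_disk_spec(distance=2.5)
        seq = ms.render_disk_frames(spec, profile=profile)
        axis = seq.axis_degrees()
        mid = seq.n_frames // 2
        cl = (seq.left_frames[mid] * axis[None, :]).sum() / seq.left_frames[mid].sum()
        cr = (seq.right_frames[mid] * axis[None, :]).sum() / seq.right_frames[mid].sum()
        assert cl - cr == pytest.approx(spec.disparity.screen_disparity, abs=profile.pixel_pitch)

    def test_zero_diameter_renders_blank(self):
        seq = ms.render_disk_frames(single_disk_spec(diameter=0.0), profile=ms.COARSE_PROFILE)
        assert seq.left_frames.sum() == 0 and seq.right_frames.sum() == 0

    def test_polarity_complement(self):
        bright = ms.render_disk_frames(single_disk_spec(), profile=ms.COARSE_PROFILE)
        dark = ms.render_disk_frames(
            single_disk_spec(polarity="dark_on_bright"), profile=ms.COARSE_PROFILE
        )
        assert np.array_equal(dark.left_frames, 1.0 - bright.left_frames)

    def test_monocular_renders_blank_unstimulated_eye(self):
        spec = ms.StimulusSpec.for_condition(Condition.MONOCULAR_LEFT, 11.25)
        seq = ms.render_disk_frames(spec, profile=ms.COARSE_PROFILE)
        assert seq.right_frames.sum() == 0 and seq.left_frames.sum() > 0

    def test_offscreen_disk_warns(self):
        spec = single_disk_spec(diameter=2.0, perpendicular_offset=500.0)
        with pytest.warns(UserWarning):
            ms.render_disk_frames(spec, profile=ms.COARSE_PROFILE)


class TestEyeSwap:
    def test_swap_is_involutive(self):
        seq = ms.render_disk_frames(single_disk_spec(), profile=ms.COARSE_PROFILE)
        back = ms.apply_uncrossed(ms.apply_uncrossed(seq))
        assert np.array_equal(back.left_frames, seq.left_frames)
        assert np.array_equal(back.target_centre_track, seq.target_centre_track)

    def test_zero_disparity_stimulus_unchanged_by_swap(self):
        seq = ms.render_disk_frames(single_disk_spec(distance=10.0), profile=ms.COARSE_PROFILE)
        swapped = ms.apply_uncrossed(seq)
        assert np.array_equal(swapped.left_frames, seq.left_frames)

    def test_ghost_b_invariant_under_swap(self):
        spec = ms.StimulusSpec.for_condition(Condition.GHOST_B, 11.4)
        seq = ms.render_disk_frames(spec, profile=ms.COARSE_PROFILE)
        swapped = ms.apply_uncrossed(seq)
        assert np.array_equal(swapped.left_frames, seq.left_frames)
        assert np.array_equal(swapped.right_frames, seq.right_frames)

    def test_swapped_crossed_equals_rendered_uncrossed(self):
        crossed = ms.render_disk_frames(single_disk_spec(distance=2.5), profile=ms.COARSE_PROFILE)
        uncrossed = ms.render_disk_frames(
            single_disk_spec(distance=2.5, condition=Condition.UNCROSSED),
            profile=ms.COARSE_PROFILE,
        )
        swapped = ms.apply_uncrossed(crossed)
        assert np.array_equal(swapped.left_frames, uncrossed.left_frames)
        assert np.array_equal(swapped.right_frames, uncrossed.right_frames)


class TestExport:
    def test_tiff_export_round_trips(self, tmp_path):
        import tifffile

        seq = ms.render_disk_frames(single_disk_spec(), profile=ms.COARSE_PROFILE)
        meta = seq.export(tmp_path, stem="stim")
        stack = tifffile.imread(tmp_path / "stim_left.tif")
        assert stack.shape == seq.left_frames.shape
        assert np.array_equal(stack > 0, seq.left_frames > 0)
        assert meta["pixel_pitch_deg"] == ms.COARSE_PROFILE.pixel_pitch
        assert (tmp_path / "stim_meta.json").exists()
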