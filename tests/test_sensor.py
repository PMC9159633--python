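"""Receptive fields, drives, the output nonlinearity and the pipeline."""

import numpy as np
import pytest

import mantis_stereo as ms
from mantis_stereo.sensor import (
    binocular_response,
    build_receptive_field,
    expected_strikes,
    monocular_drive,
    simulate_stimulus,
)


class TestReceptiveField:
    def test_region_membership_at_fitted_values(self, table2_params):
        rf = build_receptive_field(table2_params, "left")
        axis = (np.arange(680) - 340) * 0.154

        def weight_at(x_deg, y_deg):
            i = 340 + round(x_deg / 0.154)
            j = 340 + round(y_deg / 0.154)
            return rf.weight_map[j, i]

        assert weight_at(7.7, 0.0) == pytest.approx(table2_params.w_e1)
        assert weight_at(7.7, 20.0) == pytest.approx(table2_params.w_i)
        assert weight_at(7.7, 6.0) == pytest.approx(table2_params.w_e2)

    def test_mirror_placement(self, table2_params):
        left = build_receptive_field(table2_params, "left")
        right = build_receptive_field(table2_params, "right")
        assert left.centre[0] == pytest.approx(7.7)
        assert right.centre[0] == pytest.approx(-7.7)
        # mirrored probe points carry the same weights
        for x, y in [(7.7, 0.0), (7.7, 6.0), (7.7, 20.0), (2.0, 0.0), (14.0, 0.0)]:
            i_l = 340 + round(x / 0.154)
            i_r = 340 - round(x / 0.154)
            j = 340 + round(y / 0.154)
            assert left.weight_map[j, i_l] == right.weight_map[j, i_r]

    def test_zero_preferred_disparity_gives_identical_maps(self, table2_params):
        p = table2_params.with_(alpha_pref=1e-9)
        left = build_receptive_field(p, "left")
        right = build_receptive_field(p, "right")
        assert np.array_equal(left.weight_map, right.weight_map)

    def test_full_field_stimulation_is_net_inhibitory(self, table2_params):
        rf = build_receptive_field(table2_params, "left")
        assert rf.total_weight() < 0


class TestDrives:
    def test_zero_input_and_linearity(self, table2_params):
        rf = build_receptive_field(table2_params, "left", 0.616, 170)
        J = np.zeros((170, 170))
        assert monocular_drive(J, rf) == 0.0
        rng = np.random.default_rng(1)
        J = rng.random((170, 170))
        assert monocular_drive(2 * J, rf) == pytest.approx(2 * monocular_drive(J, rf))

    def test_shape_mismatch_rejected(self, table2_params):
        rf = build_receptive_field(table2_params, "left", 0.616, 170)
        with pytest.raises(ValueError):
            monocular_drive(np.zeros((10, 10)), rf)


class TestBinocularResponse:
    def test_published_worked_example(self):
        """Equal near-peak drives from the two eyes produce R ~ 0.11; the
        same drive from one eye alone produces only ~ 0.002."""
        assert round(binocular_response(0.35, 0.35, -0.054, 5.05), 2) == 0.11
        assert round(binocular_response(0.35, 0.0, -0.054, 5.05), 3) == 0.002

    def test_below_threshold_is_silent(self):
        assert binocular_response(0.02, 0.02, -0.054, 5.05) == 0.0

    def test_symmetric_in_the_two_eyes(self):
        rng = np.random.default_rng(2)
        vl, vr = rng.random(50), rng.random(50)
        assert np.array_equal(
            binocular_response(vl, vr, -0.05, 5.0), binocular_response(vr, vl, -0.05, 5.0)
        )

    def test_monotone_in_total_drive(self):
        v = np.linspace(0, 1, 101)
        r = binocular_response(v, v, -0.054, 5.05)
        assert (np.diff(r) >= 0).all()
        # uniform attenuation of the input can only lower the response
        r_att = binocular_response(0.9 * v, 0.9 * v, -0.054, 5.05)
        assert (r_att <= r).all()

    def test_invalid_exponent_rejected(self):
        with pytest.raises(ValueError):
            binocular_response(0.1, 0.1, -0.05, 0.0)


class TestExpectedStrikes:
    def test_zero_response_zero_strikes(self):
        t = np.linspace(0, 1, 101)
        assert expected_strikes(np.zeros_like(t), t) == 0.0

    def test_constant_response_integrates_to_rate_times_duration(self):
        t = np.linspace(0, 0.5, 151)
        assert expected_strikes(np.full_like(t, 0.3), t, time_unit=1.0) == pytest.approx(0.15)

    def test_triangular_response_closed_form(self):
        t = np.linspace(0, 2.0, 2001)
        peak = 0.7
        r = peak * (1 - np.abs(t - 1.0))
        assert expected_strikes(r, t, time_unit=1.0) == pytest.approx(peak * 1.0, rel=1e-5)

    def test_too_few_or_nonuniform_samples_rejected(self):
        with pytest.raises(ValueError):
            expected_strikes(np.array([1.0]), np.array([0.0]))
        with pytest.raises(ValueError):
            expected_strikes(np.ones(3), np.array([0.0, 0.1, 0.3]))


class TestSimulatePipeline:
    def test_streaming_matches_materialised_filtering(self, table2_params):
        """The memory-light streaming path equals compute_neural_input +
        per-sample inner products."""
        profile = ms.COARSE_PROFILE
        spec = ms.StimulusSpec(
            disk_diameter=11.25, disparity=ms.DisparitySpec.from_distance(2.5)
        )
        resp = simulate_stimulus(spec, table2_params, profile=profile)
        seq = ms.render_disk_frames(spec, profile=profile)
        filt = ms.compute_neural_input(seq, ms.EarlyVisionParams.for_profile(profile))
        rf_l = build_receptive_field(table2_params, "left", profile.pixel_pitch, profile.canvas_size)
        rf_r = build_receptive_field(table2_params, "right", profile.pixel_pitch, profile.canvas_size)
        v_l = np.array([monocular_drive(J, rf_l) for J in filt.J_left])
        v_r = np.array([monocular_drive(J, rf_r) for J in filt.J_right])
        assert v_l == pytest.approx(resp.v_left, rel=1e-9, abs=1e-15)
        assert v_r == pytest.approx(resp.v_right, rel=1e-9, abs=1e-15)

    def test_response_invariants(self, table2_params):
        spec = ms.StimulusSpec(
            disk_diameter=11.25, disparity=ms.DisparitySpec.from_distance(2.0)
        )
        resp = simulate_stimulus(spec, table2_params, profile=ms.COARSE_PROFILE)
        assert (resp.R >= 0).all()
        assert resp.M_model >= 0
        assert resp.M_model == pytest.approx(
            expected_strikes(resp.R, resp.sample_times), rel=1e-12
        )

    def test_preferred_distance_gives_highest_strike_rate(self, table2_params):
        """Across simulated distances the sensor's preferred distance
        (about 2.1 cm for the fitted disparity) yields the peak response."""
        d_pref = round(table2_params.preferred_distance(), 1)
        distances = [1.0, 1.5, d_pref, 2.5, 3.75, 5.63, 10.0]
        for size in (11.25, 16.88):
            m = {
                d: simulate_stimulus(
                    ms.StimulusSpec(
                        disk_diameter=size, disparity=ms.DisparitySpec.from_distance(d)
                    ),
                    table2_params,
                    profile=ms.COARSE_PROFILE,
                ).M_model
                for d in distances
            }
            assert max(m, key=m.get) == d_pref

    def test_deterministic(self, table2_params):
        spec = ms.StimulusSpec(
            disk_diameter=11.4, disparity=ms.DisparitySpec.from_distance(2.5)
        )
        a = simulate_stimulus(spec, table2_params, profile=ms.COARSE_PROFILE)
        b = simulate_stimulus(spec, table2_params, profile=ms.COARSE_PROFILE)
        assert np.array_equal(a.R, b.R) and a.M_model == b.M_model
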