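"""Strapdown core: tilt, orientation, projection, integration, slope."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from gaitslope import (
    PipelineConfig,
    detect_mid_stance,
    estimate_slopes,
    integrate_displacements,
    integrate_orientation,
    project_to_global,
    segment_strides,
    simulate_recording,
    stride_slope,
    tilt_at_mid_stance,
    zero_phase_lowpass,
)
from gaitslope.errors import OrientationError
from tests.conftest import SLOPES, noiseless_scenario


class TestTilt:
    def test_vertical_shank_has_zero_tilt(self):
        assert tilt_at_mid_stance(9.8, 0.0) == 0.0

    @pytest.mark.parametrize("angle", [0.1, -0.25, 0.4])
    def test_pure_gravity_identity(self, angle):
        tilt = tilt_at_mid_stance(9.8 * np.cos(angle), 9.8 * np.sin(angle))
        assert tilt == pytest.approx(angle, abs=1e-12)

    def test_non_upright_sensor_rejected(self):
        with pytest.raises(OrientationError):
            tilt_at_mid_stance(-0.5, 3.0)

    def test_matches_simulator_tilt_at_mid_stance(self):
        scn = noiseless_scenario(slope=0.14, n_strides=10)
        rec, truth = simulate_recording(scn)
        i = int(round(truth.mid_stance_times[0] * rec.fs))
        tilt = tilt_at_mid_stance(rec.a_n[i], rec.a_t[i])
        assert tilt == pytest.approx(truth.theta_true[i], abs=1e-3)


class TestOrientation:
    def test_zero_rate_keeps_initial_tilt(self):
        theta = integrate_orientation(np.zeros(100), 100.0, 0.2)
        np.testing.assert_allclose(theta, 0.2)

    def test_constant_rate_integral(self):
        theta = integrate_orientation(np.ones(101), 100.0, 0.0)
        assert theta[0] == 0.0
        assert theta[-1] == pytest.approx(1.0, abs=1e-6)

    def test_tracks_simulator_truth_within_2_mrad(self, noiseless_walk):
        _, rec, truth = noiseless_walk
        wf = zero_phase_lowpass(rec.omega, rec.fs, 4.0)
        events = detect_mid_stance(wf, rec.fs, PipelineConfig())
        win = segment_strides(rec, events)[0]
        sl = slice(win["start"], win["stop"] + 1)
        theta = integrate_orientation(
            win["omega"], rec.fs, float(truth.theta_true[win["start"]])
        )
        assert np.max(np.abs(theta - truth.theta_true[sl])) < 2e-3


class TestProjection:
    def test_static_vertical_shank_projects_to_rest(self):
        n = np.full(50, 9.8)
        a_v, a_ap = project_to_global(n, np.zeros(50), np.zeros(50), g=9.8)
        np.testing.assert_allclose(a_v, 0.0, atol=1e-12)
        np.testing.assert_allclose(a_ap, 0.0, atol=1e-12)

    @given(
        data=hnp.arrays(
            np.float64,
            (3, 16),
            elements=st.floats(-20, 20, allow_nan=False),
        )
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_rotation_is_an_isometry(self, data):
        a_n, a_t, theta = data
        g = 9.8
        a_v, a_ap = project_to_global(a_n, a_t, theta, g)
        np.testing.assert_allclose(
            np.hypot(a_v + g, a_ap), np.hypot(a_n, a_t), atol=1e-10
        )

    def test_matches_simulator_global_accelerations(self, noiseless_walk):
        _, rec, truth = noiseless_walk
        a_v, a_ap = project_to_global(rec.a_n, rec.a_t, truth.theta_true, 9.8)
        assert np.max(np.abs(a_v - truth.a_v_true)) < 1e-3
        assert np.max(np.abs(a_ap - truth.a_ap_true)) < 1e-3


class TestDisplacements:
    def test_rest_stays_at_rest(self):
        S_v, S_ap, V_v, V_ap = integrate_displacements(
            np.zeros(100), np.zeros(100), 100.0
        )
        assert S_v == 0.0 and S_ap == 0.0
        np.testing.assert_allclose(V_v, 0.0)
        np.testing.assert_allclose(V_ap, 0.0)

    def test_constant_acceleration_closed_form(self):
        # 2 m/s² for 1 s from rest: S = a t² / 2 = 1 m
        a = np.full(101, 2.0)
        S_v, S_ap, _, V_ap = integrate_displacements(np.zeros(101), a, 100.0)
        assert S_ap == pytest.approx(1.0, abs=1e-4)
        assert V_ap[-1] == pytest.approx(2.0, abs=1e-6)

    def test_matches_simulator_stride_displacements(self):
        scn = noiseless_scenario(slope=0.06, n_strides=10)
        rec, truth = simulate_recording(scn)
        i0 = int(round(truth.mid_stance_times[0] * rec.fs))
        i1 = int(round(truth.mid_stance_times[1] * rec.fs))
        sl = slice(i0, i1 + 1)
        S_v, S_ap, _, _ = integrate_displacements(
            truth.a_v_true[sl], truth.a_ap_true[sl], rec.fs
        )
        assert S_v == pytest.approx(truth.S_v[0], abs=1e-3)
        assert S_ap == pytest.approx(truth.S_ap[0], abs=1e-3)


class TestStrideSlope:
    @pytest.mark.parametrize(
        "S_v,S_ap,expected", [(0.02, 1.0, 0.02), (0.0, 1.3, 0.0)]
    )
    def test_ratio(self, S_v, S_ap, expected):
        slope, degenerate = stride_slope(S_v, S_ap)
        assert slope == expected
        assert not degenerate

    def test_no_forward_progression_is_flagged(self):
        _, degenerate = stride_slope(0.01, 0.02)
        assert degenerate
        val, degenerate = stride_slope(0.01, 0.0)
        assert degenerate and np.isnan(val)


class TestPipeline:
    @pytest.mark.parametrize("slope", SLOPES)
    def test_noiseless_recovery_at_every_inclination(self, slope):
        scn = noiseless_scenario(slope=slope, n_strides=12)
        rec, _ = simulate_recording(scn)
        res = estimate_slopes(rec)
        assert res.n_strides == scn.n_strides
        assert not res.flags.any()
        np.testing.assert_allclose(res.slopes, slope, atol=5e-3)

    def test_level_ground_mean_near_zero(self):
        scn = noiseless_scenario(slope=0.0, n_strides=30)
        rec, _ = simulate_recording(scn)
        res = estimate_slopes(rec)
        assert abs(res.slopes.mean()) < 2e-3

    def test_error_shrinks_with_sampling_rate(self):
        errs = []
        for fs in (100.0, 200.0, 400.0):
            scn = noiseless_scenario(slope=0.10, n_strides=8, fs=fs)
            rec, _ = simulate_recording(scn)
            res = estimate_slopes(rec)
            errs.append(np.max(np.abs(res.slopes - 0.10)))
        assert errs[0] >= errs[1] >= errs[2]

    def test_dead_accelerometer_raises_orientation_error(self):
        scn = noiseless_scenario(slope=-0.05, n_strides=5)
        rec, _ = simulate_recording(scn)
        rec.a_n[:] = 0.0
        rec.a_t[:] = 0.0
        with pytest.raises(OrientationError, match="tilt stage"):
            estimate_slopes(rec)

    def test_zero_tilt_baseline_bias_is_systematic_and_sign_linked(self):
        """Ignoring the mid-stance tilt (the predecessor method's
        assumption) biases the slope estimate in a deterministic
        direction opposite to the suppressed tilt: the unmodelled
        rotation leaks gravity into the antero-posterior channel."""
        cfg = PipelineConfig(use_tilt_correction=False)
        biases = {}
        for tilt in (0.1, -0.1):
            scn = noiseless_scenario(
                slope=0.0, n_strides=12, theta_ms_true=tilt
            )
            rec, _ = simulate_recording(scn)
            biases[tilt] = float(estimate_slopes(rec, cfg).slopes.mean())
        assert biases[0.1] < -0.01
        assert biases[-0.1] > 0.01
        # corrected pipeline has no such bias
        scn = noiseless_scenario(slope=0.0, n_strides=12, theta_ms_true=0.1)
        rec, _ = simulate_recording(scn)
        assert abs(estimate_slopes(rec).slopes.mean()) < 5e-3

    def test_mirrored_mounting_is_auto_corrected(self):
        scn = noiseless_scenario(slope=0.06, n_strides=10)
        rec, _ = simulate_recording(scn)
        rec.omega *= -1.0
        rec.a_t *= -1.0
        res = estimate_slopes(rec)
        assert res.meta["flipped"]
        np.testing.assert_allclose(res.slopes, 0.06, atol=5e-3)
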