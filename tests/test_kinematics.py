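import math

import numpy as np
import pytest

import oracles
from conftest import make_reach_meta, make_trial, quiet_bias, quiet_controller
from moveholdlab.io import TrialRecord
from moveholdlab.kinematics import (
    EventDetectionError,
    detect_end,
    detect_onset,
    lateral_signal,
    pulse_outcomes,
    reach_outcomes,
    release_outcomes,
)
from moveholdlab.synthetic import GatingMode, simulate_reach_trial, target_array

FS = 200.0


def min_jerk_trace(D=10.0, T=0.7, pre=0.5, post=0.5, direction=90.0):
    """Minimum-jerk reach of length D over T with stationary padding."""
    t = np.arange(0, pre + T + post, 1 / FS)
    tau = np.clip((t - pre) / T, 0, 1)
    s = D * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    ux, uy = math.cos(math.radians(direction)), math.sin(math.radians(direction))
    meta = make_reach_meta((0.0, 0.0), (D * ux, D * uy))
    return make_trial(t, s * ux, s * uy, meta=meta), t, tau


class TestOnset:
    def test_stationary_trial_errors(self):
        t = np.arange(0, 1, 1 / FS)
        tr = make_trial(t, np.zeros_like(t), np.zeros_like(t))
        with pytest.raises(EventDetectionError, match="never exceeds"):
            detect_onset(tr)

    def test_min_jerk_onset_at_analytic_crossing(self):
        # speed(tau) = (D/T)(30 tau^2 - 60 tau^3 + 30 tau^4) = 3.5 cm/s
        D, T, pre = 10.0, 0.7, 0.5
        tr, t, tau = min_jerk_trace(D, T, pre)
        roots = np.roots([30, -60, 30, 0, -3.5 * T / D])
        tau_star = min(r.real for r in roots if abs(r.imag) < 1e-9 and 0 < r.real < 1)
        onset = detect_onset(tr)
        assert onset == pytest.approx(pre + tau_star * T, abs=1.5 / FS)

    def test_step_velocity_onset(self):
        t = np.arange(0, 3, 1 / FS)
        x = np.where(t > 1.0, 10.0 * (t - 1.0), 0.0)
        tr = make_trial(t, x, np.zeros_like(t))
        assert detect_onset(tr) == pytest.approx(1.0, abs=2.5 / FS)


class TestEnd:
    def test_pass_through_target_no_end(self):
        # constant 20 cm/s through the target, stopping 5 cm past it
        t = np.arange(0, 2, 1 / FS)
        y = np.minimum(20.0 * t, 15.0)
        meta = make_reach_meta((0, 0), (0, 10))
        tr = make_trial(t, np.zeros_like(t), y, meta=meta)
        onset = detect_onset(tr)
        with pytest.raises(EventDetectionError):
            detect_end(tr, onset)

    def test_slow_arrival_detected_at_first_qualifying_sample(self):
        t = np.arange(0, 3, 1 / FS)
        # approach the target and crawl the last stretch at 1 cm/s
        y = np.where(t < 1.0, 9.7 * t, 9.7 + 1.0 * (t - 1.0))
        y = np.minimum(y, 10.0)
        meta = make_reach_meta((0, 0), (0, 10))
        tr = make_trial(t, np.zeros_like(t), y, meta=meta)
        onset = detect_onset(tr)
        end = detect_end(tr, onset)
        # inside the target from 0.98 s, but speed stays above 3.5 cm/s
        # until the crawl begins at t = 1.0 (plus the smoothing window)
        assert end == pytest.approx(1.0, abs=3.0 / FS)

    def test_servo_trial_matches_oracle(self):
        tg = target_array()
        tr = simulate_reach_trial(
            quiet_bias(impairment_scale=0.0), quiet_controller(),
            GatingMode(mode="off"), tg[0], tg[4], seed=0,
        )
        onset = detect_onset(tr)
        assert onset == oracles.onset_oracle(tr)
        assert detect_end(tr, onset) == oracles.end_oracle(tr, onset)


class TestReachOutcomes:
    def test_straight_reach(self):
        tr, _, _ = min_jerk_trace(direction=90.0)
        ro = reach_outcomes(tr)
        assert ro.theta_start == pytest.approx(0.0, abs=1e-9)
        assert ro.theta_end == pytest.approx(0.0, abs=1e-9)
        # the onset/end thresholds trim the sub-threshold creep at the ends
        chord = np.linalg.norm(
            tr.position()[np.searchsorted(tr.t, ro.end_t)]
            - tr.position()[np.searchsorted(tr.t, ro.onset_t)]
        )
        assert ro.path_length == pytest.approx(chord, rel=1e-9)
        assert ro.path_length == pytest.approx(10.0, rel=0.03)
        assert not ro.outlier

    def test_initial_heading_90_deg_off_is_outlier(self):
        # movement along +x while the nominal target is at +y
        t = np.arange(0, 1.5, 1 / FS)
        tau = np.clip(t / 0.7, 0, 1)
        s = 10 * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
        ang = math.radians(100.0)
        meta = make_reach_meta((0, 0), (0, 10))
        tr = make_trial(t, s * math.sin(ang) * -1.0, s * math.cos(ang), meta=meta)
        onset = detect_onset(tr)
        from moveholdlab.kinematics import _chord_angle

        theta = _chord_angle(tr, onset, np.array([0.0, 1.0]))
        assert abs(theta) >= 90.0

    def test_quarter_circle_path_length(self):
        # constant-speed quarter circle from (0,0) to (10,10): R = 10
        R = 10.0
        T = 2.0
        t = np.arange(0, T + 0.6, 1 / FS)
        phi = np.clip(t / T, 0, 1) * (math.pi / 2)
        x = R * np.sin(phi)
        y = R * (1 - np.cos(phi))
        meta = make_reach_meta((0, 0), (10.0, 10.0))
        # |target-start| is not 10 here; bypass direction norm via custom meta
        tr = make_trial(t, x, y, meta=meta)
        onset = detect_onset(tr)
        end = detect_end(tr, onset)
        ro = reach_outcomes(tr)
        analytic = (math.pi / 2) * R
        # onset trims the sub-threshold crawl at the very start of the arc
        assert ro.path_length == pytest.approx(analytic, rel=0.01)


class TestLateralSignal:
    def test_movement_along_reference_is_zero(self):
        tr, _, _ = min_jerk_trace(direction=37.0)
        lat_pos, lat_vel = lateral_signal(tr, 37.0)
        np.testing.assert_allclose(lat_pos, 0.0, atol=1e-9)
        np.testing.assert_allclose(lat_vel, 0.0, atol=1e-7)

    def test_ccw_of_up_is_leftward(self):
        t = np.arange(0, 1, 1 / FS)
        tr = make_trial(t, -2.0 * t, np.zeros_like(t))  # velocity (-2, 0)
        _, lat_vel = lateral_signal(tr, 90.0)
        np.testing.assert_allclose(lat_vel, 2.0, atol=1e-9)

    def test_rotational_invariance(self):
        tr, t, _ = min_jerk_trace(direction=0.0)
        lat0, latv0 = lateral_signal(tr, 0.0)
        ang = math.radians(37.0)
        R = np.array([[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]])
        xy = tr.position() @ R.T
        meta = make_reach_meta(tuple(R @ [0, 0]), tuple(R @ [10, 0]))
        tr2 = make_trial(tr.t, xy[:, 0], xy[:, 1], meta=meta)
        lat1, latv1 = lateral_signal(tr2, 37.0)
        np.testing.assert_allclose(lat1, lat0, atol=1e-9)
        np.testing.assert_allclose(latv1, latv0, atol=1e-7)


def _pulse_trial_from_lateral(lat_vel_profile, t, direction=90.0, pulse_t=0.1):
    """Build a pulse trial whose lateral velocity follows a given profile.

    Forward motion is fast enough that the movement never "ends" within the
    record, so settling is governed purely by the lateral-velocity rule.
    """
    lat = np.concatenate([[0.0], np.cumsum(lat_vel_profile[:-1]) / FS])
    fwd = 20.0 * t  # constant 20 cm/s, never re-enters the target slow
    meta = make_reach_meta((0, 0), (0, 10), trial_type="reach_pulse",
                           pulse_sign="CCW")
    # direction 90 deg: lateral CCW unit is (-1, 0)
    return make_trial(t, -lat, fwd, meta=meta, events={"pulse_onset": pulse_t})


class TestPulseOutcomes:
    def test_triangular_profile_settles_at_analytic_crossing(self):
        t = np.arange(0, 1.0, 1 / FS)
        v = np.interp(t, [0.0, 0.1, 0.2, 0.3, 1.0], [0.0, 0.0, 8.0, 0.0, 0.0])
        # downward crossing of 2 cm/s: between 0.2 and 0.3, v = 8-80(t-0.2)
        tr = _pulse_trial_from_lateral(v, t, pulse_t=0.1)
        po = pulse_outcomes(tr, smooth_window=0.0)
        assert po.settling_time == pytest.approx(0.275 - 0.1, abs=1.5 / FS)
        assert not po.censored

    def test_never_settling_censors_at_record_end(self):
        t = np.arange(0, 1.2, 1 / FS)
        # |lateral velocity| constant 6 cm/s: never below the 2 cm/s
        # threshold, and the movement never meets the end rule either, so
        # settling is censored at the end of the considered span
        v = np.full_like(t, 6.0)
        lat = np.cumsum(v) / FS
        fwd = 20.0 * t
        meta = make_reach_meta((0, 0), (0, 10), trial_type="reach_pulse",
                               pulse_sign="CCW")
        tr = make_trial(t, -lat, fwd, meta=meta, events={"pulse_onset": 0.2})
        po = pulse_outcomes(tr, smooth_window=0.0)
        assert po.censored
        assert po.settling_time == pytest.approx(t[-1] - 0.2, abs=1e-9)

    def test_simulated_pulse_matches_oracle(self):
        tg = target_array()
        for sign in ("CCW", "CW"):
            tr = simulate_reach_trial(
                quiet_bias(impairment_scale=0.0), quiet_controller(),
                GatingMode(mode="off"), tg[0], tg[1],
                perturbation=("pulse", sign), seed=4,
            )
            po = pulse_outcomes(tr)
            st, md, cen = oracles.pulse_oracle(tr)
            assert po.settling_time == pytest.approx(st, abs=1e-12)
            assert po.max_lateral_dev == pytest.approx(md, abs=1e-12)
            assert po.censored == cen
            assert po.max_lateral_dev > 0  # deviation follows the pulse


def _release_trial(positions, t, release_t, direction_deg=45.0, target=(0.0, 30.0)):
    meta = make_reach_meta((0.0, 20.0), target, trial_type="reach_hold_release",
                           release_dir=direction_deg)
    return make_trial(t, positions[:, 0], positions[:, 1], meta=meta,
                      events={"release_onset": release_t})


class TestReleaseOutcomes:
    def test_overdamped_return_closed_form(self):
        # displacement A*exp(-t/tau) opposite the removed 45-deg force
        A, tau = 3.0, 0.3
        t = np.arange(0, 3.0, 1 / FS)
        rel_t = 0.5
        d = np.where(t >= rel_t, A * np.exp(-(t - rel_t) / tau), A)
        u = np.array([math.cos(math.radians(225.0)), math.sin(math.radians(225.0))])
        pos = np.array([0.0, 30.0]) + d[:, None] * u[None, :]
        tr = _release_trial(pos, t, rel_t)
        ro = release_outcomes(tr, smooth_window=0.0)
        # speed A/tau e^{-t/tau} < 2 at t = tau ln(A/(2 tau)); distance < 2
        # at t = tau ln(A/2); stabilization at the later of the two
        t_speed = tau * math.log(A / (2 * tau))
        t_dist = tau * math.log(A / 2.0)
        expected = max(t_speed, t_dist)
        assert ro.time_to_stabilization == pytest.approx(expected, abs=2.5 / FS)
        assert ro.max_deviation == pytest.approx(A, abs=0.01)
        assert not ro.censored

    def test_persistence_rule_skips_brief_dip(self):
        t = np.arange(0, 3.0, 1 / FS)
        rel_t = 0.2
        # speed profile: dips below 2 cm/s at 0.5 s for only 50 ms, then
        # rises again, and finally settles for good at 1.0 s
        speed = np.piecewise(
            t,
            [t < 0.5, (t >= 0.5) & (t < 0.55), (t >= 0.55) & (t < 1.0), t >= 1.0],
            [5.0, 1.0, 5.0, 0.0],
        )
        # circle of radius 1 cm around the target: distance criterion always
        # met, hand speed equals the commanded profile
        phase = np.concatenate([[0.0], np.cumsum(speed[:-1]) / FS])
        pos = np.array([0.0, 30.0]) + np.column_stack(
            [np.cos(phase), np.sin(phase)]
        )
        tr = _release_trial(pos, t, rel_t, direction_deg=225.0)
        ro = release_outcomes(tr, smooth_window=0.0)
        assert ro.time_to_stabilization == pytest.approx(1.0 - rel_t, abs=2.5 / FS)

    def test_cap_mode_impute(self):
        t = np.arange(0, 4.0, 1 / FS)
        rel_t = 0.5
        # never stabilizes: keeps moving at 5 cm/s away from the target
        d = np.where(t >= rel_t, 5.0 * (t - rel_t), 0.0)
        u = np.array([math.cos(math.radians(225.0)), math.sin(math.radians(225.0))])
        pos = np.array([0.0, 30.0]) + d[:, None] * u[None, :]
        tr = _release_trial(pos, t, rel_t)
        ro = release_outcomes(tr, cap_mode="impute_2s", smooth_window=0.0)
        assert ro.censored
        assert ro.time_to_stabilization == 2.0
        ro_ex = release_outcomes(tr, cap_mode="exclude", smooth_window=0.0)
        assert math.isnan(ro_ex.time_to_stabilization)

    def test_simulated_release_matches_oracle(self):
        tg = target_array()
        tr = simulate_reach_trial(
            quiet_bias(impairment_scale=0.6), quiet_controller(kp=2.0, kd=0.25),
            GatingMode(), tg[0], tg[1], perturbation=("release", 135.0), seed=9,
        )
        ro = release_outcomes(tr)
        ti, pa, md, cen = oracles.release_oracle(tr)
        assert ro.time_to_stabilization == pytest.approx(ti, abs=1e-12, nan_ok=True)
        assert ro.path_to_stabilization == pytest.approx(pa, abs=1e-9)
        assert ro.max_deviation == pytest.approx(md, abs=1e-12)
        assert ro.censored == cen


class TestInvariance:
    def test_outcomes_invariant_under_rotation_translation(self):
        tg = target_array()
        tr = simulate_reach_trial(
            quiet_bias(impairment_scale=0.0), quiet_controller(),
            GatingMode(mode="off"), tg[0], tg[2], seed=2,
        )
        ro = reach_outcomes(tr)
        ang = math.radians(23.0)
        R = np.array([[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]])
        shift = np.array([4.0, -2.0])
        xy = tr.position() @ R.T + shift
        meta = make_reach_meta(
            tuple(R @ np.array(tr.meta.start_pos) + shift),
            tuple(R @ np.array(tr.meta.target_pos) + shift),
        )
        tr2 = make_trial(tr.t, xy[:, 0], xy[:, 1], meta=meta, events=dict(tr.events))
        ro2 = reach_outcomes(tr2)
        assert ro2.onset_t == pytest.approx(ro.onset_t, abs=1e-12)
        assert ro2.end_t == pytest.approx(ro.end_t, abs=1e-12)
        assert ro2.theta_start == pytest.approx(ro.theta_start, abs=1e-7)
        assert ro2.theta_end == pytest.approx(ro.theta_end, abs=1e-7)
        assert ro2.path_length == pytest.approx(ro.path_length, rel=1e-9)


class TestTrajectoryRelativeDeviation:
    def test_straight_baseline_leaves_deviation_unchanged(self):
        from moveholdlab.kinematics import unperturbed_lateral_profile

        tg = target_array()
        unpert = [
            simulate_reach_trial(
                quiet_bias(impairment_scale=0.0), quiet_controller(),
                GatingMode(mode="off"), tg[0], tg[1], seed=s,
            )
            for s in range(3)
        ]
        baseline = unperturbed_lateral_profile(unpert)
        pulse_tr = simulate_reach_trial(
            quiet_bias(impairment_scale=0.0), quiet_controller(),
            GatingMode(mode="off"), tg[0], tg[1],
            perturbation=("pulse", "CW"), seed=5,
        )
        line_rel = pulse_outcomes(pulse_tr)
        traj_rel = pulse_outcomes(pulse_tr, baseline=baseline)
        # noiseless unperturbed reaches are straight: both modes agree
        assert traj_rel.max_lateral_dev == pytest.approx(
            line_rel.max_lateral_dev, abs=0.01
        )
        assert traj_rel.settling_time == line_rel.settling_time


class TestImpairmentMonotonicity:
    def test_slower_weaker_subjects_take_longer_and_deviate_more(self):
        """Reach duration/time-to-target and release deviation grow
        monotonically with the impairment parameter."""
        from moveholdlab.synthetic import impaired_controller

        tg = target_array()
        times, devs = [], []
        for imp in (0.1, 0.5, 0.9):
            ctrl = impaired_controller(imp)
            ctrl.motor_noise_sd = 0.0
            tr = simulate_reach_trial(
                quiet_bias(impairment_scale=0.0), ctrl, GatingMode(mode="off"),
                tg[0], tg[1], seed=0,
            )
            ro = reach_outcomes(tr)
            times.append(ro.time_to_target)
            rel = simulate_reach_trial(
                quiet_bias(impairment_scale=0.0), ctrl, GatingMode(mode="off"),
                tg[0], tg[1], perturbation=("release", 225.0), seed=0,
            )
            devs.append(release_outcomes(rel).max_deviation)
        assert times[0] < times[1] < times[2]
        assert devs[0] < devs[1] < devs[2]
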