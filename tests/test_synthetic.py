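"""Synthetic-trial generator: trajectories, whole-body mechanics, EMG
synthesis and study battery structure."""

import numpy as np
import pytest

from trunkmoment.anthropometry import G_GRAVITY, build_subject
from trunkmoment.emgmod import default_geometry, predict_human_moment
from trunkmoment.synthetic_data import (GroundTruth, LiftProfile,
                                        TaskParameterError,
                                        calibration_conditions,
                                        emg_from_moment, exo_torque,
                                        generate_kinematics, generate_subject,
                                        generate_trial, minimum_jerk,
                                        reference_human_moment,
                                        evaluation_conditions, whole_body_grf)
from trunkmoment.trial_model import MomentSeries, TrialCondition, write_trial

SUBJECT = build_subject("S90")
NOISE_FREE = GroundTruth(emg_noise_sd=0.0, kin_noise_sd=0.0)


def _cond(technique, mass=7.5, velocity="normal", task="calibration_lift",
          strategy="none"):
    return TrialCondition(mass, technique, velocity, task, strategy)


class TestMinimumJerk:
    def test_degenerate_and_midpoint(self):
        flat = minimum_jerk(0.3, 0.3, 2.0, 50.0)
        np.testing.assert_allclose(flat, 0.3)
        traj = minimum_jerk(0.0, 1.0, 2.0, 50.0)
        assert traj[len(traj) // 2] == pytest.approx(0.5, abs=1e-6)
        assert traj[0] == 0.0 and traj[-1] == pytest.approx(1.0)

    def test_peak_velocity_is_1875_over_duration(self):
        fs, d, theta1 = 1000.0, 2.0, 0.8
        traj = minimum_jerk(0.0, theta1, d, fs)
        peak_vel = np.max(np.gradient(traj, 1 / fs))
        assert peak_vel == pytest.approx(1.875 * theta1 / d, rel=1e-4)


class TestKinematics:
    def test_stoop_flexes_trunk_not_knees(self):
        kin = generate_kinematics(_cond("stoop"), SUBJECT)
        knee = np.max(kin.angles["knee"].pos)
        trunk_flexion = np.max(kin.angles["hip"].pos
                               + kin.angles["lumbar"].pos)
        assert knee < np.radians(10) + 1e-9
        assert knee < trunk_flexion

    def test_squat_keeps_trunk_inclination_small(self):
        kin = generate_kinematics(_cond("squat"), SUBJECT)
        assert np.max(kin.phis["trunk"].pos) < np.radians(35)
        assert np.max(kin.angles["knee"].pos) > np.radians(90)

    def test_faster_class_has_larger_peak_trunk_velocity(self):
        slow = generate_kinematics(_cond("free", velocity="very_slow"), SUBJECT)
        fast = generate_kinematics(_cond("free", velocity="fast"), SUBJECT)
        assert np.max(np.abs(fast.phis["trunk"].vel)) \
            > np.max(np.abs(slow.phis["trunk"].vel))

    def test_unknown_technique_rejected(self):
        bad = TrialCondition(7.5, "n/a", "normal", "exo_lift", "inclination")
        with pytest.raises(TaskParameterError):
            generate_kinematics(bad, SUBJECT)


class TestWholeBodyGrf:
    def test_static_upright_supports_body_weight(self):
        kin = generate_kinematics(
            TrialCondition(0.0, "n/a", "n/a", "stack_carry", "inclination"),
            SUBJECT)
        fx, fy, cop = whole_body_grf(kin)
        pad = slice(0, 10)  # quiet standing
        np.testing.assert_allclose(fy[pad], SUBJECT.weight_n, atol=1e-6)
        np.testing.assert_allclose(fx[pad], 0.0, atol=1e-6)

    def test_held_box_adds_its_weight(self):
        kin = generate_kinematics(
            TrialCondition(15.0, "n/a", "n/a", "stack_carry", "inclination"),
            SUBJECT)
        _, fy, _ = whole_body_grf(kin)
        assert fy[3] == pytest.approx((SUBJECT.body_mass_kg + 15.0) * G_GRAVITY,
                                      abs=1e-6)

    def test_cycle_mean_vertical_force_equals_mean_weight(self):
        kin = generate_kinematics(_cond("free", mass=15.0), SUBJECT)
        _, fy, _ = whole_body_grf(kin)
        expected = np.mean(
            (SUBJECT.body_mass_kg + kin.load_mass) * G_GRAVITY)
        assert np.mean(fy) == pytest.approx(expected, rel=0.005)


class TestReferenceMoment:
    def test_upright_static_moment_is_negligible(self):
        kin = generate_kinematics(
            TrialCondition(0.0, "n/a", "n/a", "stack_carry", "inclination"),
            SUBJECT)
        m = reference_human_moment(kin)
        assert np.all(np.abs(m.values_nm[:10]) < 1.0)

    def test_deep_posture_matches_hand_statics(self):
        """At the static dwell the moment equals the sum of weight x lever
        computed directly from segment masses and positions."""
        kin = generate_kinematics(_cond("stoop", mass=15.0), SUBJECT)
        m = reference_human_moment(kin).values_nm
        i = np.argmax(kin.load_mass > 14.999)  # inside the dwell, box held
        p_x = kin.joints["l5s1"][i, 0]
        states = kin.segment_states()
        expected = sum(
            states[s]["mass"] * G_GRAVITY * (states[s]["com"][i, 0] - p_x)
            for s in ("trunk_head", "arms"))
        expected += 15.0 * G_GRAVITY * (kin.joints["hand"][i, 0] - p_x)
        assert m[i] == pytest.approx(expected, abs=0.5)

    def test_added_mass_raises_moment_by_weight_times_lever(self):
        kin_a = generate_kinematics(_cond("stoop", mass=7.5), SUBJECT)
        kin_b = generate_kinematics(_cond("stoop", mass=15.0), SUBJECT)
        i = np.argmax(kin_a.load_mass > 7.499)
        lever = kin_a.joints["hand"][i, 0] - kin_a.joints["l5s1"][i, 0]
        diff = (reference_human_moment(kin_b).values_nm[i]
                - reference_human_moment(kin_a).values_nm[i])
        assert diff == pytest.approx(7.5 * G_GRAVITY * lever, abs=0.3)

    def test_peak_moment_increases_with_mass(self):
        for technique in ("stoop", "squat", "free"):
            peaks = []
            for mass in (7.5, 15.0):
                kin = generate_kinematics(_cond(technique, mass=mass), SUBJECT)
                peaks.append(np.max(reference_human_moment(kin).values_nm))
            assert peaks[1] > peaks[0]


class TestExoTorque:
    def test_strategy_laws(self):
        kin = generate_kinematics(_cond("free"), SUBJECT)
        alpha = kin.phis["trunk"]
        np.testing.assert_allclose(exo_torque(kin, "inclination"),
                                   30.0 * alpha.pos)
        np.testing.assert_allclose(exo_torque(kin, "dynamic"),
                                   30.0 * alpha.pos + 1.0 * alpha.acc)
        np.testing.assert_allclose(exo_torque(kin, "velocity"),
                                   30.0 * alpha.pos + 5.0 * alpha.vel)
        assert np.all(exo_torque(kin, "transparent") == 0.0)
        # upright pads: zero support for every strategy
        for strategy in ("inclination", "dynamic", "velocity", "transparent"):
            assert abs(exo_torque(kin, strategy)[0]) < 1e-9

    def test_linear_law_value(self):
        kin = generate_kinematics(_cond("free"), SUBJECT)
        idx = np.argmin(np.abs(kin.phis["trunk"].pos - 0.5))
        assert kin.phis["trunk"].pos[idx] == pytest.approx(0.5, abs=0.02)
        tau = exo_torque(kin, "inclination")
        assert tau[idx] == pytest.approx(30.0 * kin.phis["trunk"].pos[idx])

    def test_unknown_strategy_rejected(self):
        kin = generate_kinematics(_cond("free"), SUBJECT)
        with pytest.raises(TaskParameterError):
            exo_torque(kin, "hybrid")


class TestEmgSynthesis:
    def _setup(self, truth):
        kin = generate_kinematics(_cond("stoop", mass=15.0), SUBJECT)
        m = reference_human_moment(kin)
        theta = kin.angles["lumbar"].pos
        theta_dot = kin.angles["lumbar"].vel
        return kin, m, theta, theta_dot

    def test_inverse_then_forward_is_exact_without_noise(self):
        _, m, theta, theta_dot = self._setup(NOISE_FREE)
        emg, feasible = emg_from_moment(m, theta, theta_dot, NOISE_FREE)
        assert feasible
        pred = predict_human_moment(emg, theta, theta_dot,
                                    NOISE_FREE.params_true, default_geometry())
        np.testing.assert_allclose(pred, m.values_nm, atol=1e-6)

    def test_doubled_active_demand_checks_out_through_forward_model(self):
        geom = default_geometry()
        kin = generate_kinematics(_cond("squat", mass=7.5), SUBJECT)
        m = reference_human_moment(kin)
        theta = kin.angles["lumbar"].pos
        theta_dot = kin.angles["lumbar"].vel
        from trunkmoment.emgmod import passive_moment

        m_pass = passive_moment(theta, NOISE_FREE.params_true, geom)
        doubled = MomentSeries(m.time_s, 2.0 * m.values_nm - m_pass, "human")
        emg2, _ = emg_from_moment(doubled, theta, theta_dot, NOISE_FREE, geom)
        pred = predict_human_moment(emg2, theta, theta_dot,
                                    NOISE_FREE.params_true, geom)
        np.testing.assert_allclose(pred, doubled.values_nm, atol=1e-6)

    def test_cocontraction_raises_flexor_drive_not_net_moment(self):
        geom = default_geometry()
        _, m, theta, theta_dot = self._setup(NOISE_FREE)
        low = GroundTruth(emg_noise_sd=0.0, kin_noise_sd=0.0,
                          cocontraction_level=0.0)
        high = GroundTruth(emg_noise_sd=0.0, kin_noise_sd=0.0,
                           cocontraction_level=0.05)
        emg_lo, _ = emg_from_moment(m, theta, theta_dot, low, geom)
        emg_hi, _ = emg_from_moment(m, theta, theta_dot, high, geom)
        flexor_cols = geom.channels[~geom.extensor_mask]
        assert emg_hi[:, flexor_cols].sum() > emg_lo[:, flexor_cols].sum()
        for emg in (emg_lo, emg_hi):
            pred = predict_human_moment(emg, theta, theta_dot,
                                        NOISE_FREE.params_true, geom)
            np.testing.assert_allclose(pred, m.values_nm, atol=1e-6)


class TestStudyBattery:
    def test_two_repetitions_of_14_conditions(self, noisy_subject):
        trials = noisy_subject.calibration_trials
        assert len(trials) == 28
        labels = [t.condition.label for t in trials]
        assert len(set(labels)) == 14

    def test_same_seed_reproduces_identical_trial_files(self, tmp_path):
        a = generate_subject(3, seed=77)
        b = generate_subject(3, seed=77)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_trial(a.calibration_trials[0], pa)
        write_trial(b.calibration_trials[0], pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_repetitions_differ_in_emg_but_not_metadata(self, noisy_subject):
        r1, r2 = noisy_subject.calibration_trials[:2]
        assert r1.condition == r2.condition
        assert not np.allclose(r1.emg, r2.emg)

    def test_test_battery_composition(self, noisy_subject):
        groups = [t.condition.task_group for t in noisy_subject.test_trials]
        assert groups.count("exo_lift") == 16
        assert groups.count("stack_lift") == 1
        assert groups.count("stack_carry") == 1
        assert groups.count("shelf_lift") == 2
        assert groups.count("push_pull") == 2
        strategies = {t.condition.exo_strategy
                      for t in noisy_subject.test_trials
                      if t.condition.task_group == "exo_lift"}
        assert strategies == {"inclination", "dynamic", "velocity",
                              "transparent"}
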