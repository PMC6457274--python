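"""Closed-chain arm kinematics, inverse dynamics, and forward simulation."""

import math

import numpy as np
import pytest

import handleprop as hp
from handleprop.arm import (
    ArmConfig,
    ReachError,
    forward_kinematics,
    inverse_dynamics,
    inverse_kinematics,
    joint_limit_torque,
    path_kinematics,
)
from handleprop.mechanism import MechanismConfig
from handleprop.path import CrankLengthProfile


class TestInverseKinematics:
    def test_full_extension(self, arm_cfg):
        s = np.array(arm_cfg.shoulder)
        direction = np.array([0.6, -0.8])
        p = s + arm_cfg.reach_max * direction
        pose = inverse_kinematics(p, arm_cfg)
        assert pose.q[1] == pytest.approx(0.0, abs=1e-6)

    def test_pythagorean_configuration(self, arm_cfg):
        s = np.array(arm_cfg.shoulder)
        d = math.hypot(arm_cfg.l_upper, arm_cfg.l_fore)
        pose = inverse_kinematics(s + [d, 0.0], arm_cfg)
        assert pose.q[1] == pytest.approx(math.pi / 2, abs=1e-9)

    def test_unreachable_point_raises(self, arm_cfg):
        s = np.array(arm_cfg.shoulder)
        with pytest.raises(ReachError):
            inverse_kinematics(s + [arm_cfg.reach_max + 0.01, 0.0], arm_cfg)

    @pytest.mark.parametrize("branch", [1, -1])
    def test_round_trip_100_random_points(self, arm_cfg, branch):
        rng = np.random.default_rng(12)
        s = np.array(arm_cfg.shoulder)
        for _ in range(100):
            d = rng.uniform(arm_cfg.reach_min + 1e-3, arm_cfg.reach_max - 1e-3)
            ang = rng.uniform(-np.pi, np.pi)
            p = s + d * np.array([np.cos(ang), np.sin(ang)])
            pose = inverse_kinematics(p, arm_cfg, branch=branch)
            p_back = forward_kinematics(pose.q, arm_cfg, branch=branch)
            assert np.hypot(*(p_back - p)) <= 1e-10


class TestPathKinematics:
    def test_concentric_circle_gives_constant_elbow(self):
        """With the shoulder placed at the crank center, a circular path
        keeps the handle at constant distance, so elbow flexion is
        constant over the cycle."""
        arm = ArmConfig(shoulder=(0.0, 0.0), l_upper=0.10, l_fore=0.10)
        mech = MechanismConfig(crank_center=(0.0, 0.0))
        pk = path_kinematics(CrankLengthProfile.from_radius(0.12), arm, mech)
        th = np.linspace(0, 2 * np.pi, 60)
        q_el = pk.q_of_theta(th)[:, 1]
        np.testing.assert_allclose(q_el, q_el[0], atol=1e-9)

    def test_joint_angles_periodic(self, printed_shape, arm_cfg, mech_cfg):
        prof = CrankLengthProfile.from_shape(printed_shape)
        pk = path_kinematics(prof, arm_cfg, mech_cfg)
        q0, qd0, _ = pk.state(0.0)
        q1, qd1, _ = pk.state(mech_cfg.period)
        np.testing.assert_allclose(q1, q0, atol=1e-9)
        np.testing.assert_allclose(qd1, qd0, atol=1e-6)

    def test_analytic_velocity_matches_finite_differences(
        self, printed_shape, arm_cfg, mech_cfg
    ):
        prof = CrankLengthProfile.from_shape(printed_shape)
        pk = path_kinematics(prof, arm_cfg, mech_cfg)
        h = 1e-5 * mech_cfg.period
        for t in (0.1, 0.5, 0.9):
            _, qd, _ = pk.state(t)
            qp, _, _ = pk.state(t + h)
            qm, _, _ = pk.state(t - h)
            np.testing.assert_allclose(qd, (qp - qm) / (2 * h), atol=1e-6)

    def test_unreachable_path_recorded_not_fatal(self, arm_cfg):
        """A crank center too far from the shoulder clips the handle back
        to the reachable annulus and books the excursion for penalties."""
        mech = MechanismConfig(crank_center=(0.9, -0.6))
        pk = path_kinematics(CrankLengthProfile.from_radius(0.12), arm_cfg, mech)
        assert pk.reach_excursion > 0


class TestJointLimitTorque:
    def test_zero_inside_range(self, arm_cfg):
        q = np.array([-0.8, 1.0])  # well inside both ranges
        tau = joint_limit_torque(q, np.zeros(2), arm_cfg)
        np.testing.assert_allclose(tau, 0.0)

    def test_elastic_torque_beyond_upper_limit(self):
        cfg = ArmConfig(k_limit=20.0, c_limit=0.0)
        q_hi = cfg.elbow_range[1]
        tau = joint_limit_torque(np.array([-0.8, q_hi + 0.1]), np.zeros(2), cfg)
        assert tau[1] == pytest.approx(-2.0)

    def test_torque_opposes_excursion(self, arm_cfg):
        lo, hi = arm_cfg.elbow_range
        above = joint_limit_torque(np.array([-0.8, hi + 0.2]), np.zeros(2), arm_cfg)
        below = joint_limit_torque(np.array([-0.8, lo - 0.2]), np.zeros(2), arm_cfg)
        assert above[1] < 0 < below[1]


class TestInverseDynamics:
    def test_static_without_gravity_is_torque_free(self):
        cfg = ArmConfig(gravity=(0.0, 0.0))
        tau = inverse_dynamics(np.array([-0.7, 1.1]), np.zeros(2), np.zeros(2), cfg)
        np.testing.assert_allclose(tau, 0.0, atol=1e-12)

    def test_static_gravity_moments_hand_computed(self, arm_cfg):
        """Horizontal straight arm: shoulder torque must hold both
        segment weights at their COM lever arms, elbow only the forearm."""
        g = 9.80665
        q = np.array([0.0, 0.0])  # both segments along +x
        tau = inverse_dynamics(q, np.zeros(2), np.zeros(2), arm_cfg, branch=1)
        lever_sh = (
            arm_cfg.m_upper * arm_cfg.com_upper
            + arm_cfg.m_fore * (arm_cfg.l_upper + arm_cfg.com_fore)
        )
        lever_el = arm_cfg.m_fore * arm_cfg.com_fore
        assert tau[0] == pytest.approx(g * lever_sh, rel=1e-9)
        assert tau[1] == pytest.approx(g * lever_el, rel=1e-9)

    def test_gravity_torque_linear_in_mass(self, arm_cfg):
        q = np.array([-0.4, 0.8])
        tau1 = inverse_dynamics(q, np.zeros(2), np.zeros(2), arm_cfg)
        heavy = ArmConfig(m_upper=2 * arm_cfg.m_upper, m_fore=2 * arm_cfg.m_fore)
        tau2 = inverse_dynamics(q, np.zeros(2), np.zeros(2), heavy)
        np.testing.assert_allclose(tau2, 2 * tau1, rtol=1e-12)


class TestSimulateCycles:
    def test_zero_excitation_never_generates_power(
        self, circle_profile, roster, arm_cfg, mech_cfg
    ):
        tr = hp.simulate_cycles(
            circle_profile, hp.constant_excitation(np.zeros(len(roster))),
            roster, arm_cfg, mech_cfg, a0=0.0,
        )
        assert np.all(tr.activations <= 1e-9)
        assert tr.net_power() <= 1e-9

    def test_constant_excitation_converges_to_its_level(self, trace_low_excitation):
        ev = trace_low_excitation.evaluation_cycle()
        np.testing.assert_allclose(ev.activations, 0.05, atol=1e-5)

    def test_cycle_to_cycle_stationarity(self, trace_phased):
        """With periodic controls the settling transient dies out: the
        last two cycles agree in activation to 1e-4."""
        tr = trace_phased
        s2 = tr.cycle_slice(tr.n_cycles - 2)
        s3 = tr.cycle_slice(tr.n_cycles - 1)
        diff = np.abs(tr.activations[s2] - tr.activations[s3]).max()
        assert diff < 1e-4

    def test_energy_balance_over_evaluation_cycle(self, trace_phased):
        """Net crank work equals musculotendon + passive joint work over
        the periodic cycle (inverse-dynamics work vanishes) within 1%."""
        eb = hp.energy_balance(trace_phased.evaluation_cycle())
        scale = max(abs(eb["crank_work_J"]), abs(eb["muscle_work_J"]), 0.1)
        assert abs(eb["residual_J"]) <= 0.01 * scale

    def test_trace_grid_and_cycle_bookkeeping(self, trace_low_excitation):
        tr = trace_low_excitation
        assert np.all(np.diff(tr.time) > 0)
        ev = tr.evaluation_cycle()
        assert ev.time.size == tr.samples_per_cycle + 1
        assert ev.time[-1] - ev.time[0] == pytest.approx(tr.period, rel=1e-9)

    def test_trace_csv_round_trip(self, trace_low_excitation, tmp_path):
        import pandas as pd

        out = tmp_path / "trace.csv"
        trace_low_excitation.write_csv(out)
        df = pd.read_csv(out)
        assert {"time_s", "theta_rad", "tau_crank_Nm", "power_W"} <= set(df.columns)
        np.testing.assert_allclose(
            df["power_W"].to_numpy(), trace_low_excitation.power, rtol=1e-6
        )
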