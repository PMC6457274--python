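"""Zone partition, muscle work, ROM, fiber mechanics, and the report bundle."""

import json
import math

import numpy as np
import pytest

import handleprop as hp
from handleprop.analysis import (
    FiberMechanics,
    MuscleWorkReport,
    ZonePartition,
    energy_balance,
    fiber_mechanics,
    muscle_work,
    peak_forces,
    report,
    rom_summary,
)
from handleprop.arm import SimulationTrace


def synthetic_trace(
    forces, v_mt, omega=2 * math.pi, n=241, activations=None, q=None
) -> SimulationTrace:
    """Hand-built single-cycle trace with prescribed muscle force and
    musculotendon velocity arrays (n_t, n_m)."""
    t = np.linspace(0.0, 2 * math.pi / omega, n)
    theta = omega * t
    n_m = forces.shape[1]
    zeros2 = np.zeros((n, 2))
    if activations is None:
        activations = np.zeros((n, n_m))
    if q is None:
        q = zeros2
    power = np.sum(forces * (-v_mt), axis=1)
    return SimulationTrace(
        time=t, theta=theta, q=q, qd=zeros2,
        muscle_names=tuple(f"m{i}" for i in range(n_m)),
        excitations=activations, activations=activations,
        l_mt=np.full((n, n_m), 0.3), v_mt=v_mt, forces=forces,
        lm_norm=np.ones((n, n_m)), vm_norm=np.zeros((n, n_m)),
        tau_muscle=zeros2, tau_limit=zeros2, tau_id=zeros2,
        tau_crank=power / omega, power=power,
        omega=omega, n_cycles=1, samples_per_cycle=n - 1,
    )


class TestZonePartition:
    def test_quadrants_tile_the_cycle(self):
        z = ZonePartition()
        th = np.linspace(0, 2 * math.pi, 1000, endpoint=False)
        idx = z.zone_of(th)
        assert set(idx) == {1, 2, 3, 4}
        assert np.all(np.diff(np.flatnonzero(np.diff(idx))) > 0)

    def test_pull_push_labels(self):
        z = ZonePartition()
        assert set(z.pull) == {1, 4}
        assert set(z.push) == {2, 3}

    def test_bad_boundaries_rejected(self):
        with pytest.raises(ValueError):
            ZonePartition(boundaries=(0.0, 2.0, 1.0, 3.0, 2 * math.pi))


class TestMuscleWork:
    def test_isometric_muscle_does_no_work(self):
        f = np.full((241, 1), 100.0)
        v = np.zeros((241, 1))
        rep = muscle_work(synthetic_trace(f, v))
        np.testing.assert_allclose(rep.zone_work, 0.0)

    def test_constant_force_and_rate_rectangle(self):
        """Constant tension F with constant shortening rate v over the
        whole cycle gives W = F*v*T split equally across the quadrants."""
        omega = 2 * math.pi  # T = 1 s
        f = np.full((481, 1), 100.0)
        v = np.full((481, 1), -0.02)  # shortening at 2 cm/s
        rep = muscle_work(synthetic_trace(f, v, omega=omega, n=481))
        np.testing.assert_allclose(rep.zone_work, 100.0 * 0.02 / 4, rtol=1e-6)
        assert rep.cycle_total[0] == pytest.approx(2.0, rel=1e-9)

    def test_zone_additivity(self, trace_phased):
        ev = trace_phased.evaluation_cycle()
        rep = muscle_work(ev)
        whole = np.trapezoid(ev.forces * (-ev.v_mt), ev.time, axis=0)
        np.testing.assert_allclose(rep.cycle_total, whole, atol=1e-4)

    def test_positive_negative_decomposition(self, trace_phased):
        rep = muscle_work(trace_phased.evaluation_cycle())
        np.testing.assert_allclose(
            rep.positive_work + rep.negative_work, rep.cycle_total, atol=1e-12
        )
        assert np.all(rep.positive_work >= 0)
        assert np.all(rep.negative_work <= 0)

    def test_partial_cycle_rejected(self, trace_phased):
        ev = trace_phased.evaluation_cycle()
        import dataclasses

        half = dataclasses.replace(
            ev,
            time=ev.time[:61], theta=ev.theta[:61], q=ev.q[:61], qd=ev.qd[:61],
            excitations=ev.excitations[:61], activations=ev.activations[:61],
            l_mt=ev.l_mt[:61], v_mt=ev.v_mt[:61], forces=ev.forces[:61],
            lm_norm=ev.lm_norm[:61], vm_norm=ev.vm_norm[:61],
            tau_muscle=ev.tau_muscle[:61], tau_limit=ev.tau_limit[:61],
            tau_id=ev.tau_id[:61], tau_crank=ev.tau_crank[:61],
            power=ev.power[:61], samples_per_cycle=60,
        )
        with pytest.raises(ValueError):
            muscle_work(half)


class TestRomSummary:
    def test_constant_angle_zero_rom(self):
        tr = synthetic_trace(np.zeros((241, 1)), np.zeros((241, 1)))
        rom = rom_summary(tr)
        assert rom.loc["shoulder", "rom_deg"] == pytest.approx(0.0)

    def test_sinusoid_extrema(self):
        n = 721
        t = np.linspace(0, 1, n)
        q = np.column_stack(
            [np.radians(40 + 10 * np.sin(2 * np.pi * t)), np.zeros(n)]
        )
        tr = synthetic_trace(np.zeros((n, 1)), np.zeros((n, 1)), n=n, q=q)
        rom = rom_summary(tr)
        assert rom.loc["shoulder", "min_deg"] == pytest.approx(30.0, abs=0.05)
        assert rom.loc["shoulder", "max_deg"] == pytest.approx(50.0, abs=0.05)

    def test_ergonomic_flag_iff_outside(self):
        n = 241
        q = np.column_stack([np.zeros(n), np.full(n, math.radians(50.0))])
        tr = synthetic_trace(np.zeros((n, 1)), np.zeros((n, 1)), q=q)
        rom = rom_summary(tr, {"shoulder": (-10.0, 10.0), "elbow": (0.0, 120.0)})
        assert not rom.loc["elbow", "outside_ergonomic"]
        assert not rom.loc["shoulder", "outside_ergonomic"]
        rom2 = rom_summary(tr, {"shoulder": (-10.0, 10.0), "elbow": (0.0, 45.0)})
        assert rom2.loc["elbow", "outside_ergonomic"]


class TestFiberMechanics:
    def test_subthreshold_activation_empty_mask(self):
        a = np.full((241, 2), 0.1)
        tr = synthetic_trace(np.zeros((241, 2)), np.zeros((241, 2)), activations=a)
        fm = fiber_mechanics(tr)
        assert not fm.active_mask.any()

    def test_constant_length_zero_velocity(self, trace_low_excitation):
        fm = fiber_mechanics(trace_low_excitation.evaluation_cycle())
        assert isinstance(fm, FiberMechanics)
        assert fm.vm_over_vmax.shape == fm.lm_norm.shape

    def test_mask_follows_threshold_crossings(self):
        n = 241
        a = np.linspace(0.0, 0.4, n)[:, None]
        tr = synthetic_trace(np.zeros((n, 1)), np.zeros((n, 1)), activations=a)
        fm = fiber_mechanics(tr)
        np.testing.assert_array_equal(fm.active_mask[:, 0], a[:, 0] > 0.2)


class TestPeakForces:
    def test_peak_at_least_mean(self, trace_phased):
        ev = trace_phased.evaluation_cycle()
        peaks = peak_forces(ev)
        means = ev.forces.mean(axis=0)
        for i, name in enumerate(ev.muscle_names):
            assert peaks[name] >= means[i]

    def test_zero_activation_peaks_are_passive_only(
        self, circle_profile, roster, arm_cfg, mech_cfg
    ):
        tr = hp.simulate_cycles(
            circle_profile, hp.constant_excitation(np.zeros(len(roster))),
            roster, arm_cfg, mech_cfg, a0=0.0, n_settle=1,
        )
        ev = tr.evaluation_cycle()
        from handleprop.muscle import passive_force_length

        peaks = peak_forces(ev)
        for i, m in enumerate(roster):
            passive = (
                m.f_iso_max
                * passive_force_length(ev.lm_norm[:, i])
                * math.cos(m.alpha_penn)
            )
            assert peaks[m.name] == pytest.approx(float(passive.max()), abs=1e-6)


class TestReport:
    def test_report_deterministic_bytes(self, trace_phased, tmp_path, printed_shape):
        ev = trace_phased.evaluation_cycle()
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        report(ev, d1, shape=printed_shape, circularity_value=0.951)
        report(ev, d2, shape=printed_shape, circularity_value=0.951)
        for name in ("summary.json", "muscle_work.csv", "rom.csv", "trace.csv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_summary_json_round_trips_and_matches_trace(
        self, trace_phased, tmp_path
    ):
        ev = trace_phased.evaluation_cycle()
        summary = report(ev, tmp_path / "rep")
        loaded = json.loads((tmp_path / "rep" / "summary.json").read_text())
        assert loaded["net_power_W"] == pytest.approx(ev.net_power(), rel=1e-12)
        assert summary["net_power_W"] == pytest.approx(ev.net_power(), rel=1e-12)


class TestWholeSystemEnergy:
    def test_muscle_plus_passive_work_equals_crank_work(self, trace_phased):
        """System-level audit on a real simulation: total musculotendon
        work plus joint-limit work accounts for the net crank work."""
        eb = energy_balance(trace_phased.evaluation_cycle())
        scale = max(abs(eb["crank_work_J"]), abs(eb["muscle_work_J"]), 0.1)
        assert abs(eb["residual_J"]) <= 0.01 * scale
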