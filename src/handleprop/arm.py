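"""Planar upper-extremity closed-chain kinematics and dynamics.

The arm is a parasagittal two-link chain — upper arm and forearm+hand —
with the hand welded to the handle of the crank mechanism.  Because the
crank turns at constant angular velocity and the handle path is
prescribed, the joint kinematics are fully determined by inverse
kinematics; only the muscle activation states carry dynamics and are
integrated forward.  The crank torque is recovered from the joint-torque
balance by virtual work:

    tau_crank(theta) = sum_j (tau_applied_j - tau_ID_j) * dq_j/dtheta

where ``tau_applied`` collects moment-arm-weighted muscle forces plus
passive joint-limit torques and ``tau_ID`` is the inverse-dynamics torque
that realizes the prescribed motion (gravity + inertia).  Instantaneous
handle power is ``tau_crank * omega``.

Coordinates: ``q = (q_sh, q_el)``.  ``q_sh`` is the global angle of the
upper arm measured counter-clockwise from the +x axis (arm hanging down
is -90 deg); ``q_el`` is elbow flexion, 0 at full extension, positive
flexing, limited to [0, 130] deg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline

from .mechanism import MechanismConfig
from .muscle import MuscleRoster
from .path import CrankLengthProfile

__all__ = [
    "ArmConfig",
    "ArmPose",
    "PathKinematics",
    "SimulationTrace",
    "ReachError",
    "SimulationError",
    "forward_kinematics",
    "inverse_kinematics",
    "path_kinematics",
    "joint_limit_torque",
    "inverse_dynamics",
    "simulate_cycles",
    "constant_excitation",
]

_GRAV = 9.80665


class ReachError(ValueError):
    """Handle point outside the arm's reachable annulus."""


class SimulationError(RuntimeError):
    """Forward integration failed; carries solver diagnostics."""


@dataclass(frozen=True)
class ArmConfig:
    """Segment anthropometry, joint ranges, and passive joint properties.

    Defaults are 50th-percentile-male-style planar segment parameters
    (upper arm 0.33 m / 2.0 kg, forearm+hand 0.46 m / 1.7 kg, COM at 45%
    of segment length, thin-rod inertia).  ``q_ref`` is the reference
    pose at which every muscle sits at its optimal fiber length.
    """

    shoulder: tuple[float, float] = (0.0, 0.10)
    l_upper: float = 0.33
    l_fore: float = 0.46
    m_upper: float = 2.0
    m_fore: float = 1.7
    com_frac: float = 0.45
    shoulder_range: tuple[float, float] = (math.radians(-135.0), math.radians(45.0))
    elbow_range: tuple[float, float] = (0.0, math.radians(130.0))
    wrist_angle: float = 0.0
    gravity: tuple[float, float] = (0.0, -_GRAV)
    k_limit: float = 50.0  # N*m/rad, elastic joint-limit stiffness
    c_limit: float = 1.0  # N*m*s/rad, damping engaged beyond the limit
    branch: int | None = None  # +1 elbow-low, -1 elbow-high, None = auto
    q_ref: tuple[float, float] = (math.radians(-60.0), math.radians(90.0))

    def __post_init__(self) -> None:
        if self.l_upper <= 0 or self.l_fore <= 0:
            raise ValueError("segment lengths must be positive")
        if self.shoulder_range[0] >= self.shoulder_range[1]:
            raise ValueError("empty shoulder range")
        if self.elbow_range[0] >= self.elbow_range[1]:
            raise ValueError("empty elbow range")

    @property
    def joint_ranges(self) -> tuple[tuple[float, float], tuple[float, float]]:
        return (self.shoulder_range, self.elbow_range)

    @property
    def reach_max(self) -> float:
        return self.l_upper + self.l_fore

    @property
    def reach_min(self) -> float:
        return abs(self.l_upper - self.l_fore)

    @property
    def com_upper(self) -> float:
        return self.com_frac * self.l_upper

    @property
    def com_fore(self) -> float:
        return self.com_frac * self.l_fore

    @property
    def inertia_upper(self) -> float:
        """Thin-rod inertia about the segment COM (kg*m^2)."""
        return self.m_upper * self.l_upper**2 / 12.0

    @property
    def inertia_fore(self) -> float:
        return self.m_fore * self.l_fore**2 / 12.0


@dataclass(frozen=True)
class ArmPose:
    """Joint-space state at one instant; ``handle_angle`` is the global
    forearm angle, which fixes the handle pin angle eta through the
    hand-handle weld."""

    q: np.ndarray
    qd: np.ndarray = field(default_factory=lambda: np.zeros(2))
    qdd: np.ndarray = field(default_factory=lambda: np.zeros(2))
    branch: int = 1

    @property
    def handle_angle(self) -> float:
        return float(self.q[0] + self.branch * self.q[1])


def forward_kinematics(q, config: ArmConfig, branch: int = 1):
    """Handle position (m, global) for joint angles ``q = (q_sh, q_el)``."""
    q = np.asarray(q, dtype=float)
    q_sh, q_el = q[..., 0], q[..., 1]
    phi1 = q_sh
    phi2 = q_sh + branch * q_el
    sx, sy = config.shoulder
    x = sx + config.l_upper * np.cos(phi1) + config.l_fore * np.cos(phi2)
    y = sy + config.l_upper * np.sin(phi1) + config.l_fore * np.sin(phi2)
    return np.stack([x, y], axis=-1)


def inverse_kinematics(handle, config: ArmConfig, branch: int | None = None) -> ArmPose:
    """Two-link IK onto a handle point, law-of-cosines solution.

    ``branch`` +1 puts the elbow on the clockwise side of the
    shoulder-handle line (elbow-low for a handle in front of and below
    the shoulder); None picks a branch whose shoulder angle lies inside
    the configured range, preferring +1.

    Raises :class:`ReachError` if the point is outside the reachable
    annulus.  Elbow flexion beyond its range is *not* fatal here; range
    handling is the caller's concern (limit torques / penalties).
    """
    h = np.asarray(handle, dtype=float)
    s = np.asarray(config.shoulder, dtype=float)
    d = float(np.hypot(*(h - s)))
    if d > config.reach_max + 1e-12 or d < config.reach_min - 1e-12:
        raise ReachError(
            f"handle at distance {d:.4f} m outside reachable annulus "
            f"[{config.reach_min:.4f}, {config.reach_max:.4f}] m"
        )
    l1, l2 = config.l_upper, config.l_fore
    cos_f = np.clip((d**2 - l1**2 - l2**2) / (2.0 * l1 * l2), -1.0, 1.0)
    q_el = math.acos(cos_f)  # elbow flexion in [0, pi)
    cos_g = np.clip((d**2 + l1**2 - l2**2) / (2.0 * d * l1), -1.0, 1.0)
    gamma = math.acos(cos_g)
    psi = math.atan2(h[1] - s[1], h[0] - s[0])
    if branch is None:
        branch = config.branch
    if branch is None:
        lo, hi = config.shoulder_range
        branch = 1 if lo <= psi - gamma <= hi else -1
    q_sh = psi - branch * gamma
    return ArmPose(q=np.array([q_sh, q_el]), branch=branch)


@dataclass(frozen=True)
class PathKinematics:
    """Periodic joint-angle splines q(theta) over one crank revolution.

    Built by inverse kinematics on a dense crank-angle grid; derivatives
    follow analytically through the splines and the chain rule
    ``qd = dq/dtheta * omega``.  Reach violations (handle clipped back to
    the reachable annulus) are recorded for penalty bookkeeping.
    """

    spline_sh: CubicSpline
    spline_el: CubicSpline
    omega: float
    branch: int
    reach_excursion: float  # integral of clipped distance over theta (m*rad)
    range_excursion: float  # integral of squared joint-range excursion (rad^2*rad)
    winding: int = 0  # shoulder-angle turns per cycle (nonzero only when
    #                   the handle orbits the shoulder)

    def q_of_theta(self, theta):
        theta = np.mod(theta, 2.0 * np.pi)
        q_sh = self.spline_sh(theta) + self.winding * theta
        return np.stack([q_sh, self.spline_el(theta)], axis=-1)

    def state(self, t):
        """q, qd, qdd arrays at time(s) ``t``; shapes (..., 2)."""
        theta = np.mod(self.omega * np.asarray(t, dtype=float), 2.0 * np.pi)
        q = np.stack(
            [self.spline_sh(theta) + self.winding * theta, self.spline_el(theta)],
            axis=-1,
        )
        qd = self.omega * np.stack(
            [self.spline_sh(theta, 1) + self.winding, self.spline_el(theta, 1)],
            axis=-1,
        )
        qdd = self.omega**2 * np.stack(
            [self.spline_sh(theta, 2), self.spline_el(theta, 2)], axis=-1
        )
        return q, qd, qdd


def path_kinematics(
    profile: CrankLengthProfile,
    config: ArmConfig,
    mech: MechanismConfig,
    n_samples: int = 361,
) -> PathKinematics:
    """Resolve the closed chain over one crank revolution.

    Unreachable handle points are clipped radially to the reachable
    annulus (with a 1 mm margin) and the clipped distance is accumulated
    into ``reach_excursion`` so the optimizer can penalize the shape
    rather than abort.
    """
    theta = np.linspace(0.0, 2.0 * np.pi, n_samples)
    cl = profile(theta)
    c = np.asarray(mech.crank_center, dtype=float)
    xy = c + cl[:, None] * mech.radial_unit(theta)
    s = np.asarray(config.shoulder, dtype=float)
    rel = xy - s
    d = np.hypot(rel[:, 0], rel[:, 1])
    d_lo = config.reach_min + 1e-3
    d_hi = config.reach_max - 1e-3
    d_clip = np.clip(d, d_lo, d_hi)
    reach_exc = float(np.trapezoid(np.abs(d - d_clip), theta))
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(d > 0, d_clip / d, 1.0)
    xy = s + rel * scale[:, None]

    # branch fixed for the whole cycle, decided at theta = 0
    pose0 = inverse_kinematics(xy[0], config)
    branch = pose0.branch
    q = np.empty((n_samples, 2))
    for i in range(n_samples):
        pose = inverse_kinematics(xy[i], config, branch=branch)
        q[i] = pose.q
    # unwrap shoulder angle so the spline never jumps across +-pi; if the
    # handle orbits the shoulder the angle winds by 2*pi per cycle, which
    # is removed before the periodic fit and restored analytically
    q[:, 0] = np.unwrap(q[:, 0])
    winding = int(round((q[-1, 0] - q[0, 0]) / (2.0 * np.pi)))
    q[:, 0] -= winding * theta
    # closure guarantees equality up to round-off; make it exact
    q[-1] = q[0]

    rng_exc = 0.0
    for j, (lo, hi) in enumerate(config.joint_ranges):
        over = np.clip(q[:, j] - hi, 0.0, None) + np.clip(lo - q[:, j], 0.0, None)
        rng_exc += float(np.trapezoid(over**2, theta))

    return PathKinematics(
        spline_sh=CubicSpline(theta, q[:, 0], bc_type="periodic"),
        spline_el=CubicSpline(theta, q[:, 1], bc_type="periodic"),
        omega=mech.omega,
        branch=branch,
        reach_excursion=reach_exc,
        range_excursion=rng_exc,
        winding=winding,
    )


def joint_limit_torque(q, qd, config: ArmConfig) -> np.ndarray:
    """Passive joint-limit torques (N*m), zero inside the range.

    Beyond a limit: elastic restoring torque ``-K * excursion`` plus
    damping ``-c * qd`` engaged only while beyond the limit.
    """
    q = np.asarray(q, dtype=float)
    qd = np.asarray(qd, dtype=float)
    tau = np.zeros_like(q)
    for j, (lo, hi) in enumerate(config.joint_ranges):
        qj = q[..., j]
        over = np.clip(qj - hi, 0.0, None)
        under = np.clip(lo - qj, 0.0, None)
        engaged = (over > 0) | (under > 0)
        tau[..., j] = (
            -config.k_limit * over
            + config.k_limit * under
            - config.c_limit * qd[..., j] * engaged
        )
    return tau


def inverse_dynamics(q, qd, qdd, config: ArmConfig, branch: int = 1) -> np.ndarray:
    """Joint torques realizing the prescribed motion (gravity + inertia),
    excluding handle constraint forces.  Standard planar two-link
    Newton-Euler in (absolute shoulder, relative elbow) coordinates,
    mapped back to the (q_sh, q_el) convention.
    """
    q = np.asarray(q, dtype=float)
    qd = np.asarray(qd, dtype=float)
    qdd = np.asarray(qdd, dtype=float)
    b = branch
    # theta1 absolute upper-arm angle, theta2 relative forearm angle
    t1, t2 = q[..., 0], b * q[..., 1]
    t1d, t2d = qd[..., 0], b * qd[..., 1]
    t1dd, t2dd = qdd[..., 0], b * qdd[..., 1]

    l1 = config.l_upper
    lc1, lc2 = config.com_upper, config.com_fore
    m1, m2 = config.m_upper, config.m_fore
    i1, i2 = config.inertia_upper, config.inertia_fore
    g = -config.gravity[1]  # magnitude for gravity along -y

    c2, s2 = np.cos(t2), np.sin(t2)
    m11 = i1 + i2 + m1 * lc1**2 + m2 * (l1**2 + lc2**2 + 2.0 * l1 * lc2 * c2)
    m12 = i2 + m2 * (lc2**2 + l1 * lc2 * c2)
    m22 = i2 + m2 * lc2**2
    h = m2 * l1 * lc2 * s2
    c1v = -h * t2d**2 - 2.0 * h * t1d * t2d
    c2v = h * t1d**2
    g1 = g * ((m1 * lc1 + m2 * l1) * np.cos(t1) + m2 * lc2 * np.cos(t1 + t2))
    g2 = g * m2 * lc2 * np.cos(t1 + t2)

    tau1 = m11 * t1dd + m12 * t2dd + c1v + g1
    tau2 = m12 * t1dd + m22 * t2dd + c2v + g2
    # virtual work: theta = T q with T = [[1, 0], [0, b]] => tau_q = T^T tau_theta
    return np.stack([tau1, b * tau2], axis=-1)


def constant_excitation(values: np.ndarray):
    """Excitation function holding every muscle at a fixed level."""
    values = np.atleast_1d(np.asarray(values, dtype=float))

    def u(t):
        t = np.asarray(t, dtype=float)
        if t.ndim == 0:
            return values.copy()
        return np.broadcast_to(values, t.shape + values.shape).copy()

    return u


@dataclass
class SimulationTrace:
    """Time series of a forward simulation over settling + evaluation cycles.

    All per-muscle arrays are (n_times, n_muscles) in roster order; the
    final cycle is the evaluation cycle.
    """

    time: np.ndarray
    theta: np.ndarray
    q: np.ndarray
    qd: np.ndarray
    muscle_names: tuple[str, ...]
    excitations: np.ndarray
    activations: np.ndarray
    l_mt: np.ndarray
    v_mt: np.ndarray
    forces: np.ndarray
    lm_norm: np.ndarray
    vm_norm: np.ndarray
    tau_muscle: np.ndarray
    tau_limit: np.ndarray
    tau_id: np.ndarray
    tau_crank: np.ndarray
    power: np.ndarray
    omega: float
    n_cycles: int
    samples_per_cycle: int
    reach_excursion: float = 0.0
    range_excursion: float = 0.0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def period(self) -> float:
        return 2.0 * math.pi / self.omega

    def cycle_slice(self, cycle: int) -> slice:
        """Index slice of one cycle (0-based), endpoints inclusive."""
        if not 0 <= cycle < self.n_cycles:
            raise IndexError(f"cycle {cycle} out of range")
        i0 = cycle * self.samples_per_cycle
        return slice(i0, i0 + self.samples_per_cycle + 1)

    def evaluation_cycle(self) -> "SimulationTrace":
        """Sub-trace of the final (steady-state evaluation) cycle."""
        sl = self.cycle_slice(self.n_cycles - 1)
        kw = {}
        for name in (
            "time", "theta", "q", "qd", "excitations", "activations", "l_mt",
            "v_mt", "forces", "lm_norm", "vm_norm", "tau_muscle", "tau_limit",
            "tau_id", "tau_crank", "power",
        ):
            kw[name] = getattr(self, name)[sl]
        return replace(
            self, n_cycles=1, **kw
        )

    def net_power(self) -> float:
        """Net propulsion power of the evaluation cycle (W)."""
        from .mechanism import net_power as _np

        ev = self if self.n_cycles == 1 else self.evaluation_cycle()
        return _np(ev.time, ev.power, period=ev.period)

    def to_dataframe(self):
        import pandas as pd

        cols = {
            "time_s": self.time,
            "theta_rad": self.theta,
            "q_shoulder_rad": self.q[:, 0],
            "q_elbow_rad": self.q[:, 1],
        }
        for i, name in enumerate(self.muscle_names):
            cols[f"a_{name}"] = self.activations[:, i]
        for i, name in enumerate(self.muscle_names):
            cols[f"F_{name}_N"] = self.forces[:, i]
        cols["tau_crank_Nm"] = self.tau_crank
        cols["power_W"] = self.power
        return pd.DataFrame(cols)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.9g")


def simulate_cycles(
    profile: CrankLengthProfile,
    excitation,
    roster: MuscleRoster,
    arm: ArmConfig,
    mech: MechanismConfig,
    n_settle: int = 3,
    a0: float = 0.050,
    samples_per_cycle: int = 120,
    path_samples: int = 361,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> SimulationTrace:
    """Forward-simulate the muscle-driven closed chain.

    Integrates the activation states with an adaptive embedded
    Runge-Kutta 4(5) method through ``n_settle`` settling cycles plus one
    evaluation cycle, starting all activations at ``a0`` (0.050 by
    default).  Kinematics are fully prescribed by the closed chain at
    constant crank speed; crank torque and power come from the
    virtual-work balance at every output sample.

    ``excitation`` is a callable: scalar t -> (n_muscles,), array t ->
    (len(t), n_muscles); it must be periodic with the crank period.
    """
    pk = path_kinematics(profile, arm, mech, n_samples=path_samples)
    n_m = len(roster)
    period = mech.period
    n_cycles = n_settle + 1
    t_total = n_cycles * period
    t_eval = np.linspace(0.0, t_total, n_cycles * samples_per_cycle + 1)

    tau_act = np.array([m.tau_act for m in roster])
    tau_deact = np.array([m.tau_deact for m in roster])

    def rhs(t, a):
        u = np.clip(excitation(t), 0.0, 1.0)
        a = np.clip(a, 0.0, 1.0)
        scale = 0.5 + 1.5 * a
        tau = np.where(u > a, tau_act * scale, tau_deact / scale)
        return (u - a) / tau

    sol = solve_ivp(
        rhs,
        (0.0, t_total),
        np.full(n_m, float(a0)),
        method="RK45",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        max_step=period / 50.0,
    )
    if not sol.success:
        raise SimulationError(f"activation integration failed: {sol.message}")
    act = np.clip(sol.y.T, 0.0, 1.0)  # (n_t, n_m)

    q, qd, qdd = pk.state(t_eval)
    theta = np.mod(mech.omega * t_eval, 2.0 * np.pi)
    exc = np.clip(excitation(t_eval), 0.0, 1.0)

    # rigid-tendon musculotendon geometry from constant moment arms
    arms = roster.moment_arm_matrix[:, :2]  # wrist fixed: constant contribution
    l_opt = np.array([m.l_opt for m in roster])
    l_slack = np.array([m.l_slack for m in roster])
    cosa = np.cos([m.alpha_penn for m in roster])
    v_max = np.array([m.v_max for m in roster])
    f_iso = np.array([m.f_iso_max for m in roster])
    q_ref = np.asarray(arm.q_ref, dtype=float)
    l_mt0 = l_slack + l_opt * cosa + arms @ q_ref

    l_mt = l_mt0[None, :] - q @ arms.T
    v_mt = -qd @ arms.T
    l_fiber = (l_mt - l_slack[None, :]) / cosa[None, :]
    if np.any(l_fiber <= 1e-6):
        bad = np.argwhere(l_fiber <= 1e-6)
        name = roster.names[bad[0, 1]]
        from .muscle import MuscleModelError

        raise MuscleModelError(
            f"{name}: fiber length non-positive during the cycle "
            "(musculotendon length below tendon slack length)"
        )
    lm = l_fiber / l_opt[None, :]
    vm = v_mt / (cosa * l_opt)[None, :]

    from .muscle import active_force_length, force_velocity, passive_force_length

    fl = active_force_length(lm)
    # force_velocity takes L_opt/s; normalize per muscle by feeding the
    # already-normalized velocity with v_max = 1
    fv = force_velocity(vm / v_max[None, :], v_max=1.0)
    fp = passive_force_length(lm)
    forces = np.clip(
        f_iso[None, :] * (act * fl * fv + fp) * cosa[None, :], 0.0, None
    )

    tau_muscle = forces @ arms  # (n_t, 2)
    tau_lim = joint_limit_torque(q, qd, arm)
    tau_id = inverse_dynamics(q, qd, qdd, arm, branch=pk.branch)
    # virtual work: tau_crank * omega = sum_j (tau_app - tau_ID)_j * qd_j
    power = np.sum((tau_muscle + tau_lim - tau_id) * qd, axis=-1)
    tau_crank = power / mech.omega

    return SimulationTrace(
        time=t_eval,
        theta=theta,
        q=q,
        qd=qd,
        muscle_names=roster.names,
        excitations=exc,
        activations=act,
        l_mt=l_mt,
        v_mt=v_mt,
        forces=forces,
        lm_norm=lm,
        vm_norm=vm / v_max[None, :],
        tau_muscle=tau_muscle,
        tau_limit=tau_lim,
        tau_id=tau_id,
        tau_crank=tau_crank,
        power=power,
        omega=mech.omega,
        n_cycles=n_cycles,
        samples_per_cycle=samples_per_cycle,
        reach_excursion=pk.reach_excursion,
        range_excursion=pk.range_excursion,
    )
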