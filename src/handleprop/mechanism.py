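"""Crank–slider kinematics, crank torque, and the propulsion-power criterion.

The crank rotates clockwise at constant angular velocity ``omega`` about a
center ``C`` fixed in the global frame (origin at the sternum).  The crank
angle ``theta`` is measured *in the rotation sense* from the global +x
axis, so the radial unit vector at crank angle ``theta`` is
``(cos(theta), -sin(theta))`` and ``theta(t) = omega * t``.  Positive
crank torque drives the crank in its propulsion (clockwise) sense, and
instantaneous handle power is ``tau * omega``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .path import CL_MAX, CL_MIN, CrankLengthProfile

__all__ = [
    "MechanismConfig",
    "CrankState",
    "place_crank_center",
    "crank_kinematics",
    "handle_trajectory",
    "crank_torque",
    "instantaneous_power",
    "net_power",
]


@dataclass(frozen=True)
class MechanismConfig:
    """Geometry and drive of the handle mechanism.

    ``crank_center`` is in the global frame (m); ``omega`` in rad/s with
    the crank turning clockwise (the propulsion sense).  The default
    cadence is 50 rpm, the isokinetic ergometer speed used for daily-living
    overground propulsion.
    """

    crank_center: tuple[float, float] = (0.30, -0.35)
    omega: float = 50.0 * 2.0 * math.pi / 60.0
    cl_bounds: tuple[float, float] = field(default=(CL_MIN, CL_MAX))

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError(f"omega must be positive, got {self.omega}")

    @classmethod
    def from_rpm(cls, rpm: float = 50.0, **kw) -> "MechanismConfig":
        return cls(omega=rpm * 2.0 * math.pi / 60.0, **kw)

    @property
    def rpm(self) -> float:
        return self.omega * 60.0 / (2.0 * math.pi)

    @property
    def period(self) -> float:
        """Duration of one crank cycle (s)."""
        return 2.0 * math.pi / self.omega

    def radial_unit(self, theta):
        """Unit vector from C toward the handle at crank angle ``theta``."""
        theta = np.asarray(theta, dtype=float)
        return np.stack([np.cos(theta), -np.sin(theta)], axis=-1)


@dataclass(frozen=True)
class CrankState:
    """Instantaneous state of the mechanism.

    ``eta`` (handle angle about its pin) is kinematically determined by
    the closed chain once an arm is attached; it is NaN at the mechanism
    level.
    """

    theta: float
    cl: float
    position: np.ndarray
    velocity: np.ndarray
    eta: float = math.nan


def place_crank_center(
    srp: tuple[float, float], knee: tuple[float, float], forearm_height: float
) -> np.ndarray:
    """Crank-center placement rule for a seated user.

    C_x is the midpoint between the seat reference point (SRP) and the
    knee joint; C_y is the forearm height above the SRP with the elbow
    flexed at 90 degrees.  All coordinates in the global (sternum) frame.
    """
    srp = np.asarray(srp, dtype=float)
    knee = np.asarray(knee, dtype=float)
    return np.array([0.5 * (srp[0] + knee[0]), srp[1] + forearm_height])


def crank_kinematics(
    profile: CrankLengthProfile, config: MechanismConfig, t: float
) -> CrankState:
    """Mechanism state at time ``t`` (s) for a prescribed C_L profile.

    The handle velocity differentiates the interpolated profile
    analytically: ``v = omega * (C_L'(theta) * e_r + C_L * d(e_r)/dtheta)``.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    theta = math.remainder(config.omega * t, 2.0 * math.pi) % (2.0 * math.pi)
    cl = float(profile(theta))
    lo, hi = config.cl_bounds
    if not (lo - 1e-9 <= cl <= hi + 1e-9):
        from .path import CrankLengthBoundError

        raise CrankLengthBoundError(
            f"C_L={cl:.4f} m outside [{lo}, {hi}] m at theta={theta:.3f}", phi=theta
        )
    c = np.asarray(config.crank_center, dtype=float)
    er = np.array([math.cos(theta), -math.sin(theta)])
    det = np.array([-math.sin(theta), -math.cos(theta)])  # d(e_r)/dtheta
    dcl = float(profile.slope(theta))
    pos = c + cl * er
    vel = config.omega * (dcl * er + cl * det)
    return CrankState(theta=theta, cl=cl, position=pos, velocity=vel)


def handle_trajectory(
    profile: CrankLengthProfile, config: MechanismConfig, t: np.ndarray
):
    """Vectorized handle position over a time grid; returns (theta, xy)."""
    t = np.asarray(t, dtype=float)
    theta = np.mod(config.omega * t, 2.0 * np.pi)
    cl = profile(theta)
    c = np.asarray(config.crank_center, dtype=float)
    xy = c + cl[..., None] * config.radial_unit(theta)
    return theta, xy


def crank_torque(
    handle_force: np.ndarray, state: CrankState, config: MechanismConfig
) -> float:
    """Crank torque (N*m) from a handle force in the global frame.

    The z-moment of the force about C, sign-positive when it drives the
    crank in the propulsion (clockwise) sense:
    ``tau = -(r_x F_y - r_y F_x)``.
    """
    f = np.asarray(handle_force, dtype=float)
    r = np.asarray(state.position, dtype=float) - np.asarray(
        config.crank_center, dtype=float
    )
    return float(-(r[0] * f[1] - r[1] * f[0]))


def instantaneous_power(torque, config: MechanismConfig):
    """Handle power P = tau * omega (W)."""
    return np.asarray(torque, dtype=float) * config.omega


def net_power(
    time: np.ndarray, power: np.ndarray, period: float | None = None
) -> float:
    """Time-average power over exactly one crank cycle (W), by trapezoid.

    If ``period`` is given the series span must match it to 0.1%.
    """
    time = np.asarray(time, dtype=float)
    power = np.asarray(power, dtype=float)
    if time.ndim != 1 or time.shape != power.shape or time.size < 2:
        raise ValueError("time and power must be matching 1-D arrays")
    span = time[-1] - time[0]
    if span <= 0:
        raise ValueError("time grid must be increasing")
    if period is not None and abs(span - period) > 1e-3 * period:
        raise ValueError(
            f"series spans {span:.6f} s, not one crank cycle ({period:.6f} s)"
        )
    return float(np.trapezoid(power, time) / span)
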