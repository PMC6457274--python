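"""Hill-type musculotendon actuators with rigid tendons.

Each of the 15 actuators of the upper-extremity model is a lumped
Hill-type musculotendon unit: first-order excitation-to-activation
dynamics, a Gaussian active force–length curve, an exponential passive
force–length curve, and a hyperbolic force–velocity curve, all in the
Thelen formulation.  The tendon is rigid, so the fiber length follows
algebraically from the musculotendon length:

    L_fiber * cos(alpha_penn) = L_MT - L_slack

and the tendon force is

    F = F_iso_max * (a * f_L(L~) * f_V(V~) + f_P(L~)) * cos(alpha_penn)

with L~ = L_fiber / L_opt and V~ the fiber velocity in optimal fiber
lengths per second (shortening negative, V_max = 10 L_opt/s by default).

In the planar model each muscle acts through constant moment arms
``r_ij`` so that ``L_MT(q) = L_MT0 - sum_j r_ij q_j`` and
``V_MT = -sum_j r_ij dq_j/dt``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "TAU_ACT",
    "TAU_DEACT",
    "V_MAX_DEFAULT",
    "MUSCLE_NAMES",
    "MuscleParams",
    "MuscleState",
    "MuscleRoster",
    "MuscleModelError",
    "activation_rate",
    "active_force_length",
    "passive_force_length",
    "force_velocity",
    "musculotendon_force",
    "load_muscle_table",
]

# Thelen-2003 constants (the source model names the formulation but prints
# no numbers; these are the formulation's published defaults)
TAU_ACT = 0.010  # activation time constant (s)
TAU_DEACT = 0.040  # deactivation time constant (s)
FL_GAMMA = 0.45  # active force-length Gaussian width
KPE = 4.0  # passive exponential shape factor
EPS0 = 0.6  # passive strain at which f_P = 1
F_LEN = 1.4  # eccentric force plateau
AF = 0.25  # force-velocity curvature (Hill a/F0)
V_MAX_DEFAULT = 10.0  # max shortening velocity (L_opt/s)

#: canonical actuator ordering of the 15-muscle upper-extremity set
MUSCLE_NAMES = (
    "Delt1", "Delt2", "Delt3", "BicLong", "BicShort",
    "TriLong", "TriLat", "Bracs", "FCR", "FCU",
    "PecM", "SUPRA", "SUBSC", "INFRA", "TMIN",
)

JOINTS = ("shoulder", "elbow", "wrist")


class MuscleModelError(ValueError):
    """Infeasible musculotendon geometry (names the muscle)."""


@dataclass(frozen=True)
class MuscleParams:
    """Constants of one Hill-type actuator.

    ``moment_arms`` are signed constants (m) per joint in the order
    (shoulder, elbow, wrist); positive means the muscle shortens as that
    joint angle increases (i.e. it is a flexor of that coordinate).
    """

    name: str
    f_iso_max: float  # N
    l_opt: float  # m
    l_slack: float  # m
    alpha_penn: float = 0.0  # rad
    v_max: float = V_MAX_DEFAULT  # L_opt/s
    tau_act: float = TAU_ACT  # s
    tau_deact: float = TAU_DEACT  # s
    moment_arms: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.f_iso_max <= 0 or self.l_opt <= 0 or self.l_slack <= 0:
            raise MuscleModelError(
                f"{self.name}: F_iso_max, L_opt, L_slack must be positive"
            )
        if not (0.0 <= self.alpha_penn < math.pi / 2):
            raise MuscleModelError(f"{self.name}: pennation must be in [0, pi/2)")
        if self.v_max <= 0:
            raise MuscleModelError(f"{self.name}: V_max must be positive")
        if len(self.moment_arms) != len(JOINTS):
            raise MuscleModelError(f"{self.name}: need {len(JOINTS)} moment arms")


@dataclass
class MuscleState:
    """Dynamic state of one actuator: activation and normalized fiber
    length/velocity (shortening negative)."""

    activation: float
    lm_norm: float
    vm_norm: float = 0.0


def activation_rate(u, a, tau_act: float = TAU_ACT, tau_deact: float = TAU_DEACT):
    """First-order excitation-to-activation dynamics, da/dt (1/s).

    da/dt = (u - a)/tau with tau = tau_act*(0.5 + 1.5 a) during
    activation (u > a) and tau_deact/(0.5 + 1.5 a) during deactivation.
    Inputs outside [0, 1] are clamped with a warning.
    """
    u = np.asarray(u, dtype=float)
    a = np.asarray(a, dtype=float)
    if np.any(u < -1e-12) or np.any(u > 1 + 1e-12) or np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
        warnings.warn("excitation/activation outside [0, 1]; clamping", stacklevel=2)
    u = np.clip(u, 0.0, 1.0)
    a = np.clip(a, 0.0, 1.0)
    scale = 0.5 + 1.5 * a
    tau = np.where(u > a, tau_act * scale, tau_deact / scale)
    return (u - a) / tau


def active_force_length(lm_norm):
    """Active force-length scale: Gaussian with optimum at L~ = 1."""
    lm = np.asarray(lm_norm, dtype=float)
    return np.exp(-((lm - 1.0) ** 2) / FL_GAMMA)


def passive_force_length(lm_norm):
    """Passive force-length scale: exponential toe, 1 at strain EPS0,
    clamped to be non-negative below slack."""
    lm = np.asarray(lm_norm, dtype=float)
    fp = (np.exp(KPE * (lm - 1.0) / EPS0) - 1.0) / (math.exp(KPE) - 1.0)
    return np.clip(fp, 0.0, None)


def force_velocity(vm, v_max: float = V_MAX_DEFAULT):
    """Force-velocity scale for fiber velocity ``vm`` in L_opt/s.

    Hyperbolic (Hill) branch for shortening (vm < 0), reaching 0 at
    -v_max; a saturating branch for lengthening with plateau F_LEN and a
    slope-matched transition at vm = 0.
    """
    v = np.asarray(vm, dtype=float) / v_max
    # concentric: (1 + v)/(1 - v/AF), zero at v = -1
    conc = np.clip((1.0 + v) / (1.0 - v / AF), 0.0, None)
    # eccentric: (F_LEN*v + c)/(v + c), slope-matched: (F_LEN-1)/c = 1 + 1/AF
    c = (F_LEN - 1.0) / (1.0 + 1.0 / AF)
    ecc = (F_LEN * v + c) / (v + c)
    return np.where(v < 0.0, conc, ecc)


def musculotendon_force(params: MuscleParams, a, l_mt, v_mt=0.0):
    """Tendon force (N) of a rigid-tendon actuator.

    ``l_mt``/``v_mt`` are musculotendon length (m) and lengthening
    velocity (m/s).  Raises :class:`MuscleModelError` if the geometry
    implies a non-positive fiber length.
    """
    cosa = math.cos(params.alpha_penn)
    l_fiber = (np.asarray(l_mt, dtype=float) - params.l_slack) / cosa
    if np.any(l_fiber <= 1e-6):
        raise MuscleModelError(
            f"{params.name}: musculotendon length {np.min(l_mt):.4f} m implies "
            "non-positive fiber length (below tendon slack length)"
        )
    lm = l_fiber / params.l_opt
    vm = np.asarray(v_mt, dtype=float) / (cosa * params.l_opt)  # L_opt/s
    a = np.clip(np.asarray(a, dtype=float), 0.0, 1.0)
    f = params.f_iso_max * (
        a * active_force_length(lm) * force_velocity(vm, params.v_max)
        + passive_force_length(lm)
    ) * cosa
    return np.clip(f, 0.0, None)


# ---------------------------------------------------------------------------
# roster and parameter table


@dataclass(frozen=True)
class MuscleRoster:
    """An ordered set of actuators with unique names.

    The canonical propulsion model uses the full 15-muscle set
    (:meth:`default`); reduced rosters for cheap runs are built with
    :meth:`subset`.
    """

    muscles: tuple[MuscleParams, ...]

    def __post_init__(self) -> None:
        if len(self.muscles) < 1:
            raise ValueError("roster must contain at least one muscle")
        names = [m.name for m in self.muscles]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate muscle names in roster: {names}")

    def __len__(self) -> int:
        return len(self.muscles)

    def __iter__(self):
        return iter(self.muscles)

    def __getitem__(self, key):
        if isinstance(key, str):
            for m in self.muscles:
                if m.name == key:
                    return m
            raise KeyError(key)
        return self.muscles[key]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.muscles)

    def subset(self, names: list[str]) -> "MuscleRoster":
        return MuscleRoster(tuple(self[n] for n in names))

    @property
    def moment_arm_matrix(self) -> np.ndarray:
        """(n_muscles, n_joints) signed moment arms (m)."""
        return np.array([m.moment_arms for m in self.muscles])

    @classmethod
    def default(cls) -> "MuscleRoster":
        """The packaged 15-muscle set (synthetic parameter fixture)."""
        with resources.files("handleprop.data").joinpath(
            "muscles_default.csv"
        ).open() as fh:
            table = load_muscle_table(fh)
        if table.names != MUSCLE_NAMES:
            raise ValueError("packaged muscle table does not match the 15-muscle set")
        return table


def load_muscle_table(source) -> MuscleRoster:
    """Read a muscle parameter CSV into a roster.

    Columns: name, F_iso_max_N, L_opt_m, L_slack_m, penn_deg,
    r_shoulder_m, r_elbow_m, r_wrist_m.
    """
    df = pd.read_csv(source, comment="#")
    required = {
        "name", "F_iso_max_N", "L_opt_m", "L_slack_m", "penn_deg",
        "r_shoulder_m", "r_elbow_m", "r_wrist_m",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"muscle table missing columns: {sorted(missing)}")
    muscles = tuple(
        MuscleParams(
            name=str(row["name"]),
            f_iso_max=float(row["F_iso_max_N"]),
            l_opt=float(row["L_opt_m"]),
            l_slack=float(row["L_slack_m"]),
            alpha_penn=math.radians(float(row["penn_deg"])),
            moment_arms=(
                float(row["r_shoulder_m"]),
                float(row["r_elbow_m"]),
                float(row["r_wrist_m"]),
            ),
        )
        for _, row in df.iterrows()
    )
    return MuscleRoster(muscles)
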