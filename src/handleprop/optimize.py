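"""Dynamic optimization of excitations and handle-path shape.

The control vector stacks, per muscle, a fixed number of excitation
nodes (10 in the full problem) placed at equal time fractions of the
crank cycle and interpolated by a *periodic* cubic spline — periodicity
of the muscle activity pattern is built into the parameterization, so
``u(t_0) = u(t_f)`` holds by construction — followed by the four shape
parameters (A, B, n, beta).  With 15 muscles and 10 nodes this is the
full 154-variable problem.

The objective is the negative net propulsion power of the steady-state
evaluation cycle (after settling cycles) plus quadratic penalties for
joint-range excursions, unreachable handle positions, non-star-shaped
paths, and crank-length bound violations.  The default search backend is
a seeded (1+lambda) evolution strategy with 1/5th-success-rule step-size
adaptation: gradient-free, monotone in accepted objective, and
bit-reproducible for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .arm import ArmConfig, SimulationError, simulate_cycles
from .mechanism import MechanismConfig
from .muscle import MuscleModelError, MuscleRoster
from .path import (
    CL_MAX,
    CL_MIN,
    CrankLengthBoundError,
    PathGeometryError,
    PathShapeParams,
    sample_path,
    to_crank_length_profile,
)

__all__ = [
    "ControlVector",
    "ObjectiveReport",
    "PenaltyWeights",
    "ExcitationSplines",
    "PropulsionObjective",
    "OptimizeResult",
    "excitation_signal",
    "assemble_controls",
    "disassemble_controls",
    "optimize",
    "optimize_propulsion",
]

N_SHAPE = 4
BETA_BOUNDS = (-math.pi / 2.0, math.pi / 2.0)


@dataclass(frozen=True)
class ControlVector:
    """Excitation nodes (n_muscles x n_nodes, each in [0, 1]) plus the
    four shape parameters."""

    nodes: np.ndarray
    shape: PathShapeParams

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        if nodes.ndim != 2:
            raise ValueError("nodes must be a (n_muscles, n_nodes) matrix")
        if np.any(nodes < -1e-12) or np.any(nodes > 1 + 1e-12):
            raise ValueError("excitation nodes must lie in [0, 1]")
        object.__setattr__(self, "nodes", nodes)

    def __len__(self) -> int:
        return self.nodes.size + N_SHAPE

    def to_array(self) -> np.ndarray:
        """Flat vector: muscles in roster order row-wise, then A, B, n, beta."""
        s = self.shape
        return np.concatenate([self.nodes.ravel(), [s.A, s.B, s.n, s.beta]])

    @classmethod
    def from_array(cls, x: np.ndarray, n_muscles: int, n_nodes: int) -> "ControlVector":
        x = np.asarray(x, dtype=float)
        if x.size != n_muscles * n_nodes + N_SHAPE:
            raise ValueError(
                f"expected {n_muscles * n_nodes + N_SHAPE} variables, got {x.size}"
            )
        nodes = x[: n_muscles * n_nodes].reshape(n_muscles, n_nodes)
        A, B, n, beta = x[-N_SHAPE:]
        return cls(nodes=nodes, shape=PathShapeParams(A=A, B=B, n=n, beta=beta))


def assemble_controls(
    roster: MuscleRoster, shape: PathShapeParams, node_matrix: np.ndarray
) -> ControlVector:
    """Bundle per-muscle excitation nodes and shape parameters.

    ``node_matrix`` must be (len(roster), n_nodes); the full problem uses
    the 15-muscle roster with 10 nodes each, giving 154 variables.
    """
    nodes = np.asarray(node_matrix, dtype=float)
    if nodes.ndim != 2 or nodes.shape[0] != len(roster):
        raise ValueError(
            f"node matrix must have {len(roster)} rows, got shape {nodes.shape}"
        )
    return ControlVector(nodes=nodes, shape=shape)


def disassemble_controls(
    x: np.ndarray, roster: MuscleRoster, n_nodes: int
) -> ControlVector:
    return ControlVector.from_array(x, n_muscles=len(roster), n_nodes=n_nodes)


def excitation_signal(nodes: np.ndarray, t, cycle: float):
    """Excitation u(t) from control nodes at equal time fractions.

    Periodic cubic-spline interpolation (node 0 serves as both endpoints
    of the cycle) clipped to [0, 1] against spline overshoot.
    """
    nodes = np.asarray(nodes, dtype=float)
    k = nodes.size
    knots = np.linspace(0.0, cycle, k + 1)
    sp = CubicSpline(knots, np.append(nodes, nodes[0]), bc_type="periodic")
    return np.clip(sp(np.mod(t, cycle)), 0.0, 1.0)


class ExcitationSplines:
    """Vectorized periodic excitation splines for a whole roster.

    Callable: scalar t -> (n_muscles,), array t -> (len(t), n_muscles).
    """

    def __init__(self, node_matrix: np.ndarray, cycle: float):
        nodes = np.asarray(node_matrix, dtype=float)
        if nodes.ndim != 2:
            raise ValueError("node matrix must be 2-D")
        self.cycle = float(cycle)
        k = nodes.shape[1]
        knots = np.linspace(0.0, cycle, k + 1)
        ext = np.concatenate([nodes, nodes[:, :1]], axis=1)  # close the cycle
        self._spline = CubicSpline(knots, ext.T, bc_type="periodic")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return np.clip(self._spline(np.mod(t, self.cycle)), 0.0, 1.0)


@dataclass(frozen=True)
class PenaltyWeights:
    """Quadratic penalty weights of the objective (minimization form)."""

    joint_range: float = 100.0  # per rad^2*rad of range excursion
    reach: float = 1.0e4  # reach / non-star-shape indicator
    cl_bound: float = 1.0e3  # per m^2 of C_L excursion beyond the slider


@dataclass(frozen=True)
class ObjectiveReport:
    """One objective evaluation: net power, penalties, total, feasibility."""

    net_power: float
    penalties: dict = field(default_factory=dict)
    feasible: bool = True
    failure: str | None = None

    @property
    def total(self) -> float:
        return -self.net_power + sum(self.penalties.values())


class PropulsionObjective:
    """Net-power-with-penalties objective over the control vector.

    Each evaluation builds the handle path, converts it to a
    crank-length profile, resolves the closed chain, forward-simulates
    the muscle states through settling + evaluation cycles and returns
    ``-net_power + penalties``.  Infeasible geometry is penalized, not
    fatal; simulation failures return a large finite objective with a
    failure flag so search backends can continue.
    """

    FAILURE_OBJECTIVE = 1.0e6

    def __init__(
        self,
        roster: MuscleRoster,
        arm: ArmConfig | None = None,
        mech: MechanismConfig | None = None,
        n_nodes: int = 10,
        weights: PenaltyWeights | None = None,
        n_settle: int = 3,
        samples_per_cycle: int = 120,
        path_points: int = 256,
    ):
        self.roster = roster
        self.arm = arm or ArmConfig()
        self.mech = mech or MechanismConfig()
        self.n_nodes = n_nodes
        self.weights = weights or PenaltyWeights()
        self.n_settle = n_settle
        self.samples_per_cycle = samples_per_cycle
        self.path_points = path_points

    @property
    def n_vars(self) -> int:
        return len(self.roster) * self.n_nodes + N_SHAPE

    def bounds(self) -> np.ndarray:
        """(n_vars, 2) box bounds: nodes in [0,1], A,B in the slider
        travel, n in [0,1], beta in +-90 deg."""
        lo = np.zeros(self.n_vars)
        hi = np.ones(self.n_vars)
        lo[-4:] = [CL_MIN, CL_MIN, 0.0, BETA_BOUNDS[0]]
        hi[-4:] = [CL_MAX, CL_MAX, 1.0, BETA_BOUNDS[1]]
        return np.column_stack([lo, hi])

    def _profile_and_penalties(self, shape: PathShapeParams):
        w = self.weights
        penalties = {}
        poly = sample_path(shape, self.path_points)
        if not poly.is_star_shaped():
            penalties["star_shape"] = w.reach
            return None, penalties
        try:
            profile = to_crank_length_profile(poly, bounds=self.mech.cl_bounds)
        except CrankLengthBoundError:
            # quantify the excursion, then clip the profile back into the
            # slider travel so the simulation can proceed
            profile = to_crank_length_profile(poly, bounds=(0.0, np.inf))
            lo, hi = self.mech.cl_bounds
            exc = np.clip(profile.cl - hi, 0.0, None) + np.clip(
                lo - profile.cl, 0.0, None
            )
            penalties["cl_bound"] = w.cl_bound * float(
                np.trapezoid(exc**2, profile.phi)
            )
            from .path import CrankLengthProfile

            profile = CrankLengthProfile(
                phi=profile.phi, cl=np.clip(profile.cl, lo, hi)
            )
        return profile, penalties

    def evaluate(self, controls: ControlVector, return_trace: bool = False):
        w = self.weights
        try:
            profile, penalties = self._profile_and_penalties(controls.shape)
        except (PathGeometryError, ValueError) as e:
            report = ObjectiveReport(
                net_power=-self.FAILURE_OBJECTIVE,
                penalties={},
                feasible=False,
                failure=str(e),
            )
            return (report, None) if return_trace else report
        if profile is None:
            report = ObjectiveReport(net_power=0.0, penalties=penalties, feasible=False)
            return (report, None) if return_trace else report

        excitation = ExcitationSplines(controls.nodes, cycle=self.mech.period)
        try:
            trace = simulate_cycles(
                profile,
                excitation,
                self.roster,
                self.arm,
                self.mech,
                n_settle=self.n_settle,
                samples_per_cycle=self.samples_per_cycle,
            )
        except (SimulationError, MuscleModelError, PathGeometryError) as e:
            report = ObjectiveReport(
                net_power=-self.FAILURE_OBJECTIVE,
                penalties=penalties,
                feasible=False,
                failure=str(e),
            )
            return (report, None) if return_trace else report

        if trace.reach_excursion > 0:
            penalties["reach"] = w.reach * trace.reach_excursion
        if trace.range_excursion > 0:
            penalties["joint_range"] = w.joint_range * trace.range_excursion
        report = ObjectiveReport(
            net_power=trace.net_power(),
            penalties=penalties,
            feasible=not penalties,
        )
        return (report, trace) if return_trace else report

    def __call__(self, x: np.ndarray) -> float:
        controls = ControlVector.from_array(
            np.asarray(x, dtype=float), len(self.roster), self.n_nodes
        )
        return self.evaluate(controls).total


@dataclass
class OptimizeResult:
    """Best iterate of a search run plus its accepted-objective history."""

    x: np.ndarray
    objective: float
    history: list
    n_evaluations: int
    converged: bool
    message: str = ""


def optimize(
    objective,
    bounds: np.ndarray,
    seed: int,
    x0: np.ndarray | None = None,
    max_iter: int = 100,
    popsize: int = 6,
    sigma0: float = 0.15,
    sigma_min: float = 1e-4,
) -> OptimizeResult:
    """Bound-constrained minimization by a (1+lambda) evolution strategy.

    Each iteration samples ``popsize`` Gaussian perturbations of the
    incumbent (scaled per coordinate by the box width, reflected into the
    box) and accepts the best candidate only if it improves, so the
    history of accepted objectives is monotone non-increasing.  Step size
    follows the 1/5th success rule.  Fully deterministic for a given
    seed.
    """
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    width = hi - lo
    rng = np.random.default_rng(seed)
    if x0 is None:
        x = lo + width * rng.random(lo.size)
    else:
        x = np.clip(np.asarray(x0, dtype=float), lo, hi)
    f = float(objective(x))
    history = [f]
    n_eval = 1
    sigma = sigma0
    for _ in range(max_iter):
        cand = x[None, :] + sigma * width[None, :] * rng.standard_normal(
            (popsize, lo.size)
        )
        # reflect into the box
        cand = np.where(cand < lo, 2 * lo - cand, cand)
        cand = np.where(cand > hi, 2 * hi - cand, cand)
        cand = np.clip(cand, lo, hi)
        f_cand = np.array([objective(c) for c in cand])
        n_eval += popsize
        i_best = int(np.argmin(f_cand))
        if f_cand[i_best] < f:
            x = cand[i_best]
            f = float(f_cand[i_best])
            sigma = min(sigma * 1.3, 0.5)
        else:
            sigma = max(sigma * 0.85, sigma_min)
        history.append(f)
    return OptimizeResult(
        x=x,
        objective=f,
        history=history,
        n_evaluations=n_eval,
        converged=sigma <= sigma_min * 1.01,
        message="iteration budget exhausted" if sigma > sigma_min * 1.01 else "",
    )


def _random_feasible_shape(rng: np.random.Generator, mech: MechanismConfig,
                           max_tries: int = 50) -> PathShapeParams:
    """Draw a random shape whose path is star-shaped with C_L in bounds."""
    last = None
    for _ in range(max_tries):
        shape = PathShapeParams(
            A=rng.uniform(CL_MIN, CL_MAX),
            B=rng.uniform(CL_MIN, CL_MAX),
            n=rng.uniform(0.0, 1.0),
            beta=rng.uniform(*BETA_BOUNDS),
        )
        last = shape
        poly = sample_path(shape, 256)
        if not poly.is_star_shaped():
            continue
        try:
            to_crank_length_profile(poly, bounds=mech.cl_bounds)
        except (CrankLengthBoundError, PathGeometryError):
            continue
        return shape
    return last


def optimize_propulsion(
    roster: MuscleRoster,
    seed: int,
    arm: ArmConfig | None = None,
    mech: MechanismConfig | None = None,
    n_nodes: int = 10,
    max_iter: int = 100,
    popsize: int = 6,
    weights: PenaltyWeights | None = None,
    n_settle: int = 3,
    samples_per_cycle: int = 120,
):
    """Run the full propulsion optimization from a random initial point.

    Initial excitation nodes are drawn uniformly in [0, 1] and the
    initial shape uniformly within its box, redrawn until geometrically
    feasible.  Returns ``(objective, result, initial_controls)`` where
    ``objective`` is the :class:`PropulsionObjective` (for re-evaluating
    iterates) and ``result`` the search outcome.
    """
    obj = PropulsionObjective(
        roster,
        arm=arm,
        mech=mech,
        n_nodes=n_nodes,
        weights=weights,
        n_settle=n_settle,
        samples_per_cycle=samples_per_cycle,
    )
    rng = np.random.default_rng(seed)
    shape0 = _random_feasible_shape(rng, obj.mech)
    nodes0 = rng.random((len(roster), n_nodes))
    x0 = assemble_controls(roster, shape0, nodes0).to_array()
    result = optimize(
        obj,
        obj.bounds(),
        seed=int(rng.integers(2**31 - 1)),
        x0=x0,
        max_iter=max_iter,
        popsize=popsize,
    )
    initial = ControlVector.from_array(x0, len(roster), n_nodes)
    return obj, result, initial
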