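"""Parametric closed handle paths and their effective-crank-length profiles.

The handle path of the propulsion mechanism is a four-parameter closed
curve in the crank frame (origin at the crank center ``C``)::

    P_X(t) = A cos(t)
    P_Y(t) = B sin(t) sin^n(t/2)
    P'(t)  = R_z(beta) @ P(t)        (beta > 0 tilts the path clockwise)

``A`` and ``B`` scale the curve (meters), the exponent ``n`` in [0, 1]
morphs it between an ellipse (n = 0) and an egg-like asymmetric oval, and
``beta`` tilts the whole path about ``C``.  With A = B and n = 0 the path
degenerates to a circle.  Because the handle rides on the crank's slider,
a path is usable only if it is star-shaped about ``C`` — every crank angle
must see exactly one path point — and every radius must stay inside the
slider's travel, 0.030 m to 0.155 m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CL_MIN",
    "CL_MAX",
    "PathShapeParams",
    "PathPolyline",
    "CrankLengthProfile",
    "PathParameterError",
    "PathGeometryError",
    "CrankLengthBoundError",
    "eval_path",
    "sample_path",
    "circularity",
    "to_crank_length_profile",
]

#: slider travel limits of the crank mechanism (m); also bound A and B
CL_MIN = 0.030
CL_MAX = 0.155


class PathParameterError(ValueError):
    """Shape parameters outside their admissible box."""


class PathGeometryError(ValueError):
    """Polyline violates a geometric precondition (open, self-intersecting,
    or not star-shaped about the crank center)."""


class CrankLengthBoundError(ValueError):
    """A crank-length value left the slider's travel range.

    Carries the offending crank angle(s) in ``phi`` (rad).
    """

    def __init__(self, message: str, phi: np.ndarray):
        super().__init__(message)
        self.phi = np.atleast_1d(phi)


@dataclass(frozen=True)
class PathShapeParams:
    """The four shape controls of the handle path.

    Parameters
    ----------
    A, B : float
        Length scales in meters, each within the slider travel
        [0.030, 0.155] m.
    n : float
        Shape exponent in [0, 1]; 0 gives an ellipse.
    beta : float
        Tilt angle in radians; positive tilts the path clockwise about
        the crank center.
    """

    A: float
    B: float
    n: float
    beta: float = 0.0

    def __post_init__(self) -> None:
        if not (CL_MIN <= self.A <= CL_MAX) or not (CL_MIN <= self.B <= CL_MAX):
            raise PathParameterError(
                f"A and B must lie in [{CL_MIN}, {CL_MAX}] m, "
                f"got A={self.A}, B={self.B}"
            )
        if not (0.0 <= self.n <= 1.0):
            raise PathParameterError(f"shape exponent n must be in [0, 1], got {self.n}")
        if not math.isfinite(self.beta):
            raise PathParameterError(f"beta must be finite, got {self.beta}")

    @classmethod
    def from_degrees(cls, A: float, B: float, n: float, beta_deg: float = 0.0) -> "PathShapeParams":
        return cls(A=A, B=B, n=n, beta=math.radians(beta_deg))

    @property
    def beta_deg(self) -> float:
        return math.degrees(self.beta)


@dataclass(frozen=True)
class PathPolyline:
    """A closed polyline sampling of a handle path in the crank frame.

    ``theta`` is the generating curve parameter (not the crank angle);
    the first and last vertex coincide.
    """

    theta: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (theta.shape == x.shape == y.shape) or theta.ndim != 1:
            raise PathGeometryError("theta, x, y must be 1-D arrays of equal length")
        if theta.size < 4:
            raise PathGeometryError("polyline needs at least 4 vertices")
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def radii(self) -> np.ndarray:
        """Distance of each vertex from the crank center."""
        return np.hypot(self.x, self.y)

    def is_closed(self, tol: float = 1e-9) -> bool:
        return (
            abs(self.x[0] - self.x[-1]) <= tol and abs(self.y[0] - self.y[-1]) <= tol
        )

    def crank_angles(self) -> np.ndarray:
        """Polar angle of each vertex measured in the crank's (clockwise)
        rotation sense from the +x axis, in [0, 2*pi)."""
        return np.mod(-np.arctan2(self.y, self.x), 2.0 * np.pi)

    def is_star_shaped(self) -> bool:
        """True if the polar angle is strictly monotonic around the loop,
        i.e. every crank angle sees exactly one path point."""
        psi = np.unwrap(np.arctan2(self.y, self.x)[:-1])
        d = np.diff(psi)
        if np.any(d == 0.0):
            return False
        return bool(np.all(d > 0) or np.all(d < 0))


def eval_path(params: PathShapeParams, theta):
    """Evaluate the parametric path at curve parameter ``theta`` (rad).

    Returns the (x, y) point in meters in the crank frame, tilted
    clockwise by ``params.beta``.  ``theta`` may be a scalar or array.
    """
    theta = np.asarray(theta, dtype=float)
    x0 = params.A * np.cos(theta)
    # 0**0 == 1 here, so n = 0 cleanly degenerates to an ellipse
    y0 = params.B * np.sin(theta) * np.abs(np.sin(0.5 * theta)) ** params.n
    cb, sb = math.cos(params.beta), math.sin(params.beta)
    # active clockwise rotation by beta
    x = cb * x0 + sb * y0
    y = -sb * x0 + cb * y0
    return x, y


def sample_path(params: PathShapeParams, n_points: int = 720) -> PathPolyline:
    """Sample the path on a uniform parameter grid over one revolution.

    ``n_points`` counts the vertices including the repeated closing
    vertex; the polyline is exactly closed by construction.
    """
    if n_points < 16:
        raise PathParameterError(f"n_points must be >= 16, got {n_points}")
    theta = np.linspace(0.0, 2.0 * np.pi, n_points)
    x, y = eval_path(params, theta)
    # close exactly against round-off
    x[-1], y[-1] = x[0], y[0]
    return PathPolyline(theta=theta, x=x, y=y)


def _perimeter(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.sum(np.hypot(np.diff(x), np.diff(y))))


def _shoelace_area(x: np.ndarray, y: np.ndarray) -> float:
    return 0.5 * float(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))


def circularity(poly: PathPolyline) -> float:
    """Isoperimetric (Miller) circularity ratio, 4*pi*Area/Perimeter^2.

    Equals 1 for a circle and decreases toward 0 as the shape elongates.
    Area by the shoelace formula, perimeter as the chord-length sum.
    """
    if not poly.is_closed(tol=1e-9):
        raise PathGeometryError("polyline must be closed")
    if not _is_simple(poly):
        raise PathGeometryError("polyline is self-intersecting")
    area = abs(_shoelace_area(poly.x, poly.y))
    per = _perimeter(poly.x, poly.y)
    if per <= 0.0 or area <= 0.0:
        raise PathGeometryError("degenerate polyline (zero area or perimeter)")
    return 4.0 * math.pi * area / per**2


def _is_simple(poly: PathPolyline) -> bool:
    # star-shaped about the origin implies simple; fall back to an exact
    # segment-intersection test only for the exotic cases
    if poly.is_star_shaped():
        return True
    try:
        from shapely.geometry import LineString

        return bool(LineString(np.column_stack([poly.x, poly.y])).is_simple)
    except ImportError:  # pragma: no cover
        return True


@dataclass(frozen=True)
class CrankLengthProfile:
    """Effective crank length C_L as a periodic function of crank angle.

    Tabulated on a uniform crank-angle grid ``phi`` over [0, 2*pi]
    (endpoint repeated, values periodic) with linear interpolation in
    between, matching how the slider motion is prescribed.
    """

    phi: np.ndarray
    cl: np.ndarray
    bounds: tuple[float, float] = field(default=(CL_MIN, CL_MAX))

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi, dtype=float)
        cl = np.asarray(self.cl, dtype=float)
        if phi.shape != cl.shape or phi.ndim != 1 or phi.size < 2:
            raise PathGeometryError("phi and cl must be matching 1-D arrays")
        if abs(phi[0]) > 1e-12 or abs(phi[-1] - 2.0 * np.pi) > 1e-9:
            raise PathGeometryError("phi grid must span [0, 2*pi]")
        if abs(cl[0] - cl[-1]) > 1e-9:
            raise PathGeometryError("profile must be periodic: cl(0) == cl(2*pi)")
        object.__setattr__(self, "phi", phi)
        object.__setattr__(self, "cl", cl)

    @classmethod
    def from_radius(cls, radius: float, n_phi: int = 361) -> "CrankLengthProfile":
        """Constant (circular) profile."""
        phi = np.linspace(0.0, 2.0 * np.pi, n_phi)
        return cls(phi=phi, cl=np.full_like(phi, float(radius)))

    @classmethod
    def from_shape(
        cls, params: PathShapeParams, n_points: int = 720
    ) -> "CrankLengthProfile":
        return to_crank_length_profile(sample_path(params, n_points))

    def __call__(self, phi):
        """Linear-interpolated C_L at crank angle(s) ``phi`` (rad, any real)."""
        p = np.mod(phi, 2.0 * np.pi)
        return np.interp(p, self.phi, self.cl)

    def slope(self, phi):
        """dC_L/dphi of the linear interpolant (piecewise constant)."""
        p = np.mod(phi, 2.0 * np.pi)
        idx = np.clip(np.searchsorted(self.phi, p, side="right") - 1, 0, self.phi.size - 2)
        h = self.phi[1] - self.phi[0]
        return (self.cl[idx + 1] - self.cl[idx]) / h

    @property
    def cl_min(self) -> float:
        return float(np.min(self.cl))

    @property
    def cl_max(self) -> float:
        return float(np.max(self.cl))

    def to_points(self) -> tuple[np.ndarray, np.ndarray]:
        """Reconstruct crank-frame (x, y) vertices from the polar table."""
        return self.cl * np.cos(self.phi), -self.cl * np.sin(self.phi)


def to_crank_length_profile(
    poly: PathPolyline, n_phi: int = 720, bounds: tuple[float, float] = (CL_MIN, CL_MAX)
) -> CrankLengthProfile:
    """Convert a star-shaped polyline to a crank-length profile.

    Each vertex's polar angle (measured in the crank's rotation sense)
    becomes the crank angle, its radius the effective crank length; the
    table is resampled by linear interpolation onto a uniform grid.

    Raises
    ------
    PathGeometryError
        If the polyline is not star-shaped about the crank center
        (C_L would be multivalued).
    CrankLengthBoundError
        If any resampled C_L leaves ``bounds``.
    """
    if not poly.is_closed(tol=1e-9):
        raise PathGeometryError("polyline must be closed")
    if not poly.is_star_shaped():
        raise PathGeometryError(
            "path is not star-shaped about the crank center; "
            "C_L(phi) would be multivalued"
        )
    phi_raw = poly.crank_angles()[:-1]
    r_raw = poly.radii[:-1]
    order = np.argsort(phi_raw)
    phi_s = phi_raw[order]
    r_s = r_raw[order]
    # periodic padding so interpolation wraps across 0/2*pi
    phi_pad = np.concatenate([[phi_s[-1] - 2.0 * np.pi], phi_s, [phi_s[0] + 2.0 * np.pi]])
    r_pad = np.concatenate([[r_s[-1]], r_s, [r_s[0]]])
    phi_grid = np.linspace(0.0, 2.0 * np.pi, n_phi)
    cl = np.interp(phi_grid, phi_pad, r_pad)
    cl[-1] = cl[0]
    lo, hi = bounds
    bad = (cl < lo - 1e-12) | (cl > hi + 1e-12)
    if np.any(bad):
        raise CrankLengthBoundError(
            f"C_L leaves [{lo}, {hi}] m (range [{cl.min():.4f}, {cl.max():.4f}] m)",
            phi=phi_grid[bad],
        )
    return CrankLengthProfile(phi=phi_grid, cl=cl, bounds=bounds)
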