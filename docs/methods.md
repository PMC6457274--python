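# Methods

This note documents the model, its assumptions, the parameter choices
that matter, and what the synthetic defaults do and do not represent.

## Scope and architecture

The package implements a desk-scale, planar re-formulation of a
muscle-driven handle-propulsion optimization.  The original problem
couples a 3-D OpenSim shoulder–arm model to the handle mechanism; that
model's muscle parameters, wrapping geometry and shoulder-girdle
regression kinematics are not publicly printed, so this package instead
builds a *parasagittal planar reduction* that preserves the structure of
the problem — the parametric path family, the crank–slider mechanism,
the Hill-type actuator set, the power objective, the control
parameterization and the settling protocol — while remaining fully
self-contained and reproducible.  Headline power values from the 3-D
model are therefore **not** reproduction targets; the shape-geometry
quantities (circularity, crank-length extrema) are, since they depend
only on the printed shape parameters.

Because the crank turns at constant angular velocity and the hand is
welded to the handle, the skeletal kinematics are *prescribed* once the
path is fixed: q(θ) follows from two-link inverse kinematics.  The only
dynamic states are the 15 muscle activations.  "Forward simulation"
integrates those; rigid-body effects enter through inverse dynamics, and
crank torque is recovered by virtual work,
τ_crank = Σⱼ (τ_app,j − τ_ID,j)·∂q_j/∂θ.  This is the one place where a
genuine architectural choice had to be made (the original work does not
describe how the redundant closed chain is resolved); the virtual-work
route makes the energy audit exact: over a periodic cycle the
inverse-dynamics work vanishes, so net crank work must equal
musculotendon work plus passive joint-limit work, which the tests assert
to 1%.

## Handle path

- Family: P_X = A cos θ, P_Y = B sin θ sinⁿ(θ/2), rotated clockwise by β.
  n = 0 degenerates to an ellipse (circle when A = B).
- Circularity is the isoperimetric (Miller) ratio 4π·Area/Perimeter²,
  the standard compactness measure equal to 1 for a circle.  Area by the
  shoelace formula, perimeter by chord-length sum, on a uniform
  720-point parameter grid by default (discretization error O(1/N²),
  ~1e-5 at this resolution).
- Conversion to the crank-length profile C_L(φ) requires the path to be
  star-shaped about the crank center (polar angle strictly monotonic);
  non-star paths are rejected with an error and handled by penalty in
  the optimizer, never silently repaired.  An empirical scan found no
  non-star member of the family inside the admissible parameter box,
  consistent with the family's construction, so this guard matters only
  for hand-built polylines.
- C_L(φ) uses *linear* interpolation on a uniform crank-angle grid
  (matching how a slider prescription is tabulated); everything else
  uses cubic splines.
- Convexity of the path is reported by geometry checks where needed but
  never enforced; it is an empirical property of the family, not an
  invariant.

## Mechanism

- Crank angle θ is measured in the rotation (clockwise, propulsion)
  sense from the global +x axis; the radial unit vector is
  (cos θ, −sin θ), θ = ωt, and positive crank torque drives propulsion.
  θ = 0 pointing along +x is a convention the source leaves open.
- ω defaults to 50 rpm (isokinetic daily-living cadence); configurable.
- Net power is the trapezoidal time average of τ·ω over exactly one
  cycle.  On a periodic grid the trapezoid rule is spectrally accurate,
  so the zero-excitation passivity check is asserted at 1e-9 W rather
  than exactly 0 (sign of the ~1e-12 W residual is round-off).
- Crank-center placement rule for a seated user: C_x midway between seat
  reference point and knee, C_y one forearm height (elbow at 90°) above
  the seat reference point.  The packaged default geometry — shoulder at
  (0, 0.10) m from the sternum origin, crank center (0.30, −0.35) m —
  was chosen once so that the *entire* slider annulus [0.030, 0.155] m
  about C lies inside the arm's reachable annulus with elbow flexion in
  [0°, 130°]; this keeps every admissible shape kinematically feasible
  and makes reach penalties a property of configurations, not of the
  default geometry.

## Musculotendon model

- Thelen-formulation curves with the formulation's published constants
  (none are printed in the source study): τ_act = 10 ms,
  τ_deact = 40 ms with the (0.5 + 1.5a) activation-dependence; active
  force–length Gaussian width γ = 0.45; passive exponential with shape
  factor 4 normalized to 1 at strain 0.6 (clamped non-negative below
  slack); force–velocity with Hill curvature a/F₀ = 0.25, eccentric
  plateau 1.4 and a slope-matched transition at zero velocity;
  V_max = 10 L_opt/s.
- **Rigid tendon**: fiber length is algebraic in musculotendon length,
  L_fiber cos α = L_MT − L_slack (constant-thickness pennation).  This
  halves the state dimension and is accurate for the short-tendon
  upper-limb muscles at this cadence; an elastic tendon is an
  acknowledged extension, not implemented.
- **Constant moment arms** per muscle–joint pair replace wrapping
  geometry: L_MT(q) = L_MT0 − Σⱼ r_ij q_j, V_MT = −Σⱼ r_ij q̇_j.  The
  reference length L_MT0 is set so every fiber sits at L_opt at the
  reference pose q_ref = (−60°, 90°), the middle of the task workspace —
  so the default muscles operate near their optimum in typical cycles.
- The packaged 15-muscle table is a **synthetic fixture** with
  literature-plausible magnitudes (max isometric forces 74–1180 N,
  optimal fiber lengths 5–14 cm); it is *not* a reproduction of any
  published model.  The rotator cuff muscles are retained with small
  in-plane shoulder moment arms so control-vector sizes match the full
  problem; their 3-D rotation action is out of scope.  The wrist is
  fixed, so wrist moment arms are carried in the table but contribute
  only a constant absorbed into L_MT0.

## Arm dynamics

- Two links: upper arm 0.33 m / 2.0 kg, forearm+hand 0.46 m / 1.7 kg,
  COM at 45% of length, thin-rod inertia — 50th-percentile-male-style
  defaults, configurable, not fitted to any subject.
- Coordinates: q_sh is the global upper-arm angle (CCW from +x), q_el
  elbow flexion in [0°, 130°].  Shoulder in-plane range defaults to
  [−135°, 45°].
- IK branch: elbow flexion from the law of cosines is branch-independent,
  so the two branches differ only in shoulder angle.  The branch whose
  shoulder angle lies inside its configured range at the cycle's first
  crank angle is chosen (preferring the elbow-low branch) and held for
  the whole cycle — no branch switching.
- Unreachable handle points are clipped radially back to the reachable
  annulus (1 mm margin) and the clipped distance is integrated into a
  reach-excursion penalty; this keeps the objective finite and smooth at
  the feasibility boundary instead of failing.
- If a handle path orbits the shoulder, the shoulder angle winds by 2π
  per cycle; the winding is removed before the periodic spline fit and
  restored analytically.  Normal geometries have zero winding.
- Joint limits: elastic torque K·(excursion) with K = 50 N·m/rad plus
  damping c = 1 N·m·s/rad engaged only beyond the limit.  In well-posed
  optimized cycles these torques are essentially inactive; they exist to
  keep penalized iterates physical.
- Inverse dynamics: standard planar two-link equations in
  (absolute, relative) angles, mapped to (q_sh, q_el) by the branch
  Jacobian; gravity 9.80665 m/s² along −y.
- Integrator: SciPy's adaptive embedded Runge–Kutta 4(5), rtol 1e-6,
  atol 1e-8, max step 1/50 cycle so spline excitation detail is never
  skipped.  Settling protocol: activations start at 0.050, 3 settling
  cycles then 1 evaluation cycle; with 40 ms as the slowest time
  constant the cycle-to-cycle activation difference is far below the
  1e-4 stationarity assertion.

## Optimization

- Controls: per-muscle excitation nodes at equal time fractions,
  interpolated by a *periodic* cubic spline and clipped to [0, 1]
  (splines may overshoot).  Periodicity of the spline makes the
  endpoint-equality constraint structural, and the terminal condition
  θ(t_f) = 360° holds by construction at constant ω.
- Objective: −P̄ plus quadratic penalties — 100·∫(joint-range
  excursion)² dθ, 10⁴ per unit of reach/star-shape violation, 10³·∫(C_L
  excursion)² dθ.  Weights are design choices (none are published);
  they are large enough that no penalized iterate ever beats a feasible
  one in practice.  Simulation failures return a large finite objective
  (1e6) with a failure flag.
- Backend: (1+λ) evolution strategy, λ = 6, per-coordinate steps scaled
  by the box width, candidates reflected into the box, 1/5th-success
  step adaptation (×1.3 on success, ×0.85 on failure).  The incumbent
  only improves, so the accepted-objective history is monotone
  non-increasing; a fixed seed makes runs bit-reproducible.  A
  gradient-based interior-point backend would need objective gradients
  through the integrator, which this package deliberately avoids
  (gradient-free contract).
- Initialization: excitation nodes uniform in [0, 1]; the shape is drawn
  uniformly in its box and redrawn (≤50 tries) until star-shaped with
  C_L in bounds — whether the original study constrained its random
  initial shape is unstated, and an infeasible start merely wastes early
  iterations.
- β bounds default to ±90° (unstated in the source).

## Analysis

- Zones: crank-angle quadrants starting at θ = 0 (boundaries are only
  shown graphically in the source; quadrants are this package's
  convention, configurable).  Pull = zones 1, 4; push = zones 2, 3.
- Muscle work is defined on *musculotendon* length, W = ∫F·(−dL_MT/dt)dt,
  so that per-muscle works sum exactly to the crank energy balance under
  the rigid tendon.  Per-interval trapezoid contributions are assigned
  to zones by interval-midpoint crank angle, making zone works sum
  exactly to cycle totals.
- Activity threshold for fiber-mechanics masks: activation > 0.2,
  exposed as a parameter.

## Problem sizes and test scale

The default simulation uses 361 inverse-kinematics samples per
revolution, 120 output samples per cycle and 4 cycles total; one
objective evaluation costs ~0.2 s.  The packaged scaled-down
optimization study (4 muscles × 5 nodes, 100 iterations, 601
evaluations) was sized to demonstrate end-to-end behavior — positive
optimized power, near-circular recovered shape — at a scale a laptop
runs in ~2 minutes; the full 154-variable problem uses the same code
paths with a larger budget.

## What the synthetic defaults do and do not show

Passing tests demonstrate internal consistency: energy conservation,
passivity without excitation, activation invariants, kinematic
round-trips, optimizer monotonicity/reproducibility, and recovery of the
published *shape geometry*.  They do not validate the synthetic muscle
table or anthropometry against experimental propulsion data, do not
capture 3-D shoulder mechanics (elevation plane, rotation,
scapulothoracic motion), trunk action, wrist dynamics, or
wheelchair/drivetrain inertia and rolling/air resistance.  Absolute
power levels from the planar model with synthetic parameters are
illustrative, not predictive.
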