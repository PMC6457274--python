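# handleprop

Forward-dynamic optimization of **handle-based isokinetic wheelchair
propulsion**: a muscle-driven planar upper-extremity model is
closed-chained to a crank–slider handle mechanism turning at constant
cadence, and the closed handle-path shape plus per-muscle excitation
trajectories are jointly optimized to maximize net crank power.

Push-rim propulsion is biomechanically inefficient and loads the
shoulder and wrist at extreme joint angles.  A handle on a variable-length
crank (a slider changes the effective crank length C_L during rotation)
allows a *continuous, cyclic* propulsion movement whose path shape can be
tailored to the musculoskeletal architecture of the arm.  This package is
for biomechanics and rehabilitation-engineering researchers who want to
study that design space in a transparent, desk-scale model.

## Model

**Handle path.** A four-parameter closed curve in the crank frame
(origin at the crank center C):

    P_X(θ) = A cos θ
    P_Y(θ) = B sin θ sinⁿ(θ/2)
    P'     = R_z(β) · P          (β > 0 tilts the path clockwise)

with A, B ∈ [0.030, 0.155] m (the slider travel), n ∈ [0, 1].  The path
is converted to polar form C_L(φ) about C and the slider follows it as a
prescribed function of crank angle.

**Muscles.** 15 Hill-type musculotendon actuators (deltoids, biceps,
triceps, brachialis, wrist flexors, pectoralis major, rotator cuff) with
Thelen-formulation curves — first-order excitation→activation dynamics
(τ_act = 10 ms, τ_deact = 40 ms), Gaussian active force–length,
exponential passive force–length, hyperbolic force–velocity with
V_max = 10 L_opt/s — under a rigid-tendon reduction and constant planar
moment arms: L_MT(q) = L_MT0 − Σⱼ r_ij q_j.

**Dynamics.** With the crank at constant ω (default 50 rpm) and the hand
welded to the handle, the joint kinematics q(θ) are fully prescribed by
two-link inverse kinematics; only the muscle activations are integrated
forward (adaptive RK45, rtol 1e-6).  Crank torque follows from the
virtual-work balance

    τ_crank(θ) = Σⱼ (τ_muscle,j + τ_limit,j − τ_ID,j) · ∂q_j/∂θ,

and the optimization objective is the cycle-averaged net power
P̄ = ⟨τ_crank · ω⟩ minus penalties for joint-range, reach and
crank-length-bound violations.  The full control vector is 154 variables:
15 muscles × 10 periodic-spline excitation nodes + (A, B, n, β).  The
default search backend is a seeded (1+λ) evolution strategy.

## Worked example

```bash
$ python examples/01_handle_path.py
circularity ratio     : 0.9518   (1.0 would be a perfect circle)
effective crank length: 0.1095 .. 0.1510 m
slider travel         : 0.0300 .. 0.1550 m (mechanical limits)
C_L at crank angle 90d: 0.1121 m
```

The published optimized shape (A = 0.151 m, B = 0.152 m, n = 0.700,
β = 15.95°) is nearly circular — isoperimetric circularity
4π·Area/Perimeter² ≈ 0.95 — and every radius stays inside the slider
travel, so the path is mechanically realizable as-is.

```bash
$ python examples/03_optimize_reduced.py
initial net power  : -3.93 W (random controls)
optimized net power: +25.32 W after 601 evaluations
optimized shape    : A=0.152 m  B=0.148 m  n=0.053  beta=20.9 deg
shape circularity  : 0.999
```

A scaled-down search (4 muscles, 5 nodes each, 100 iterations) already
recovers the qualitative result: phased agonist/antagonist excitation
turns a power-absorbing random start into a cycle delivering >25 W, and
the optimal path is driven nearly circular with a clockwise tilt.

`examples/02_simulate_cycle.py` audits a simulated cycle for energy
balance (crank work = muscle + passive work on a periodic cycle) and
`examples/04_analyze_zones.py` partitions muscle work into the four
pull/push zones of the revolution.  A thin CLI mirrors the library:
`handleprop path|simulate|optimize|analyze --help`.

## Layout

- `src/handleprop/path.py` — parametric shape, circularity, C_L profile
- `src/handleprop/mechanism.py` — crank–slider kinematics, torque, power
- `src/handleprop/muscle.py` — Hill-type actuators and the 15-muscle roster
- `src/handleprop/arm.py` — planar closed-chain IK/ID and forward simulation
- `src/handleprop/optimize.py` — controls, objective, evolution strategy
- `src/handleprop/analysis.py` — zone work, ROM, fiber mechanics, reports
- `src/handleprop/cli.py` — thin command-line front end

See `docs/methods.md` for modeling assumptions, parameter choices and
known limitations.
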