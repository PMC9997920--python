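# Methods

`landsim` is a desk-scale reimplementation of a predictive-simulation
pipeline for single-leg drop landings and the ACL-injury risk factors they
expose.  This note documents the models, the numerical methods, the
parameters that matter, and the limits of what the test suite demonstrates.

## Musculoskeletal models

Two reduced rigid-body models describe the same 1.80 m, 75.16 kg subject.

**Planar model (9 coordinates, 16 muscle-tendon actuators).**  A sagittal
head-arms-trunk (HAT) segment carries two three-segment legs
(thigh, shank, foot).  Coordinates: pelvis translation (tx, ty), pelvis
tilt, and hip, knee, ankle flexion per leg.  Eight grouped actuators per
leg: iliopsoas, glutei, hamstrings, rectus femoris, vasti, gastrocnemius,
soleus, tibialis anterior.

**Reduced 3-D model (23 coordinates, 12 left-leg actuators).**  Pelvis
(6 DoF), torso on a 3-DoF lumbar joint, and per leg: 3-DoF hip, hinge
knee, ankle, subtalar and toe (MTP) joints.  The right limb is locked in a
flexed pose — hip 25°, knee 120°, ankle plantarflexed 20° — so the swing
leg stays clear of the ground, and carries no muscles.  The left (landing)
leg carries twelve grouped actuators spanning all hip, knee and ankle
torques; the lumbar joint, which has no muscles in this model family, is
driven by strong coordinate actuators (250 N·m), while every other
unlocked coordinate has a weak 2 N·m reserve.

Segment masses, lengths and inertias come from standard anthropometric
regression fractions (Winter/de Leva) scaled to the subject; segment
masses are rescaled so the total is exactly 75.16 kg.  In both models the
knee is a pure hinge: there is no tibiofemoral contact, no ligament
bundle, and therefore no direct ACL load — the package reports the
standard proxy quantities instead.

**Muscle model.**  Rigid-tendon Hill actuators: active force–length
(Gaussian, width 0.6), force–velocity (Hill hyperbola with a C¹
lengthening branch saturating at 1.4 F0), exponential passive curve, and
first-order excitation–activation dynamics (τ_act 10 ms, τ_deact 40 ms).
Because each actuator lumps a muscle group over its full joint excursion,
optimal fiber lengths are longer than any individual muscle's
(0.07–0.18 m), and tendon slack lengths are calibrated at build time so
each fiber sits at (or slightly below) its optimal length in the default
standing pose.  Muscle paths are straight-line polylines with at most one
via point.  The knee extensors additionally wrap an idealized 4.5 cm
patellar pulley: the wrap contributes `R·q_knee` to the musculotendon
length and a pure extension torque `F·R`, which keeps the extensor moment
arm from collapsing at deep flexion — the known failure mode of
straight-line extensor paths.

**Joint stops.**  Each coordinate range acts as a compliant stop: a C¹
torque (2000 N·m/rad) with light damping engages just outside the range,
the role ligaments play at the end of range of motion.  Inside the range
the stop force is exactly zero.

**Foot–ground contact.**  Five spheres per foot (one toe, four hindfoot),
radius 3.2 cm.  The normal force is a smoothed Hunt–Crossley law
`k·x^{3/2}(1 + 1.5 c ẋ)` with stiffness k = 1×10⁵ N/m^{3/2} and
dissipation c = 1 s/m; the penetration enters through a C¹ positive part
(2 mm smoothing) that is exactly zero when the sphere is clear of the
ground.  Friction is tanh-regularized Coulomb (μ = 0.8, transition
velocity 0.2 m/s) plus a small viscous term (0.1).  The stiffness is
deliberately at the soft end of published landing models: the impact
transient then lasts ~25 ms, which a 5–10 ms collocation mesh resolves,
and static penetration stays near 1 cm.  All parameters are config-exposed.

## Dynamics engine

Forward dynamics uses ground-frame spatial algebra over a tree of
elementary one-DoF joints (composite-rigid-body mass matrix, recursive
Newton–Euler bias with muscle path-point and contact forces applied as
external spatial forces).  Everything is batched: a collocation mesh, a
finite-difference Jacobian, or a CMA-ES population is evaluated in one
set of numpy calls.  Joint reaction loads are the wrenches transmitted
through a joint onto its child segment from the same Newton–Euler balance,
with muscle forces treated as applied loads (the free-body convention of
standard joint-reaction analyses).  Knee loads are expressed in the tibia
frame: x anterior (AF +), y proximal (compression ⇒ CF < 0), z medial for
the left leg (MF +); AbdM is the x moment (+ abduction) and IRM the y
moment (internal rotation negative).

## Objectives

* Stability: `p_s = w_s (t_max − t_sim)/t_max`, where `t_sim` is the first
  time the COM-height ratio falls below a threshold `th` (default 0.4 — a
  held single-leg deep squat sits near 0.5, so the fall threshold must lie
  below it), or the full horizon.
* Joint-range: `p_j = Σ w_j·dist(jR_m, jR_t)`, absolute difference for
  scalar targets and distance-to-interval for range targets; trajectories
  are scored at their worst sample.
* GRF band: weighted time-integral of vertical-GRF excursions outside a
  `[lower, upper]` body-weight band.
* Effort: `(1/d)∫ Σ w_c |x_c|^p dt` over all controls, exponent p = 2,
  normalized by the pelvis displacement (floored at 1 cm) or by 1.
* Tracking: time-integral of weighted squared state errors against a
  reference motion.

All integrals use trapezoidal quadrature on the trajectory's own grid.
The cost a solver reports is always these functions re-evaluated on the
returned trajectory.

## Trajectory optimization

**Collocation.**  One-step θ-method transcription on a fixed time grid:
defects `x_{k+1} − x_k − h[(1−θ)f_k + θf_{k+1}]`.  θ = 0.5 (trapezoidal)
is the default and is used for the smooth verification problems; the
landing stages use θ = 1 (backward Euler), the L-stable member of the
family, because the trapezoidal equations have no solution through the
stiff contact transient at tractable step sizes while backward Euler
damps the contact chatter that otherwise makes the NLP hostile.
Convergence is declared on the unscaled defect (state units) at 1e-4.

The NLP is solved either by scipy's `trust-constr` (small smooth
problems) or, by default, by an augmented-Lagrangian loop whose inner
subproblems are bound-constrained sparse least-squares solved with a
projected Levenberg–Marquardt iteration (exact sparse-LU factorization of
the block-banded normal equations, stale-Jacobian reuse).  Jacobians are
node-local finite differences, one batched dynamics call per Jacobian.
Before the first inner solve the guess's states are replaced by an
implicit (θ-consistent) rollout of its controls, so the iterate starts
essentially feasible; a fine semi-implicit rollout is the fallback.
Default path bounds leave a 0.1 rad margin beyond each coordinate range,
because the ranges are compliant stops, not rigid walls.

**Shooting.**  Piecewise-linear excitation knots optimized by an
in-package CMA-ES (rank-1 + rank-μ covariance update, cumulative step-size
adaptation, population 16, seeded).  Rollouts integrate a whole population
per batched call with symplectic Euler at 0.5 ms (activation updated by
its exact exponential); rollouts that leave a sanity envelope are scored
with a maximal penalty.  Muscles that span only locked coordinates are
excluded from the search space.

## The three-stage pipeline

1. **Predict (planar, shooting).**  From pelvis height 1.25 m (a 30 cm
   landing height above the 0.954 m standing hip height), left hip 5°,
   knee 12°, ankle 34°, right limb locked, CMA-ES minimizes the composite
   stability + joint-range + GRF cost.  The search is seeded with a
   two-phase "squat catch" excitation policy (light pre-landing tone, then
   a strong extensor burst after the expected touchdown); the GRF band
   (≤2.5 BW, weight 20) and knee-range penalty (weight 25) are set high
   enough that locking the knee against its extension stop — the
   degenerate stiff-landing optimum — is never competitive.
2. **Track (3-D, collocation).**  The sagittal reference is mapped onto
   the 3-D model's coordinates; non-sagittal coordinates are tracked to
   their defaults.  Subtalar, MTP and the (muscle-less) lumbar coordinates
   are locked during the collocation stages; the window opens a few
   centimeters above touchdown (the free fall carries no information) and
   runs 0.35 s on a uniform 10 ms mesh.  The guess is a reflex-like
   muscle-space PD rollout that tracks the reference, so the solver starts
   near a dynamically consistent, near-optimal iterate.
3. **Predict what-if (3-D, collocation).**  Effort goal (p = 2) plus a
   firm GRF band (≤2.5 BW, weight 2), the tracked motion as the guess.
   Scenario families: landing height 0.30–0.55 m (entering through the
   ballistic touchdown velocity, with the opening clearance chosen so
   touchdown falls on a mesh node — this keeps the sampled impact
   transient comparable across scenarios); hip rotation and trunk
   orientation (prescribed by locking the coordinate at the scenario
   angle for the whole phase); quadriceps/hamstrings strength (F0 × 1.35
   or × 0.65); and the effort-goal weight.  The scenario seed replays the
   baseline's open-loop controls from the scenario's initial state, so
   every scenario starts from the same landing strategy.  The mesh is
   5 ms through the impact window and 10 ms after.

Risk factors are sampled at the mesh node of peak left-foot vertical GRF:
vGRF, AF, MF, CF in body weights; AbdM, IRM divided by body weight in
newtons (units of meters — the output metadata flags this normalization
choice); summed quadriceps and hamstrings forces in newtons and their
ratio.

## Synthetic data

`generate_reference_landing` builds the object the tracking stage
consumes: ballistic pelvis descent (closed form under g = 9.81 m/s²) to
the exact sphere-touchdown height, then minimum-jerk joint-flexion
profiles over a configurable absorption window; speeds are the exact
analytic derivatives of the positions.  It emulates the smooth
single-support kinematics of a predicted landing; it does not emulate
motion-capture artifacts, and passing tests on it say nothing about
marker noise or soft-tissue artifact.  Toy fixtures (pendulum,
double integrator, block-on-sphere) carry closed-form references used as
independent oracles by the test suite.

## Problem sizes and verification scale

The package runs everything on one CPU at desk scale: stage-1 uses 12–20
CMA-ES generations; tracking and prediction meshes have 30–50 nodes; the
verification suite uses the same sizes.  The double-integrator check runs
at mesh 200–400 where the trapezoidal discretization error is below
1e-4 relative.  These sizes are the package's own defaults and are all
config-exposed.

## Known limitations

* The hinge knee carries no ligament or articular contact model; AF, CF
  and the knee moments are proxies, not ACL forces.
* Grouped actuators with pulley knees reproduce torque capacity, not
  individual muscle force sharing; quadriceps/hamstrings forces are
  group totals by construction.
* The contact parameters are at the soft end of the published range, so
  absolute peak-vGRF magnitudes sit above experimentally reported
  single-leg values at the same drop heights; cross-scenario comparisons,
  not absolute magnitudes, are the supported use.
* Stage-3 solutions stay in the basin of their seed, and with the
  default final-support band the effort-minimal landing of this reduced
  model is nearly passive — the compliant joint stops can absorb a 0.30 m
  landing — so the effort-weight sweep moves integrated activation only
  weakly (it is non-increasing, but close to flat).  Demanding a higher
  final support height makes the sweep pronounced at the cost of much
  slower convergence for the deeper drops.
* The shooting stage is open-loop (direct control parameterization); it
  cannot reproduce reflex-feedback balance, and its solution quality
  depends on the seeded policy.
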