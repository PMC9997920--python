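"""Synthetic test inputs: toy mechanical fixtures with closed-form answers
and kinematically consistent drop-landing reference motions.

The landing generator emulates the object the tracking stage consumes: a
ballistic pelvis descent under gravity until the foot spheres touch the
ground, followed by minimum-jerk (quintic) joint-flexion profiles that
absorb the impact over a configurable duration.  Speeds are the exact
analytic derivatives of the positions, so finite differences of the
generated coordinates reproduce the stored speeds.  The generator emulates
the smooth, single-support kinematics of a predicted landing; it does not
emulate measurement noise sources of real motion capture (soft-tissue
artifact, marker occlusion) beyond optional white angle noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (CoordinateSpec, ModelSpec, SegmentSpec,
                    ReserveActuatorSpec, ContactSphereSpec)
from .trajectory import Trajectory

G = 9.81


@dataclass
class SyntheticLandingParams:
    drop_height: float = 0.30          # [m] pelvis height above standing
    touchdown_pose: dict = field(default_factory=dict)   # coordinate -> rad
    flexion_depth: dict = field(default_factory=dict)    # coordinate -> rad
    absorb_duration: float = 0.25      # [s]
    noise_sd: float = 0.0              # [rad]
    seed: int = 0

    def __post_init__(self):
        if self.drop_height <= 0 or self.absorb_duration <= 0:
            raise ValueError("drop_height and absorb_duration must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


#: default joint flexion added during absorption (left leg lands)
DEFAULT_FLEXION_DEPTH = {
    "hip_flexion_l": np.deg2rad(30.0),
    "knee_flexion_l": np.deg2rad(45.0),
    "ankle_flexion_l": np.deg2rad(15.0),
}


def _min_jerk(s):
    """Quintic minimum-jerk profile: 0 -> 1 with zero end velocity/accel."""
    s = np.clip(s, 0.0, 1.0)
    return 10 * s ** 3 - 15 * s ** 4 + 6 * s ** 5


def _min_jerk_rate(s, T):
    s = np.clip(s, 0.0, 1.0)
    return (30 * s ** 2 - 60 * s ** 3 + 30 * s ** 4) / T


def touchdown_clearance(model: ModelSpec, pose: np.ndarray) -> float:
    """Lowest contact-sphere point height above ground at the given pose."""
    from .tree import CompiledTree

    tree = CompiledTree(model)
    q = tree.full_q(pose[None, :])
    R, p, Sa, Sl = tree.kinematics(q)
    va, vl = tree.velocities(np.zeros_like(q), Sa, Sl)
    C, _ = tree.sphere_states(R, p, va, vl)
    lows = [C[k][0, 1] - s.radius
            for k, s in enumerate(model.contact_spheres)
            if s.name.startswith("l")]
    return float(min(lows))


def generate_reference_landing(model: ModelSpec,
                               p: SyntheticLandingParams,
                               dt: float = 0.005) -> Trajectory:
    """Ballistic descent + minimum-jerk absorption reference trajectory."""
    pose = model.default_pose()
    cnames = model.coordinate_names
    for nm, val in p.touchdown_pose.items():
        i = cnames.index(nm)
        lo, hi = model.coordinates[i].range
        if not lo - 1e-9 <= val <= hi + 1e-9:
            raise ValueError(f"touchdown pose for {nm} outside coordinate range")
        if not model.coordinates[i].locked:
            pose[i] = val

    ity = cnames.index("pelvis_ty")
    # place the pelvis so the lowest left-foot sphere just touches at the
    # touchdown pose, then raise it by the drop height
    clearance = touchdown_clearance(model, pose)
    td_height = pose[ity] - clearance
    start_height = td_height + p.drop_height

    t_fall = np.sqrt(2.0 * p.drop_height / G)
    t_end = t_fall + p.absorb_duration
    times = np.arange(0.0, t_end + dt / 2, dt)
    if times[-1] < t_end - 1e-12:
        times = np.append(times, t_end)
    N = len(times)

    q = np.tile(pose, (N, 1))
    u = np.zeros_like(q)

    fall = times <= t_fall
    q[fall, ity] = start_height - 0.5 * G * times[fall] ** 2
    u[fall, ity] = -G * times[fall]
    ta = times[~fall] - t_fall
    T = p.absorb_duration
    # pelvis keeps decelerating to rest via the same quintic blend
    v_td = -G * t_fall
    s = ta / T
    # velocity eases out to zero with a quintic blend; position is its
    # exact integral, so the reference is kinematically consistent
    q[~fall, ity] = td_height + v_td * T * _min_jerk_integral(s)
    u[~fall, ity] = v_td * (1.0 - _min_jerk(s))

    flex = dict(DEFAULT_FLEXION_DEPTH)
    flex.update(p.flexion_depth)
    for nm, depth in flex.items():
        if nm not in cnames:
            continue
        i = cnames.index(nm)
        if model.coordinates[i].locked:
            continue
        q[~fall, i] = pose[i] + depth * _min_jerk(s)
        u[~fall, i] = depth * _min_jerk_rate(s, T)
        lo, hi = model.coordinates[i].range
        if q[:, i].max() > hi + 1e-9 or q[:, i].min() < lo - 1e-9:
            raise ValueError(f"flexion profile for {nm} leaves coordinate range")

    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        ang = [i for i, c in enumerate(model.coordinates)
               if c.kind == "rotational" and not c.locked]
        q[:, ang] += rng.normal(0.0, p.noise_sd, (N, len(ang)))

    nm_, nr_ = len(model.muscles), len(model.reserves)
    return Trajectory(times, list(cnames), model.muscle_names,
                      [r.coordinate for r in model.reserves],
                      q, u, np.zeros((N, nm_)), np.zeros((N, nm_)),
                      np.zeros((N, nr_)))


def _min_jerk_integral(s):
    """Integral of (1 - min_jerk) from 0 to s (dimensionless)."""
    s = np.clip(s, 0.0, 1.0)
    return s - (2.5 * s ** 4 - 3.0 * s ** 5 + s ** 6)


# ---------------------------------------------------------------------------
# toy fixtures


def pendulum_model(length: float = 1.0, mass: float = 2.0) -> ModelSpec:
    """Uniform rod pinned at one end, swinging in the x-y plane.

    Released horizontal, the angular acceleration is ``3 g / (2 L)``.
    """
    inertia = np.diag([1e-8, mass * length ** 2 / 12.0,
                       mass * length ** 2 / 12.0])
    seg = SegmentSpec("pelvis", mass, np.array([length / 2, 0.0, 0.0]),
                      inertia, length, np.zeros(3), None, "pin")
    coord = CoordinateSpec("swing", "pin", np.array([0.0, 0.0, 1.0]),
                           (-4 * np.pi, 4 * np.pi))
    return ModelSpec("pendulum", (seg,), (coord,), ())


def double_integrator_problem(target: float = 1.0, duration: float = 1.0,
                              mesh: int = 50):
    """Minimum-squared-control point-to-point transfer of a unit point mass.

    Returns ``(OCProblem, analytic_cost)``.  The force is a reserve
    actuator of optimal force ``F`` driven by the control ``r`` in [-1, 1],
    so the continuous-time optimum of the effort integral of ``r**2`` is
    ``12 X^2 / (T^3 F^2)``.
    """
    from .objectives import EffortGoalConfig
    from .ocp import EffortTerm, OCProblem

    F = 10.0
    seg = SegmentSpec("pelvis", 1.0, np.zeros(3), np.diag([1e-8] * 3),
                      1.0, np.zeros(3), None, "slider")
    coord = CoordinateSpec("x", "slider", np.array([1.0, 0.0, 0.0]),
                           (-5.0, 5.0), kind="translational")
    model = ModelSpec("double_integrator", (seg,), (coord,), (),
                      reserves=(ReserveActuatorSpec("x", F),),
                      gravity=np.zeros(3))
    problem = OCProblem(
        model, (0.0, duration), mesh=mesh,
        state_bounds={
            "x": {"initial": (0.0, 0.0), "final": (target, target)},
            "x_u": {"initial": (0.0, 0.0), "final": (0.0, 0.0)},
        },
        objective_terms=[EffortTerm(EffortGoalConfig(d_mode="unit"))],
        name="double_integrator")
    analytic = 12.0 * target ** 2 / duration ** 3 / F ** 2
    return problem, analytic


def block_on_sphere(mass: float = 10.0) -> ModelSpec:
    """A block on one vertical-sliding contact sphere; static normal force m g."""
    seg = SegmentSpec("pelvis", mass, np.zeros(3), np.diag([0.1] * 3),
                      0.3, np.zeros(3), None, "slider")
    coord = CoordinateSpec("height", "slider", np.array([0.0, 1.0, 0.0]),
                           (-1.0, 2.0), default=0.05, kind="translational")
    sphere = ContactSphereSpec("l_block", "pelvis", np.array([0.0, -0.02, 0.0]))
    return ModelSpec("block", (seg,), (coord,), (), contact_spheres=(sphere,))


def toy_fixtures() -> dict:
    """Named fixtures, each carrying its analytic reference value."""
    prob, analytic = double_integrator_problem()
    return {
        "pendulum": {
            "model": pendulum_model(),
            "reference_alpha": -3.0 * G / 2.0,   # released horizontal [rad/s^2]
        },
        "double_integrator": {
            "problem": prob,
            "reference_cost": analytic,
        },
        "block_on_sphere": {
            "model": block_on_sphere(),
            "reference_normal_force": 10.0 * G,  # [N]
        },
    }
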