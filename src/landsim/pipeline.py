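"""The chained predict → track → predict workflow and the scenario engine.

Stage 1 predicts a single-leg landing with the planar model by shooting:
piecewise-linear muscle excitations are optimized by CMA-ES against the
composite cost (stability + joint-range + GRF penalties).  The motion
starts with the pelvis at 1.25 m (a 30 cm landing height), left hip flexed
5°, left knee 12°, left ankle 34°, and the right limb locked out of the
way (hip 25°, knee 120°, ankle plantarflexed).

Stage 2 tracks the predicted sagittal motion on the 3-D model by direct
collocation, producing a dynamically consistent 3-D landing that seeds
stage 3.

Stage 3 re-predicts the landing under a what-if scenario — landing height,
pinned hip rotation, pinned trunk orientation, scaled muscle strengths, or
a different effort-goal weight — by collocation with a squared-control
effort goal plus a GRF-band penalty, using the tracked motion as the
initial guess.  Scenario rows are summarized by the risk-factor extractor.

Desk-scale reformulation: the collocation stages open a few centimeters
above touchdown with the ballistic vertical velocity of the configured
drop height, rather than spending mesh nodes on the free fall; the drop
height therefore sets the touchdown energy exactly while the mesh
resolves the impact, which is where the risk factors live.  Subtalar and
toe joints are held neutral during the collocation stages, as is common
in landing simulations; the coordinates remain defined in the model.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np

from .dynamics import Engine
from .model import (ModelSpec, STANDING_PELVIS_HEIGHT, build_planar_model,
                    build_reduced3d_model, lock_right_limb,
                    scale_muscle_group)
from .objectives import (EffortGoalConfig, GRFPenaltyConfig,
                         JointRangePenaltyConfig, StabilityMeasureConfig)
from .ocp import (CollocationSettings, EffortTerm, GRFPenaltyTerm,
                  JointRangeTerm, OCProblem, ShootingSettings, Solution,
                  StabilityTerm, TrackingTerm, resample, solve_collocation,
                  solve_shooting)
from .risk_factors import report_at_peak, report_table
from .trajectory import Trajectory

G = 9.81

#: stage-1 initial pose (left leg prepares to land; right limb locked)
STAGE1_INITIAL_POSE = {
    "pelvis_ty": 1.25,
    "hip_flexion_l": np.deg2rad(5.0),
    "knee_flexion_l": np.deg2rad(12.0),
    "ankle_flexion_l": np.deg2rad(34.0),
}

#: coordinates held neutral by the collocation stages; locking them merges
#: the foot into one rigid assembly whose contact dynamics are as well
#: conditioned as the planar model's
TRACKING_PINNED = {"subtalar_l": 0.0, "mtp_l": 0.0}


def _pipeline_model(base: ModelSpec | None = None,
                    extra_locks: dict | None = None) -> ModelSpec:
    """Collocation-stage variant of the 3-D model.

    Subtalar/toe joints, the (muscle-less) lumbar joint and any
    scenario-prescribed coordinates are locked exactly; reserves on locked
    coordinates are dropped.  All 23 coordinates remain defined.
    """
    from dataclasses import replace as _rep

    from .model import lock_coordinates

    model = base if base is not None else build_reduced3d_model()
    pins = dict(TRACKING_PINNED)
    pins.update(dict.fromkeys(_LUMBAR, 0.0))
    pins.update(extra_locks or {})
    pins = {nm: v for nm, v in pins.items()
            if nm in model.coordinate_names}
    model = lock_coordinates(model, pins)
    live = {c.name for c in model.unlocked_coordinates}
    reserves = tuple(r for r in model.reserves if r.coordinate in live)
    return _rep(model, reserves=reserves)

#: sagittal coordinates shared between the planar and 3-D models
SAGITTAL_COORDS = ["pelvis_tx", "pelvis_ty", "pelvis_tilt",
                   "hip_flexion_l", "knee_flexion_l", "ankle_flexion_l"]

_LUMBAR = ("lumbar_extension", "lumbar_bending", "lumbar_rotation")

#: the study's scenario families and their catalogued parameter values
SCENARIO_FAMILIES = {
    "landing_height": [0.30, 0.35, 0.40, 0.45, 0.50, 0.55],          # [m]
    "hip_rotation": [-30, -25, -20, -15, -10, -5, 0,
                     5, 10, 15, 20, 25, 30],                          # [deg, internal +]
    "trunk_flexion_extension": [-20, -15, -10, -5, 0,
                                5, 10, 15, 20, 25, 30],               # [deg, flexion +]
    "trunk_bending": [-30, -25, -20, -15, -10, -5, 0,
                      5, 10, 15, 20, 25, 30],                         # [deg, right +]
    "muscle_strength": [0.65, 1.0, 1.35],                             # F0 factors
    "effort_weight": [0, 0.1, 0.2, 0.5, 1, 2, 5, 10],
}

#: muscle-strength permutation labels (strong/normal/weak quadriceps x hamstrings)
STRENGTH_CASES = {
    f"{q}q_{h}h": ({"s": 1.35, "n": 1.0, "w": 0.65}[q],
                   {"s": 1.35, "n": 1.0, "w": 0.65}[h])
    for q in "snw" for h in "snw"
}


@dataclass
class ScenarioConfig:
    """One what-if case of the scenario matrix."""

    family: str
    parameter: float = 0.0
    bound_overrides: dict = field(default_factory=dict)
    muscle_scalings: dict = field(default_factory=dict)
    effort_weight: float = 1.0
    seed: int = 0
    label: str = ""
    extrapolation: bool = False

    def __post_init__(self):
        if self.family not in SCENARIO_FAMILIES:
            raise ValueError(f"unknown scenario family {self.family!r}")
        catalog = SCENARIO_FAMILIES[self.family]
        if self.family == "muscle_strength":
            bad = {g: f for g, f in self.muscle_scalings.items()
                   if f not in catalog}
            if bad and not self.extrapolation:
                raise ValueError(f"muscle scalings outside the catalog: {bad}")
        elif not self.extrapolation and \
                not any(np.isclose(self.parameter, v) for v in catalog):
            raise ValueError(
                f"{self.family} parameter {self.parameter} is not in the "
                f"catalogued set {catalog}; pass extrapolation=True to force")
        if not self.label:
            self.label = f"{self.family}={self.parameter:g}"

    def config_hash(self) -> str:
        blob = json.dumps(
            [self.family, self.parameter, sorted(self.bound_overrides.items()),
             sorted(self.muscle_scalings.items()), self.effort_weight,
             self.seed], sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StageResult:
    stage: str                 # predict1 | track2 | predict3
    solution: Solution
    provenance: dict


def _provenance(stage: str, seed, extra=None) -> dict:
    prov = {"stage": stage, "seed": seed,
            "timestamp": _time.strftime("%Y-%m-%dT%H:%M:%S")}
    if extra:
        prov.update(extra)
    return prov


# ---------------------------------------------------------------------------
# stage 1: shooting prediction on the planar model


@dataclass
class Stage1Config:
    # th = 0.4: a held single-leg deep squat sits near a COM ratio of 0.5,
    # so the fall threshold must lie below it
    stability: StabilityMeasureConfig = field(
        default_factory=lambda: StabilityMeasureConfig(th=0.4, w_s=100.0,
                                                       t_max=1.0))
    # a soft landing: keep vGRF under ~2.5 BW and the landing knee flexed;
    # the weights must dominate the stability term's preference for locking
    # the knee against its extension stop (a degenerate stiff landing)
    grf: GRFPenaltyConfig = field(
        default_factory=lambda: GRFPenaltyConfig(upper=2.5, weight=20.0))
    joint_weight: float = 25.0
    shooting: ShootingSettings = field(default_factory=ShootingSettings)


def stage1_predict(planar: ModelSpec | None = None,
                   initial: dict | None = None,
                   cfg: Stage1Config | None = None,
                   seed: int = 0) -> StageResult:
    """Predict the initial single-leg landing by shooting (stage 1)."""
    cfg = cfg or Stage1Config()
    model = planar if planar is not None else lock_right_limb(build_planar_model())
    pose = dict(STAGE1_INITIAL_POSE)
    pose.update(initial or {})

    bounds = {}
    for name, val in pose.items():
        if name in model.coordinate_names and not model.coordinate(name).locked:
            bounds[name] = {"initial": (val, val)}
    for c in model.unlocked_coordinates:
        bounds.setdefault(f"{c.name}_u", {})["initial"] = (0.0, 0.0)

    # keep the landing-leg joints inside physiological landing ranges: a
    # flexed knee and near-level pelvis exclude stiff-legged bouncing
    jr = JointRangePenaltyConfig(
        weights={"knee_flexion_l": cfg.joint_weight,
                 "hip_flexion_l": cfg.joint_weight / 2,
                 "pelvis_tilt": cfg.joint_weight / 2},
        targets={"knee_flexion_l": (np.deg2rad(2.0), np.deg2rad(110.0)),
                 "hip_flexion_l": (np.deg2rad(0.0), np.deg2rad(90.0)),
                 "pelvis_tilt": (np.deg2rad(-20.0), np.deg2rad(20.0))})

    # two-phase excitation seed: light pre-landing tone, then a strong
    # extensor burst after the expected touchdown that catches the body in
    # a one-leg squat; CMA-ES refines from here
    pre = {"iliopsoas": 0.02, "glutei": 0.10, "hamstrings": 0.30,
           "rect_fem": 0.05, "vasti": 0.10, "gastroc": 0.10,
           "soleus": 0.10, "tib_ant": 0.05}
    post = {"iliopsoas": 0.02, "glutei": 0.40, "hamstrings": 0.15,
            "rect_fem": 0.10, "vasti": 0.70, "gastroc": 0.20,
            "soleus": 0.30, "tib_ant": 0.05}

    def _policy(table):
        return np.array([next((v for k, v in table.items()
                               if m.name.startswith(k)), 0.02)
                         for m in model.muscles])

    q0 = model.default_pose()
    for name, val in pose.items():
        if name in model.coordinate_names:
            q0[model.coordinate_names.index(name)] = val
    drop = max(q0[model.coordinate_names.index("pelvis_ty")]
               - STANDING_PELVIS_HEIGHT, 0.05)
    t_td = np.sqrt(2.0 * drop / 9.81)
    nres = len(model.reserves)
    tsamp = np.array([0.0, t_td, t_td + 0.05, cfg.stability.t_max])
    e_rows = np.stack([_policy(pre), _policy(pre), _policy(post),
                       _policy(post)])
    policy_guess = Trajectory(
        tsamp, model.coordinate_names, model.muscle_names,
        [r.coordinate for r in model.reserves],
        np.tile(q0, (4, 1)), np.zeros((4, len(q0))),
        np.zeros((4, len(model.muscles))), e_rows, np.zeros((4, nres)))

    t_max = cfg.stability.t_max
    problem = OCProblem(
        model, (0.0, t_max), mesh=max(int(t_max / 0.05), 2),
        state_bounds=bounds,
        objective_terms=[StabilityTerm(cfg.stability), JointRangeTerm(jr),
                         GRFPenaltyTerm(cfg.grf)],
        initial_guess=policy_guess, name="stage1_predict")
    settings = _dc_replace(cfg.shooting, seed=seed)
    sol = solve_shooting(problem, settings)
    return StageResult("predict1", sol, _provenance(
        "predict1", seed, {"model": model.name,
                           "config_hash": _hash_obj([pose, t_max])}))


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _feedback_guess(engine: Engine, ref: Trajectory, grid: np.ndarray,
                    kp: float = 400.0, kd: float = 40.0,
                    tone: float = 0.02, dt: float = 5.0e-4,
                    q_init: np.ndarray | None = None,
                    u_init: np.ndarray | None = None) -> Trajectory:
    """Dynamically consistent tracking seed via a muscle-space PD rollout.

    A joint-space PD torque toward the reference is distributed over the
    muscles through their moment arms (a crude stretch-reflex), with
    reserves taking the remainder; the recorded open-loop controls and
    states form the collocation guess.
    """
    from .tree import muscle_tendon_lengths_at

    model = engine.model
    free = engine.free
    nf, nmus, nres = engine.nf, engine.nm, engine.nr

    # moment arms at the default pose: arm[m, j] = -d lmt_m / d q_j
    q0 = model.default_pose()
    eps = 1e-5
    lmt0 = muscle_tendon_lengths_at(model, q0)
    arms = np.zeros((nmus, nf))
    for j, cj in enumerate(free):
        qp = q0.copy()
        qp[cj] += eps
        arms[:, j] = -(muscle_tendon_lengths_at(model, qp) - lmt0) / eps
    gain = arms * engine.F0[:, None]                    # torque per unit e
    norm = np.maximum((gain ** 2).sum(axis=0), 1e-6)    # per coordinate

    cn = model.coordinate_names
    qref = np.array([np.interp(grid, ref.time, ref.column(c))
                     for c in [cn[i] for i in free]]).T
    uref = np.array([np.interp(grid, ref.time, ref.column(f"{c}_u"))
                     for c in [cn[i] for i in free]]).T
    tgrid = grid

    def control_fn_factory():
        state = {}

        def fn(t, q=None, u=None):
            qr = np.array([np.interp(t, tgrid, qref[:, j]) for j in range(nf)])
            ur = np.array([np.interp(t, tgrid, uref[:, j]) for j in range(nf)])
            if q is None:
                return state["e"], state["r"]
            tau = kp * (qr - q[0, free]) + kd * (ur - u[0, free])
            e = np.clip(tone + gain @ (tau / norm), 0.0, 1.0)
            r = np.clip(tau[engine_res_local] / engine.res_F, -1.0, 1.0) \
                if nres else np.zeros(0)
            state["e"], state["r"] = e[None, :], r[None, :]
            return state["e"], state["r"]
        return fn

    # local index of each reserve coordinate among the free coordinates
    free_list = list(free)
    engine_res_local = np.array(
        [free_list.index(ci) for ci in engine.res_coord], int) \
        if nres else np.zeros(0, int)

    # closed-loop semi-implicit rollout (feedback evaluated per step)
    from .muscles import TAU_ACT, TAU_DEACT

    q = engine.tree.full_q(np.atleast_2d(
        ref.q[0] if q_init is None else q_init))
    u = np.zeros_like(q)
    u[0, free] = uref[0] if u_init is None else u_init[free]
    a = np.full((1, nmus), tone)
    fn = control_fn_factory()
    nsteps = int(round((grid[-1] - grid[0]) / dt))
    rec_t, rec = [grid[0]], [(q.copy(), u.copy(), a.copy(),
                              np.full((1, nmus), tone), np.zeros((1, nres)))]
    t = grid[0]
    for s in range(nsteps):
        e, r = fn(t, q, u)
        qdd = engine.accelerations(q, u, a, r)
        u = u + dt * qdd
        q = q + dt * u
        tau_a = np.where(e > a, TAU_ACT, TAU_DEACT)
        a = np.clip(e + (a - e) * np.exp(-dt / tau_a), 0.0, 1.0)
        t += dt
        rec_t.append(t)
        rec.append((q.copy(), u.copy(), a.copy(), e.copy(), r.copy()))
        if not np.all(np.isfinite(q)):
            break
    times = np.array(rec_t[:len(rec)])
    dense = Trajectory(times, cn, model.muscle_names,
                       [rr.coordinate for rr in model.reserves],
                       np.concatenate([f[0] for f in rec]),
                       np.concatenate([f[1] for f in rec]),
                       np.concatenate([f[2] for f in rec]),
                       np.concatenate([f[3] for f in rec]),
                       np.concatenate([f[4] for f in rec]))
    return resample(dense, np.clip(grid, times[0], times[-1]))


# ---------------------------------------------------------------------------
# stage 2: collocation tracking on the 3-D model


def stage_mesh(horizon: float, fine_window: float = 0.35,
               fine_h: float = 0.01, coarse_h: float = 0.02) -> np.ndarray:
    """Impact-refined node grid: fine spacing through touchdown, coarse after."""
    fw = min(fine_window, horizon)
    fine = np.arange(0.0, fw, fine_h)
    coarse = np.arange(fw, horizon, coarse_h)
    return np.unique(np.round(np.concatenate([fine, coarse, [horizon]]), 9))


@dataclass
class Stage2Settings:
    horizon: float = 0.35          # [s] from just above touchdown
    clearance: float = 0.05        # [m] initial pelvis height above touchdown
    fine_window: float = 0.35
    fine_h: float = 0.01
    coarse_h: float = 0.02
    speed_weight: float = 0.01
    nonsagittal_weight: float = 0.1
    regularization: float = 1.0e-4
    collocation: CollocationSettings = field(
        default_factory=lambda: CollocationSettings(theta=1.0))


def _pin(value, tol=0.0):
    return {"initial": (value - tol, value + tol),
            "path": (value - tol, value + tol)}


def _touchdown_start(model3d, engine, reference, clearance):
    """Crop/shift the reference so t=0 sits ``clearance`` above touchdown."""
    pose = model3d.default_pose()
    cn = model3d.coordinate_names
    heights = reference.column("pelvis_ty")
    N = len(reference.time)
    Q = np.tile(pose, (N, 1))
    for nm in SAGITTAL_COORDS:
        if nm in cn and reference.has_column(nm):
            Q[:, cn.index(nm)] = reference.column(nm)
    lows = engine.foot_clearance_batch(Q)
    below = np.flatnonzero(lows <= 0.0)
    td = int(below[0]) if len(below) else None
    if td is None or td == 0:
        return reference
    # first sample at least `clearance` above the touchdown height
    td_h = heights[td]
    k0 = td
    while k0 > 0 and heights[k0] < td_h + clearance:
        k0 -= 1
    cropped = reference.copy()
    sl = slice(k0, None)
    cropped.time = reference.time[sl] - reference.time[k0]
    for f in ("q", "u", "a", "e", "r"):
        setattr(cropped, f, getattr(reference, f)[sl])
    return cropped


def stage2_track(reference: Trajectory, model3d: ModelSpec | None = None,
                 settings: Stage2Settings | None = None) -> StageResult:
    """Track a (planar) landing reference with the 3-D model (stage 2)."""
    settings = settings or Stage2Settings()
    model = _pipeline_model(model3d)
    engine = Engine(model)
    cn = model.coordinate_names

    missing = [nm for nm in SAGITTAL_COORDS if not reference.has_column(nm)]
    if missing:
        raise KeyError(f"reference lacks tracked column(s): {missing}")

    ref = _touchdown_start(model, engine, reference, settings.clearance)
    t_f = min(settings.horizon, ref.time[-1])
    grid = stage_mesh(t_f, settings.fine_window, settings.fine_h,
                      settings.coarse_h)

    full_reference = (list(ref.coord_names) == list(cn)
                      and ref.a.shape[1] == len(model.muscles))
    if full_reference:
        # the reference already lives on this model: track it as given
        ref3d = resample(ref, np.clip(grid, ref.time[0], ref.time[-1]))
        ref3d.time = grid
    else:
        # planar reference: map the sagittal columns; every other coordinate
        # holds its default (the reference defines no motion for them)
        nmus, nres = len(model.muscles), len(model.reserves)
        q = np.tile(model.default_pose(), (len(grid), 1))
        u = np.zeros_like(q)
        for nm in SAGITTAL_COORDS:
            lo, hi = model.coordinate(nm).range
            q[:, cn.index(nm)] = np.clip(
                np.interp(grid, ref.time, ref.column(nm)), lo, hi)
            u[:, cn.index(nm)] = np.interp(grid, ref.time,
                                           ref.column(f"{nm}_u"))
        ref3d = Trajectory(grid, cn, model.muscle_names,
                           [r.coordinate for r in model.reserves], q, u,
                           np.zeros((len(grid), nmus)),
                           np.zeros((len(grid), nmus)),
                           np.zeros((len(grid), nres)))

    weights = {}
    for c in model.unlocked_coordinates:
        sagittal = c.name in SAGITTAL_COORDS
        weights[c.name] = 1.0 if sagittal else settings.nonsagittal_weight
        weights[f"{c.name}_u"] = settings.speed_weight

    bounds = {}
    for c in model.unlocked_coordinates:
        nm = c.name
        q0 = float(np.clip(ref3d.column(nm)[0], *c.range))
        u0 = float(np.clip(ref3d.column(f"{nm}_u")[0], -20.0, 20.0))
        bounds[nm] = {"initial": (q0, q0)}
        bounds[f"{nm}_u"] = {"initial": (u0, u0)}

    if full_reference:
        guess = ref3d.copy()
    else:
        # seed with a reflex-like tracking rollout of the mapped reference
        guess = _feedback_guess(engine, ref3d, grid)

    problem = OCProblem(
        model, (0.0, t_f), state_bounds=bounds,
        objective_terms=[
            TrackingTerm(ref3d, weights),
            EffortTerm(EffortGoalConfig(d_mode="unit"),
                       weight=settings.regularization)],
        initial_guess=guess, mesh_times=grid, name="stage2_track")
    sol = solve_collocation(problem, settings.collocation, engine=engine)
    return StageResult("track2", sol, _provenance(
        "track2", None, {"model": model.name,
                         "config_hash": _hash_obj([list(grid), t_f])}))


# ---------------------------------------------------------------------------
# stage 3: collocation prediction of the what-if scenarios


@dataclass
class Stage3Settings:
    horizon: float = 0.35
    clearance: float = 0.05
    fine_window: float = 0.08
    fine_h: float = 0.005
    coarse_h: float = 0.01
    # cushioned landings: penalize vGRF beyond ~2.5 BW firmly, so the
    # predicted strategies stay comparable across scenarios
    grf: GRFPenaltyConfig = field(
        default_factory=lambda: GRFPenaltyConfig(upper=2.5, weight=2.0))
    feedback_seed: bool = False   # reflex-rollout seed vs. direct replay
    collocation: CollocationSettings = field(
        default_factory=lambda: CollocationSettings(theta=1.0))


def _scenario_locks(scenario: ScenarioConfig) -> dict:
    """Coordinates a scenario prescribes for the whole phase (rad)."""
    locks = {}
    if scenario.family == "hip_rotation" and scenario.parameter != 0:
        # a zero-rotation case is exactly the baseline (no-op override)
        locks["hip_rotation_l"] = np.deg2rad(scenario.parameter)
    elif scenario.family == "trunk_flexion_extension":
        locks["lumbar_extension"] = np.deg2rad(scenario.parameter)
    elif scenario.family == "trunk_bending":
        locks["lumbar_bending"] = np.deg2rad(scenario.parameter)
    return locks


def _scenario_model(scenario: ScenarioConfig,
                    base: ModelSpec) -> ModelSpec:
    model = base
    for group, factor in scenario.muscle_scalings.items():
        model = scale_muscle_group(model, group, factor)
    return model


def _scenario_bounds(scenario: ScenarioConfig, model: ModelSpec,
                     settings: Stage3Settings, guess: Trajectory,
                     engine: Engine) -> dict:
    cn = model.coordinate_names
    bounds = {nm: _pin(val) for nm, val in TRACKING_PINNED.items()
              if nm in cn and not model.coordinate(nm).locked}

    # initial state: the guess's start pose, dropped with the ballistic
    # velocity of the scenario's landing height; the opening clearance is
    # chosen so touchdown falls on a mesh node, which keeps the sampled
    # impact transient comparable across scenarios
    drop = 0.30
    if scenario.family == "landing_height":
        drop = float(scenario.parameter)
    t_td = 4.0 * settings.fine_h
    v_td = np.sqrt(2.0 * G * drop)
    dh = v_td * t_td - 0.5 * G * t_td ** 2
    v0 = -(v_td - G * t_td)

    pose0 = model.default_pose()
    for c in model.unlocked_coordinates:
        pose0[cn.index(c.name)] = np.clip(guess.column(c.name)[0], *c.range)
    c0 = float(engine.foot_clearance_batch(pose0[None])[0])

    for c in model.unlocked_coordinates:
        nm = c.name
        if nm in bounds and "initial" in bounds[nm]:
            continue
        q0 = float(pose0[cn.index(nm)])
        u0 = float(np.clip(guess.column(f"{nm}_u")[0], -20.0, 20.0))
        if nm == "pelvis_ty":
            q0 = q0 - c0 + dh
            u0 = v0
        bounds.setdefault(nm, {})["initial"] = (q0, q0)
        bounds.setdefault(f"{nm}_u", {})["initial"] = (u0, u0)

    # a landing must end supported and arrested: the pelvis settles in a
    # crouch (not a collapse onto the joint stops) with its descent
    # essentially stopped — this is what forces muscular effort
    bounds.setdefault("pelvis_ty", {})["final"] = (0.35, 1.05)
    bounds["pelvis_ty"]["path"] = (0.3, 2.0)
    bounds.setdefault("pelvis_ty_u", {})["final"] = (-0.35, 0.6)

    # pelvis roll stays bounded (no falling over); yaw drift is left free —
    # it is a real feature of asymmetric single-leg landings
    bounds.setdefault("pelvis_list", {})["path"] = (-0.5, 0.5)
    for nm, over in scenario.bound_overrides.items():
        bounds.setdefault(nm, {}).update(over)
    return bounds


def stage3_predict(scenario: ScenarioConfig, guess: Trajectory,
                   model3d: ModelSpec | None = None,
                   settings: Stage3Settings | None = None) -> StageResult:
    """Predict one what-if landing scenario by collocation (stage 3)."""
    settings = settings or Stage3Settings()
    base = _pipeline_model(model3d, extra_locks=_scenario_locks(scenario))
    model = _scenario_model(scenario, base)
    engine = Engine(model)

    w = scenario.effort_weight
    if scenario.family == "effort_weight":
        w = float(scenario.parameter)
    terms = [GRFPenaltyTerm(settings.grf)]
    if w > 0:
        terms.insert(0, EffortTerm(EffortGoalConfig(), weight=w))

    bounds = _scenario_bounds(scenario, model, settings, guess, engine)
    t_f = min(settings.horizon, guess.time[-1] - guess.time[0])
    grid = stage_mesh(t_f, settings.fine_window, settings.fine_h,
                      settings.coarse_h)

    # seed: a reflex rollout from the scenario's own initial state (drop
    # velocity, prescribed pose) that tracks the chained baseline motion
    q0 = model.default_pose()
    u0 = np.zeros(len(q0))
    cn = model.coordinate_names
    for c in model.unlocked_coordinates:
        over = bounds.get(c.name, {})
        if "initial" in over:
            q0[cn.index(c.name)] = 0.5 * (over["initial"][0]
                                          + over["initial"][1])
        uover = bounds.get(f"{c.name}_u", {})
        if "initial" in uover:
            u0[cn.index(c.name)] = 0.5 * (uover["initial"][0]
                                          + uover["initial"][1])
    if settings.feedback_seed:
        seed = _feedback_guess(engine, guess, grid, q_init=q0, u_init=u0)
    else:
        # direct replay: keep the baseline's open-loop controls; the solver
        # restoration rolls them out from the scenario's initial state, so
        # every scenario starts from the same landing strategy
        seed = resample(guess, np.clip(grid, guess.time[0], guess.time[-1]))
        seed.time = grid
        seed.q[0] = q0
        cn2 = model.coordinate_names
        for c in model.unlocked_coordinates:
            seed.u[0, cn2.index(c.name)] = u0[cn2.index(c.name)]

    problem = OCProblem(model, (0.0, t_f),
                        state_bounds=bounds, objective_terms=terms,
                        initial_guess=seed, mesh_times=grid,
                        name=f"stage3[{scenario.label}]")
    sol = solve_collocation(problem, settings.collocation, engine=engine)
    if sol.status == "infeasible":
        sol.info["binding"] = sorted(
            k for k, v in bounds.items()
            if "path" in v and v["path"][0] >= v["path"][1] - 1e-9)
    sol.info["scenario"] = scenario.label
    return StageResult("predict3", sol, _provenance(
        "predict3", scenario.seed,
        {"model": model.name, "scenario": scenario.label,
         "config_hash": scenario.config_hash()}))


def run_case_study(scenarios, guess: Trajectory,
                   model3d: ModelSpec | None = None,
                   settings: Stage3Settings | None = None):
    """Solve a list of scenarios and tabulate their risk-factor rows.

    Failures are marked in the ``flagged`` column, never dropped.
    """
    base = model3d if model3d is not None else build_reduced3d_model()
    reports = []
    results = []
    for sc in scenarios:
        res = stage3_predict(sc, guess, base, settings)
        results.append(res)
        model = _scenario_model(
            sc, _pipeline_model(base, extra_locks=_scenario_locks(sc)))
        rep = report_at_peak(res.solution, model, sc.label)
        if res.solution.status != "converged":
            rep.flagged = True
            rep.note = (f"solver status {res.solution.status}; " + rep.note)
        reports.append(rep)
    return report_table(reports), results


# ---------------------------------------------------------------------------
# quiet stance (static verification case)


def quiet_stance(model3d: ModelSpec | None = None) -> Solution:
    """Single-leg quiet-stance equilibrium as a (static) Solution.

    Solves for a pose, activations and reserve controls with vanishing
    accelerations; at equilibrium the summed vertical contact force equals
    body weight exactly, and the knee transmits a compressive load.
    """
    import scipy.optimize as sopt

    from .objectives import CostBreakdown

    model = _pipeline_model(model3d)
    engine = Engine(model)
    cn = model.coordinate_names
    free = engine.free
    nf, nmus, nres = engine.nf, engine.nm, engine.nr

    q0 = model.default_pose()
    # drop the pelvis a touch so contact can carry weight; lean it over the
    # stance (left) foot
    q0[cn.index("pelvis_ty")] -= 0.004
    q0[cn.index("pelvis_tz")] = -0.0835
    # pose regularization: keep rotations near the nominal stance but let
    # the pelvis translate freely to find support
    pose_w = np.array([0.0 if model.coordinates[i].kind == "translational"
                       else 3.0 for i in free])

    x0 = np.concatenate([q0[free], np.full(nmus, 0.05), np.zeros(nres)])
    lo = np.concatenate([[model.coordinates[i].range[0] for i in free],
                         np.zeros(nmus), -np.ones(nres)])
    hi = np.concatenate([[model.coordinates[i].range[1] for i in free],
                         np.ones(nmus), np.ones(nres)])

    nx = len(x0)

    def _unpack(x):
        q = q0.copy()
        q[free] = x[:nf]
        return q, x[nf:nf + nmus], x[nf + nmus:]

    def _qdd_batch(X):
        B = X.shape[0]
        Q = np.tile(q0, (B, 1))
        Q[:, free] = X[:, :nf]
        return engine.accelerations(Q, np.zeros((B, engine.nc)),
                                    X[:, nf:nf + nmus],
                                    X[:, nf + nmus:])[:, free]

    def residual(x):
        qdd = _qdd_batch(x[None, :])[0]
        # keep the regularization tiny: equilibrium dominates
        return np.concatenate([qdd, 0.03 * x[nf:nf + nmus],
                               0.03 * x[nf + nmus:],
                               pose_w * (x[:nf] - q0[free])])

    def jac(x):
        eps = 1e-7
        base = _qdd_batch(x[None, :])[0]
        pert = _qdd_batch(x[None, :] + eps * np.eye(nx))
        J = np.zeros((nf + nmus + nres + nf, nx))
        J[:nf] = (pert - base).T / eps
        J[nf:nf + nmus, nf:nf + nmus] = 0.03 * np.eye(nmus)
        J[nf + nmus:nf + nmus + nres, nf + nmus:] = 0.03 * np.eye(nres)
        J[nf + nmus + nres:, :nf] = np.diag(pose_w)
        return J

    res = sopt.least_squares(residual, x0, jac=jac, bounds=(lo, hi),
                             method="trf", x_scale="jac",
                             xtol=1e-15, ftol=1e-15, gtol=1e-15,
                             max_nfev=800)
    q = q0.copy()
    q[free] = res.x[:nf]
    a = res.x[nf:nf + nmus]
    r = res.x[nf + nmus:]
    qdd = engine.accelerations(q[None], np.zeros((1, engine.nc)),
                               a[None], r[None])[0]

    times = np.linspace(0.0, 0.1, 3)
    N = len(times)
    traj = Trajectory(times, cn, model.muscle_names,
                      [rr.coordinate for rr in model.reserves],
                      np.tile(q, (N, 1)), np.zeros((N, engine.nc)),
                      np.tile(a, (N, 1)), np.tile(a, (N, 1)),
                      np.tile(r, (N, 1)))
    resid = float(np.abs(qdd[free]).max())
    status = "converged" if resid < 0.5 else "max_iter"
    return Solution(traj, CostBreakdown(), status, 0.0,
                    int(res.nfev), info={"equilibrium_residual": resid})


# ---------------------------------------------------------------------------
# whole pipeline


def run_pipeline(seed: int = 0,
                 stage1_cfg: Stage1Config | None = None,
                 stage2_settings: Stage2Settings | None = None,
                 scenarios=None,
                 stage3_settings: Stage3Settings | None = None):
    """Run predict → track → predict end to end; returns all stage results.

    ``scenarios`` defaults to the baseline 0.30 m landing.
    """
    s1 = stage1_predict(cfg=stage1_cfg, seed=seed)
    s2 = stage2_track(s1.solution.trajectory, settings=stage2_settings)
    if scenarios is None:
        scenarios = [ScenarioConfig("landing_height", 0.30, seed=seed)]
    table, s3 = run_case_study(scenarios, s2.solution.trajectory,
                               settings=stage3_settings)
    return {"stage1": s1, "stage2": s2, "stage3": s3, "table": table}
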