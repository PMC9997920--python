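"""Reduced musculoskeletal models for single-leg drop-landing simulation.

Two rigid-body models of the same 1.80 m / 75.16 kg subject are provided:

* a sagittal-plane model with 9 generalized coordinates and 16 grouped
  muscle-tendon actuators (8 per leg), used by the shooting-based motion
  prediction stage, and
* a 3-D model defining 23 coordinates (6 pelvis, 3 lumbar, 7 per leg) with
  the right limb locked in a flexed, out-of-the-way pose, muscles on the
  left (landing) leg only, and low-strength reserve actuators on every
  unlocked coordinate, used by the collocation tracking/prediction stages.

Segment masses, lengths and inertias follow standard anthropometric
regression fractions (Winter/de Leva) scaled to the subject, since only the
subject's total height and mass are prescribed.  Muscle paths are
straight-line origin-insertion polylines with at most one via point; tendon
slack lengths are calibrated at build time so every fiber sits at its
optimal length in the default standing pose.

Conventions: x anterior, y up, z to the subject's right; angles in radians
internally; flexion positive.  Each segment frame has its origin at the
proximal joint.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

SUBJECT_MASS = 75.16  # kg
SUBJECT_HEIGHT = 1.80  # m
GRAVITY = np.array([0.0, -9.81, 0.0])

#: canonical muscle group labels
MUSCLE_GROUPS = (
    "quadriceps",
    "hamstrings",
    "gastrocnemius",
    "tibialis_anterior",
    "gluteals",
    "iliopsoas",
    "soleus",
    "other",
)

# Winter anthropometric fractions (of total body mass / stature)
_FRAC_HAT = 0.678           # head-arms-trunk incl. pelvis
_FRAC_PELVIS = 0.142
_FRAC_TORSO = _FRAC_HAT - _FRAC_PELVIS
_FRAC_THIGH = 0.100
_FRAC_SHANK = 0.0465
_FRAC_FOOT = 0.0145
_LEN_FEMUR = 0.245 * SUBJECT_HEIGHT     # 0.441 m
_LEN_TIBIA = 0.246 * SUBJECT_HEIGHT     # 0.4428 m
_LEN_FOOT = 0.152 * SUBJECT_HEIGHT      # 0.2736 m
_ANKLE_HEIGHT = SUBJECT_HEIGHT * (0.530 - 0.245 - 0.246)  # 0.0702 m

#: pelvis origin (mid-hip) height in quiet double-leg standing
STANDING_PELVIS_HEIGHT = _LEN_FEMUR + _LEN_TIBIA + _ANKLE_HEIGHT  # 0.954 m

# right-limb locked pose (rad): hip flexion 25 deg, knee flexion 120 deg,
# ankle plantarflexed 20 deg
RIGHT_LIMB_LOCKED_POSE = {
    "hip_flexion_r": np.deg2rad(25.0),
    "knee_flexion_r": np.deg2rad(120.0),
    "ankle_flexion_r": np.deg2rad(-20.0),
    "hip_adduction_r": 0.0,
    "hip_rotation_r": 0.0,
    "subtalar_r": 0.0,
    "mtp_r": 0.0,
}


def _vec(x) -> np.ndarray:
    return np.asarray(x, dtype=float).reshape(3)


@dataclass(frozen=True)
class SegmentSpec:
    """A rigid segment. Frame origin sits at the proximal joint."""

    name: str
    mass: float
    com_offset: np.ndarray       # COM in segment frame [m]
    inertia: np.ndarray          # 3x3 about COM, segment frame [kg m^2]
    length: float
    parent_attachment: np.ndarray  # joint location in parent frame [m]
    parent: str | None = None    # None => root (pelvis)
    joint: str | None = None     # name of the joint to the parent


@dataclass(frozen=True)
class CoordinateSpec:
    name: str
    joint: str
    axis: np.ndarray             # unit axis in the parent frame
    range: tuple[float, float]   # [rad] or [m]
    default: float = 0.0
    locked: bool = False
    locked_value: float = 0.0
    kind: str = "rotational"     # or "translational"


@dataclass(frozen=True)
class MuscleSpec:
    name: str
    group: str
    F0: float                    # max isometric force [N]
    l_opt: float                 # optimal fiber length [m]
    l_slack: float               # tendon slack length [m]
    v_max: float = 10.0          # [l_opt/s]
    pennation: float = 0.0       # [rad]
    path: tuple[tuple[str, np.ndarray], ...] = ()  # (segment, local point)
    #: idealized wraps: (coordinate, radius [m]); each adds radius*q to the
    #: musculotendon length and a pure torque -F*radius on the coordinate
    #: (the patellar mechanism of the knee extensors)
    pulleys: tuple[tuple[str, float], ...] = ()


@dataclass(frozen=True)
class ReserveActuatorSpec:
    coordinate: str
    optimal_force: float = 2.0   # [N] or [N m]


@dataclass(frozen=True)
class ContactSphereSpec:
    name: str
    segment: str
    local_position: np.ndarray
    radius: float = 0.032
    stiffness: float = 1.0e5     # [N / m^1.5]
    dissipation: float = 1.0     # [s/m]
    mu_static: float = 0.8
    mu_dynamic: float = 0.8
    mu_viscous: float = 0.1


@dataclass(frozen=True)
class ModelSpec:
    name: str
    segments: tuple[SegmentSpec, ...]
    coordinates: tuple[CoordinateSpec, ...]
    muscles: tuple[MuscleSpec, ...]
    reserves: tuple[ReserveActuatorSpec, ...] = ()
    contact_spheres: tuple[ContactSphereSpec, ...] = ()
    gravity: np.ndarray = field(default_factory=lambda: GRAVITY.copy())
    subject_height: float = SUBJECT_HEIGHT

    # -- convenience accessors -------------------------------------------
    @property
    def total_mass(self) -> float:
        return float(sum(s.mass for s in self.segments))

    @property
    def coordinate_names(self) -> list[str]:
        return [c.name for c in self.coordinates]

    @property
    def muscle_names(self) -> list[str]:
        return [m.name for m in self.muscles]

    def coordinate(self, name: str) -> CoordinateSpec:
        for c in self.coordinates:
            if c.name == name:
                return c
        raise KeyError(f"unknown coordinate {name!r}")

    def segment(self, name: str) -> SegmentSpec:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(f"unknown segment {name!r}")

    def muscles_in_group(self, group: str) -> list[MuscleSpec]:
        if group not in MUSCLE_GROUPS:
            raise KeyError(f"unknown muscle group {group!r}")
        return [m for m in self.muscles if m.group == group]

    def default_pose(self) -> np.ndarray:
        return np.array(
            [c.locked_value if c.locked else c.default for c in self.coordinates]
        )

    @property
    def unlocked_coordinates(self) -> list[CoordinateSpec]:
        return [c for c in self.coordinates if not c.locked]


# ---------------------------------------------------------------------------
# invariant checking


def validate_model(model: ModelSpec) -> list[str]:
    """Return a list of human-readable invariant violations (empty if valid)."""
    bad: list[str] = []
    seg_names = [s.name for s in model.segments]
    if len(set(seg_names)) != len(seg_names):
        bad.append("duplicate segment names")
    for s in model.segments:
        if not s.mass > 0:
            bad.append(f"segment {s.name}: mass must be > 0")
        if not s.length > 0:
            bad.append(f"segment {s.name}: length must be > 0")
        inert = np.asarray(s.inertia)
        if not np.allclose(inert, inert.T):
            bad.append(f"segment {s.name}: inertia not symmetric")
        elif np.linalg.eigvalsh(inert).min() < -1e-12:
            bad.append(f"segment {s.name}: inertia not positive semi-definite")
        if s.parent is not None and s.parent not in seg_names:
            bad.append(f"segment {s.name}: unknown parent {s.parent!r}")
    roots = [s for s in model.segments if s.parent is None]
    if len(roots) != 1 or roots[0].name != "pelvis":
        bad.append("model must have exactly one root segment named 'pelvis'")

    joints = {s.joint for s in model.segments if s.joint}
    coord_names = [c.name for c in model.coordinates]
    if len(set(coord_names)) != len(coord_names):
        bad.append("duplicate coordinate names")
    for c in model.coordinates:
        lo, hi = c.range
        if not lo <= hi:
            bad.append(f"coordinate {c.name}: empty range")
        if not lo - 1e-9 <= c.default <= hi + 1e-9:
            bad.append(f"coordinate {c.name}: default outside range")
        if c.locked and not lo - 1e-9 <= c.locked_value <= hi + 1e-9:
            bad.append(f"coordinate {c.name}: locked_value outside range")
        if c.joint not in joints:
            bad.append(f"coordinate {c.name}: unknown joint {c.joint!r}")
        if abs(np.linalg.norm(c.axis) - 1.0) > 1e-9:
            bad.append(f"coordinate {c.name}: axis not unit length")

    for m in model.muscles:
        if not m.F0 > 0:
            bad.append(f"muscle {m.name}: F0 must be > 0")
        if not m.l_opt > 0:
            bad.append(f"muscle {m.name}: l_opt must be > 0")
        if m.l_slack < 0:
            bad.append(f"muscle {m.name}: l_slack must be >= 0")
        if m.group not in MUSCLE_GROUPS:
            bad.append(f"muscle {m.name}: unknown group {m.group!r}")
        if len(m.path) < 2 or len({seg for seg, _ in m.path}) < 2:
            bad.append(f"muscle {m.name}: path must span >= 2 segments")
        for coord, radius in m.pulleys:
            if coord not in coord_names:
                bad.append(f"muscle {m.name}: pulley on unknown coordinate "
                           f"{coord!r}")
            if radius == 0:
                bad.append(f"muscle {m.name}: zero pulley radius")
        for seg, _ in m.path:
            if seg not in seg_names:
                bad.append(f"muscle {m.name}: path references unknown segment {seg!r}")

    for r in model.reserves:
        if r.coordinate not in coord_names:
            bad.append(f"reserve on unknown coordinate {r.coordinate!r}")
        if not r.optimal_force > 0:
            bad.append(f"reserve {r.coordinate}: optimal_force must be > 0")

    for s in model.contact_spheres:
        if s.segment not in seg_names:
            bad.append(f"contact sphere {s.name}: unknown segment {s.segment!r}")
        if not s.radius > 0:
            bad.append(f"contact sphere {s.name}: radius must be > 0")
        if not s.stiffness > 0:
            bad.append(f"contact sphere {s.name}: stiffness must be > 0")
        if s.dissipation < 0:
            bad.append(f"contact sphere {s.name}: dissipation must be >= 0")
        if not s.mu_static >= s.mu_dynamic >= 0:
            bad.append(f"contact sphere {s.name}: need mu_static >= mu_dynamic >= 0")
    return bad


# ---------------------------------------------------------------------------
# segment factories


def _leg_inertia(mass: float, length: float, rg_frac: float = 0.32) -> np.ndarray:
    it = mass * (rg_frac * length) ** 2
    ia = mass * (0.05 * length) ** 2 + 1e-4
    return np.diag([it, ia, it])


def _segment(name, mass, com, inertia, length, attach, parent, joint):
    return SegmentSpec(name, mass, _vec(com), np.asarray(inertia, float),
                       length, _vec(attach), parent, joint)


def _coord(name, joint, axis, rng_deg=None, rng=None, default=0.0,
           kind="rotational", locked=False, locked_value=0.0):
    if rng is None:
        rng = tuple(np.deg2rad(rng_deg))
    return CoordinateSpec(name, joint, _vec(axis), (float(rng[0]), float(rng[1])),
                          float(default), locked, float(locked_value), kind)


def _foot_spheres(segment: str, y: float, prefix: str) -> list[ContactSphereSpec]:
    """Five spheres: one under the toes, four under the hindfoot."""
    layout = [
        ("heel_med", -0.04, 0.025), ("heel_lat", -0.04, -0.025),
        ("mid_med", 0.06, 0.03), ("mid_lat", 0.06, -0.03),
    ]
    spheres = [
        ContactSphereSpec(f"{prefix}_{nm}", segment, _vec([x, y, z]))
        for nm, x, z in layout
    ]
    spheres.append(ContactSphereSpec(f"{prefix}_toe", segment, _vec([0.20, y, 0.0])))
    return spheres


def _calibrate_slack_lengths(model: ModelSpec) -> ModelSpec:
    """Set each tendon slack length so the fiber is at l_opt in the default pose."""
    from .tree import muscle_tendon_lengths_at

    lmt = muscle_tendon_lengths_at(model, model.default_pose())
    muscles = []
    for m, l in zip(model.muscles, lmt):
        # short-path muscles keep a minimal tendon and sit slightly below
        # optimal fiber length in the reference pose
        slack = float(max(l - m.l_opt * np.cos(m.pennation), 0.05 * l))
        muscles.append(replace(m, l_slack=slack))
    return replace(model, muscles=tuple(muscles))


# ---------------------------------------------------------------------------
# planar (stage-1) model


def build_planar_model() -> ModelSpec:
    """Sagittal-plane model: 9 coordinates, 16 muscle-tendon actuators.

    Pelvis, torso, head and arms are lumped into a single HAT root segment.
    Coordinates: pelvis tx/ty/tilt plus hip, knee and ankle flexion per leg.
    """
    mt = SUBJECT_MASS
    segments = [
        _segment("pelvis", _FRAC_HAT * mt, [-0.02, 0.30, 0.0],
                 np.diag([2.8, 1.0, 2.8]), 0.80, [0, 0, 0], None, "ground_pelvis"),
    ]
    for side, sgn in (("l", -1.0), ("r", 1.0)):
        segments += [
            _segment(f"femur_{side}", _FRAC_THIGH * mt, [0, -0.433 * _LEN_FEMUR, 0],
                     _leg_inertia(_FRAC_THIGH * mt, _LEN_FEMUR), _LEN_FEMUR,
                     [0.0, 0.0, sgn * 0.0835], "pelvis", f"hip_{side}"),
            _segment(f"tibia_{side}", _FRAC_SHANK * mt, [0, -0.433 * _LEN_TIBIA, 0],
                     _leg_inertia(_FRAC_SHANK * mt, _LEN_TIBIA), _LEN_TIBIA,
                     [0.0, -_LEN_FEMUR, 0.0], f"femur_{side}", f"knee_{side}"),
            _segment(f"foot_{side}", _FRAC_FOOT * mt, [0.05, -0.03, 0],
                     _leg_inertia(_FRAC_FOOT * mt, _LEN_FOOT, 0.25), _LEN_FOOT,
                     [0.0, -_LEN_TIBIA, 0.0], f"tibia_{side}", f"ankle_{side}"),
        ]

    coords = [
        _coord("pelvis_tx", "ground_pelvis", [1, 0, 0], rng=(-5, 5),
               kind="translational"),
        _coord("pelvis_ty", "ground_pelvis", [0, 1, 0], rng=(0, 3),
               default=STANDING_PELVIS_HEIGHT, kind="translational"),
        _coord("pelvis_tilt", "ground_pelvis", [0, 0, 1], rng_deg=(-90, 90)),
    ]
    for side in ("l", "r"):
        coords += [
            _coord(f"hip_flexion_{side}", f"hip_{side}", [0, 0, 1], rng_deg=(-35, 140)),
            _coord(f"knee_flexion_{side}", f"knee_{side}", [0, 0, -1], rng_deg=(0, 140)),
            _coord(f"ankle_flexion_{side}", f"ankle_{side}", [0, 0, 1], rng_deg=(-60, 45)),
        ]

    muscles = []
    for side in ("l", "r"):
        pel, fem, tib, foot = "pelvis", f"femur_{side}", f"tibia_{side}", f"foot_{side}"
        mdef = [
            ("iliopsoas", "iliopsoas", 2000, 0.12, 0.0,
             [(pel, [0.05, 0.02, 0]), (fem, [0.01, -0.06, 0])]),
            ("glutei", "gluteals", 3000, 0.16, 0.0,
             [(pel, [-0.07, 0.03, 0]), (fem, [-0.03, -0.10, 0])]),
            ("hamstrings", "hamstrings", 3500, 0.16, 0.0,
             [(pel, [-0.07, -0.02, 0]), (tib, [-0.027, -0.05, 0])]),
            ("rect_fem", "quadriceps", 1200, 0.16, 0.0,
             [(pel, [0.05, -0.01, 0]), (tib, [0.0, 0.0, 0])]),
            ("vasti", "quadriceps", 5000, 0.18, 0.0,
             [(fem, [0.03, -0.15, 0]), (tib, [0.0, 0.0, 0])]),
            ("gastroc", "gastrocnemius", 2500, 0.09, 0.0,
             [(fem, [-0.02, -0.40, 0]), (foot, [-0.05, -0.03, 0])]),
            ("soleus", "soleus", 4000, 0.07, 0.35,
             [(tib, [-0.025, -0.15, 0]), (foot, [-0.05, -0.03, 0])]),
            ("tib_ant", "tibialis_anterior", 1200, 0.08, 0.0,
             [(tib, [0.025, -0.17, 0]), (foot, [0.09, 0.01, 0])]),
        ]
        for nm, grp, f0, lopt, penn, path in mdef:
            pulleys = ((f"knee_flexion_{side}", 0.045),) \
                if grp == "quadriceps" else ()
            muscles.append(MuscleSpec(
                f"{nm}_{side}", grp, float(f0), lopt, 0.0, 10.0, penn,
                tuple((seg, _vec(p)) for seg, p in path), pulleys))

    spheres = (_foot_spheres("foot_l", -0.040, "l")
               + _foot_spheres("foot_r", -0.040, "r"))

    model = ModelSpec(
        name="planar9_16",
        segments=_rescale_masses(tuple(segments)),
        coordinates=tuple(coords),
        muscles=tuple(muscles),
        contact_spheres=tuple(spheres),
    )
    return _calibrate_slack_lengths(model)


# ---------------------------------------------------------------------------
# reduced 3-D model

#: default left-leg muscle grouping for the 3-D model (~12 actuators)
DEFAULT_GROUPING: dict[str, tuple[str, ...]] = {
    "quadriceps": ("rect_fem_l", "vasti_l"),
    "hamstrings": ("bflh_l", "semimem_l"),
    "gluteals": ("glut_max_l", "glut_med_l"),
    "iliopsoas": ("iliopsoas_l",),
    "gastrocnemius": ("gastroc_l",),
    "soleus": ("soleus_l",),
    "tibialis_anterior": ("tib_ant_l",),
    "other": ("adductors_l", "hip_rotators_l"),
}

# name -> (F0 [N], l_opt [m], pennation [rad], path)
_MUSCLES_3D: dict[str, tuple] = {
    "rect_fem_l": (1200, 0.16, 0.0,
                   [("pelvis", [0.05, -0.01, -0.08]), ("tibia_l", [0.0, 0.0, 0])]),
    "vasti_l": (5000, 0.18, 0.0,
                [("femur_l", [0.03, -0.15, 0]), ("tibia_l", [0.0, 0.0, 0])]),
    "bflh_l": (1500, 0.16, 0.0,
               [("pelvis", [-0.07, -0.02, -0.07]), ("tibia_l", [-0.028, -0.05, -0.03])]),
    "semimem_l": (2000, 0.16, 0.0,
                  [("pelvis", [-0.07, -0.02, -0.10]), ("tibia_l", [-0.025, -0.05, 0.02])]),
    "glut_max_l": (3000, 0.11, 0.0,
                   [("pelvis", [-0.08, 0.02, -0.06]), ("femur_l", [-0.03, -0.10, 0.01])]),
    "glut_med_l": (2500, 0.05, 0.0,
                   [("pelvis", [-0.02, 0.05, -0.10]), ("femur_l", [0.0, -0.03, -0.05])]),
    "iliopsoas_l": (2000, 0.08, 0.0,
                    [("pelvis", [0.05, 0.02, -0.07]), ("femur_l", [0.01, -0.06, 0.01])]),
    "adductors_l": (2000, 0.12, 0.0,
                    [("pelvis", [0.02, -0.04, -0.03]), ("femur_l", [0.0, -0.20, 0.02])]),
    "hip_rotators_l": (1000, 0.07, 0.0,
                       [("pelvis", [-0.06, -0.01, -0.04]), ("femur_l", [-0.01, -0.02, -0.05])]),
    "gastroc_l": (2500, 0.09, 0.0,
                  [("femur_l", [-0.02, -0.40, 0]), ("calcn_l", [-0.06, 0.0, 0])]),
    "soleus_l": (4000, 0.07, 0.35,
                 [("tibia_l", [-0.025, -0.15, 0]), ("calcn_l", [-0.06, 0.0, 0])]),
    "tib_ant_l": (1200, 0.08, 0.0,
                  [("tibia_l", [0.025, -0.17, 0]), ("calcn_l", [0.09, 0.02, -0.01])]),
}

_GROUP_OF_3D = {nm: grp for grp, names in DEFAULT_GROUPING.items() for nm in names}


def build_reduced3d_model(
    muscle_grouping: dict[str, tuple[str, ...]] | None = None,
) -> ModelSpec:
    """3-D model: 23 defined coordinates, left-leg muscles only.

    The right-limb coordinates are locked at the stage-1 pose (hip flexed
    25 deg, knee flexed 120 deg, ankle plantarflexed) so the swing leg stays
    clear of the ground; all right-leg muscles are omitted and every
    unlocked coordinate carries one low-strength reserve actuator.
    """
    grouping = DEFAULT_GROUPING if muscle_grouping is None else muscle_grouping
    _check_grouping(grouping)

    mt = SUBJECT_MASS
    foot_m = _FRAC_FOOT * mt
    segments = [
        _segment("pelvis", _FRAC_PELVIS * mt, [-0.05, 0.03, 0.0],
                 np.diag([0.10, 0.09, 0.09]), 0.20, [0, 0, 0], None, "ground_pelvis"),
        _segment("torso", _FRAC_TORSO * mt, [0.0, 0.30, 0.0],
                 np.diag([2.0, 0.8, 2.2]), 0.60, [-0.03, 0.10, 0.0],
                 "pelvis", "lumbar"),
    ]
    for side, sgn in (("l", -1.0), ("r", 1.0)):
        segments += [
            _segment(f"femur_{side}", _FRAC_THIGH * mt, [0, -0.433 * _LEN_FEMUR, 0],
                     _leg_inertia(_FRAC_THIGH * mt, _LEN_FEMUR), _LEN_FEMUR,
                     [0.0, 0.0, sgn * 0.0835], "pelvis", f"hip_{side}"),
            _segment(f"tibia_{side}", _FRAC_SHANK * mt, [0, -0.433 * _LEN_TIBIA, 0],
                     _leg_inertia(_FRAC_SHANK * mt, _LEN_TIBIA), _LEN_TIBIA,
                     [0.0, -_LEN_FEMUR, 0.0], f"femur_{side}", f"knee_{side}"),
            _segment(f"talus_{side}", 0.05 * foot_m, [0, 0, 0],
                     np.diag([1e-3, 1e-3, 1e-3]), 0.05,
                     [0.0, -_LEN_TIBIA, 0.0], f"tibia_{side}", f"ankle_{side}"),
            _segment(f"calcn_{side}", 0.77 * foot_m, [0.06, -0.01, 0],
                     _leg_inertia(0.77 * foot_m, _LEN_FOOT, 0.25), _LEN_FOOT,
                     [0.0, -0.04, 0.0], f"talus_{side}", f"subtalar_{side}"),
            _segment(f"toes_{side}", 0.18 * foot_m, [0.02, -0.01, 0],
                     np.diag([2e-4, 2e-4, 2e-4]), 0.07,
                     [0.18, 0.0, 0.0], f"calcn_{side}", f"mtp_{side}"),
        ]

    coords = [
        _coord("pelvis_tx", "ground_pelvis", [1, 0, 0], rng=(-5, 5),
               kind="translational"),
        _coord("pelvis_ty", "ground_pelvis", [0, 1, 0], rng=(0, 3),
               default=STANDING_PELVIS_HEIGHT, kind="translational"),
        _coord("pelvis_tz", "ground_pelvis", [0, 0, 1], rng=(-3, 3),
               kind="translational"),
        _coord("pelvis_tilt", "ground_pelvis", [0, 0, 1], rng_deg=(-90, 90)),
        _coord("pelvis_list", "ground_pelvis", [1, 0, 0], rng_deg=(-90, 90)),
        _coord("pelvis_rotation", "ground_pelvis", [0, 1, 0], rng_deg=(-90, 90)),
        _coord("lumbar_extension", "lumbar", [0, 0, -1], rng_deg=(-35, 35)),
        _coord("lumbar_bending", "lumbar", [1, 0, 0], rng_deg=(-35, 35)),
        _coord("lumbar_rotation", "lumbar", [0, 1, 0], rng_deg=(-35, 35)),
    ]
    for side, sgn in (("l", -1.0), ("r", 1.0)):
        coords += [
            _coord(f"hip_flexion_{side}", f"hip_{side}", [0, 0, 1], rng_deg=(-35, 140)),
            _coord(f"hip_adduction_{side}", f"hip_{side}", [-sgn, 0, 0],
                   rng_deg=(-50, 30)),
            _coord(f"hip_rotation_{side}", f"hip_{side}", [0, -sgn, 0],
                   rng_deg=(-45, 45)),
            _coord(f"knee_flexion_{side}", f"knee_{side}", [0, 0, -1], rng_deg=(0, 140)),
            _coord(f"ankle_flexion_{side}", f"ankle_{side}", [0, 0, 1],
                   rng_deg=(-60, 45)),
            _coord(f"subtalar_{side}", f"subtalar_{side}", [1, 0, 0], rng_deg=(-30, 30)),
            _coord(f"mtp_{side}", f"mtp_{side}", [0, 0, 1], rng_deg=(-30, 45)),
        ]
    # lock the right limb at the stage-1 pose
    coords = [
        replace(c, locked=True, locked_value=RIGHT_LIMB_LOCKED_POSE[c.name])
        if c.name in RIGHT_LIMB_LOCKED_POSE else c
        for c in coords
    ]

    muscles = []
    for grp, names in grouping.items():
        for nm in names:
            f0, lopt, penn, path = _MUSCLES_3D[nm]
            pulleys = (("knee_flexion_l", 0.045),) if grp == "quadriceps" else ()
            muscles.append(MuscleSpec(
                nm, grp, float(f0), lopt, 0.0, 10.0, penn,
                tuple((seg, _vec(p)) for seg, p in path), pulleys))

    spheres = []
    for side in ("l", "r"):
        hind = _foot_spheres(f"calcn_{side}", 0.0, side)[:4]
        toe = ContactSphereSpec(f"{side}_toe", f"toes_{side}", _vec([0.02, 0.0, 0.0]))
        spheres += hind + [toe]

    # the trunk has no muscles in this model family: the lumbar coordinates
    # are driven by strong coordinate actuators, as in the reference gait
    # models; every other unlocked coordinate gets a weak assistive reserve
    reserves = tuple(
        ReserveActuatorSpec(c.name, 250.0 if c.name.startswith("lumbar") else 2.0)
        for c in coords if not c.locked
    )

    model = ModelSpec(
        name="reduced3d_23",
        segments=_rescale_masses(tuple(segments)),
        coordinates=tuple(coords),
        muscles=tuple(muscles),
        reserves=reserves,
        contact_spheres=tuple(spheres),
    )
    return _calibrate_slack_lengths(model)


def _check_grouping(grouping: dict[str, tuple[str, ...]]) -> None:
    if len(grouping) < 6:
        raise ValueError("grouping policy must name >= 6 muscle groups")
    for required in ("quadriceps", "hamstrings"):
        if required not in grouping or not grouping[required]:
            raise ValueError(f"grouping policy must include {required!r}")
    for grp, names in grouping.items():
        if grp not in MUSCLE_GROUPS:
            raise ValueError(f"unknown muscle group {grp!r}")
        for nm in names:
            if nm not in _MUSCLES_3D:
                raise ValueError(f"unknown muscle {nm!r} in group {grp!r}")


def _rescale_masses(segments: tuple[SegmentSpec, ...]) -> tuple[SegmentSpec, ...]:
    """Scale all segment masses so the total is exactly the subject mass."""
    total = sum(s.mass for s in segments)
    f = SUBJECT_MASS / total
    return tuple(replace(s, mass=s.mass * f) for s in segments)


# ---------------------------------------------------------------------------
# model editing


def scale_muscle_group(model: ModelSpec, group: str, factor: float) -> ModelSpec:
    """Multiply the max isometric force of every muscle in ``group`` by ``factor``.

    Used by the muscle-strength what-if scenarios: strengthening a group is
    F0 x 1.35, weakening it is F0 x 0.65.
    """
    if factor <= 0:
        raise ValueError("scale factor must be > 0")
    members = model.muscles_in_group(group)
    if not members:
        raise KeyError(f"model has no muscles in group {group!r}")
    names = {m.name for m in members}
    muscles = tuple(
        replace(m, F0=m.F0 * factor) if m.name in names else m
        for m in model.muscles
    )
    return replace(model, muscles=muscles)


def lock_coordinates(model: ModelSpec, values: dict[str, float]) -> ModelSpec:
    """Return a copy with the named coordinates locked at the given values (rad/m)."""
    unknown = set(values) - set(model.coordinate_names)
    if unknown:
        raise KeyError(f"unknown coordinates: {sorted(unknown)}")
    coords = tuple(
        replace(c, locked=True, locked_value=float(values[c.name]))
        if c.name in values else c
        for c in model.coordinates
    )
    return replace(model, coordinates=coords)


def lock_right_limb(model: ModelSpec) -> ModelSpec:
    """Lock the right-limb coordinates at the stage-1 pose (planar model)."""
    values = {k: v for k, v in RIGHT_LIMB_LOCKED_POSE.items()
              if k in model.coordinate_names}
    return lock_coordinates(model, values)


# ---------------------------------------------------------------------------
# serialization (declarative key-value document; lossless round-trip)


def _spec_to_dict(obj) -> dict:
    d = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if isinstance(v, np.ndarray):
            v = v.tolist()
        elif f.name == "path":
            v = [[seg, list(map(float, p))] for seg, p in v]
        elif f.name == "pulleys":
            v = [[c, float(r)] for c, r in v]
        elif isinstance(v, tuple):
            v = [float(x) if isinstance(x, (np.floating, np.integer)) else x
                 for x in v]
        elif isinstance(v, (np.floating, np.integer)):
            v = float(v)
        d[f.name] = v
    return d


def save_model(model: ModelSpec, path) -> None:
    doc = {
        "name": model.name,
        "subject_height": model.subject_height,
        "gravity": model.gravity.tolist(),
        "segments": [_spec_to_dict(s) for s in model.segments],
        "coordinates": [_spec_to_dict(c) for c in model.coordinates],
        "muscles": [_spec_to_dict(m) for m in model.muscles],
        "reserves": [_spec_to_dict(r) for r in model.reserves],
        "contact_spheres": [_spec_to_dict(s) for s in model.contact_spheres],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_model(path) -> ModelSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    segs = tuple(
        SegmentSpec(d["name"], d["mass"], _vec(d["com_offset"]),
                    np.asarray(d["inertia"], float), d["length"],
                    _vec(d["parent_attachment"]), d["parent"], d["joint"])
        for d in doc["segments"])
    coords = tuple(
        CoordinateSpec(d["name"], d["joint"], _vec(d["axis"]),
                       (float(d["range"][0]), float(d["range"][1])), d["default"],
                       d["locked"], d["locked_value"], d["kind"])
        for d in doc["coordinates"])
    muscles = tuple(
        MuscleSpec(d["name"], d["group"], d["F0"], d["l_opt"], d["l_slack"],
                   d["v_max"], d["pennation"],
                   tuple((seg, _vec(p)) for seg, p in d["path"]),
                   tuple((c, r) for c, r in d.get("pulleys", [])))
        for d in doc["muscles"])
    reserves = tuple(
        ReserveActuatorSpec(d["coordinate"], d["optimal_force"])
        for d in doc["reserves"])
    spheres = tuple(
        ContactSphereSpec(d["name"], d["segment"], _vec(d["local_position"]),
                          d["radius"], d["stiffness"], d["dissipation"],
                          d["mu_static"], d["mu_dynamic"], d["mu_viscous"])
        for d in doc["contact_spheres"])
    return ModelSpec(doc["name"], segs, coords, muscles, reserves, spheres,
                     _vec(doc["gravity"]), doc["subject_height"])
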