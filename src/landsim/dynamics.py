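"""Forward dynamics, ground contact and joint-reaction analysis.

The public surface operates on single states; internally every operation is
batched (see :mod:`landsim.tree`) so that collocation transcriptions,
finite-difference Jacobians and shooting populations evaluate the dynamics
of many states per numpy call.

The equations of motion are ``M(q) qdd = tau_reserve - bias(q, u, f_ext)``
where the bias term (gravity, Coriolis, muscle path-point forces and
contact forces, all applied as external spatial forces) comes from a
recursive Newton-Euler pass and ``M`` from the composite-rigid-body
algorithm.  Locked coordinates are held at their locked value and return
zero acceleration.

Joint reaction loads are the wrenches transmitted through a joint onto its
child segment, obtained from the same Newton-Euler balance over the distal
subtree with all muscle, contact, gravity and inertial loads applied — the
free-body convention in which muscle forces count as applied loads.  For
the knee of the landing (left) leg, expressed in the tibia frame
(x anterior, y proximal, z to the subject's right = medial for the left
leg), the components are read as AF (+x anterior), MF (+z medial),
CF (y; compression negative), AbdM (+x moment = abduction) and IRM
(y moment; internal rotation negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contact import contact_force, hunt_crossley  # noqa: F401  (re-export)
from .model import ModelSpec
from .muscles import activation_rate, hill_force, muscle_force  # noqa: F401
from .tree import CompiledTree

__all__ = [
    "State", "Control", "ContactForce", "JointLoad", "Engine",
    "forward_dynamics", "joint_reaction", "muscle_force", "activation_rate",
    "contact_force",
]


@dataclass
class State:
    """Generalized coordinates, speeds and muscle activations."""

    q: np.ndarray
    u: np.ndarray
    a: np.ndarray

    def copy(self) -> "State":
        return State(self.q.copy(), self.u.copy(), self.a.copy())


@dataclass
class Control:
    """Muscle excitations and reserve-actuator controls."""

    e: np.ndarray
    r: np.ndarray = field(default_factory=lambda: np.zeros(0))


@dataclass
class ContactForce:
    sphere: str
    force: np.ndarray   # ground frame [N]
    point: np.ndarray   # contact point, ground frame [m]


@dataclass
class JointLoad:
    joint: str
    force: np.ndarray   # child-segment frame [N]
    moment: np.ndarray  # child-segment frame, about the joint center [N m]


class Engine:
    """Compiled dynamics of one :class:`ModelSpec`."""

    def __init__(self, model: ModelSpec):
        self.model = model
        self.tree = CompiledTree(model)
        mus = model.muscles
        self.F0 = np.array([m.F0 for m in mus])
        self.l_opt = np.array([m.l_opt for m in mus])
        self.l_slack = np.array([m.l_slack for m in mus])
        self.v_max = np.array([m.v_max for m in mus])
        self.pennation = np.array([m.pennation for m in mus])
        cnames = model.coordinate_names
        self.res_coord = np.array(
            [cnames.index(r.coordinate) for r in model.reserves], int)
        self.res_F = np.array([r.optimal_force for r in model.reserves])
        sph = model.contact_spheres
        self.sph_radius = np.array([s.radius for s in sph])
        self.sph_k = np.array([s.stiffness for s in sph])
        self.sph_c = np.array([s.dissipation for s in sph])
        self.sph_mud = np.array([s.mu_dynamic for s in sph])
        self.sph_muv = np.array([s.mu_viscous for s in sph])
        self.left_spheres = [k for k, s in enumerate(sph) if s.name.startswith("l")]
        self.nc = len(cnames)
        self.nm = len(mus)
        self.nr = len(model.reserves)
        self.nf = self.tree.nf
        self.free = self.tree.free_coords
        self.body_weight = model.total_mass * 9.81
        self.q_lo = np.array([c.range[0] for c in model.coordinates])
        self.q_hi = np.array([c.range[1] for c in model.coordinates])

    # coordinate-limit torques: a smooth restoring torque engaging just
    # outside the coordinate range, with damping, so passive rollouts do not
    # hyperextend joints (the role of ligaments at range of motion)
    _LIMIT_K = 2000.0    # [N m / rad] (or N/m for translational)
    _LIMIT_D = 5.0       # [N m s / rad]
    _LIMIT_MARGIN = 0.02
    _LIMIT_EPS = 0.005

    def _limit_torque(self, q, u):
        m, eps = self._LIMIT_MARGIN, self._LIMIT_EPS
        over = q - (self.q_hi + m)
        under = (self.q_lo - m) - q

        def hp(x):
            # C1 positive part, exactly zero below -eps
            mid = (x + eps) ** 2 / (4.0 * eps)
            return np.where(x <= -eps, 0.0, np.where(x >= eps, x, mid))

        def w(x):
            return np.clip((x + eps) / (2.0 * eps), 0.0, 1.0)

        return (-self._LIMIT_K * (hp(over) - hp(under))
                - self._LIMIT_D * (w(over) + w(under)) * u)

    # -- batched core ------------------------------------------------------
    def _clean_qu(self, q, u):
        t = self.tree
        q = t.full_q(np.atleast_2d(np.asarray(q, float)))
        u = np.array(np.atleast_2d(np.asarray(u, float)))
        u[:, t.locked_coord] = 0.0
        return q, u

    def _forces(self, q, u, act):
        """Kinematics plus all applied external forces for a batch of states."""
        t = self.tree
        R, p, Sa, Sl = t.kinematics(q)
        va, vl = t.velocities(u, Sa, Sl)
        B = q.shape[0]
        fa = np.zeros((t.nb, B, 3))
        fl = np.zeros((t.nb, B, 3))

        tension = np.zeros((B, self.nm))
        tau_pulley = np.zeros((B, self.nc))
        if self.nm:
            P, V = t.point_states(R, p, va, vl)
            lmt, vmt = t.muscle_lengths(P, V, q, u)
            tension = hill_force(self.F0, self.l_opt, self.l_slack, self.v_max,
                                 self.pennation, act, lmt, vmt)
            t.apply_muscle_forces(P, tension, fa, fl)
            for mi, ci, radius in t.pulleys:
                tau_pulley[:, ci] -= radius * tension[:, mi]

        sphere_forces = np.zeros((t.ns, B, 3))
        sphere_points = np.zeros((t.ns, B, 3))
        if t.ns:
            C, Vp = t.sphere_states(R, p, va, vl)
            for k in range(t.ns):
                pen = self.sph_radius[k] - C[k][:, 1]
                rate = -Vp[k][:, 1]
                vt = Vp[k][:, [0, 2]]
                fn, ft = hunt_crossley(self.sph_k[k], self.sph_c[k],
                                       self.sph_mud[k], self.sph_muv[k],
                                       pen, rate, vt)
                F = np.stack([ft[:, 0], fn, ft[:, 1]], axis=1)
                L = C[k].copy()
                L[:, 1] -= self.sph_radius[k]
                b = t.sphere_body[k]
                fl[b] += F
                fa[b] += np.cross(L, F)
                sphere_forces[k] = F
                sphere_points[k] = L
        return dict(R=R, p=p, Sa=Sa, Sl=Sl, va=va, vl=vl, fa=fa, fl=fl,
                    tension=tension, tau_pulley=tau_pulley,
                    sphere_forces=sphere_forces, sphere_points=sphere_points)

    def _tau_applied(self, B, res, q=None, u=None):
        tau = np.zeros((B, self.nc))
        if self.nr and res is not None:
            tau[:, self.res_coord] = np.atleast_2d(res) * self.res_F
        if q is not None:
            tau += self._limit_torque(q, u)
        return tau

    def accelerations(self, q, u, act, res=None, parts=None):
        """Batched coordinate accelerations (B, nc); locked entries zero."""
        q, u = self._clean_qu(q, u)
        act = np.atleast_2d(np.asarray(act, float))
        B = q.shape[0]
        w = parts if parts is not None else self._forces(q, u, act)
        t = self.tree
        zero = np.zeros_like(q)
        bias = t.rnea(q, u, zero, w["R"], w["p"], w["Sa"], w["Sl"],
                      w["va"], w["vl"], w["fa"], w["fl"])
        M = t.crba(w["R"], w["p"], w["Sa"], w["Sl"])
        rhs = (self._tau_applied(B, res, q, u) + w["tau_pulley"]
               - bias)[:, self.free]
        qdd = np.zeros((B, self.nc))
        qdd[:, self.free] = np.linalg.solve(M, rhs[..., None])[..., 0]
        return qdd

    def state_derivative(self, q, u, act, exc, res=None):
        """Batched (B, 2*nf + nm) derivative [qdot_free, qdd_free, adot]."""
        q2, u2 = self._clean_qu(q, u)
        qdd = self.accelerations(q2, u2, act, res)
        adot = activation_rate(np.atleast_2d(exc), np.atleast_2d(act))
        return np.concatenate(
            [u2[:, self.free], qdd[:, self.free], adot], axis=1)

    def node_eval(self, q, u, act, exc, res=None, want_vgrf=False):
        """Batched state derivative plus (optionally) left-foot vertical GRF.

        Shares one kinematics/force pass between the dynamics defects and
        any GRF-dependent objective, which is what the collocation
        transcription evaluates at every mesh node.
        """
        q, u = self._clean_qu(q, u)
        act = np.atleast_2d(np.asarray(act, float))
        w = self._forces(q, u, act)
        qdd = self.accelerations(q, u, act, res, parts=w)
        adot = activation_rate(np.atleast_2d(exc), act)
        deriv = np.concatenate(
            [u[:, self.free], qdd[:, self.free], adot], axis=1)
        if not want_vgrf:
            return deriv, None
        if self.left_spheres:
            vgrf = w["sphere_forces"][self.left_spheres].sum(axis=0)[:, 1]
        else:
            vgrf = np.zeros(q.shape[0])
        return deriv, vgrf

    # -- single-state public operations ------------------------------------
    def forward_dynamics(self, state: State, control: Control) -> np.ndarray:
        """Coordinate accelerations (nc,) for one state/control pair."""
        self._check(state, control)
        return self.accelerations(state.q, state.u, state.a, control.r)[0]

    def joint_reaction(self, state: State, control: Control,
                       joint: str) -> JointLoad:
        """Wrench transmitted through ``joint`` to its child segment."""
        self._check(state, control)
        t = self.tree
        chain = [b for b in range(t.nb)
                 if self.model.coordinates[t.coord_of_joint[b]].joint == joint]
        if not chain:
            raise KeyError(f"unknown joint {joint!r}")
        first, last = chain[0], chain[-1]

        q, u = self._clean_qu(state.q, state.u)
        act = np.atleast_2d(state.a)
        w = self._forces(q, u, act)
        qdd = self.accelerations(q, u, act, control.r, parts=w)
        _, fa, fl = t.rnea(q, u, qdd, w["R"], w["p"], w["Sa"], w["Sl"],
                           w["va"], w["vl"], w["fa"], w["fl"],
                           return_wrenches=True)
        # joint center in world frame
        par = t.parent[first]
        if par >= 0:
            pj = w["p"][par][0] + w["R"][par][0] @ t.offset[first]
        else:
            pj = t.offset[first].copy()
        n_joint = fa[first][0] - np.cross(pj, fl[first][0])
        Rc = w["R"][last][0]
        return JointLoad(joint, Rc.T @ fl[first][0], Rc.T @ n_joint)

    def contact_forces(self, state: State) -> list[ContactForce]:
        q, u = self._clean_qu(state.q, state.u)
        w = self._forces(q, u, np.atleast_2d(state.a))
        return [ContactForce(s.name, w["sphere_forces"][k][0],
                             w["sphere_points"][k][0])
                for k, s in enumerate(self.model.contact_spheres)]

    def muscle_forces(self, state: State) -> np.ndarray:
        q, u = self._clean_qu(state.q, state.u)
        w = self._forces(q, u, np.atleast_2d(state.a))
        return w["tension"][0]

    # -- batched trace extraction ------------------------------------------
    def grf_batch(self, q, u, act, side="l"):
        """Summed ground-reaction force (B, 3) of one foot's spheres."""
        q, u = self._clean_qu(q, u)
        w = self._forces(q, u, np.atleast_2d(act))
        idx = [k for k, s in enumerate(self.model.contact_spheres)
               if s.name.startswith(side)]
        if not idx:
            return np.zeros((q.shape[0], 3))
        return w["sphere_forces"][idx].sum(axis=0)

    def muscle_forces_batch(self, q, u, act):
        q, u = self._clean_qu(q, u)
        return self._forces(q, u, np.atleast_2d(act))["tension"]

    def foot_clearance_batch(self, q, side: str = "l") -> np.ndarray:
        """Lowest contact-sphere point height (batched) for one foot."""
        t = self.tree
        q = t.full_q(np.atleast_2d(np.asarray(q, float)))
        R, p, Sa, Sl = t.kinematics(q)
        zeros = np.zeros((t.nb, q.shape[0], 3))
        C, _ = t.sphere_states(R, p, zeros, zeros)
        lows = [C[k][:, 1] - s.radius
                for k, s in enumerate(self.model.contact_spheres)
                if s.name.startswith(side)]
        return np.min(lows, axis=0)

    def com_height(self, q) -> np.ndarray:
        t = self.tree
        q = t.full_q(np.atleast_2d(np.asarray(q, float)))
        R, p, *_ = t.kinematics(q)
        num = np.zeros(q.shape[0])
        for b in range(t.nb):
            if t.mass[b]:
                cw = p[b] + np.einsum("bij,j->bi", R[b], t.com[b])
                num += t.mass[b] * cw[:, 1]
        return num / t.mass.sum()

    def total_energy(self, q, u) -> np.ndarray:
        """Kinetic + gravitational potential energy (batched)."""
        t = self.tree
        q, u = self._clean_qu(q, u)
        R, p, Sa, Sl = t.kinematics(q)
        va, vl = t.velocities(u, Sa, Sl)
        E = np.zeros(q.shape[0])
        g = -self.model.gravity[1]
        for b in range(t.nb):
            m = t.mass[b]
            if not m:
                continue
            cw = p[b] + np.einsum("bij,j->bi", R[b], t.com[b])
            vc = vl[b] + np.cross(va[b], cw)
            Iw = np.einsum("bij,jk,blk->bil", R[b], t.inertia[b], R[b])
            E += (0.5 * m * np.einsum("bi,bi->b", vc, vc)
                  + 0.5 * np.einsum("bi,bij,bj->b", va[b], Iw, va[b])
                  + m * g * cw[:, 1])
        return E

    def _check(self, state: State, control: Control) -> None:
        if len(state.q) != self.nc or len(state.u) != self.nc:
            raise ValueError("state dimension mismatch with model")
        if len(state.a) != self.nm:
            raise ValueError("activation dimension mismatch with model")
        if np.any(state.a < -1e-9) or np.any(state.a > 1 + 1e-9):
            raise ValueError("activations must lie in [0, 1]")
        if not (np.all(np.isfinite(state.q)) and np.all(np.isfinite(state.u))):
            raise ValueError("non-finite state")
        if control.r is not None and len(control.r) not in (0, self.nr):
            raise ValueError("reserve control dimension mismatch")


# -- module-level conveniences (spec operation surface) ----------------------

def forward_dynamics(model: ModelSpec, state: State,
                     control: Control) -> np.ndarray:
    return Engine(model).forward_dynamics(state, control)


def joint_reaction(model: ModelSpec, state: State, control: Control,
                   joint: str) -> JointLoad:
    return Engine(model).joint_reaction(state, control, joint)
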