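"""Batched rigid-body tree machinery behind the dynamics module.

A :class:`ModelSpec` is compiled into a chain of *elementary* single-DoF
joints (one per coordinate; multi-DoF joints such as the 6-DoF pelvis become
a chain through massless intermediate bodies).  All quantities are computed
in ground-frame Plücker coordinates about the world origin, with spatial
vectors stored as (angular, linear) pairs of ``(B, 3)`` arrays so that a
whole batch of states — collocation nodes, finite-difference perturbations,
or a shooting population — is evaluated with a fixed number of numpy calls
independent of the batch size ``B``.

Locked coordinates remain part of the kinematic chain (they shape the
geometry and carry reaction loads) but are held at their locked value with
zero speed and acceleration and are excluded from the generalized mass
matrix.
"""

from __future__ import annotations

import numpy as np

from .model import ModelSpec

_REV, _PRISM = 0, 1


def _skew(a: np.ndarray) -> np.ndarray:
    return np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0.0]])


class CompiledTree:
    """Array-level compilation of a :class:`ModelSpec` kinematic tree."""

    def __init__(self, model: ModelSpec):
        self.model = model
        segs = {s.name: s for s in model.segments}

        # topological order of segments (parents first)
        ordered, placed = [], set()
        pending = list(model.segments)
        while pending:
            progressed = False
            for s in list(pending):
                if s.parent is None or s.parent in placed:
                    ordered.append(s)
                    placed.add(s.name)
                    pending.remove(s)
                    progressed = True
            if not progressed:
                raise ValueError("segment graph is not a tree rooted at pelvis")

        coord_index = {c.name: k for k, c in enumerate(model.coordinates)}
        by_joint: dict[str, list] = {}
        for c in model.coordinates:
            by_joint.setdefault(c.joint, []).append(c)

        parent, axis, kind, offset = [], [], [], []
        mass, com, inertia = [], [], []
        self.seg_body: dict[str, int] = {}
        self.coord_of_joint: list[int] = []   # spec coordinate index per eljoint
        for s in ordered:
            chain = by_joint.get(s.joint, [])
            if not chain:
                raise ValueError(f"segment {s.name} has no coordinates on joint {s.joint}")
            pb = -1 if s.parent is None else self.seg_body[s.parent]
            for j, c in enumerate(chain):
                parent.append(pb)
                axis.append(np.asarray(c.axis, float))
                kind.append(_PRISM if c.kind == "translational" else _REV)
                offset.append(np.asarray(s.parent_attachment, float) if j == 0
                              else np.zeros(3))
                last = j == len(chain) - 1
                mass.append(s.mass if last else 0.0)
                com.append(np.asarray(s.com_offset, float) if last else np.zeros(3))
                inertia.append(np.asarray(s.inertia, float) if last
                               else np.zeros((3, 3)))
                self.coord_of_joint.append(coord_index[c.name])
                pb = len(parent) - 1
            self.seg_body[s.name] = pb

        self.nb = len(parent)
        if self.nb != len(model.coordinates):
            raise ValueError("every coordinate must belong to exactly one joint chain")
        self.parent = np.array(parent)
        self.axis = np.array(axis)
        self.kind = np.array(kind)
        self.offset = np.array(offset)
        self.mass = np.array(mass)
        self.com = np.array(com)
        self.inertia = np.array(inertia)
        self.K = np.array([_skew(a) for a in self.axis])        # for Rodrigues
        self.K2 = np.einsum("nij,njk->nik", self.K, self.K)

        # eljoint order follows segment topology; map spec coordinate order
        self.joint_of_coord = np.empty(self.nb, int)
        for b, ci in enumerate(self.coord_of_joint):
            self.joint_of_coord[ci] = b

        locked = np.array([c.locked for c in model.coordinates])
        self.locked_coord = locked
        self.free_coords = np.flatnonzero(~locked)
        self.nf = len(self.free_coords)
        self.locked_values = np.array([c.locked_value for c in model.coordinates])

        # ancestor lists for CRBA (per eljoint, excluding self)
        self.ancestors: list[list[int]] = []
        for b in range(self.nb):
            anc, j = [], self.parent[b]
            while j >= 0:
                anc.append(j)
                j = self.parent[j]
            self.ancestors.append(anc)

        self._compile_muscles()
        self._compile_spheres()
        self.gravity = np.asarray(model.gravity, float)

    # -- muscle path / contact sphere tables ------------------------------
    def _compile_muscles(self) -> None:
        pts_body, pts_local, slices = [], [], []
        coord_index = {c.name: k for k, c in enumerate(self.model.coordinates)}
        pulleys = []
        for mi, m in enumerate(self.model.muscles):
            start = len(pts_body)
            for seg, loc in m.path:
                pts_body.append(self.seg_body[seg])
                pts_local.append(np.asarray(loc, float))
            slices.append((start, len(pts_body)))
            for coord, radius in m.pulleys:
                pulleys.append((mi, coord_index[coord], float(radius)))
        self.npts = len(pts_body)
        self.pt_body = np.array(pts_body, int) if pts_body else np.empty(0, int)
        self.pt_local = (np.array(pts_local) if pts_local
                         else np.empty((0, 3)))
        self.muscle_slices = slices
        self.pulleys = pulleys          # (muscle, coordinate, radius)
        self.nm = len(self.model.muscles)

    def _compile_spheres(self) -> None:
        self.sphere_body = np.array(
            [self.seg_body[s.segment] for s in self.model.contact_spheres], int)
        self.sphere_local = (np.array([s.local_position
                                       for s in self.model.contact_spheres])
                             if self.model.contact_spheres else np.empty((0, 3)))
        self.ns = len(self.model.contact_spheres)

    # -- kinematics --------------------------------------------------------
    def full_q(self, q_any: np.ndarray) -> np.ndarray:
        """Force locked coordinates to their locked values (batched)."""
        q = np.array(q_any, float, ndmin=2)
        q[:, self.locked_coord] = self.locked_values[self.locked_coord]
        return q

    def kinematics(self, q: np.ndarray):
        """Body rotations/origins and joint motion subspaces for batch ``q``.

        Returns ``R (nb,B,3,3)``, ``p (nb,B,3)``, ``S_ang``, ``S_lin``
        (both ``(nb,B,3)``).
        """
        B = q.shape[0]
        R = np.empty((self.nb, B, 3, 3))
        p = np.empty((self.nb, B, 3))
        Sa = np.zeros((self.nb, B, 3))
        Sl = np.empty((self.nb, B, 3))
        eye = np.broadcast_to(np.eye(3), (B, 3, 3))
        for b in range(self.nb):
            par = self.parent[b]
            Rp = eye if par < 0 else R[par]
            pp = 0.0 if par < 0 else p[par]
            pj = pp + Rp @ self.offset[b]
            aw = Rp @ self.axis[b]
            qb = q[:, self.coord_of_joint[b]]
            if self.kind[b] == _REV:
                s, c = np.sin(qb), np.cos(qb)
                Rj = (np.eye(3) + s[:, None, None] * self.K[b]
                      + (1.0 - c)[:, None, None] * self.K2[b])
                R[b] = np.einsum("bij,bjk->bik", Rp, Rj) if par >= 0 else Rj
                p[b] = pj
                Sa[b] = aw
                Sl[b] = np.cross(pj, aw)
            else:
                R[b] = Rp
                p[b] = pj + aw * qb[:, None]
                Sl[b] = aw
        return R, p, Sa, Sl

    def velocities(self, u: np.ndarray, Sa, Sl):
        B = u.shape[0]
        va = np.zeros((self.nb, B, 3))
        vl = np.zeros((self.nb, B, 3))
        for b in range(self.nb):
            ub = u[:, self.coord_of_joint[b], None]
            par = self.parent[b]
            if par >= 0:
                va[b] = va[par] + Sa[b] * ub
                vl[b] = vl[par] + Sl[b] * ub
            else:
                va[b] = Sa[b] * ub
                vl[b] = Sl[b] * ub
        return va, vl

    # -- inverse dynamics --------------------------------------------------
    def rnea(self, q, u, qdd, R, p, Sa, Sl, va, vl,
             fext_ang=None, fext_lin=None, return_wrenches=False):
        """Generalized forces needed to realize ``qdd`` (gravity included).

        ``fext_*`` are per-body applied spatial forces about the world
        origin.  When ``return_wrenches`` is set, also returns the wrench
        transmitted through each elementary joint (force applied by the
        parent onto the distal subtree), about the world origin.
        """
        B = q.shape[0]
        aa = np.zeros((self.nb, B, 3))
        al = np.zeros((self.nb, B, 3))
        a0 = -self.gravity  # gravity trick: accelerate the base upward
        cw = np.empty((self.nb, B, 3))
        fa = np.empty((self.nb, B, 3))
        fl = np.empty((self.nb, B, 3))
        for b in range(self.nb):
            ci = self.coord_of_joint[b]
            ub = u[:, ci, None]
            qddb = qdd[:, ci, None]
            par = self.parent[b]
            pva = np.zeros((B, 3)) if par < 0 else va[par]
            pvl = np.zeros((B, 3)) if par < 0 else vl[par]
            ca = np.cross(pva, Sa[b] * ub)
            cl = np.cross(pva, Sl[b] * ub) + np.cross(pvl, Sa[b] * ub)
            if par >= 0:
                aa[b] = aa[par] + Sa[b] * qddb + ca
                al[b] = al[par] + Sl[b] * qddb + cl
            else:
                aa[b] = Sa[b] * qddb + ca
                al[b] = a0 + Sl[b] * qddb + cl

            m = self.mass[b]
            cw[b] = p[b] + np.einsum("bij,j->bi", R[b], self.com[b])
            if m == 0.0:
                fa[b] = 0.0
                fl[b] = 0.0
            else:
                Iw = np.einsum("bij,jk,blk->bil", R[b], self.inertia[b], R[b])
                # momentum and its bias derivative
                pv = m * (vl[b] + np.cross(va[b], cw[b]))
                hO = np.einsum("bij,bj->bi", Iw, va[b]) + np.cross(cw[b], pv)
                pa = m * (al[b] + np.cross(aa[b], cw[b]))
                ha = np.einsum("bij,bj->bi", Iw, aa[b]) + np.cross(cw[b], pa)
                fa[b] = ha + np.cross(va[b], hO) + np.cross(vl[b], pv)
                fl[b] = pa + np.cross(va[b], pv)
            if fext_ang is not None:
                fa[b] -= fext_ang[b]
                fl[b] -= fext_lin[b]

        tau = np.empty((B, self.nb))
        for b in range(self.nb - 1, -1, -1):
            par = self.parent[b]
            if par >= 0:
                fa[par] = fa[par] + fa[b]
                fl[par] = fl[par] + fl[b]
        for b in range(self.nb):
            tau[:, self.coord_of_joint[b]] = (np.einsum("bi,bi->b", Sa[b], fa[b])
                                              + np.einsum("bi,bi->b", Sl[b], fl[b]))
        if return_wrenches:
            return tau, fa, fl
        return tau

    # -- mass matrix -------------------------------------------------------
    def crba(self, R, p, Sa, Sl):
        """Joint-space mass matrix over the free coordinates, shape (B, nf, nf)."""
        nb, B = self.nb, R.shape[1]
        mC = np.empty((nb, B))
        cC = np.empty((nb, B, 3))
        IC = np.empty((nb, B, 3, 3))
        for b in range(nb):
            mC[b] = self.mass[b]
            cC[b] = p[b] + np.einsum("bij,j->bi", R[b], self.com[b])
            IC[b] = np.einsum("bij,jk,blk->bil", R[b], self.inertia[b], R[b])
        eye = np.eye(3)
        for b in range(nb - 1, -1, -1):
            par = self.parent[b]
            if par < 0:
                continue
            mT = mC[par] + mC[b]
            safe = np.where(mT > 0, mT, 1.0)
            cT = (mC[par, :, None] * cC[par] + mC[b, :, None] * cC[b]) / safe[:, None]
            for j in (par, b):
                d = cC[j] - cT
                d2 = np.einsum("bi,bi->b", d, d)
                IC[par] = IC[par] + (IC[j] if j == b else 0.0) + mC[j][:, None, None] * (
                    d2[:, None, None] * eye - np.einsum("bi,bj->bij", d, d))
            mC[par] = mT
            cC[par] = cT

        fidx = {c: k for k, c in enumerate(self.free_coords)}
        M = np.zeros((B, self.nf, self.nf))
        for b in range(nb):
            ci = self.coord_of_joint[b]
            if self.locked_coord[ci]:
                continue
            i = fidx[ci]
            pF = mC[b][:, None] * (Sl[b] + np.cross(Sa[b], cC[b]))
            hF = np.einsum("bij,bj->bi", IC[b], Sa[b]) + np.cross(cC[b], pF)
            M[:, i, i] = (np.einsum("bi,bi->b", Sa[b], hF)
                          + np.einsum("bi,bi->b", Sl[b], pF))
            for a in self.ancestors[b]:
                cj = self.coord_of_joint[a]
                if self.locked_coord[cj]:
                    continue
                j = fidx[cj]
                mij = (np.einsum("bi,bi->b", Sa[a], hF)
                       + np.einsum("bi,bi->b", Sl[a], pF))
                M[:, i, j] = mij
                M[:, j, i] = mij
        return M

    # -- muscle geometry ---------------------------------------------------
    def point_states(self, R, p, va=None, vl=None):
        """World positions (and velocities) of all muscle path points."""
        B = R.shape[1]
        P = np.empty((self.npts, B, 3))
        V = np.empty((self.npts, B, 3)) if va is not None else None
        for k in range(self.npts):
            b = self.pt_body[k]
            P[k] = p[b] + np.einsum("bij,j->bi", R[b], self.pt_local[k])
            if va is not None:
                V[k] = vl[b] + np.cross(va[b], P[k])
        return P, V

    def muscle_lengths(self, P, V=None, q=None, u=None):
        """Muscle-tendon lengths (B, nm) and lengthening speeds (B, nm).

        ``q``/``u`` are needed when any muscle wraps a pulley.
        """
        B = P.shape[1] if self.npts else 1
        lmt = np.zeros((B, self.nm))
        vmt = np.zeros((B, self.nm))
        for mi, (s, e) in enumerate(self.muscle_slices):
            for k in range(s, e - 1):
                d = P[k + 1] - P[k]
                ln = np.linalg.norm(d, axis=1)
                lmt[:, mi] += ln
                if V is not None:
                    uhat = d / ln[:, None]
                    vmt[:, mi] += np.einsum("bi,bi->b", uhat, V[k + 1] - V[k])
        for mi, ci, radius in self.pulleys:
            if q is not None:
                lmt[:, mi] += radius * q[:, ci]
            if u is not None:
                vmt[:, mi] += radius * u[:, ci]
        return lmt, vmt

    def apply_muscle_forces(self, P, tension, fext_ang, fext_lin):
        """Accumulate path-point forces for per-muscle tensions (B, nm)."""
        for mi, (s, e) in enumerate(self.muscle_slices):
            T = tension[:, mi, None]
            for k in range(s, e - 1):
                d = P[k + 1] - P[k]
                uhat = d / np.linalg.norm(d, axis=1)[:, None]
                F = T * uhat
                b1, b2 = self.pt_body[k], self.pt_body[k + 1]
                fext_lin[b1] += F
                fext_ang[b1] += np.cross(P[k], F)
                fext_lin[b2] -= F
                fext_ang[b2] -= np.cross(P[k + 1], F)

    # -- sphere kinematics -------------------------------------------------
    def sphere_states(self, R, p, va, vl):
        """Centers and lowest-point velocities of all contact spheres."""
        B = R.shape[1]
        C = np.empty((self.ns, B, 3))
        Vp = np.empty((self.ns, B, 3))
        for k in range(self.ns):
            b = self.sphere_body[k]
            C[k] = p[b] + np.einsum("bij,j->bi", R[b], self.sphere_local[k])
            low = C[k].copy()
            low[:, 1] -= self.model.contact_spheres[k].radius
            Vp[k] = vl[b] + np.cross(va[b], low)
        return C, Vp


def muscle_tendon_lengths_at(model: ModelSpec, q: np.ndarray) -> np.ndarray:
    """Muscle-tendon lengths of every muscle at pose ``q`` (spec order)."""
    tree = CompiledTree(model)
    qb = tree.full_q(q[None, :])
    R, p, *_ = tree.kinematics(qb)
    P, _ = tree.point_states(R, p)
    lmt, _ = tree.muscle_lengths(P, q=qb)
    return lmt[0]
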