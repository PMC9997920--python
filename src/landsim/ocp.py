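"""Trajectory optimization: direct collocation and shooting.

Two transcriptions of the landing optimal-control problems are provided,
mirroring the two tool families used for this kind of study:

* :func:`solve_collocation` — direct collocation with a one-step
  theta-method: defects ``x_{k+1} - x_k - h[(1-theta) f_k + theta
  f_{k+1}]`` on a (possibly non-uniform) node grid; theta = 0.5 is the
  trapezoidal rule, theta = 1 the L-stable backward-Euler member used for
  the stiff landing phases.  The NLP is solved either by scipy
  ``trust-constr`` (small smooth problems) or by an augmented-Lagrangian
  loop with projected Levenberg-Marquardt inner iterations on the sparse
  block-banded least-squares system.  Constraint Jacobians exploit the
  node-local structure of the defects: all perturbations of all mesh
  nodes are evaluated in one batched dynamics call.

* :func:`solve_shooting` — forward-shooting with piecewise-linear control
  knots optimized by a seeded CMA-ES (rank-1 + rank-mu covariance update,
  cumulative step-size adaptation), the strategy family used by
  reflex-controller gait optimizers.  Candidate rollouts integrate the
  dynamics a whole population per batched call; rollouts that blow up are
  scored with a maximal penalty rather than raising.

Objective terms bridge the measures in :mod:`landsim.objectives` to both
solvers; the cost a solver reports is always the objectives module
re-evaluated on the returned trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize as sopt
import scipy.sparse as sp

from .dynamics import Engine
from .model import ModelSpec
from .objectives import (CostBreakdown, EffortGoalConfig, GRFPenaltyConfig,
                         JointRangePenaltyConfig, StabilityMeasureConfig,
                         SimOutcome, effort_displacement, effort_goal,
                         grf_penalty, joint_range_penalty, stability_penalty,
                         termination_time, tracking_objective)
from .trajectory import Trajectory, resample

__all__ = [
    "OCProblem", "Solution", "CollocationSettings", "ShootingSettings",
    "EffortTerm", "TrackingTerm", "GRFPenaltyTerm", "StabilityTerm",
    "JointRangeTerm", "solve_collocation", "solve_shooting", "resample",
    "rollout", "trapezoid_rollout",
]

_SPEED_BOUND = 40.0   # default path bound on coordinate speeds [rad/s, m/s]
_RANGE_MARGIN = 0.10  # slack beyond coordinate ranges (compliant joint stops)


# ---------------------------------------------------------------------------
# objective terms


class Term:
    """One weighted objective component; evaluable on any trajectory."""

    slot = "effort"
    weight = 1.0

    def value(self, traj: Trajectory, engine: Engine) -> float:
        raise NotImplementedError

    def gradient(self, trans: "_Transcription", X, C):
        raise NotImplementedError(
            f"{type(self).__name__} cannot be used by the collocation solver")


class EffortTerm(Term):
    """Displacement-normalized squared-control effort (collocation stage)."""

    slot = "effort"

    def __init__(self, cfg: EffortGoalConfig | None = None, weight: float = 1.0):
        self.cfg = cfg or EffortGoalConfig()
        self.weight = weight

    def value(self, traj, engine):
        return self.weight * effort_goal(traj, self.cfg)

    def gradient(self, trans, X, C):
        cfg = self.cfg
        if cfg.t_i is not None or cfg.t_f is not None:
            raise NotImplementedError("phase-restricted effort in collocation")
        w = trans.control_weight_vector(cfg.w_c)
        traj = trans.build_trajectory(X, C)
        d = effort_displacement(traj, cfg)
        g = np.zeros((trans.K, trans.nloc))
        p = cfg.p
        integrand_grad = (w[None, :] * p * np.abs(C) ** (p - 1.0) * np.sign(C))
        g[:, trans.nx:] = self.weight * trans.trapw[:, None] * integrand_grad / d
        if cfg.d_mode == "pelvis_displacement":
            # value = A/d  =>  dV/dvar = -(V/d) * dd/dvar on pelvis tx/ty ends
            val = self.weight * effort_goal(traj, cfg)
            dx = (traj.column("pelvis_tx")[-1] - traj.column("pelvis_tx")[0])
            dy = (traj.column("pelvis_ty")[-1] - traj.column("pelvis_ty")[0])
            for nm, comp in (("pelvis_tx", dx), ("pelvis_ty", dy)):
                j = trans.state_local_index(nm)
                if j is None:
                    continue
                dd = comp / d
                g[-1, j] -= val / d * dd
                g[0, j] += val / d * dd
        return g


class TrackingTerm(Term):
    """Integrated squared state error against a reference motion."""

    slot = "tracking"

    def __init__(self, reference: Trajectory, weights: dict, weight: float = 1.0):
        self.reference = reference
        self.weights = dict(weights)
        self.weight = weight

    def value(self, traj, engine):
        return self.weight * tracking_objective(traj, self.reference, self.weights)

    def gradient(self, trans, X, C):
        g = np.zeros((trans.K, trans.nloc))
        for name, w in self.weights.items():
            if w == 0.0:
                continue
            j = trans.state_local_index(name)
            ref = np.interp(trans.times, self.reference.time,
                            self.reference.column(name))
            if j is None:
                continue  # tracked state is locked/fixed: constant error
            g[:, j] += (self.weight * trans.trapw * 2.0 * w
                        * (X[:, j] - ref))
        return g


class GRFPenaltyTerm(Term):
    """Penalty on vGRF excursions outside a body-weight band."""

    slot = "p_grf"

    def __init__(self, cfg: GRFPenaltyConfig | None = None, side: str = "l"):
        self.cfg = cfg or GRFPenaltyConfig()
        self.side = side

    def vgrf_bw(self, traj, engine):
        v = engine.grf_batch(traj.q, traj.u, traj.a, self.side)[:, 1]
        return v / engine.body_weight

    def value(self, traj, engine):
        return grf_penalty(traj.time, self.vgrf_bw(traj, engine), self.cfg)

    def gradient(self, trans, X, C):
        # chain rule through the per-node vGRF, node-local FD on (q, u)
        eng = trans.engine
        cfg = self.cfg
        q, u, a, e, r = trans.split(X, C)
        _, v0 = eng.node_eval(q, u, a, e, r, want_vgrf=True)
        vbw = v0 / eng.body_weight
        dV_dv = (trans.trapw * cfg.weight
                 * (np.where(vbw > cfg.upper, 1.0, 0.0)
                    - np.where(vbw < cfg.lower, 1.0, 0.0)) / eng.body_weight)
        g = np.zeros((trans.K, trans.nloc))
        active = np.flatnonzero(dV_dv != 0.0)
        if len(active) == 0:
            return g
        eps = 1.0e-6
        nqu = 2 * trans.nf
        Qb, Ub, Ab, Eb, Rb, cols = [], [], [], [], [], []
        for k in active:
            for j in range(nqu):
                qq, uu = q[k].copy(), u[k].copy()
                if j < trans.nf:
                    qq[trans.free_coords[j]] += eps
                else:
                    uu[trans.free_coords[j - trans.nf]] += eps
                Qb.append(qq)
                Ub.append(uu)
                Ab.append(a[k])
                Eb.append(e[k])
                Rb.append(r[k])
                cols.append((k, j))
        _, vp = eng.node_eval(np.array(Qb), np.array(Ub), np.array(Ab),
                              np.array(Eb), np.array(Rb), want_vgrf=True)
        for m, (k, j) in enumerate(cols):
            g[k, j] += dV_dv[k] * (vp[m] - v0[k]) / eps
        return g


class StabilityTerm(Term):
    """Falling penalty from the COM-height ratio (shooting stage)."""

    slot = "p_s"

    def __init__(self, cfg: StabilityMeasureConfig | None = None):
        self.cfg = cfg or StabilityMeasureConfig()

    def value(self, traj, engine):
        com = engine.com_height(traj.q)
        t_sim = termination_time(traj.time, com, com[0], self.cfg.th,
                                 self.cfg.t_max)
        return stability_penalty(SimOutcome(t_sim, com, com[0]), self.cfg)


class JointRangeTerm(Term):
    """Penalty on worst-sample joint deviations from desired targets."""

    slot = "p_j"

    def __init__(self, cfg: JointRangePenaltyConfig):
        self.cfg = cfg

    def value(self, traj, engine):
        from .objectives import _dist_to_target

        measured = {}
        for name in self.cfg.weights:
            x = traj.column(name)
            dist = np.array([_dist_to_target(v, self.cfg.targets[name])
                             for v in x])
            measured[name] = x[int(np.argmax(dist))]
        return joint_range_penalty(measured, self.cfg)


# ---------------------------------------------------------------------------
# problems and solutions


@dataclass
class OCProblem:
    """A fixed-horizon optimal-control problem on one model."""

    model: ModelSpec
    horizon: tuple[float, float]
    mesh: int = 10
    state_bounds: dict = field(default_factory=dict)
    control_bounds: dict = field(default_factory=dict)
    objective_terms: list = field(default_factory=list)
    initial_guess: Trajectory | None = None
    mesh_times: np.ndarray | None = None    # explicit (non-uniform) node grid
    name: str = ""

    def __post_init__(self):
        if self.mesh_times is not None:
            self.mesh_times = np.asarray(self.mesh_times, float)
            if len(self.mesh_times) < 3 or np.any(np.diff(self.mesh_times) <= 0):
                raise ValueError("mesh_times must be >= 3 increasing nodes")
            self.horizon = (float(self.mesh_times[0]), float(self.mesh_times[-1]))
            self.mesh = len(self.mesh_times) - 1
        if self.mesh < 2:
            raise ValueError("mesh must have at least 2 intervals")
        t0, tf = self.horizon
        if not tf > t0:
            raise ValueError("empty horizon")


@dataclass
class Solution:
    """A solved trajectory with its cost breakdown and solver diagnostics."""

    trajectory: Trajectory
    cost: CostBreakdown
    status: str               # converged | max_iter | infeasible
    defect_norm: float
    niter: int = 0
    info: dict = field(default_factory=dict)

    def plot(self, columns=None, ax=None):
        """Plot solution state time-series (delegates to the trajectory)."""
        return self.trajectory.plot(columns=columns, ax=ax)

    def summary(self) -> str:
        c = self.cost
        lines = [
            "Optimal-control solution",
            "------------------------",
            f"status       : {self.status}",
            f"iterations   : {self.niter}",
            f"defect norm  : {self.defect_norm:.3e}",
            f"p_s          : {c.p_s:.6g}",
            f"p_j          : {c.p_j:.6g}",
            f"p_GRF        : {c.p_grf:.6g}",
            f"effort       : {c.effort:.6g}",
            f"tracking     : {c.tracking:.6g}",
            f"total cost   : {c.total:.6g}",
        ]
        return "\n".join(lines)


@dataclass
class CollocationSettings:
    """Augmented-Lagrangian least-squares solve of the transcribed NLP.

    The defects enter as residuals ``sqrt(mu) * (defect + lambda/mu)``; the
    multipliers are updated between outer rounds, so the solution converges
    to the constrained optimum without penalty bias.  ``tol`` applies to
    the h-scaled defects.
    """

    maxiter: int = 60          # inner trust-region-reflective iterations
    outer: int = 5             # multiplier updates
    tol: float = 1.0e-4
    mu0: float = 1.0e2
    mu_max: float = 1.0e8
    verbose: int = 0
    method: str = "alsq"       # or "trust-constr" for small smooth problems
    restore_feasibility: bool = True   # implicit rollout of the guess controls
    theta: float = 0.5         # one-step scheme: 0.5 trapezoid, 1.0 backward Euler


@dataclass
class ShootingSettings:
    knots: int = 5
    population: int = 16
    generations: int = 20
    sigma0: float = 0.15
    dt: float = 0.0005
    record_every: int = 20
    integrator: str = "semi_implicit"   # or "rk4"
    seed: int = 0


def evaluate_cost(terms, traj: Trajectory, engine: Engine) -> CostBreakdown:
    parts = CostBreakdown()
    for term in terms:
        setattr(parts, term.slot, getattr(parts, term.slot)
                + term.value(traj, engine))
    return parts


# ---------------------------------------------------------------------------
# collocation transcription


class _Transcription:
    def __init__(self, problem: OCProblem, engine: Engine, theta: float = 0.5):
        self.problem = problem
        self.engine = engine
        self.theta = theta
        t0, tf = problem.horizon
        self.K = problem.mesh + 1
        if problem.mesh_times is not None:
            self.times = problem.mesh_times.copy()
        else:
            self.times = np.linspace(t0, tf, self.K)
        self.h_arr = np.diff(self.times)
        tw = np.zeros(self.K)
        tw[:-1] += self.h_arr / 2
        tw[1:] += self.h_arr / 2
        self.trapw = tw

        self.nf = engine.nf
        self.nm = engine.nm
        self.nr = engine.nr
        self.nx = 2 * self.nf + self.nm
        self.nu = self.nm + self.nr
        self.nloc = self.nx + self.nu
        self.free_coords = engine.free

        model = problem.model
        fc = [model.coordinate_names[i] for i in self.free_coords]
        self.state_names = (fc + [f"{c}_u" for c in fc]
                            + [f"{m}_a" for m in model.muscle_names])
        self.control_names = ([f"{m}_e" for m in model.muscle_names]
                              + [f"reserve_{r.coordinate}" for r in model.reserves])
        self.local_names = self.state_names + self.control_names
        self._build_bounds()

    # -- bounds ------------------------------------------------------------
    def _default_bounds(self, name):
        model = self.problem.model
        if name.endswith("_u") and name[:-2] in model.coordinate_names:
            return (-_SPEED_BOUND, _SPEED_BOUND)
        if name.endswith("_a") or name.endswith("_e"):
            return (0.0, 1.0)
        if name.startswith("reserve_"):
            return (-1.0, 1.0)
        # coordinate ranges are compliant stops (limit torques), not rigid
        # walls: leave the transcription a small margin beyond them
        lo, hi = model.coordinate(name).range
        margin = _RANGE_MARGIN
        return (lo - margin, hi + margin)

    def _build_bounds(self):
        K, nloc = self.K, self.nloc
        lb = np.empty((K, nloc))
        ub = np.empty((K, nloc))
        spec = {**self.problem.state_bounds, **self.problem.control_bounds}
        for j, name in enumerate(self.local_names):
            dlo, dhi = self._default_bounds(name)
            over = spec.get(name, {})
            plo, phi = over.get("path", (dlo, dhi))
            lb[:, j] = plo
            ub[:, j] = phi
            if "initial" in over:
                lb[0, j], ub[0, j] = over["initial"]
            if "final" in over:
                lb[-1, j], ub[-1, j] = over["final"]
        unknown = set(spec) - set(self.local_names)
        if unknown:
            raise KeyError(f"bounds on unknown columns: {sorted(unknown)}")
        if np.any(lb > ub + 1e-12):
            raise ValueError("inconsistent bounds (lower > upper)")
        self.lb, self.ub = lb, ub
        self.fixed = lb >= ub - 1e-15
        self.free_mask = ~self.fixed
        self.nz = int(self.free_mask.sum())

    def state_local_index(self, name):
        """Index of a state column among the *local* NLP variables, else None."""
        if name in self.state_names:
            return self.state_names.index(name)
        return None

    def control_weight_vector(self, w_c):
        if np.isscalar(w_c):
            return np.full(self.nu, float(w_c))
        return np.array([float(w_c.get(nm, 0.0)) for nm in self.control_names])

    # -- packing -----------------------------------------------------------
    def pack(self, X, C):
        Z = np.concatenate([X, C], axis=1)
        return Z[self.free_mask]

    def unpack(self, z):
        Z = np.where(self.fixed, self.lb, 0.0)
        Z[self.free_mask] = z
        return Z[:, :self.nx], Z[:, self.nx:]

    def split(self, X, C):
        """Full-width (q, u, a, e, r) arrays for the whole mesh."""
        t = self.engine.tree
        K = self.K
        q = np.tile(t.locked_values, (K, 1))
        u = np.zeros((K, self.engine.nc))
        q[:, self.free_coords] = X[:, :self.nf]
        u[:, self.free_coords] = X[:, self.nf:2 * self.nf]
        a = X[:, 2 * self.nf:]
        e = C[:, :self.nm]
        r = C[:, self.nm:]
        return q, u, a, e, r

    def build_trajectory(self, X, C) -> Trajectory:
        q, u, a, e, r = self.split(X, C)
        model = self.problem.model
        return Trajectory(self.times.copy(), model.coordinate_names,
                          model.muscle_names,
                          [res.coordinate for res in model.reserves],
                          q, u, a, e, r)

    # -- dynamics at the nodes --------------------------------------------
    def node_derivatives(self, X, C):
        q, u, a, e, r = self.split(X, C)
        f, _ = self.engine.node_eval(q, u, a, e, r)
        return f

    def defects(self, X, C):
        f = self.node_derivatives(X, C)
        h = self.h_arr[:, None]
        th = self.theta
        D = (X[1:] - X[:-1]) - h * (th * f[1:] + (1.0 - th) * f[:-1])
        return (D / h).ravel()

    def defect_norm_unscaled(self, scaled_defects) -> float:
        """Max |defect| in state units (the h-scaled rows are the
        constraint residuals handed to the solver)."""
        D = scaled_defects.reshape(self.K - 1, self.nx) * self.h_arr[:, None]
        return float(np.abs(D).max())

    def defect_jacobian(self, X, C):
        """Sparse Jacobian of the scaled defects w.r.t. the reduced variables."""
        K, nx, nloc = self.K, self.nx, self.nloc
        eps = 1.0e-6
        q, u, a, e, r = self.split(X, C)
        f0, _ = self.engine.node_eval(q, u, a, e, r)

        # batched one-sided differences for every free local of every node
        pert = []
        for k in range(K):
            for j in np.flatnonzero(self.free_mask[k]):
                pert.append((k, j))
        Qb = np.empty((len(pert), self.engine.nc))
        Ub = np.empty_like(Qb)
        Ab = np.empty((len(pert), self.nm))
        Eb = np.empty_like(Ab)
        Rb = np.empty((len(pert), self.nr))
        for m, (k, j) in enumerate(pert):
            qq, uu, aa, ee, rr = q[k].copy(), u[k].copy(), a[k].copy(), \
                e[k].copy(), r[k].copy()
            if j < self.nf:
                qq[self.free_coords[j]] += eps
            elif j < 2 * self.nf:
                uu[self.free_coords[j - self.nf]] += eps
            elif j < nx:
                aa[j - 2 * self.nf] += eps
            elif j < nx + self.nm:
                ee[j - nx] += eps
            else:
                rr[j - nx - self.nm] += eps
            Qb[m], Ub[m], Ab[m], Eb[m], Rb[m] = qq, uu, aa, ee, rr
        fp, _ = self.engine.node_eval(Qb, Ub, Ab, Eb, Rb)

        # reduced column index of each (node, local)
        colid = np.full((K, nloc), -1, int)
        colid[self.free_mask] = np.arange(self.nz)

        rows, cols, data = [], [], []
        state_rows = np.arange(nx)
        for m, (k, j) in enumerate(pert):
            dfdv = (fp[m] - f0[k]) / eps          # (nx,)
            cid = colid[k, j]
            th = self.theta
            if k > 0:      # defect block k-1: node k enters with weight theta
                base = (k - 1) * nx
                vals = -th * dfdv
                if j < nx:
                    vals = vals.copy()
                    vals[j] += 1.0 / self.h_arr[k - 1]
                rows.append(base + state_rows)
                cols.append(np.full(nx, cid))
                data.append(vals)
            if k < K - 1:  # defect block k: node k enters with weight 1-theta
                base = k * nx
                vals = -(1.0 - th) * dfdv
                if j < nx:
                    vals = vals.copy()
                    vals[j] -= 1.0 / self.h_arr[k]
                rows.append(base + state_rows)
                cols.append(np.full(nx, cid))
                data.append(vals)
        J = sp.coo_matrix(
            (np.concatenate(data),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=((K - 1) * nx, self.nz))
        return J.tocsr()

    # -- objective ---------------------------------------------------------
    def objective(self, X, C):
        traj = self.build_trajectory(X, C)
        return sum(t.value(traj, self.engine)
                   for t in self.problem.objective_terms)

    def objective_grad(self, X, C):
        g = np.zeros((self.K, self.nloc))
        for t in self.problem.objective_terms:
            g += t.gradient(self, X, C)
        return g[self.free_mask]

    # -- initial guess -----------------------------------------------------
    def initial_point(self):
        guess = self.problem.initial_guess
        if guess is None:
            X = np.zeros((self.K, self.nx))
            model = self.problem.model
            for i, ci in enumerate(self.free_coords):
                c = model.coordinates[ci]
                X[:, i] = np.clip(c.default, self.lb[0, i], self.ub[0, i])
            C = np.zeros((self.K, self.nu))
        else:
            gt = guess.time
            t0, tf = self.times[0], self.times[-1]
            if abs(gt[0] - t0) > 1e-9 or abs(gt[-1] - tf) > 1e-9:
                scaled = t0 + (gt - gt[0]) / (gt[-1] - gt[0]) * (tf - t0)
                guess = guess.copy()
                guess.time = scaled
            rs = resample(guess, self.times)
            X = np.concatenate([rs.q[:, self.free_coords],
                                rs.u[:, self.free_coords], rs.a], axis=1)
            C = np.concatenate([rs.e, rs.r], axis=1)
        Z = np.clip(np.concatenate([X, C], axis=1), self.lb, self.ub)
        return Z[self.free_mask]


class _ObjectiveResiduals:
    """Least-squares residual form of the supported objective terms.

    Tracking and (p = 2) effort terms are linear residual rows; the GRF
    penalty contributes one nonlinear row per node (squared violation
    inside the solver; the reported cost is always the objectives module's
    own integral re-evaluated on the returned trajectory).  The effort
    displacement normalization is frozen during each inner solve and
    refreshed between multiplier updates.
    """

    def __init__(self, trans: "_Transcription"):
        self.trans = trans
        self.colid = np.full((trans.K, trans.nloc), -1, int)
        self.colid[trans.free_mask] = np.arange(trans.nz)
        self.lin_k, self.lin_j, self.lin_w, self.lin_ref = [], [], [], []
        self.effort_terms = []   # (row slice info for d refresh)
        self.grf_terms = []
        tw = trans.trapw
        for term in trans.problem.objective_terms:
            if isinstance(term, TrackingTerm):
                for name, w in term.weights.items():
                    if w == 0.0:
                        continue
                    j = trans.state_local_index(name)
                    if not term.reference.has_column(name):
                        raise KeyError(
                            f"reference trajectory lacks tracked column {name!r}")
                    if j is None:
                        continue
                    ref = np.interp(trans.times, term.reference.time,
                                    term.reference.column(name))
                    for k in range(trans.K):
                        if self.colid[k, j] >= 0:
                            self._add_lin(k, j, term.weight * w * tw[k], ref[k])
            elif isinstance(term, EffortTerm):
                if term.cfg.p != 2.0:
                    raise NotImplementedError(
                        "collocation effort terms require exponent p = 2")
                wc = trans.control_weight_vector(term.cfg.w_c)
                start = len(self.lin_k)
                for j in range(trans.nu):
                    if wc[j] == 0.0:
                        continue
                    jj = trans.nx + j
                    for k in range(trans.K):
                        if self.colid[k, jj] >= 0:
                            self._add_lin(k, jj, term.weight * wc[j] * tw[k],
                                          0.0)
                self.effort_terms.append((term, start, len(self.lin_k)))
            elif isinstance(term, GRFPenaltyTerm):
                self.grf_terms.append(term)
            else:
                raise NotImplementedError(
                    f"{type(term).__name__} is not usable by the collocation "
                    "solver")
        self.lin_k = np.array(self.lin_k, int)
        self.lin_j = np.array(self.lin_j, int)
        self.lin_w = np.array(self.lin_w)       # squared-weight per row
        self.lin_ref = np.array(self.lin_ref)
        self.lin_cols = (self.colid[self.lin_k, self.lin_j]
                         if len(self.lin_k) else np.zeros(0, int))
        self.nlin = len(self.lin_k)
        self.d_scale = np.ones(max(len(self.effort_terms), 1))

    def _add_lin(self, k, j, w2, ref):
        self.lin_k.append(k)
        self.lin_j.append(j)
        self.lin_w.append(w2)
        self.lin_ref.append(ref)

    def refresh_displacement(self, X, C):
        """Update the frozen 1/d factors of effort terms from the iterate."""
        traj = self.trans.build_trajectory(X, C)
        self.d_vals = []
        for term, start, end in self.effort_terms:
            self.d_vals.append(effort_displacement(traj, term.cfg))

    def sqrt_weights(self):
        w = self.lin_w.copy()
        for (term, start, end), d in zip(self.effort_terms, self.d_vals):
            w[start:end] = w[start:end] / d
        return np.sqrt(w)

    def residuals(self, X, C):
        sw = self.sqrt_weights()
        Z = np.concatenate([X, C], axis=1)
        r = [sw * (Z[self.lin_k, self.lin_j] - self.lin_ref)]
        for term in self.grf_terms:
            r.append(self._grf_residual(term, X, C))
        return np.concatenate(r) if r else np.zeros(0)

    def _grf_residual(self, term, X, C):
        trans = self.trans
        eng = trans.engine
        q, u, a, e, r = trans.split(X, C)
        _, v = eng.node_eval(q, u, a, e, r, want_vgrf=True)
        vbw = v / eng.body_weight
        cfg = term.cfg
        viol = np.maximum(cfg.lower - vbw, 0.0) + np.maximum(vbw - cfg.upper, 0.0)
        return np.sqrt(cfg.weight * trans.trapw) * viol

    def jacobian(self, X, C):
        trans = self.trans
        sw = self.sqrt_weights()
        J = sp.coo_matrix((sw, (np.arange(self.nlin), self.lin_cols)),
                          shape=(self.nlin, trans.nz)).tocsr()
        blocks = [J]
        for term in self.grf_terms:
            blocks.append(self._grf_jacobian(term, X, C))
        return sp.vstack(blocks).tocsr() if len(blocks) > 1 else J

    def _grf_jacobian(self, term, X, C):
        trans = self.trans
        eng = trans.engine
        cfg = term.cfg
        q, u, a, e, r = trans.split(X, C)
        _, v0 = eng.node_eval(q, u, a, e, r, want_vgrf=True)
        vbw = v0 / eng.body_weight
        sign = (np.where(vbw > cfg.upper, 1.0, 0.0)
                - np.where(vbw < cfg.lower, 1.0, 0.0))
        pref = np.sqrt(cfg.weight * trans.trapw) * sign / eng.body_weight
        rows, cols, data = [], [], []
        active = np.flatnonzero(pref != 0.0)
        if len(active):
            eps = 1.0e-6
            nqu = 2 * trans.nf
            Qb, Ub, meta = [], [], []
            for k in active:
                for j in range(nqu):
                    if self.colid[k, j] < 0:
                        continue
                    qq, uu = q[k].copy(), u[k].copy()
                    if j < trans.nf:
                        qq[trans.free_coords[j]] += eps
                    else:
                        uu[trans.free_coords[j - trans.nf]] += eps
                    Qb.append(qq)
                    Ub.append(uu)
                    meta.append((k, j))
            if meta:
                ks = np.array([m[0] for m in meta])
                _, vp = eng.node_eval(np.array(Qb), np.array(Ub), a[ks],
                                      e[ks], r[ks], want_vgrf=True)
                for m, (k, j) in enumerate(meta):
                    rows.append(k)
                    cols.append(self.colid[k, j])
                    data.append(pref[k] * (vp[m] - v0[k]) / eps)
        return sp.coo_matrix((data, (rows, cols)),
                             shape=(trans.K, trans.nz)).tocsr()


def _bounded_lm(fun, jac, z0, lo, hi, maxiter, gtol=1e-10, verbose=0):
    """Projected Levenberg-Marquardt on 0.5*||fun||^2 with box bounds.

    The normal equations are factorized exactly with a sparse LU — the
    collocation Jacobian is block-banded, so this is fast and immune to
    the conditioning that starves iterative least-squares steps.  Steps
    are clipped into the box; a step is accepted when it reduces the cost.
    """
    from scipy.sparse.linalg import splu

    z = np.clip(z0, lo, hi)
    r = fun(z)
    cost = 0.5 * float(r @ r)
    lam = 1.0e-6
    nfev = 1
    status = 0
    J = None
    stale = 0
    for it in range(maxiter):
        # reuse the Jacobian across a few accepted steps: evaluating it is
        # the dominant cost and the linearization drifts slowly
        if J is None or stale >= 4:
            J = jac(z).tocsr()
            stale = 0
        g = J.T @ r
        # projected gradient: ignore pushes out of the box at active bounds
        pg = g.copy()
        pg[(z <= lo + 1e-12) & (g > 0)] = 0.0
        pg[(z >= hi - 1e-12) & (g < 0)] = 0.0
        if np.abs(pg).max() < gtol:
            status = 1
            break
        JtJ = (J.T @ J).tocsc()
        dscale = np.maximum(JtJ.diagonal(), 1e-10)
        accepted = False
        for _ in range(25):
            H = (JtJ + sp.diags(lam * dscale)).tocsc()
            try:
                dz = splu(H).solve(-g)
            except RuntimeError:
                lam *= 10.0
                continue
            znew = np.clip(z + dz, lo, hi)
            rn = fun(znew)
            nfev += 1
            costn = 0.5 * float(rn @ rn)
            if np.isfinite(costn) and costn < cost:
                rel = (cost - costn) / max(cost, 1e-300)
                z, r, cost = znew, rn, costn
                lam = max(lam / 3.0, 1e-12)
                accepted = True
                stale += 1
                break
            lam *= 4.0
            if lam > 1e14:
                break
        if verbose:
            print(f"    lm it {it}: cost={cost:.6e} lam={lam:.1e}")
        if not accepted:
            if stale:       # the stale linear model may be at fault: refresh
                J = None
                lam = max(lam / 64.0, 1e-12)
                continue
            status = 2
            break
        if rel < 1e-14:
            status = 3
            break
    return z, cost, nfev, status


def solve_collocation(problem: OCProblem,
                      settings: CollocationSettings | None = None,
                      engine: Engine | None = None) -> Solution:
    """Solve a collocation transcription of ``problem``; never raises on
    non-convergence — the status field reports it."""
    settings = settings or CollocationSettings()
    engine = engine or Engine(problem.model)
    try:
        trans = _Transcription(problem, engine, theta=settings.theta)
        resid = _ObjectiveResiduals(trans)
    except ValueError as err:
        if "inconsistent bounds" not in str(err):
            raise
        model = problem.model
        empty = Trajectory(np.array(problem.horizon),
                           model.coordinate_names, model.muscle_names,
                           [r.coordinate for r in model.reserves],
                           np.zeros((2, len(model.coordinates))),
                           np.zeros((2, len(model.coordinates))),
                           np.zeros((2, len(model.muscles))),
                           np.zeros((2, len(model.muscles))),
                           np.zeros((2, len(model.reserves))))
        return Solution(empty, CostBreakdown(), "infeasible", np.inf,
                        info={"error": str(err)})

    if settings.method == "trust-constr":
        return _solve_trust_constr(problem, settings, engine, trans)

    ndef = (trans.K - 1) * trans.nx
    lam = np.zeros(ndef)
    mu = settings.mu0
    z = trans.initial_point()
    if settings.restore_feasibility:
        # replace the guess states by a fine-step forward rollout of its
        # controls: the iterate then starts nearly feasible and the inner
        # solves only trade feasibility against optimality locally
        X, C = trans.unpack(z)
        q, u, a, e, r = trans.split(X, C)
        t0, tf = trans.times[0], trans.times[-1]
        restored = False
        try:
            rolled = trapezoid_rollout(engine, q[0], u[0], a[0], e, r,
                                       trans.times, theta=settings.theta)
            Xr = np.concatenate([rolled.q[:, trans.free_coords],
                                 rolled.u[:, trans.free_coords],
                                 rolled.a], axis=1)
            restored = True
        except (RuntimeError, np.linalg.LinAlgError):
            pass

        def _ctrl(t):
            ek = np.array([np.interp(t, trans.times, e[:, j])
                           for j in range(trans.nm)])
            rk = np.array([np.interp(t, trans.times, r[:, j])
                           for j in range(trans.nr)])
            return ek[None, :], rk[None, :]

        if not restored:
            rolled, alive = _rollout_population(
                engine, q[:1], u[:1], a[:1], _ctrl, t0, tf, 5.0e-4, 2,
                "semi_implicit")
            if alive[0]:
                rs = resample(rolled[0], trans.times)
                Xr = np.concatenate([rs.q[:, trans.free_coords],
                                     rs.u[:, trans.free_coords], rs.a], axis=1)
                restored = True
        if restored:
            Z0 = np.concatenate([Xr, C], axis=1)
            Z = np.clip(Z0, trans.lb, trans.ub)
            z = Z[trans.free_mask]
            if settings.verbose:
                Xc, Cc = trans.unpack(z)
                clip = np.abs(Z0 - Z)
                k, j = np.unravel_index(np.argmax(clip), clip.shape)
                print(f"  restoration: raw defect "
                      f"{trans.defect_norm_unscaled(trans.defects(Xr, C)):.2e}"
                      f", clipped {trans.defect_norm_unscaled(trans.defects(Xc, Cc)):.2e}"
                      f", clip {clip.max():.3f} at node {k} "
                      f"{trans.local_names[j]}")
        elif settings.verbose:
            print("  restoration failed; using raw guess")
    lo = trans.lb[trans.free_mask]
    hi = trans.ub[trans.free_mask]

    nfev_total = 0
    defect_norm = np.inf
    prev_defect = np.inf
    prev_obj = None
    for outer in range(settings.outer):
        X, C = trans.unpack(z)
        resid.refresh_displacement(X, C)
        smu = np.sqrt(mu)

        def fun(zz):
            X, C = trans.unpack(zz)
            d = trans.defects(X, C)
            return np.concatenate([smu * (d + lam / mu), resid.residuals(X, C)])

        def jac(zz):
            X, C = trans.unpack(zz)
            return sp.vstack([smu * trans.defect_jacobian(X, C),
                              resid.jacobian(X, C)]).tocsr()

        z, _, nfev, lm_status = _bounded_lm(
            fun, jac, z, lo, hi, settings.maxiter,
            verbose=max(settings.verbose - 1, 0))
        nfev_total += nfev
        X, C = trans.unpack(z)
        d = trans.defects(X, C)
        defect_norm = trans.defect_norm_unscaled(d)
        if settings.verbose:
            print(f"  outer {outer}: mu={mu:.1e} defect={defect_norm:.3e} "
                  f"lm_status={lm_status}")
        # stop once feasible and either the inner solve terminated on its
        # own or the objective has stagnated across outer rounds
        obj = trans.objective(X, C)
        if defect_norm <= settings.tol and outer >= 1:
            if lm_status != 0 or (prev_obj is not None and
                                  abs(obj - prev_obj)
                                  <= 1e-6 * max(1.0, abs(obj))):
                break
        prev_obj = obj
        lam = lam + mu * d
        # raise the penalty only when feasibility progress stalls
        if defect_norm > 0.25 * prev_defect:
            mu = min(mu * 10.0, settings.mu_max)
        prev_defect = defect_norm

    traj = trans.build_trajectory(X, C)
    cost = evaluate_cost(problem.objective_terms, traj, engine)
    if defect_norm <= settings.tol:
        status = "converged"
    elif defect_norm > 1000 * settings.tol:
        status = "infeasible"
    else:
        status = "max_iter"
    return Solution(traj, cost, status, defect_norm, nfev_total,
                    info={"mu_final": mu})


def _solve_trust_constr(problem, settings, engine, trans) -> Solution:
    """Sequential quadratic solve via scipy trust-constr; best suited to
    small, smooth transcriptions (toy verification problems)."""
    cache = {}

    def _eval(z):
        key = z.tobytes()
        if key not in cache:
            cache.clear()
            cache[key] = trans.unpack(z)
        return cache[key]

    def fun(z):
        return trans.objective(*_eval(z))

    def jac(z):
        return trans.objective_grad(*_eval(z))

    nlc = sopt.NonlinearConstraint(
        lambda z: trans.defects(*_eval(z)), 0.0, 0.0,
        jac=lambda z: trans.defect_jacobian(*_eval(z)))
    res = sopt.minimize(
        fun, trans.initial_point(), jac=jac,
        bounds=sopt.Bounds(trans.lb[trans.free_mask],
                           trans.ub[trans.free_mask]),
        constraints=[nlc], method="trust-constr",
        options=dict(maxiter=max(settings.maxiter * 5, 200), gtol=1e-10,
                     xtol=1e-12, verbose=settings.verbose))
    X, C = trans.unpack(res.x)
    traj = trans.build_trajectory(X, C)
    defect_norm = trans.defect_norm_unscaled(trans.defects(X, C))
    cost = evaluate_cost(problem.objective_terms, traj, engine)
    if defect_norm <= settings.tol and res.status != 0:
        status = "converged"
    elif defect_norm > 1000 * settings.tol:
        status = "infeasible"
    else:
        status = "max_iter"
    return Solution(traj, cost, status, defect_norm, int(res.niter),
                    info={"scipy_status": int(res.status)})


# ---------------------------------------------------------------------------
# forward simulation


def rollout(engine: Engine, q0, u0, a0, control_fn, t0, tf, dt,
            record_every: int = 1, integrator: str = "rk4") -> Trajectory:
    """Fixed-step forward integration of one state (convenience wrapper)."""
    traj, _ = _rollout_population(
        engine, np.atleast_2d(q0), np.atleast_2d(u0), np.atleast_2d(a0),
        lambda t: tuple(np.atleast_2d(x) for x in control_fn(t)),
        t0, tf, dt, record_every, integrator)
    return traj[0]


def _rollout_population(engine, Q0, U0, A0, control_fn, t0, tf, dt,
                        record_every, integrator="rk4"):
    """Integrate a population forward; returns trajectories and alive mask.

    ``semi_implicit`` uses symplectic Euler on (q, u) with an exact
    exponential update of the activation ODE — one dynamics evaluation per
    step, markedly more robust through stiff contact than explicit RK4.
    """
    nsteps = int(round((tf - t0) / dt))
    P = Q0.shape[0]
    q, u, a = Q0.copy(), U0.copy(), A0.copy()
    alive = np.ones(P, bool)
    free = engine.free
    rec_t, rec = [], []

    from .muscles import TAU_ACT, TAU_DEACT, activation_rate

    def deriv(q, u, a, e, r):
        qdd = engine.accelerations(q, u, a, r)
        return u.copy(), qdd, activation_rate(e, a)

    def record(t):
        rec_t.append(t)
        rec.append((q.copy(), u.copy(), a.copy()) + tuple(
            np.asarray(x).copy() for x in control_fn(t)))

    record(t0)
    for s in range(nsteps):
        t = t0 + s * dt
        if integrator == "semi_implicit":
            e1, r1 = control_fn(t)
            qdd = engine.accelerations(q, u, a, r1)
            du = dt * qdd
            dq = dt * (u + du)
            tau = np.where(np.atleast_2d(e1) > a, TAU_ACT, TAU_DEACT)
            a_new = e1 + (a - e1) * np.exp(-dt / tau)
            da = a_new - a
        else:
            e1, r1 = control_fn(t)
            e2, r2 = control_fn(t + dt / 2)
            e3, r3 = control_fn(t + dt)
            k1 = deriv(q, u, a, e1, r1)
            k2 = deriv(q + dt / 2 * k1[0], u + dt / 2 * k1[1],
                       np.clip(a + dt / 2 * k1[2], 0, 1), e2, r2)
            k3 = deriv(q + dt / 2 * k2[0], u + dt / 2 * k2[1],
                       np.clip(a + dt / 2 * k2[2], 0, 1), e2, r2)
            k4 = deriv(q + dt * k3[0], u + dt * k3[1],
                       np.clip(a + dt * k3[2], 0, 1), e3, r3)
            dq = dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            du = dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            da = dt / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        ok = (np.all(np.isfinite(dq), axis=1) & np.all(np.isfinite(du), axis=1)
              & (np.abs(u[:, free]).max(axis=1) < 2000.0)
              & (np.abs(q[:, free]).max(axis=1) < 50.0))
        alive &= ok
        upd = alive
        q[upd] += dq[upd]
        u[upd] += du[upd]
        a[upd] = np.clip(a[upd] + da[upd], 0.0, 1.0)
        if (s + 1) % record_every == 0 or s == nsteps - 1:
            record(t + dt)

    model = engine.model
    times = np.array(rec_t)
    trajs = []
    for pi in range(P):
        qs = np.array([fr[0][pi] for fr in rec])
        us = np.array([fr[1][pi] for fr in rec])
        as_ = np.array([fr[2][pi] for fr in rec])
        es = np.array([fr[3][pi] for fr in rec])
        rs = np.array([fr[4][pi] for fr in rec])
        trajs.append(Trajectory(times, model.coordinate_names,
                                model.muscle_names,
                                [r.coordinate for r in model.reserves],
                                qs, us, as_, es, rs))
    return trajs, alive


def trapezoid_rollout(engine: Engine, q0, u0, a0, E, R, times,
                      theta: float = 0.5) -> Trajectory:
    """Implicit one-step (theta-method) integration on ``times``: the result
    satisfies the collocation defect equations of :func:`solve_collocation`
    exactly for the same ``theta`` (0.5 trapezoid, 1.0 backward Euler).

    ``E`` (N, nm) and ``R`` (N, nres) are the controls at the grid points.
    """
    nf, nm = engine.nf, engine.nm
    free = engine.free
    N = len(times)

    def xvec(q, u, a):
        return np.concatenate([q[free], u[free], a])

    def unx(x, qtmpl):
        q = qtmpl.copy()
        q[free] = x[:nf]
        u = np.zeros_like(q)
        u[free] = x[nf:2 * nf]
        return q, u, x[2 * nf:]

    qt = engine.tree.full_q(np.atleast_2d(q0))[0]
    Q = np.tile(qt, (N, 1))
    U = np.zeros_like(Q)
    A = np.zeros((N, nm))
    Q[0], U[0], A[0] = qt, np.asarray(u0, float), np.asarray(a0, float)
    x = xvec(Q[0], U[0], A[0])
    nx = len(x)
    for k in range(N - 1):
        h = times[k + 1] - times[k]
        f_k, _ = engine.node_eval(Q[k], U[k], A[k], E[k], R[k])
        f_k = f_k[0]

        def residual(xn):
            qn, un, an = unx(xn, qt)
            f_n, _ = engine.node_eval(qn, un, np.clip(an, 0, 1),
                                      E[k + 1], R[k + 1])
            return xn - x - h * ((1.0 - theta) * f_k + theta * f_n[0])

        def jac(xn):
            eps = 1e-7
            base = residual(xn)
            Xp = xn[None, :] + eps * np.eye(nx)
            Qp = np.tile(qt, (nx, 1))
            Qp[:, free] = Xp[:, :nf]
            Up = np.zeros_like(Qp)
            Up[:, free] = Xp[:, nf:2 * nf]
            Ap = np.clip(Xp[:, 2 * nf:], 0, 1)
            fp, _ = engine.node_eval(Qp, Up, Ap, np.tile(E[k + 1], (nx, 1)),
                                     np.tile(R[k + 1], (nx, 1)))
            qn, un, an = unx(xn, qt)
            f_n, _ = engine.node_eval(qn, un, np.clip(an, 0, 1),
                                      E[k + 1], R[k + 1])
            return np.eye(nx) - theta * h * (fp - f_n[0]).T / eps

        res = sopt.root(residual, x + h * f_k, jac=jac, method="hybr",
                        tol=1e-13)
        if np.all(np.isfinite(res.x)) and np.abs(residual(res.x)).max() <= 1e-8:
            x = res.x
        else:
            # subdivide the interval with implicit substeps; the node value
            # is then only approximately defect-free on the coarse grid
            x = _implicit_substep(engine, x, times[k], times[k + 1],
                                  E[k], E[k + 1], R[k], R[k + 1],
                                  theta, unx, qt, free, nf, nx)
        Q[k + 1], U[k + 1], A[k + 1] = unx(x, qt)
        A[k + 1] = np.clip(A[k + 1], 0, 1)
    model = engine.model
    return Trajectory(np.asarray(times, float), model.coordinate_names,
                      model.muscle_names,
                      [r.coordinate for r in model.reserves],
                      Q, U, A, np.asarray(E, float), np.asarray(R, float))


def _implicit_substep(engine, x0, t0, t1, E0, E1, R0, R1, theta, unx, qt,
                      free, nf, nx, levels: int = 6):
    """Integrate one interval with recursively halved implicit steps."""
    for lev in range(1, levels + 1):
        nsub = 2 ** lev
        hs = (t1 - t0) / nsub
        x = x0.copy()
        ok = True
        for s in range(nsub):
            w0 = s / nsub
            w1 = (s + 1) / nsub
            Ek = E0 * (1 - w0) + E1 * w0
            Ek1 = E0 * (1 - w1) + E1 * w1
            Rk = R0 * (1 - w0) + R1 * w0
            Rk1 = R0 * (1 - w1) + R1 * w1
            q, u, a = unx(x, qt)
            f_k, _ = engine.node_eval(q, u, np.clip(a, 0, 1), Ek, Rk)
            f_k = f_k[0]

            def residual(xn):
                qn, un, an = unx(xn, qt)
                f_n, _ = engine.node_eval(qn, un, np.clip(an, 0, 1), Ek1, Rk1)
                return xn - x - hs * ((1.0 - theta) * f_k + theta * f_n[0])

            res = sopt.root(residual, x + hs * f_k, method="hybr", tol=1e-12)
            if not (np.all(np.isfinite(res.x))
                    and np.abs(residual(res.x)).max() <= 1e-8):
                ok = False
                break
            x = res.x
        if ok:
            return x
    raise RuntimeError(
        f"implicit step failed to converge on [{t0:.3f}, {t1:.3f}] even "
        "after subdivision; use a finer grid")


# ---------------------------------------------------------------------------
# CMA-ES shooting


class CMAES:
    """Compact covariance-matrix-adaptation evolution strategy (minimizing)."""

    def __init__(self, x0, sigma0, lower, upper, popsize=16, seed=0):
        self.n = len(x0)
        self.mean = np.asarray(x0, float).copy()
        self.sigma = float(sigma0)
        self.lo, self.hi = np.asarray(lower, float), np.asarray(upper, float)
        self.lam = int(popsize)
        self.mu = self.lam // 2
        w = np.log(self.mu + 0.5) - np.log(np.arange(1, self.mu + 1))
        self.w = w / w.sum()
        self.mueff = 1.0 / np.sum(self.w ** 2)
        n, mueff = self.n, self.mueff
        self.cs = (mueff + 2) / (n + mueff + 5)
        self.ds = 1 + 2 * max(0.0, np.sqrt((mueff - 1) / (n + 1)) - 1) + self.cs
        self.cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
        self.c1 = 2 / ((n + 1.3) ** 2 + mueff)
        self.cmu = min(1 - self.c1,
                       2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
        self.chiN = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n ** 2))
        self.C = np.eye(n)
        self.ps = np.zeros(n)
        self.pc = np.zeros(n)
        self.rng = np.random.default_rng(seed)
        self._decompose()
        self.count = 0

    def _decompose(self):
        d, B = np.linalg.eigh(self.C)
        self.D = np.sqrt(np.maximum(d, 1e-20))
        self.B = B

    def ask(self) -> np.ndarray:
        z = self.rng.standard_normal((self.lam, self.n))
        y = z @ (self.B * self.D).T
        x = self.mean + self.sigma * y
        return np.clip(x, self.lo, self.hi)

    def tell(self, X, fitness) -> None:
        order = np.argsort(fitness, kind="stable")
        Xs = X[order[:self.mu]]
        y = (Xs - self.mean) / self.sigma
        yw = self.w @ y
        self.mean = self.mean + self.sigma * yw
        Cinvhalf = self.B @ np.diag(1.0 / self.D) @ self.B.T
        self.ps = ((1 - self.cs) * self.ps
                   + np.sqrt(self.cs * (2 - self.cs) * self.mueff)
                   * (Cinvhalf @ yw))
        self.count += 1
        hs = (np.linalg.norm(self.ps)
              / np.sqrt(1 - (1 - self.cs) ** (2 * self.count))
              < (1.4 + 2 / (self.n + 1)) * self.chiN)
        self.pc = ((1 - self.cc) * self.pc
                   + hs * np.sqrt(self.cc * (2 - self.cc) * self.mueff) * yw)
        rank_mu = sum(wi * np.outer(yi, yi) for wi, yi in zip(self.w, y))
        self.C = ((1 - self.c1 - self.cmu) * self.C
                  + self.c1 * (np.outer(self.pc, self.pc)
                               + (not hs) * self.cc * (2 - self.cc) * self.C)
                  + self.cmu * rank_mu)
        self.sigma *= np.exp(self.cs / self.ds
                             * (np.linalg.norm(self.ps) / self.chiN - 1))
        self._decompose()


_BLOWUP_COST = 1.0e9


def _active_muscles(engine: Engine) -> list[int]:
    """Indices of muscles with a nonzero moment arm on any free coordinate."""
    from .tree import muscle_tendon_lengths_at

    if engine.nm == 0:
        return []
    model = engine.model
    q0 = model.default_pose()
    lmt0 = muscle_tendon_lengths_at(model, q0)
    spans = np.zeros(engine.nm, bool)
    for ci in engine.free:
        qp = q0.copy()
        qp[ci] += 1e-5
        arm = (muscle_tendon_lengths_at(model, qp) - lmt0) / 1e-5
        spans |= np.abs(arm) > 1e-6
    return list(np.flatnonzero(spans))


def solve_shooting(problem: OCProblem,
                   settings: ShootingSettings | None = None,
                   engine: Engine | None = None) -> Solution:
    """Optimize piecewise-linear control knots over forward rollouts."""
    settings = settings or ShootingSettings()
    engine = engine or Engine(problem.model)
    t0, tf = problem.horizon
    nm, nr = engine.nm, engine.nr
    knots = settings.knots
    knot_t = np.linspace(t0, tf, knots)

    # muscles spanning only locked coordinates cannot move the model:
    # exclude them from the search space (their excitation stays at rest)
    active = _active_muscles(engine)
    nact = len(active)
    nparam = (nact + nr) * knots
    lo = np.concatenate([np.zeros(nact * knots), -np.ones(nr * knots)])
    hi = np.ones(nparam)

    # initial state from bounds/defaults
    trans = _Transcription(problem, engine)
    q0 = engine.tree.locked_values.copy()
    u0 = np.zeros(engine.nc)
    for i, ci in enumerate(engine.free):
        lo0, hi0 = trans.lb[0, i], trans.ub[0, i]
        c = problem.model.coordinates[ci]
        q0[ci] = np.clip(c.default, lo0, hi0)
        lu, hu = trans.lb[0, trans.nf + i], trans.ub[0, trans.nf + i]
        u0[ci] = np.clip(0.0, lu, hu)
    a0 = np.zeros(nm)

    _REST = 0.02
    if problem.initial_guess is not None:
        g = problem.initial_guess
        x0 = np.concatenate([
            np.stack([np.interp(knot_t, g.time, g.e[:, j]) for j in active],
                     axis=0).ravel() if nact else np.zeros(0),
            np.stack([np.interp(knot_t, g.time, g.r[:, j]) for j in range(nr)],
                     axis=0).ravel() if nr else np.zeros(0)])
        q0[engine.free] = g.q[0, engine.free]
        u0[engine.free] = g.u[0, engine.free]
        a0 = g.a[0].copy()
    else:
        x0 = np.full(nparam, 0.05)
        x0[nact * knots:] = 0.0
    x0 = np.clip(x0, lo, hi)

    def evaluate(pop):
        P = pop.shape[0]
        Ea = pop[:, :nact * knots].reshape(P, nact, knots)
        R = pop[:, nact * knots:].reshape(P, nr, knots)

        def fn(t):
            wloc = np.clip((t - t0) / (tf - t0) * (knots - 1), 0, knots - 1)
            i0 = int(np.floor(wloc))
            i1 = min(i0 + 1, knots - 1)
            wfrac = wloc - i0
            e = np.full((P, nm), _REST)
            if nact:
                e[:, active] = Ea[:, :, i0] * (1 - wfrac) + Ea[:, :, i1] * wfrac
            return e, R[:, :, i0] * (1 - wfrac) + R[:, :, i1] * wfrac

        trajs, alive = _rollout_population(
            engine, np.tile(q0, (P, 1)), np.tile(u0, (P, 1)),
            np.tile(a0, (P, 1)), fn, t0, tf, settings.dt,
            settings.record_every, settings.integrator)
        fits = np.empty(P)
        breakdowns = []
        for pi in range(P):
            if not alive[pi]:
                fits[pi] = _BLOWUP_COST
                breakdowns.append(None)
                continue
            parts = evaluate_cost(problem.objective_terms, trajs[pi], engine)
            fits[pi] = parts.total
            breakdowns.append(parts)
        return trajs, fits, breakdowns

    es = CMAES(x0, settings.sigma0, lo, hi, settings.population, settings.seed)
    best = None
    history = []
    for gen in range(settings.generations):
        pop = es.ask()
        if gen == 0:
            pop[0] = x0      # keep the supplied guess in the first population
        trajs, fits, parts = evaluate(pop)
        es.tell(pop, fits)
        k = int(np.argmin(fits))
        if best is None or fits[k] < best[0]:
            best = (fits[k], trajs[k], parts[k], pop[k])
        history.append(float(fits[k]))

    fit, traj, parts, params = best
    if parts is None:
        parts = CostBreakdown(p_s=_BLOWUP_COST)
    status = "converged" if fit < _BLOWUP_COST else "max_iter"
    return Solution(traj, parts, status, 0.0, settings.generations,
                    info={"best_cost_trace": history, "params": params})
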