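"""Objective terms and penalty measures for the landing optimizations.

The shooting stage scores a forward rollout with a composite cost

    cost = p_s + p_j + p_GRF

where ``p_s = w_s (t_max - t_sim)/t_max`` penalizes falling (``t_sim`` is
the first time the COM-height ratio drops below a threshold ``th``, or the
full horizon if it never does), ``p_j = sum w_j |jR_m - jR_t|`` penalizes
joint angles straying from their desired values or ranges, and ``p_GRF``
integrates excursions of the body-weight-normalized vertical GRF outside a
configured band.

The collocation stages use a squared-control effort goal

    (1/d) * integral over [t_i, t_f] of sum_c w_c |x_c(t)|^p dt

normalized by the system displacement ``d``, and a state-tracking
objective: the time-integral of the weighted squared difference between
each tracked state and its reference.

All integrals use trapezoidal quadrature on the trajectory's own grid,
matching the transcription order of the collocation solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory import Trajectory

DISPLACEMENT_FLOOR = 0.01   # [m]


# ---------------------------------------------------------------------------
# configs


@dataclass
class StabilityMeasureConfig:
    th: float = 0.5        # COM-height ratio threshold
    w_s: float = 100.0     # penalty weight
    t_max: float = 1.0     # simulation horizon [s]

    def __post_init__(self):
        if not 0.0 < self.th <= 1.0:
            raise ValueError("th must lie in (0, 1]")
        if self.w_s < 0 or self.t_max <= 0:
            raise ValueError("need w_s >= 0 and t_max > 0")


@dataclass
class SimOutcome:
    """Result of a forward rollout, as seen by the stability measure."""

    t_sim: float                 # termination time [s]
    com_h_trace: np.ndarray      # COM height time series [m]
    com_h_in: float              # initial COM height [m]


@dataclass
class JointRangePenaltyConfig:
    weights: dict         # coordinate -> w_j
    targets: dict         # coordinate -> scalar target or (lo, hi) interval [rad]


@dataclass
class GRFPenaltyConfig:
    lower: float = 0.0    # [BW]
    upper: float = 3.0    # [BW]
    weight: float = 0.1

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError("lower threshold above upper")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


@dataclass
class EffortGoalConfig:
    w_c: float | dict = 1.0      # scalar or per-control-name weights
    p: float = 2.0               # exponent
    d_mode: str = "pelvis_displacement"   # or "unit"
    t_i: float | None = None
    t_f: float | None = None

    def __post_init__(self):
        if self.p < 1:
            raise ValueError("exponent must be >= 1")


@dataclass
class CostBreakdown:
    p_s: float = 0.0
    p_j: float = 0.0
    p_grf: float = 0.0
    effort: float = 0.0
    tracking: float = 0.0

    @property
    def total(self) -> float:
        return self.p_s + self.p_j + self.p_grf + self.effort + self.tracking


# ---------------------------------------------------------------------------
# measures


def termination_time(times, com_h_trace, com_h_in, th, t_max) -> float:
    """First time the COM-height ratio crosses below ``th`` (interpolated).

    Returns ``t_max`` if the trace never crosses within the horizon.
    """
    ratio = np.asarray(com_h_trace, float) / com_h_in
    below = ratio < th
    if not below.any():
        return float(t_max)
    k = int(np.argmax(below))
    if k == 0:
        return float(times[0])
    # linear interpolation of the crossing instant
    t0, t1 = times[k - 1], times[k]
    r0, r1 = ratio[k - 1], ratio[k]
    return float(min(t0 + (th - r0) / (r1 - r0) * (t1 - t0), t_max))


def stability_penalty(out: SimOutcome, cfg: StabilityMeasureConfig) -> float:
    if out.com_h_in <= 0:
        raise ValueError("initial COM height must be positive")
    if not 0.0 <= out.t_sim <= cfg.t_max + 1e-12:
        raise ValueError("t_sim outside [0, t_max]")
    return cfg.w_s * (cfg.t_max - out.t_sim) / cfg.t_max


def _dist_to_target(value: float, target) -> float:
    if np.isscalar(target):
        return abs(value - target)
    lo, hi = target
    return max(lo - value, 0.0) + max(value - hi, 0.0)


def joint_range_penalty(measured: dict, cfg: JointRangePenaltyConfig) -> float:
    """Sum of weighted deviations of measured joint values from their targets.

    Scalar targets use the absolute difference; interval targets use the
    distance to the nearest bound (zero inside the interval).
    """
    missing = set(cfg.weights) - set(measured)
    if missing:
        raise KeyError(f"measured values missing for {sorted(missing)}")
    total = 0.0
    for name, w in cfg.weights.items():
        if w < 0:
            raise ValueError(f"negative weight for {name}")
        total += w * _dist_to_target(measured[name], cfg.targets[name])
    return total


def grf_penalty(times, vgrf_bw, cfg: GRFPenaltyConfig) -> float:
    """Weighted time-integral of vGRF excursions outside [lower, upper] BW."""
    v = np.asarray(vgrf_bw, float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite GRF trace")
    violation = np.maximum(cfg.lower - v, 0.0) + np.maximum(v - cfg.upper, 0.0)
    return cfg.weight * float(np.trapezoid(violation, times))


def composite_cost(parts: CostBreakdown) -> float:
    """Stage-1 composite objective: stability + joint-range + GRF penalties."""
    return parts.p_s + parts.p_j + parts.p_grf


def _control_weights(traj: Trajectory, w_c) -> np.ndarray:
    names = traj.control_names
    if np.isscalar(w_c):
        return np.full(len(names), float(w_c))
    return np.array([float(w_c.get(nm, 0.0)) for nm in names])


def effort_displacement(traj: Trajectory, cfg: EffortGoalConfig) -> float:
    if cfg.d_mode == "unit":
        return 1.0
    if cfg.d_mode == "pelvis_displacement":
        d = traj.pelvis_displacement(cfg.t_i, cfg.t_f)
        if d < DISPLACEMENT_FLOOR:
            raise ValueError(
                f"displacement {d:.4f} m under d_mode="
                f"{cfg.d_mode!r} is below the {DISPLACEMENT_FLOOR} m floor")
        return d
    raise ValueError(f"unknown d_mode {cfg.d_mode!r}")


def effort_goal(traj: Trajectory, cfg: EffortGoalConfig) -> float:
    """Displacement-normalized integral of weighted |controls|^p."""
    t = traj.time
    t_i = t[0] if cfg.t_i is None else cfg.t_i
    t_f = t[-1] if cfg.t_f is None else cfg.t_f
    if not t_i < t_f:
        raise ValueError("need t_i < t_f")
    w = _control_weights(traj, cfg.w_c)
    x = np.abs(traj.controls()) ** cfg.p
    integrand = x @ w
    mask = (t >= t_i - 1e-12) & (t <= t_f + 1e-12)
    d = effort_displacement(traj, cfg)
    return float(np.trapezoid(integrand[mask], t[mask])) / d


def tracking_objective(traj: Trajectory, reference: Trajectory,
                       weights: dict) -> float:
    """Integrated weighted squared state error against a reference motion."""
    t = traj.time
    if t[0] < reference.time[0] - 1e-9 or t[-1] > reference.time[-1] + 1e-9:
        raise ValueError("reference does not cover the trajectory time span")
    total = np.zeros_like(t)
    for name, w in weights.items():
        if w == 0.0:
            continue
        if not reference.has_column(name):
            raise KeyError(f"reference trajectory lacks tracked column {name!r}")
        ref = np.interp(t, reference.time, reference.column(name))
        total += w * (traj.column(name) - ref) ** 2
    return float(np.trapezoid(total, t))
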