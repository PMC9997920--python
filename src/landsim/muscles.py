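"""Rigid-tendon Hill-type muscle model and first-order activation dynamics.

The muscle-tendon force is

    F = F0 * [a * f_L(l~) * f_V(v~) + f_P(l~)] * cos(pennation)

with the normalized fiber length ``l~ = (lmt - l_slack) / (cos(pennation) *
l_opt)`` under the rigid-tendon assumption, and ``v~`` the fiber velocity
normalized by ``v_max * l_opt``.  The three curves are the standard
phenomenological shapes: a Gaussian active force-length curve with
``f_L(1) = 1``, a Hill hyperbola for shortening blended C1-continuously
into a saturating lengthening branch with ``f_V(0) = 1``, and an
exponential passive curve with ``f_P(1) = 0``.  All expressions are smooth
enough for gradient-based collocation.
"""

from __future__ import annotations

import numpy as np

# curve shape constants (dimensionless, standard values for gait-model actuators)
FL_WIDTH = 0.60          # Gaussian width of the active force-length curve
FV_AF = 0.25             # Hill force-velocity shape factor
FV_FMAX = 1.4            # eccentric force plateau
FP_KPE = 4.0             # passive exponential shape
FP_E0 = 0.6              # passive strain at one normalized force

TAU_ACT = 0.010          # activation time constant [s]
TAU_DEACT = 0.040        # deactivation time constant [s]


def _smooth_pos(x, eps=1.0e-6):
    return 0.5 * (x + np.sqrt(x * x + eps))


def active_force_length(lnorm):
    """Gaussian active force-length curve, f_L(1) = 1."""
    d = np.asarray(lnorm) - 1.0
    return np.exp(-d * d / FL_WIDTH)


def force_velocity(vnorm):
    """Force-velocity curve; vnorm < 0 is shortening, f_V(0) = 1."""
    v = np.asarray(vnorm, float)
    shortening = _smooth_pos((1.0 + v) / (1.0 - v / FV_AF))
    k = (1.0 + 1.0 / FV_AF) / (FV_FMAX - 1.0)   # slope continuity at v = 0
    lengthening = 1.0 + (FV_FMAX - 1.0) * k * v / (k * v + 1.0)
    return np.where(v < 0.0, shortening, lengthening)


def passive_force_length(lnorm):
    """Exponential passive curve, zero at and below the optimal length."""
    strain = np.maximum(np.asarray(lnorm) - 1.0, 0.0)
    return (np.exp(FP_KPE * strain / FP_E0) - 1.0) / (np.exp(FP_KPE) - 1.0)


def hill_force(F0, l_opt, l_slack, v_max, pennation, a, lmt, vmt):
    """Vectorized rigid-tendon Hill muscle-tendon force [N] (always >= 0)."""
    cosp = np.cos(pennation)
    ln = (lmt - l_slack) / (l_opt * cosp)
    vn = vmt / (l_opt * cosp * v_max)
    return F0 * (a * active_force_length(ln) * force_velocity(vn)
                 + passive_force_length(ln)) * cosp


def muscle_force(m, a, lmt, vmt):
    """Hill force of a single :class:`~landsim.model.MuscleSpec` at one instant."""
    if not np.all(np.isfinite([a, lmt, vmt])):
        raise ValueError("non-finite muscle-force input")
    if not 0.0 <= a <= 1.0:
        raise ValueError("activation must lie in [0, 1]")
    if lmt <= 0:
        raise ValueError("muscle-tendon length must be positive")
    return float(hill_force(m.F0, m.l_opt, m.l_slack, m.v_max, m.pennation,
                            a, lmt, vmt))


def activation_rate(e, a, tau_act=TAU_ACT, tau_deact=TAU_DEACT):
    """First-order excitation-to-activation dynamics, da/dt [1/s]."""
    e = np.asarray(e, float)
    a = np.asarray(a, float)
    tau = np.where(e > a, tau_act, tau_deact)
    return (e - a) / tau
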