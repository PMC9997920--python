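"""Smoothed Hunt-Crossley sphere-on-plane contact with regularized friction.

The normal force of a sphere penetrating the ground plane (y = 0) by depth
``x`` at rate ``xdot`` is

    f_n = k * x^(3/2) * (1 + (3/2) * c * xdot)

clipped smoothly to be non-negative and vanishing for airborne spheres.
Friction opposes the tangential velocity of the contact point with a
tanh-regularized Coulomb term plus a viscous term,

    f_t = -f_n * (mu_d * tanh(|v_t| / v0) * v_t/|v_t| + mu_v * v_t),

with transition velocity ``v0`` = 0.2 m/s.  Both laws are continuous in
all arguments — a requirement of the collocation transcription.
"""

from __future__ import annotations

import numpy as np

from .model import ContactSphereSpec

PENETRATION_SMOOTHING = 2.0e-3   # [m]
CLIP_SMOOTHING = 0.05            # on the dissipation factor, dimensionless
TRANSITION_VELOCITY = 0.2        # [m/s]
_VEPS = 1.0e-6


def _smooth_pos(x, eps):
    return 0.5 * (x + np.sqrt(x * x + eps * eps))


def _hermite_pos(x, eps):
    """C1 positive part: exactly 0 below -eps, x above +eps."""
    x = np.asarray(x, float)
    mid = (x + eps) ** 2 / (4.0 * eps)
    return np.where(x <= -eps, 0.0, np.where(x >= eps, x, mid))


def hunt_crossley(stiffness, dissipation, mu_d, mu_v, penetration,
                  penetration_rate, vt):
    """Vectorized normal force (..,) and tangential force (.., 2)."""
    x = _hermite_pos(np.asarray(penetration, float), PENETRATION_SMOOTHING)
    hertz = stiffness * x ** 1.5
    damp = _smooth_pos(1.0 + 1.5 * dissipation * np.asarray(penetration_rate, float),
                       CLIP_SMOOTHING)
    fn = hertz * damp

    vt = np.asarray(vt, float)
    speed = np.sqrt(np.einsum("...i,...i->...", vt, vt) + _VEPS ** 2)
    coul = mu_d * np.tanh(speed / TRANSITION_VELOCITY) / speed
    ft = -fn[..., None] * (coul[..., None] + mu_v) * vt
    return fn, ft


def contact_force(sphere: ContactSphereSpec, penetration: float,
                  penetration_rate: float = 0.0,
                  tangential_velocity=(0.0, 0.0)):
    """Ground-frame force of one sphere; negative penetration = airborne.

    Returns ``(force, point)`` with ``force`` the 3-vector (fx, fn, fz) and
    ``point`` the contact point on the ground plane.
    """
    fn, ft = hunt_crossley(sphere.stiffness, sphere.dissipation,
                           sphere.mu_dynamic, sphere.mu_viscous,
                           penetration, penetration_rate,
                           np.asarray(tangential_velocity, float))
    force = np.array([ft[0], fn, ft[1]])
    return force
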