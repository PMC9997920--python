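"""Time-gridded state/control histories.

A :class:`Trajectory` stores coordinate values, speeds, activations,
excitations and reserve controls on a strictly increasing time grid, plus
optional derived force traces (GRF, muscle forces, joint loads).  State
columns are addressed by name: coordinates by their coordinate name,
speeds as ``<coordinate>_u`` and activations as ``<muscle>_a``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline


@dataclass
class Trajectory:
    time: np.ndarray                 # (N,), strictly increasing [s]
    coord_names: list[str]
    muscle_names: list[str]
    reserve_names: list[str]
    q: np.ndarray                    # (N, nc)
    u: np.ndarray                    # (N, nc)
    a: np.ndarray                    # (N, nm)
    e: np.ndarray                    # (N, nm)
    r: np.ndarray                    # (N, nres)
    derived: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time grid must be strictly increasing")

    # -- column access -----------------------------------------------------
    @property
    def state_names(self) -> list[str]:
        return (list(self.coord_names)
                + [f"{c}_u" for c in self.coord_names]
                + [f"{m}_a" for m in self.muscle_names])

    @property
    def control_names(self) -> list[str]:
        return ([f"{m}_e" for m in self.muscle_names]
                + [f"reserve_{c}" for c in self.reserve_names])

    def states(self) -> np.ndarray:
        return np.concatenate([self.q, self.u, self.a], axis=1)

    def controls(self) -> np.ndarray:
        return np.concatenate([self.e, self.r], axis=1)

    def column(self, name: str) -> np.ndarray:
        if name in self.coord_names:
            return self.q[:, self.coord_names.index(name)]
        if name.endswith("_u") and name[:-2] in self.coord_names:
            return self.u[:, self.coord_names.index(name[:-2])]
        if name.endswith("_a") and name[:-2] in self.muscle_names:
            return self.a[:, self.muscle_names.index(name[:-2])]
        if name.endswith("_e") and name[:-2] in self.muscle_names:
            return self.e[:, self.muscle_names.index(name[:-2])]
        if name.startswith("reserve_") and name[8:] in self.reserve_names:
            return self.r[:, self.reserve_names.index(name[8:])]
        raise KeyError(f"unknown trajectory column {name!r}")

    def has_column(self, name: str) -> bool:
        try:
            self.column(name)
            return True
        except KeyError:
            return False

    # -- geometry helpers --------------------------------------------------
    def pelvis_displacement(self, t_i=None, t_f=None) -> float:
        """Planar displacement magnitude of the pelvis origin over [t_i, t_f]."""
        t_i = self.time[0] if t_i is None else t_i
        t_f = self.time[-1] if t_f is None else t_f
        out = []
        for nm in ("pelvis_tx", "pelvis_ty"):
            x = self.column(nm)
            out.append(np.interp(t_f, self.time, x)
                       - np.interp(t_i, self.time, x))
        return float(np.hypot(*out))

    def copy(self) -> "Trajectory":
        return Trajectory(self.time.copy(), list(self.coord_names),
                          list(self.muscle_names), list(self.reserve_names),
                          self.q.copy(), self.u.copy(), self.a.copy(),
                          self.e.copy(), self.r.copy(), dict(self.derived))

    # -- plotting ----------------------------------------------------------
    def plot(self, columns=None, ax=None):
        """Quick time-series plot of selected columns (default: coordinates)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for nm in (columns or self.coord_names):
            ax.plot(self.time, self.column(nm), label=nm)
        ax.set_xlabel("time [s]")
        ax.legend(fontsize=7)
        return ax


def resample(traj: Trajectory, new_grid: np.ndarray) -> Trajectory:
    """Cubic interpolation of states, linear of controls, onto ``new_grid``.

    The new grid must lie within the original time span.
    """
    new_grid = np.asarray(new_grid, float)
    t = traj.time
    if new_grid[0] < t[0] - 1e-12 or new_grid[-1] > t[-1] + 1e-12:
        raise ValueError("resample grid extends beyond the trajectory span")
    if len(new_grid) == len(t) and np.allclose(new_grid, t):
        return traj.copy()

    def cubic(arr):
        if arr.shape[1] == 0 or len(t) < 4:
            return _linear(arr)
        return CubicSpline(t, arr, axis=0)(np.clip(new_grid, t[0], t[-1]))

    def _linear(arr):
        out = np.empty((len(new_grid), arr.shape[1]))
        for j in range(arr.shape[1]):
            out[:, j] = np.interp(new_grid, t, arr[:, j])
        return out

    return Trajectory(new_grid, list(traj.coord_names),
                      list(traj.muscle_names), list(traj.reserve_names),
                      cubic(traj.q), cubic(traj.u), cubic(traj.a),
                      _linear(traj.e), _linear(traj.r))
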