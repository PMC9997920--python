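"""ACL-injury risk indicators extracted at the instant of peak vertical GRF.

Every what-if scenario is summarized by one row: the peak vertical
ground-reaction force of the landing (left) foot in body weights, and — all
sampled at that same instant — the knee joint reaction force components AF
(anterior, +), MF (medial, +) and CF (compressive, −) in BW, the knee
joint reaction moments AbdM (abduction, +) and IRM (internal rotation, −)
normalized by body weight (divisor BW in newtons, so the moment columns
carry units of meters), and the summed quadriceps and hamstrings tendon
forces in newtons with their Q/H ratio.

Peak detection uses the solver mesh directly (single-instant sampling, no
smoothing); an optional parabolic refinement of the peak time is available
but reports still sample model quantities at the nearest mesh node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import Control, Engine, State
from .model import ModelSpec
from .trajectory import Trajectory

#: CSV column headers matching the result tables of the study layout
REPORT_COLUMNS = ["scenario", "vGRF", "AF(+)", "MF(+)", "CF(-)", "AbdM(+)",
                  "IRM(-)", "QuadForce", "HamForce", "Q/H_ratio", "t_peak",
                  "flagged"]


@dataclass
class RiskFactorReport:
    scenario_id: str
    peak_vgrf: float          # [BW]
    t_peak: float             # [s]
    af: float                 # anterior knee force [BW], + anterior
    mf: float                 # medial knee force [BW], + medial
    cf: float                 # compressive knee force [BW], compression < 0
    abdm: float               # abduction moment / BW [m], + abduction
    irm: float                # internal-rotation moment / BW [m], internal < 0
    quad_force: float         # [N]
    ham_force: float          # [N]
    qh_ratio: float
    flagged: bool = False
    note: str = ""

    def row(self) -> dict:
        return {"scenario": self.scenario_id, "vGRF": self.peak_vgrf,
                "AF(+)": self.af, "MF(+)": self.mf, "CF(-)": self.cf,
                "AbdM(+)": self.abdm, "IRM(-)": self.irm,
                "QuadForce": self.quad_force, "HamForce": self.ham_force,
                "Q/H_ratio": self.qh_ratio, "t_peak": self.t_peak,
                "flagged": self.flagged}

    def summary(self) -> str:
        lines = [f"Risk factors at peak vGRF — {self.scenario_id}",
                 "-" * 46]
        for k, v in self.row().items():
            if k == "scenario":
                continue
            lines.append(f"{k:<10}: {v}")
        if self.note:
            lines.append(f"note      : {self.note}")
        return "\n".join(lines)


def peak_vgrf(times, vgrf_trace, body_weight,
              refine: bool = False) -> tuple[float, float, bool]:
    """Peak of a vertical-GRF trace in body weights and its time.

    Ties break to the earliest sample.  Returns ``(value_bw, t_peak,
    flagged)`` where ``flagged`` marks an all-zero (no contact) trace.
    """
    v = np.asarray(vgrf_trace, float)
    times = np.asarray(times, float)
    if v.size == 0 or body_weight <= 0:
        raise ValueError("empty trace or non-positive body weight")
    if np.allclose(v, 0.0, atol=1e-9):
        return 0.0, float(times[0]), True
    k = int(np.argmax(v))   # argmax returns the first maximal sample
    t_pk = float(times[k])
    if refine and 0 < k < len(v) - 1:
        y0, y1, y2 = v[k - 1], v[k], v[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            t_pk = float(times[k] + 0.5 * (y0 - y2) / denom
                         * (times[k + 1] - times[k]))
    return float(v[k] / body_weight), t_pk, False


def muscle_group_force(traj: Trajectory, group: str, t: float,
                       model: ModelSpec, engine: Engine | None = None) -> float:
    """Summed tendon force [N] of a muscle group at time ``t`` (interpolated)."""
    if not traj.time[0] - 1e-9 <= t <= traj.time[-1] + 1e-9:
        raise ValueError("t outside the trajectory span")
    members = model.muscles_in_group(group)
    if not members:
        raise KeyError(f"model has no muscles in group {group!r}")
    engine = engine or Engine(model)
    forces = engine.muscle_forces_batch(traj.q, traj.u, traj.a)
    idx = [model.muscle_names.index(m.name) for m in members]
    total = forces[:, idx].sum(axis=1)
    return float(np.interp(t, traj.time, total))


def qh_ratio(quad_force: float, ham_force: float) -> float:
    """Quadriceps-to-hamstrings force ratio; undefined for ham_force <= 0."""
    if ham_force <= 0:
        raise ValueError("hamstrings force must be positive for a Q/H ratio")
    return quad_force / ham_force


def report_at_peak(solution, model: ModelSpec, scenario_id: str = "",
                   engine: Engine | None = None,
                   refine_peak: bool = False) -> RiskFactorReport:
    """Assemble the full risk-factor row of one solved scenario."""
    engine = engine or Engine(model)
    traj = solution.trajectory
    bw = engine.body_weight
    vgrf = traj.derived.get("vgrf_left")
    if vgrf is None:
        vgrf = engine.grf_batch(traj.q, traj.u, traj.a, "l")[:, 1]
    peak, t_pk, flagged = peak_vgrf(traj.time, vgrf, bw, refine=refine_peak)
    k = int(np.argmin(np.abs(traj.time - t_pk)))

    state = State(traj.q[k], traj.u[k], traj.a[k])
    control = Control(traj.e[k], traj.r[k])
    note = "moments normalized by BW in newtons (units m)"
    if flagged:
        return RiskFactorReport(scenario_id, 0.0, t_pk, *np.zeros(5),
                                0.0, 0.0, np.nan, flagged=True,
                                note="no ground contact; " + note)
    load = engine.joint_reaction(state, control, "knee_l")
    af, cf, mf = (load.force / bw)           # tibia frame: x ant, y prox, z med
    abdm, irm, _ = (load.moment / bw)

    forces = engine.muscle_forces_batch(traj.q[k], traj.u[k], traj.a[k])[0]
    quad = sum(forces[model.muscle_names.index(m.name)]
               for m in model.muscles_in_group("quadriceps"))
    ham = sum(forces[model.muscle_names.index(m.name)]
              for m in model.muscles_in_group("hamstrings"))
    if ham > 0:
        ratio = qh_ratio(quad, ham)
    else:
        ratio, flagged = np.nan, True
        note = "hamstrings force non-positive; " + note
    return RiskFactorReport(scenario_id, peak, t_pk, float(af), float(mf),
                            float(cf), float(abdm), float(irm), float(quad),
                            float(ham), float(ratio), flagged, note)


def report_table(reports) -> pd.DataFrame:
    """Stack per-scenario reports into the study's result-table layout."""
    df = pd.DataFrame([r.row() for r in reports])
    return df.reindex(columns=REPORT_COLUMNS) if len(df) else \
        pd.DataFrame(columns=REPORT_COLUMNS)
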