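"""Motion-storage text dialect reader/writer (.sto/.mot-compatible).

The dialect is the tab-delimited time-series format of the OpenSim tool
family: a free-form header terminated by ``endheader`` carrying ``name``,
``nRows``, ``nColumns`` and ``inDegrees`` keys, one line of column labels
(first column ``time``), then whitespace-delimited numeric rows.  Numbers
are written with 8 significant digits, so write-then-read round-trips at
that precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory import Trajectory


class StorageParseError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        where = f" (line {line})" if line is not None else ""
        super().__init__(message + where)


@dataclass
class StorageDocument:
    name: str
    column_labels: list[str]
    rows: np.ndarray                  # (n, len(labels)); first column time
    in_degrees: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.rows = np.atleast_2d(np.asarray(self.rows, float))
        if self.rows.size and self.rows.shape[1] != len(self.column_labels):
            raise StorageParseError("row width does not match label count")
        if self.column_labels and self.column_labels[0] != "time":
            raise StorageParseError("first column must be 'time'")
        t = self.rows[:, 0] if self.rows.size else np.zeros(0)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise StorageParseError("time column must be strictly increasing")

    def column(self, label: str) -> np.ndarray:
        return self.rows[:, self.column_labels.index(label)]


def write_storage(doc: StorageDocument, path) -> str:
    path = str(path)
    n, m = doc.rows.shape if doc.rows.size else (0, len(doc.column_labels))
    with open(path, "w") as fh:
        fh.write(f"{doc.name}\n")
        fh.write(f"version=1\n")
        fh.write(f"nRows={n}\n")
        fh.write(f"nColumns={m}\n")
        fh.write(f"inDegrees={'yes' if doc.in_degrees else 'no'}\n")
        for k, v in doc.metadata.items():
            fh.write(f"{k}={v}\n")
        fh.write("endheader\n")
        fh.write("\t".join(doc.column_labels) + "\n")
        for row in doc.rows:
            fh.write("\t".join(f"{v:.8g}" for v in row) + "\n")
    return path


def read_storage(path) -> StorageDocument:
    name = ""
    in_degrees = False
    meta = {}
    nrows = ncols = None
    with open(path) as fh:
        lines = fh.readlines()
    k = 0
    seen_end = False
    for k, line in enumerate(lines):
        s = line.strip()
        if s == "endheader":
            seen_end = True
            break
        if "=" in s:
            key, _, val = s.partition("=")
            key, val = key.strip(), val.strip()
            if key == "nRows":
                nrows = int(val)
            elif key == "nColumns":
                ncols = int(val)
            elif key == "inDegrees":
                in_degrees = val.lower() in ("yes", "true", "1")
            elif key != "version":
                meta[key] = val
        elif s and k == 0:
            name = s
    if not seen_end:
        raise StorageParseError("missing 'endheader' sentinel")
    body = [ln for ln in lines[k + 1:] if ln.strip()]
    if not body:
        raise StorageParseError("missing column label line", k + 2)
    labels = body[0].split()
    rows = []
    for i, ln in enumerate(body[1:], start=k + 3):
        vals = ln.split()
        if len(vals) != len(labels):
            raise StorageParseError(
                f"ragged row: {len(vals)} values for {len(labels)} columns",
                i)
        try:
            rows.append([float(v) for v in vals])
        except ValueError:
            raise StorageParseError("non-numeric value", i) from None
    rows = np.array(rows) if rows else np.zeros((0, len(labels)))
    if nrows is not None and nrows != len(rows):
        raise StorageParseError(
            f"header declares nRows={nrows}, body has {len(rows)}")
    if ncols is not None and ncols != len(labels):
        raise StorageParseError(
            f"header declares nColumns={ncols}, body has {len(labels)}")
    try:
        return StorageDocument(name, labels, rows, in_degrees, meta)
    except StorageParseError as err:
        raise StorageParseError(str(err)) from None


def force_traces_to_storage(engine, traj: Trajectory,
                            name: str = "forces") -> StorageDocument:
    """GRF, per-muscle tendon forces and knee loads along a trajectory."""
    import numpy as _np

    grf_l = engine.grf_batch(traj.q, traj.u, traj.a, "l")
    grf_r = engine.grf_batch(traj.q, traj.u, traj.a, "r")
    muscle = engine.muscle_forces_batch(traj.q, traj.u, traj.a)
    from .dynamics import Control, State

    knee = []
    has_knee = any(c.joint == "knee_l"
                   for c in engine.model.coordinates)
    for k in range(len(traj.time)):
        if not has_knee:
            break
        load = engine.joint_reaction(
            State(traj.q[k], traj.u[k], traj.a[k]),
            Control(traj.e[k], traj.r[k]), "knee_l")
        knee.append(_np.concatenate([load.force, load.moment]))
    labels = (["time"]
              + [f"grf_l_{c}" for c in "xyz"]
              + [f"grf_r_{c}" for c in "xyz"]
              + [f"{m}_force" for m in traj.muscle_names])
    cols = [traj.time[:, None], grf_l, grf_r, muscle]
    if knee:
        labels += ["knee_l_fx", "knee_l_fy", "knee_l_fz",
                   "knee_l_mx", "knee_l_my", "knee_l_mz"]
        cols.append(_np.array(knee))
    return StorageDocument(name, labels, _np.column_stack(cols),
                           metadata={"moment_normalization":
                                     "raw N m (divide by BW in N for "
                                     "body-weight units)"})


# -- trajectory interchange --------------------------------------------------

def trajectory_to_storage(traj: Trajectory, name: str = "motion",
                          in_degrees: bool = False,
                          model=None) -> StorageDocument:
    """States and controls of a trajectory as one storage document."""
    labels = (["time"] + traj.state_names + traj.control_names)
    rows = np.column_stack([traj.time, traj.states(), traj.controls()])
    if in_degrees:
        if model is None:
            raise ValueError("writing in degrees requires the model (to "
                             "tell rotational from translational columns)")
        rot = {c.name for c in model.coordinates if c.kind == "rotational"}
        rows = rows.copy()
        for j, lab in enumerate(labels):
            base = lab[:-2] if lab.endswith("_u") else lab
            if base in rot:
                rows[:, j] = np.rad2deg(rows[:, j])
    return StorageDocument(name, labels, rows, in_degrees)


def storage_to_trajectory(doc: StorageDocument, model) -> Trajectory:
    """Rebuild a trajectory for ``model`` from a storage document.

    Angle columns are converted to radians when the document is in degrees.
    """
    cn = model.coordinate_names
    mn = model.muscle_names
    rn = [r.coordinate for r in model.reserves]
    t = doc.column("time")
    N = len(t)

    def col(label, default=0.0):
        if label in doc.column_labels:
            return doc.column(label).copy()
        return np.full(N, default)

    q = np.stack([col(c) for c in cn], axis=1)
    u = np.stack([col(f"{c}_u") for c in cn], axis=1)
    a = (np.stack([col(f"{m}_a") for m in mn], axis=1)
         if mn else np.zeros((N, 0)))
    e = (np.stack([col(f"{m}_e") for m in mn], axis=1)
         if mn else np.zeros((N, 0)))
    r = (np.stack([col(f"reserve_{c}") for c in rn], axis=1)
         if rn else np.zeros((N, 0)))
    if doc.in_degrees:
        for j, c in enumerate(model.coordinates):
            if c.kind == "rotational":
                q[:, j] = np.deg2rad(q[:, j])
                u[:, j] = np.deg2rad(u[:, j])
    return Trajectory(t, cn, mn, rn, q, u, a, e, r)
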