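"""Risk-factor extraction at the peak-vGRF instant."""

import numpy as np
import pytest

import landsim as ls
from landsim.objectives import CostBreakdown
from landsim.ocp import Solution
from landsim.risk_factors import (muscle_group_force, peak_vgrf, qh_ratio,
                                  report_at_peak, report_table)
from landsim.trajectory import Trajectory


class TestPeakVgrf:
    def test_constant_stance_trace(self):
        t = np.linspace(0, 1, 11)
        bw = 737.3
        val, t_pk, flagged = peak_vgrf(t, np.full(11, bw), bw)
        assert val == pytest.approx(1.0)
        assert t_pk == t[0] and not flagged     # ties break earliest

    def test_triangular_pulse(self):
        t = np.linspace(0, 0.24, 25)
        bw = 500.0
        v = np.interp(t, [0, 0.1, 0.12, 0.2, 0.24], [0, 0, 2 * bw, 0, 0])
        val, t_pk, flagged = peak_vgrf(t, v, bw)
        assert val == pytest.approx(2.0)
        assert t_pk == pytest.approx(0.12)

    def test_noisy_trace_matches_exhaustive_scan(self, rng):
        t = np.linspace(0, 1, 400)
        v = np.abs(rng.normal(500, 200, 400))
        val, t_pk, _ = peak_vgrf(t, v, 700.0)
        best = max(range(400), key=lambda k: v[k])
        assert t_pk == t[best] and val == pytest.approx(v[best] / 700.0)

    def test_no_contact_is_flagged_not_raised(self):
        t = np.linspace(0, 1, 5)
        val, t_pk, flagged = peak_vgrf(t, np.zeros(5), 700.0)
        assert flagged and val == 0.0


class TestQHRatio:
    @pytest.mark.parametrize("quad, ham, expected", [
        (4508.183, 663.738, 6.792),
        (4210.184, 324.788, 12.963),
        (2027.969, 674.048, 3.009),
    ])
    def test_published_force_pairs(self, quad, ham, expected):
        assert round(qh_ratio(quad, ham), 3) == pytest.approx(expected)

    def test_identity(self, rng):
        x = float(rng.uniform(10, 5000))
        assert qh_ratio(x, x) == pytest.approx(1.0)

    def test_nonpositive_hamstrings_rejected(self):
        with pytest.raises(ValueError):
            qh_ratio(1000.0, 0.0)


class TestMuscleGroupForce:
    def test_quiet_muscles_at_reference_pose_give_zero(self, engine3d,
                                                       model3d):
        q = np.tile(model3d.default_pose(), (3, 1))
        traj = Trajectory(np.array([0.0, 0.1, 0.2]),
                          model3d.coordinate_names, model3d.muscle_names,
                          [r.coordinate for r in model3d.reserves],
                          q, np.zeros_like(q), np.zeros((3, 12)),
                          np.zeros((3, 12)), np.zeros((3, 16)))
        f = muscle_group_force(traj, "soleus", 0.1, model3d, engine3d)
        assert f == pytest.approx(0.0, abs=2.0)

    def test_matches_per_muscle_summation_oracle(self, engine3d, model3d,
                                                 rng):
        N = 5
        q = np.tile(model3d.default_pose(), (N, 1))
        q[:, engine3d.free] += rng.normal(0, 0.05, (N, engine3d.nf))
        a = rng.uniform(0, 1, (N, 12))
        traj = Trajectory(np.linspace(0, 0.4, N),
                          model3d.coordinate_names, model3d.muscle_names,
                          [r.coordinate for r in model3d.reserves],
                          q, np.zeros_like(q), a, a, np.zeros((N, 16)))
        t = 0.2
        total = muscle_group_force(traj, "quadriceps", t, model3d, engine3d)
        forces = engine3d.muscle_forces_batch(traj.q, traj.u, traj.a)
        idx = [model3d.muscle_names.index(m.name)
               for m in model3d.muscles_in_group("quadriceps")]
        oracle = np.interp(t, traj.time, forces[:, idx].sum(axis=1))
        assert total == pytest.approx(oracle, abs=1e-9)

    def test_unknown_group_raises(self, engine3d, model3d):
        traj = Trajectory(np.array([0.0, 1.0]), model3d.coordinate_names,
                          model3d.muscle_names,
                          [r.coordinate for r in model3d.reserves],
                          np.tile(model3d.default_pose(), (2, 1)),
                          np.zeros((2, 23)), np.zeros((2, 12)),
                          np.zeros((2, 12)), np.zeros((2, 16)))
        with pytest.raises(KeyError):
            muscle_group_force(traj, "wings", 0.5, model3d, engine3d)


class TestReportAtPeak:
    def _solution(self, model, q, a=None, N=5):
        nmus = len(model.muscles)
        nres = len(model.reserves)
        qs = np.tile(q, (N, 1))
        a = np.zeros((N, nmus)) if a is None else np.tile(a, (N, 1))
        traj = Trajectory(np.linspace(0, 0.2, N), model.coordinate_names,
                          model.muscle_names,
                          [r.coordinate for r in model.reserves],
                          qs, np.zeros_like(qs), a, a, np.zeros((N, nres)))
        return Solution(traj, CostBreakdown(), "converged", 0.0)

    def test_no_contact_trajectory_is_flagged(self, model3d):
        q = model3d.default_pose()
        q[1] = 2.0
        rep = report_at_peak(self._solution(model3d, q), model3d, "air")
        assert rep.flagged and rep.peak_vgrf == 0.0

    def test_static_stance_reports_body_weight_and_compression(
            self, stance_solution):
        from landsim.pipeline import _pipeline_model

        model = _pipeline_model()
        rep = report_at_peak(stance_solution, model, "stance")
        assert rep.peak_vgrf == pytest.approx(1.0, abs=0.02)
        assert rep.cf < 0.0
        assert rep.qh_ratio == pytest.approx(rep.quad_force / rep.ham_force,
                                             abs=1e-9)

    def test_rerun_is_bit_identical(self, stance_solution):
        from landsim.pipeline import _pipeline_model

        model = _pipeline_model()
        r1 = report_at_peak(stance_solution, model, "s")
        r2 = report_at_peak(stance_solution, model, "s")
        assert r1 == r2

    def test_report_table_layout(self, model3d):
        q = model3d.default_pose()
        q[1] = 2.0
        rep = report_at_peak(self._solution(model3d, q), model3d, "row")
        df = report_table([rep])
        assert list(df.columns[:10]) == ["scenario", "vGRF", "AF(+)",
                                         "MF(+)", "CF(-)", "AbdM(+)",
                                         "IRM(-)", "QuadForce", "HamForce",
                                         "Q/H_ratio"]
        assert len(df) == 1
        assert report_table([]).empty
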