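"""Objective measures: worked examples and brute-force quadrature oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from landsim.objectives import (CostBreakdown, EffortGoalConfig,
                                GRFPenaltyConfig, JointRangePenaltyConfig,
                                SimOutcome, StabilityMeasureConfig,
                                composite_cost, effort_goal, grf_penalty,
                                joint_range_penalty, stability_penalty,
                                termination_time, tracking_objective)
from landsim.trajectory import Trajectory


def _traj(time, controls=None, q_cols=None, nm=1, nres=0):
    time = np.asarray(time, float)
    N = len(time)
    q = np.zeros((N, 2))
    coord_names = ["pelvis_tx", "pelvis_ty"]
    if q_cols is not None:
        q = np.asarray(q_cols, float)
    e = np.zeros((N, nm)) if controls is None else np.asarray(controls, float)
    return Trajectory(time, coord_names, [f"m{i}" for i in range(nm)],
                      [f"r{i}" for i in range(nres)], q, np.zeros_like(q),
                      np.zeros((N, nm)), e, np.zeros((N, nres)))


class TestStabilityPenalty:
    def test_survival_gives_zero(self):
        cfg = StabilityMeasureConfig(th=0.5, w_s=100.0, t_max=2.0)
        out = SimOutcome(2.0, np.full(10, 1.0), 1.0)
        assert stability_penalty(out, cfg) == 0.0

    def test_direct_substitution(self):
        cfg = StabilityMeasureConfig(th=0.5, w_s=100.0, t_max=2.0)
        out = SimOutcome(0.5, np.full(10, 1.0), 1.0)
        assert stability_penalty(out, cfg) == pytest.approx(75.0)

    def test_crossing_time_matches_dense_resampling_oracle(self):
        # COM ratio decays linearly: crossing time is analytic
        t = np.linspace(0.0, 2.0, 41)
        com = 1.0 - 0.4 * t          # ratio crosses 0.5 at t = 1.25
        t_sim = termination_time(t, com, 1.0, 0.5, 2.0)
        dense_t = np.linspace(0.0, 2.0, 200001)
        dense = 1.0 - 0.4 * dense_t
        k = np.argmax(dense < 0.5)
        assert t_sim == pytest.approx(dense_t[k], abs=t[1] - t[0])
        assert t_sim == pytest.approx(1.25, abs=1e-9)

    def test_monotone_in_t_sim(self):
        cfg = StabilityMeasureConfig(th=0.5, w_s=100.0, t_max=2.0)
        pens = [stability_penalty(SimOutcome(ts, np.ones(3), 1.0), cfg)
                for ts in (0.2, 0.8, 1.4, 2.0)]
        assert pens == sorted(pens, reverse=True)

    def test_invalid_com_height_raises(self):
        cfg = StabilityMeasureConfig()
        with pytest.raises(ValueError):
            stability_penalty(SimOutcome(0.5, np.ones(3), -1.0), cfg)


class TestJointRangePenalty:
    def test_on_target_is_zero(self):
        cfg = JointRangePenaltyConfig(weights={"knee": 1.0},
                                      targets={"knee": 0.4})
        assert joint_range_penalty({"knee": 0.4}, cfg) == 0.0

    def test_scalar_formula(self):
        cfg = JointRangePenaltyConfig(weights={"knee": 2.0},
                                      targets={"knee": 0.5})
        assert joint_range_penalty({"knee": 0.6}, cfg) == pytest.approx(0.2)

    def test_interval_uses_distance_to_nearest_bound(self):
        cfg = JointRangePenaltyConfig(weights={"knee": 1.0},
                                      targets={"knee": (0.2, 0.8)})
        assert joint_range_penalty({"knee": 0.5}, cfg) == 0.0
        assert joint_range_penalty({"knee": 0.95}, cfg) == pytest.approx(0.15)
        assert joint_range_penalty({"knee": 0.1}, cfg) == pytest.approx(0.1)

    def test_matches_elementwise_loop_oracle(self, rng):
        names = [f"c{i}" for i in range(6)]
        w = dict(zip(names, rng.uniform(0, 3, 6)))
        tgt = dict(zip(names, rng.uniform(-1, 1, 6)))
        meas = dict(zip(names, rng.uniform(-1, 1, 6)))
        cfg = JointRangePenaltyConfig(weights=w, targets=tgt)
        expected = sum(w[n] * abs(meas[n] - tgt[n]) for n in names)
        assert joint_range_penalty(meas, cfg) == pytest.approx(expected,
                                                               abs=1e-12)


class TestGRFPenalty:
    def test_inside_band_is_zero(self):
        cfg = GRFPenaltyConfig(lower=0.0, upper=3.0, weight=1.0)
        t = np.linspace(0, 1, 11)
        assert grf_penalty(t, np.full(11, 1.5), cfg) == 0.0

    def test_rectangle_integral(self):
        cfg = GRFPenaltyConfig(lower=0.0, upper=3.0, weight=1.0)
        t = np.linspace(0, 1, 101)
        assert grf_penalty(t, np.full(101, 3.5), cfg) == pytest.approx(0.5)

    def test_piecewise_matches_fine_riemann_oracle(self):
        cfg = GRFPenaltyConfig(lower=0.5, upper=2.0, weight=0.7)

        def trace(t):
            return 2.5 * np.abs(np.sin(4 * t))

        t = np.linspace(0, 1, 2001)
        val = grf_penalty(t, trace(t), cfg)
        tf = np.linspace(0, 1, 400001)
        viol = np.maximum(cfg.lower - trace(tf), 0) \
            + np.maximum(trace(tf) - cfg.upper, 0)
        riemann = cfg.weight * np.sum(viol[:-1] * np.diff(tf))
        assert val == pytest.approx(riemann, rel=1e-5)


class TestCompositeCost:
    def test_zero(self):
        assert composite_cost(CostBreakdown()) == 0.0

    def test_addition(self):
        parts = CostBreakdown(p_s=75.0, p_j=0.2, p_grf=0.5)
        assert composite_cost(parts) == pytest.approx(75.7)

    def test_total_is_sum_of_terms(self, rng):
        vals = rng.uniform(0, 10, 5)
        parts = CostBreakdown(*vals)
        assert parts.total == pytest.approx(vals.sum(), abs=1e-12)


class TestEffortGoal:
    def test_zero_controls(self):
        traj = _traj(np.linspace(0, 1, 11))
        assert effort_goal(traj, EffortGoalConfig(d_mode="unit")) == 0.0

    def test_constant_control_analytic(self):
        t = np.linspace(0, 1, 21)
        traj = _traj(t, controls=np.full((21, 1), 0.5))
        cfg = EffortGoalConfig(w_c=1.0, p=2.0, d_mode="unit")
        assert effort_goal(traj, cfg) == pytest.approx(0.25)

    def test_spline_matches_fine_quadrature_oracle(self):
        t = np.linspace(0, 1, 2001)
        c = 0.3 + 0.2 * np.sin(7 * t)
        traj = _traj(t, controls=c[:, None])
        val = effort_goal(traj, EffortGoalConfig(p=2.0, d_mode="unit"))
        tf = np.linspace(0, 1, 400001)
        cf = 0.3 + 0.2 * np.sin(7 * tf)
        assert val == pytest.approx(np.trapezoid(cf ** 2, tf), rel=1e-5)

    @given(lam=st.floats(0.1, 1.9))
    @settings(max_examples=25, deadline=None)
    def test_homogeneity_in_control_scaling(self, lam):
        t = np.linspace(0, 1, 51)
        c = 0.4 * np.abs(np.sin(3 * t))[:, None]
        cfg = EffortGoalConfig(p=2.0, d_mode="unit")
        base = effort_goal(_traj(t, controls=c), cfg)
        scaled = effort_goal(_traj(t, controls=lam * c), cfg)
        assert scaled == pytest.approx(lam ** 2 * base, rel=1e-9)

    def test_displacement_normalization_and_floor(self):
        t = np.linspace(0, 1, 11)
        q = np.zeros((11, 2))
        q[:, 1] = np.linspace(1.0, 0.5, 11)    # pelvis drops 0.5 m
        traj = _traj(t, controls=np.full((11, 1), 0.5), q_cols=q)
        val = effort_goal(traj, EffortGoalConfig())
        assert val == pytest.approx(0.25 / 0.5)
        still = _traj(t, controls=np.full((11, 1), 0.5))
        with pytest.raises(ValueError, match="pelvis_displacement"):
            effort_goal(still, EffortGoalConfig())


class TestTrackingObjective:
    def test_identical_trajectories_score_zero(self):
        t = np.linspace(0, 1, 21)
        traj = _traj(t, q_cols=np.column_stack([np.sin(t), np.cos(t)]))
        assert tracking_objective(traj, traj, {"pelvis_tx": 1.0}) == 0.0

    def test_constant_offset_analytic(self):
        t = np.linspace(0, 1, 101)
        ref = _traj(t)
        shifted = _traj(t, q_cols=np.column_stack(
            [np.full(101, 0.1), np.zeros(101)]))
        val = tracking_objective(shifted, ref, {"pelvis_tx": 1.0})
        assert val == pytest.approx(0.01)

    def test_matches_pointwise_summation_oracle(self, rng):
        t = np.linspace(0, 1, 64)
        qa = rng.normal(0, 1, (64, 2))
        qb = rng.normal(0, 1, (64, 2))
        w = {"pelvis_tx": 0.7, "pelvis_ty": 1.3}
        val = tracking_objective(_traj(t, q_cols=qa), _traj(t, q_cols=qb), w)
        integrand = (w["pelvis_tx"] * (qa[:, 0] - qb[:, 0]) ** 2
                     + w["pelvis_ty"] * (qa[:, 1] - qb[:, 1]) ** 2)
        assert val == pytest.approx(np.trapezoid(integrand, t), abs=1e-9)

    def test_missing_reference_column_raises(self):
        t = np.linspace(0, 1, 5)
        traj = _traj(t, nm=1)
        ref = _traj(t, nm=0)     # reference lacks the muscle columns
        with pytest.raises(KeyError, match="m0_a"):
            tracking_objective(traj, ref, {"m0_a": 1.0})


@given(ws=st.floats(0, 50), tsim=st.floats(0, 2.0))
@settings(max_examples=40, deadline=None)
def test_penalties_are_nonnegative(ws, tsim):
    cfg = StabilityMeasureConfig(th=0.5, w_s=ws, t_max=2.0)
    assert stability_penalty(SimOutcome(tsim, np.ones(2), 1.0), cfg) >= 0.0
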