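"""Hill muscle curves, activation dynamics and the compliant contact law,
checked against independently coded formula oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import landsim as ls
from landsim import muscles as mus
from landsim.contact import hunt_crossley
from landsim.model import MuscleSpec


def _muscle(F0=1000.0, l_opt=0.1, l_slack=0.2, pennation=0.0):
    return MuscleSpec("m", "other", F0, l_opt, l_slack, 10.0, pennation,
                      (("a", np.zeros(3)), ("b", np.zeros(3))))


class TestMuscleForce:
    def test_zero_activation_at_optimal_length_gives_zero(self):
        m = _muscle()
        assert ls.muscle_force(m, 0.0, m.l_slack + m.l_opt, 0.0) == \
            pytest.approx(0.0, abs=1e-9)

    def test_isometric_maximum(self):
        m = _muscle(pennation=0.3)
        lmt = m.l_slack + m.l_opt * np.cos(m.pennation)
        F = ls.muscle_force(m, 1.0, lmt, 0.0)
        assert F == pytest.approx(m.F0 * np.cos(0.3), rel=1e-12)

    def test_matches_pointwise_curve_formula_oracle(self):
        # independent evaluation of the three published curve shapes
        m = _muscle(F0=1000.0)
        lnorm, vnorm = 1.1, -0.2
        lmt = m.l_slack + m.l_opt * lnorm
        vmt = vnorm * m.l_opt * m.v_max
        a = 0.5
        fl = np.exp(-((lnorm - 1.0) ** 2) / mus.FL_WIDTH)
        fv = (1.0 + vnorm) / (1.0 - vnorm / mus.FV_AF)
        fp = (np.exp(mus.FP_KPE * (lnorm - 1.0) / mus.FP_E0) - 1.0) \
            / (np.exp(mus.FP_KPE) - 1.0)
        expected = m.F0 * (a * fl * fv + fp)
        assert ls.muscle_force(m, a, lmt, vmt) == \
            pytest.approx(expected, rel=1e-4)

    def test_non_finite_input_raises(self):
        with pytest.raises(ValueError):
            ls.muscle_force(_muscle(), 0.5, np.nan, 0.0)

    @given(a=st.floats(0, 1), lnorm=st.floats(0.6, 1.8),
           vnorm=st.floats(-1.5, 1.5))
    @settings(max_examples=80, deadline=None)
    def test_force_never_negative(self, a, lnorm, vnorm):
        m = _muscle()
        F = ls.muscle_force(m, a, m.l_slack + m.l_opt * lnorm,
                            vnorm * m.l_opt * m.v_max)
        assert F >= 0.0


class TestActivationDynamics:
    def test_equilibrium(self):
        assert ls.activation_rate(0.3, 0.3) == 0.0

    def test_step_rate(self):
        assert ls.activation_rate(1.0, 0.0, tau_act=0.01) == \
            pytest.approx(100.0)

    def test_rate_matches_analytic_solution_derivative(self):
        # closed-form solution a(t) = e + (a0 - e) exp(-t/tau); the rate
        # returned at a(t) must equal its analytic derivative
        e, a0, tau = 0.8, 0.1, mus.TAU_ACT
        for t in (0.0, 0.005, 0.02, 0.1):
            at = e + (a0 - e) * np.exp(-t / tau)
            da_dt = -(a0 - e) / tau * np.exp(-t / tau)
            assert ls.activation_rate(e, at) == pytest.approx(da_dt, rel=1e-9)


class TestContact:
    def test_airborne_is_force_free(self, planar_model):
        sphere = planar_model.contact_spheres[0]
        f = ls.contact_force(sphere, -0.01)
        assert np.linalg.norm(f) < 1e-6

    def test_static_penetration_is_hertzian(self, planar_model):
        sphere = planar_model.contact_spheres[0]
        x = 0.005
        f = ls.contact_force(sphere, x, 0.0, (0.0, 0.0))
        # smoothing adds a small offset near zero penetration
        assert f[1] == pytest.approx(sphere.stiffness * x ** 1.5, rel=0.25)
        assert abs(f[0]) < 1e-9 and abs(f[2]) < 1e-9

    def test_matches_unsmoothed_hunt_crossley_grid_oracle(self, planar_model):
        s = planar_model.contact_spheres[0]
        rng = np.random.default_rng(7)
        pen = rng.uniform(0.003, 0.02, 50)
        rate = rng.uniform(-0.2, 0.5, 50)
        vt = rng.uniform(-0.5, 0.5, (50, 2))
        fn, ft = hunt_crossley(s.stiffness, s.dissipation, s.mu_dynamic,
                               s.mu_viscous, pen, rate, vt)
        # independent, unsmoothed evaluation
        raw = s.stiffness * pen ** 1.5 * np.maximum(
            1.0 + 1.5 * s.dissipation * rate, 0.0)
        np.testing.assert_allclose(fn, raw, rtol=0.15, atol=5.0)
        speed = np.linalg.norm(vt, axis=1)
        fric = np.linalg.norm(ft, axis=1)
        cap = fn * (s.mu_dynamic + s.mu_viscous * speed) + 1e-9
        assert np.all(fric <= cap * 1.001)

    @given(pen=st.floats(-0.02, 0.02), rate=st.floats(-1.0, 1.0),
           vx=st.floats(-1.0, 1.0))
    @settings(max_examples=60, deadline=None)
    def test_continuity_in_all_arguments(self, planar_model, pen, rate, vx):
        s = planar_model.contact_spheres[0]
        eps = 1e-7
        base = ls.contact_force(s, pen, rate, (vx, 0.0))
        for dp, dr, dv in ((eps, 0, 0), (0, eps, 0), (0, 0, eps)):
            near = ls.contact_force(s, pen + dp, rate + dr, (vx + dv, 0.0))
            assert np.linalg.norm(near - base) < 1.0   # no jumps

    def test_normal_force_nonnegative_under_rebound(self, planar_model):
        s = planar_model.contact_spheres[0]
        f = ls.contact_force(s, 0.01, -5.0, (0.0, 0.0))
        assert f[1] >= 0.0
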