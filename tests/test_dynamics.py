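"""COM-ZMP pendulum dynamics: eigenstructure, closed form, capture point."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gaitbalance.dynamics import (
    FeedbackGains,
    PendulumParams,
    PlanarState,
    SupportBounds,
    angular_momentum_about_com,
    capture_point,
    closed_form_solution,
    com_acceleration,
    feedback_gains,
    natural_frequency,
    saturate_zmp,
    system_matrix,
    target_zmp_feedback,
    zmp_from_kinematics,
)

zetas = st.floats(0.5, 8.0)
positions = st.floats(-1.0, 1.0)
velocities = st.floats(-2.0, 2.0)


def rk4_oracle(state, x_zmp, params, t_end, dt=1e-3):
    """Fixed-step RK4 integration of the equation of motion (independent of
    the closed-form path)."""

    def f(y):
        return np.array([y[1], com_acceleration(PlanarState(y[0], y[1]), x_zmp, params)])

    y = np.array([state.x, state.xdot])
    n = int(round(t_end / dt))
    for _ in range(n):
        k1 = f(y)
        k2 = f(y + 0.5 * dt * k1)
        k3 = f(y + 0.5 * dt * k2)
        k4 = f(y + dt * k3)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return PlanarState(y[0], y[1])


class TestNaturalFrequency:
    @pytest.mark.parametrize(
        "z,g,expected",
        [(9.81, 9.81, 1.0), (1.131, 9.81, 2.945), (0.25, 9.81, 6.264)],
    )
    def test_values(self, z, g, expected):
        assert natural_frequency(z, g) == pytest.approx(expected, abs=1e-3)

    def test_square_matches_constraint_product(self):
        # the eigenvalue product constraint 8.67 corresponds to a ~1.13 m
        # pendulum length
        assert natural_frequency(9.81 / 8.67) ** 2 == pytest.approx(8.67, rel=1e-12)

    def test_nonpositive_height_rejected(self):
        with pytest.raises(ValueError):
            natural_frequency(0.0)


class TestComAcceleration:
    def test_equilibrium(self):
        p = PendulumParams(3.0, 3.0)
        assert com_acceleration(PlanarState(0.2, 0.0), 0.2, p) == 0.0

    def test_symmetric_limit_kills_velocity_term(self):
        p = PendulumParams(3.0, 3.0)
        for xd in (-5.0, 0.0, 5.0):
            assert com_acceleration(PlanarState(0.1, xd), 0.0, p) == pytest.approx(0.9)

    def test_asymmetric_value(self):
        p = PendulumParams(4.0, 2.16)
        acc = com_acceleration(PlanarState(0.1, 0.2), 0.0, p)
        assert acc == pytest.approx(8.64 * 0.1 + 1.84 * 0.2, rel=1e-12)

    @given(z=zetas, x=positions, xd=velocities, zmp=positions)
    def test_symmetric_limit_equivalence(self, z, x, xd, zmp):
        sym = PendulumParams(z, z)
        s = PlanarState(x, xd)
        assert com_acceleration(s, zmp, sym) == z * z * (x - zmp)


class TestSystemMatrix:
    def test_symmetric_companion_form(self):
        a = system_matrix(PendulumParams(3.0, 3.0))
        np.testing.assert_allclose(a, [[0, 1], [9, 0]])
        np.testing.assert_allclose(sorted(np.linalg.eigvals(a)), [-3, 3], atol=1e-12)

    def test_eigendecomposition_identity(self):
        # T D T^-1 built from the explicit eigen-factors equals the
        # companion matrix elementwise
        z1, z2 = 4.0, 2.16
        T = np.array([[1.0, 1.0], [z1, -z2]])
        D = np.diag([z1, -z2])
        np.testing.assert_allclose(
            T @ D @ np.linalg.inv(T), system_matrix(PendulumParams(z1, z2)), atol=1e-12
        )

    @given(z1=zetas, z2=zetas)
    def test_eigenpairs(self, z1, z2):
        a = system_matrix(PendulumParams(z1, z2))
        w, v = np.linalg.eig(a)
        np.testing.assert_allclose(sorted(w), sorted([z1, -z2]), rtol=1e-9, atol=1e-9)
        for lam, vec_expect in ((z1, [1, z1]), (-z2, [1, -z2])):
            i = int(np.argmin(np.abs(w - lam)))
            vec = v[:, i] / v[0, i]
            np.testing.assert_allclose(vec.real, vec_expect, rtol=1e-7, atol=1e-7)


class TestClosedFormSolution:
    def test_initial_condition(self):
        p = PendulumParams(4.0, 2.16)
        s0 = PlanarState(0.12, -0.3)
        s = closed_form_solution(s0, 0.05, p, 0.0)
        assert (s.x, s.xdot) == (pytest.approx(0.12), pytest.approx(-0.3))

    def test_stable_eigendirection_converges(self):
        p = PendulumParams(4.0, 2.16)
        zmp = 0.1
        x0 = 0.3
        s0 = PlanarState(x0, -p.zeta2 * (x0 - zmp))  # divergent coefficient zero
        s = closed_form_solution(s0, zmp, p, 5.0)
        assert s.x == pytest.approx(zmp, abs=1e-4)
        assert s.xdot == pytest.approx(0.0, abs=1e-3)

    @given(
        z1=st.floats(1.0, 6.0),
        z2=st.floats(1.0, 6.0),
        x=positions,
        xd=velocities,
        zmp=positions,
    )
    def test_matches_rk4_oracle(self, z1, z2, x, xd, zmp):
        p = PendulumParams(z1, z2)
        s0 = PlanarState(x, xd)
        cf = closed_form_solution(s0, zmp, p, 0.5)
        rk = rk4_oracle(s0, zmp, p, 0.5)
        assert abs(cf.x - rk.x) < 1e-8
        assert abs(cf.xdot - rk.xdot) < 1e-7

    def test_matches_rk4_over_two_seconds(self):
        p = PendulumParams(4.0, 2.16)
        s0 = PlanarState(0.02, 0.1)
        cf = closed_form_solution(s0, 0.0, p, 2.0)
        rk = rk4_oracle(s0, 0.0, p, 2.0, dt=2e-4)
        assert abs(cf.x - rk.x) < 1e-6 * max(1.0, abs(rk.x))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            closed_form_solution(PlanarState(0, 0), 0.0, PendulumParams(3, 3), -0.1)


class TestCapturePoint:
    def test_stationary_com(self):
        assert capture_point(PlanarState(0.4, 0.0), 2.16) == 0.4

    def test_identified_parameters_value(self):
        assert capture_point(PlanarState(0.1, 0.216), 2.16) == pytest.approx(0.2)

    def test_holding_zmp_at_capture_point_stops_com(self):
        p = PendulumParams(4.0, 2.16)
        s = PlanarState(0.05, 0.35)
        xc = capture_point(s, p.zeta2)
        out = closed_form_solution(s, xc, p, 4.0)
        assert out.xdot == pytest.approx(0.0, abs=1e-4)
        assert out.x == pytest.approx(xc, abs=1e-4)


class TestFeedback:
    def test_gain_formulas(self):
        g = feedback_gains(1.0, 1.0, 3.0)
        assert (g.k1, g.k2) == (pytest.approx(2.0), pytest.approx(2.0 / 3.0))
        assert feedback_gains(0.0, 7.0, 3.0).k1 == pytest.approx(1.0)

    @given(q1=st.floats(0.1, 3.0), q2=st.floats(0.1, 3.0), z=st.floats(1.0, 6.0))
    def test_closed_loop_eigenvalues(self, q1, q2, z):
        g = feedback_gains(q1, q2, z)
        a = np.array([[0.0, 1.0], [z * z * (1 - g.k1), -z * z * g.k2]])
        np.testing.assert_allclose(
            sorted(np.linalg.eigvals(a).real), sorted([-z * q1, -z * q2]), rtol=1e-7, atol=1e-9
        )

    def test_target_zmp_at_reference(self):
        g = FeedbackGains(k1=2.0, k2=0.5, xd=0.3)
        assert target_zmp_feedback(PlanarState(0.3, 0.0), g) == pytest.approx(0.3)
        g0 = FeedbackGains(k1=2.0, k2=0.5, xd=0.0)
        assert target_zmp_feedback(PlanarState(0.1, 0.0), g0) == pytest.approx(0.2)

    def test_feedback_converges_to_reference(self):
        p = PendulumParams(3.0, 3.0)
        g = feedback_gains(1.0, 1.0, 3.0)
        g = FeedbackGains(k1=g.k1, k2=g.k2, xd=0.25)
        s = PlanarState(0.1, 0.0)
        dt = 1e-3
        for _ in range(6000):
            zmp = target_zmp_feedback(s, g)
            s = closed_form_solution(s, zmp, p, dt)
        assert s.x == pytest.approx(0.25, abs=1e-6)


class TestSaturation:
    def test_branches(self):
        b = SupportBounds(-0.05, 0.13)
        assert saturate_zmp(0.02, b) == 0.02
        assert saturate_zmp(0.5, b) == 0.13
        assert saturate_zmp(-0.2, b) == -0.05

    @given(x=st.floats(-10, 10))
    def test_idempotence(self, x):
        b = SupportBounds(-0.05, 0.13)
        assert saturate_zmp(saturate_zmp(x, b), b) == saturate_zmp(x, b)


class TestZmpFromKinematics:
    def test_static_stance(self):
        assert zmp_from_kinematics([0.2, 0, 1.0], [0, 0, 0], 0.0, 57.0) == pytest.approx(0.2)

    def test_acceleration_shifts_zmp(self):
        assert zmp_from_kinematics([0.0, 0, 1.0], [1.0, 0, 0], 0.0, 57.0) == pytest.approx(
            -1.0 / 9.81, abs=1e-5
        )

    def test_angular_momentum_correction_sign(self):
        base = zmp_from_kinematics([0.0, 0, 1.0], [0, 0, 0], 0.0, 57.0)
        corrected = zmp_from_kinematics([0.0, 0, 1.0], [0, 0, 0], 10.0, 57.0)
        assert corrected - base == pytest.approx(-10.0 / (57.0 * 9.81))

    def test_flight_rejected(self):
        with pytest.raises(ValueError):
            zmp_from_kinematics([0, 0, 1], [0, 0, -20.0], 0.0, 57.0)


class TestAngularMomentum:
    def test_point_mass_at_com(self):
        np.testing.assert_allclose(
            angular_momentum_about_com([[0, 0, 0]], [[1, 2, 3]], [5.0]), np.zeros(3)
        )

    def test_cross_product(self):
        L = angular_momentum_about_com([[1, 0, 0]], [[0, 1, 0]], [2.0])
        np.testing.assert_allclose(L, [0, 0, 2.0])

    def test_mirrored_pair_cancels_pitch(self):
        coms = [[0.2, 0.1, 0.0], [0.2, -0.1, 0.0]]
        vels = [[0.0, 0.0, 0.3], [0.0, 0.0, 0.3]]
        L = angular_momentum_about_com(coms, vels, [1.0, 1.0])
        assert L[0] == pytest.approx(0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            angular_momentum_about_com([[0, 0, 0]], [[0, 0, 0], [1, 1, 1]], [1.0])
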