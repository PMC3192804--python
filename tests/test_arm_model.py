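"""Unit and property tests of the two-link arm model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from armioc.arm_model import (
    ArmParams,
    ArmState,
    coriolis_matrix,
    coriolis_vector,
    dynamics_rhs,
    fingertip_chain,
    forward_kinematics,
    gravity_vector,
    inverse_dynamics,
    inverse_kinematics,
    kinetic_energy,
    mass_matrix,
    potential_energy,
    torque_accel,
    torque_rate,
)


class TestKinematics:
    def test_fully_extended_along_x(self):
        p = ArmParams(l1=0.30, l2=0.35)
        assert np.allclose(forward_kinematics((0.0, 0.0), p), [0.65, 0.0])

    def test_fully_extended_along_z(self):
        p = ArmParams(l1=0.30, l2=0.35)
        assert np.allclose(forward_kinematics((np.pi / 2, 0.0), p),
                           [0.0, 0.65], atol=1e-15)

    def test_inverse_at_annulus_boundary(self):
        p = ArmParams(l1=0.30, l2=0.35)
        q = inverse_kinematics(np.array([0.65, 0.0]), p)
        assert np.allclose(q, [0.0, 0.0], atol=1e-6)

    def test_inverse_right_angle_geometry(self):
        # p = (l1, -l2): the negative-elbow branch gives q = (0, -pi/2);
        # the default positive branch gives its mirror
        p = ArmParams(l1=0.30, l2=0.35)
        q_neg = inverse_kinematics(np.array([0.30, -0.35]), p,
                                   branch="negative")
        assert np.allclose(q_neg, [0.0, -np.pi / 2], atol=1e-12)
        q_pos = inverse_kinematics(np.array([0.30, -0.35]), p)
        assert q_pos[1] == pytest.approx(np.pi / 2)
        assert np.allclose(forward_kinematics(q_pos, p), [0.30, -0.35])

    def test_unreachable_raises(self, params):
        with pytest.raises(ValueError, match="exceeds arm length"):
            inverse_kinematics(np.array([1.0, 1.0]), params)
        with pytest.raises(ValueError, match="inner workspace"):
            inverse_kinematics(np.array([0.01, 0.0]), params)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(r_frac=st.floats(0.01, 0.99), angle=st.floats(-np.pi, np.pi),
           branch=st.sampled_from(["positive", "negative"]))
    def test_roundtrip_random_reachable_points(self, r_frac, angle, branch):
        p = ArmParams()
        lo = abs(p.l1 - p.l2)
        r = lo + r_frac * (p.L - lo)
        target = r * np.array([np.cos(angle), np.sin(angle)])
        q = inverse_kinematics(target, p, branch=branch)
        assert np.linalg.norm(forward_kinematics(q, p) - target) < 1e-10

    def test_fingertip_chain_matches_finite_differences(self, params):
        # independent oracle: central differences of the position signal
        t = np.linspace(0, 1, 2001)
        q = np.stack([0.3 * np.sin(2 * np.pi * t),
                      1.5 + 0.4 * np.cos(3 * t)], axis=1)
        qd = np.stack([0.3 * 2 * np.pi * np.cos(2 * np.pi * t),
                       -1.2 * np.sin(3 * t)], axis=1)
        qdd = np.stack([-0.3 * (2 * np.pi) ** 2 * np.sin(2 * np.pi * t),
                        -3.6 * np.cos(3 * t)], axis=1)
        qddd = np.stack([-0.3 * (2 * np.pi) ** 3 * np.cos(2 * np.pi * t),
                         10.8 * np.sin(3 * t)], axis=1)
        pos, vel, acc, jerk = fingertip_chain(q, qd, qdd, qddd, params=params)
        for deriv, sig in ((vel, pos), (acc, vel), (jerk, acc)):
            fd = np.gradient(sig, t, axis=0)
            assert np.allclose(deriv[50:-50], fd[50:-50], rtol=1e-3,
                               atol=1e-3)


class TestDynamics:
    def test_static_equilibrium(self, params):
        q = np.array([0.3, 1.2])
        state = ArmState.rest(q, params)
        deriv = dynamics_rhs(state, np.zeros(2), params)
        assert np.allclose(deriv, 0.0, atol=1e-12)

    def test_gravity_compensation(self, params):
        q = np.array([-0.5, 2.0])
        tau = inverse_dynamics(q, np.zeros(2), np.zeros(2), params)
        assert np.allclose(tau, gravity_vector(q, params))

    def test_inertia_column_from_unit_acceleration(self):
        p = ArmParams(g=0.0)
        q = np.array([0.4, 1.1])
        tau = inverse_dynamics(q, np.zeros(2), np.array([1.0, 0.0]), p)
        assert np.allclose(tau, mass_matrix(q, p)[:, 0])

    def test_inverse_dynamics_roundtrip(self, params, rng):
        for _ in range(50):
            q = rng.uniform(-1.5, 2.5, 2)
            qd = rng.normal(0, 3, 2)
            qdd = rng.normal(0, 20, 2)
            tau = inverse_dynamics(q, qd, qdd, params)
            state = np.concatenate([q, qd, tau, np.zeros(2)])
            deriv = dynamics_rhs(state, np.zeros(2), params)
            assert np.allclose(deriv[2:4], qdd, atol=1e-10)

    def test_nan_state_rejected(self, params):
        state = np.full(8, np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            dynamics_rhs(state, np.zeros(2), params)

    def test_mass_matrix_positive_definite(self, rng):
        p = ArmParams()
        q = rng.uniform(-np.pi, np.pi, size=(1000, 2))
        M = mass_matrix(q, p)
        assert np.allclose(M, np.swapaxes(M, -1, -2))
        assert np.linalg.eigvalsh(M).min() > 0

    def test_passivity_skew_symmetry(self, params, rng):
        # d/dt M - 2C must be skew-symmetric in this Coriolis convention
        for _ in range(100):
            q = rng.uniform(-np.pi, np.pi, 2)
            qd = rng.normal(0, 5, 2)
            eps = 1e-7
            Md = (mass_matrix(q + eps * qd, params)
                  - mass_matrix(q - eps * qd, params)) / (2 * eps)
            S = Md - 2 * coriolis_matrix(q, qd, params)
            assert np.allclose(S, -S.T, atol=1e-6)

    def test_coriolis_matrix_consistent_with_vector(self, params, rng):
        q = rng.uniform(-np.pi, np.pi, 2)
        qd = rng.normal(0, 3, 2)
        assert np.allclose(coriolis_matrix(q, qd, params) @ qd,
                           coriolis_vector(q, qd, params))

    def test_pendulum_small_oscillation_period(self):
        # distal segment made negligible: shoulder behaves as a physical
        # pendulum of period 2*pi*sqrt((I1 + m1 lc1^2)/(m1 g lc1))
        p = ArmParams(m2=1e-7, lc2=1e-9, I2=1e-7, B=np.zeros((2, 2)))
        T_exact = 2 * np.pi * np.sqrt((p.I1 + p.m1 * p.lc1**2)
                                      / (p.m1 * p.g * p.lc1))
        q_eq = -np.pi / 2
        x0 = np.concatenate([[q_eq + 0.02, 0.0], np.zeros(6)])
        sol = solve_ivp(lambda t, x: dynamics_rhs(x, np.zeros(2), p),
                        (0, 3 * T_exact), x0, rtol=1e-10, atol=1e-12,
                        dense_output=True)
        t = np.linspace(0, 3 * T_exact, 30000)
        dev = sol.sol(t)[0] - q_eq
        crossings = t[np.where(np.diff(np.sign(dev)) > 0)[0]]
        period = np.mean(np.diff(crossings))
        assert period == pytest.approx(T_exact, rel=5e-3)

    def test_energy_balance_conservative(self):
        # with B = 0: d/dt(kinetic + potential) = tau . qdot
        p = ArmParams(B=np.zeros((2, 2)))
        x0 = np.concatenate([[0.3, 1.0], [1.0, -2.0],
                             gravity_vector(np.array([0.3, 1.0]), p) + [2, 1],
                             [0.5, -0.5]])
        u = np.array([3.0, -1.0])
        sol = solve_ivp(lambda t, x: dynamics_rhs(x, u, p), (0, 0.5), x0,
                        rtol=1e-11, atol=1e-12, dense_output=True)
        t = np.linspace(0, 0.5, 2000)
        x = sol.sol(t)
        q, qd, tau = x[0:2].T, x[2:4].T, x[4:6].T
        E = kinetic_energy(q, qd, p) + potential_energy(q, p)
        work = np.concatenate([[0], np.cumsum(
            0.5 * (np.sum(tau * qd, 1)[1:] + np.sum(tau * qd, 1)[:-1])
            * np.diff(t))])
        assert np.allclose(E - E[0], work, atol=1e-6)


@pytest.fixture(scope="module")
def smooth_motion():
    t = np.linspace(0, 1, 4001)
    q = np.stack([0.25 * np.sin(5 * t) - 0.8,
                  1.6 + 0.35 * np.cos(4 * t)], axis=1)
    derivs = [q]
    derivs.append(np.stack([0.25 * 5 * np.cos(5 * t),
                            -0.35 * 4 * np.sin(4 * t)], axis=1))
    derivs.append(np.stack([-0.25 * 25 * np.sin(5 * t),
                            -0.35 * 16 * np.cos(4 * t)], axis=1))
    derivs.append(np.stack([-0.25 * 125 * np.cos(5 * t),
                            0.35 * 64 * np.sin(4 * t)], axis=1))
    derivs.append(np.stack([0.25 * 625 * np.sin(5 * t),
                            0.35 * 256 * np.cos(4 * t)], axis=1))
    return t, derivs


class TestTorqueDerivatives:
    """tau-dot and tau-ddot closed forms against a finite-difference oracle."""

    def test_torque_rate_matches_fd(self, params, smooth_motion):
        t, (q, qd, qdd, qddd, _) = smooth_motion
        tau = inverse_dynamics(q, qd, qdd, params)
        taud = torque_rate(q, qd, qdd, qddd, params)
        fd = np.gradient(tau, t, axis=0)
        assert np.allclose(taud[20:-20], fd[20:-20], rtol=1e-4, atol=1e-4)

    def test_torque_accel_matches_fd(self, params, smooth_motion):
        t, (q, qd, qdd, qddd, qdddd) = smooth_motion
        taud = torque_rate(q, qd, qdd, qddd, params)
        taudd = torque_accel(q, qd, qdd, qddd, qdddd, params)
        fd = np.gradient(taud, t, axis=0)
        assert np.allclose(taudd[20:-20], fd[20:-20], rtol=1e-4, atol=1e-3)


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ArmParams(l1=-0.1)
        with pytest.raises(ValueError):
            ArmParams(lc1=0.5, l1=0.3)
        with pytest.raises(ValueError):
            ArmParams(B=np.array([[1.0, 0.5], [0.4, 1.0]]))

    def test_anthropometric_scaling(self):
        p = ArmParams.from_anthropometry(body_mass=80.0, height=1.80)
        assert p.l1 == pytest.approx(0.186 * 1.80)
        assert p.m2 == pytest.approx(0.022 * 80.0)
        assert p.lc1 < p.l1 and p.lc2 < p.l2
        assert p.L == pytest.approx(p.l1 + p.l2)

    def test_dict_roundtrip(self, params):
        p2 = ArmParams.from_dict(params.to_dict())
        assert p2.l1 == params.l1 and np.allclose(p2.B, params.B)
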