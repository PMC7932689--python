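"""Equations of motion, energy conservation, and step simulation."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from arslip.core_model import ARSLIPParams, CoMState, InitialConditions
from arslip.dynamics import (FallError, arslip_derivatives, energy_drift,
                             simulate_step, simulate_symmetric_step,
                             total_energy)

FLY = ARSLIPParams(k_s=0.009, k_a=1.1e-8, R=2e-3, m=1e-6, g=9.807)


class TestDerivatives:
    def test_static_fixed_point(self):
        r_star = FLY.R - FLY.m * FLY.g / FLY.k_s
        acc = arslip_derivatives(CoMState(r=r_star, theta=0.0), FLY)
        assert acc == pytest.approx((0.0, 0.0), abs=1e-9)

    def test_worked_values(self):
        state = CoMState(r=1.8e-3, theta=0.1, r_dot=0.0, theta_dot=10.0)
        r_dd, th_dd = arslip_derivatives(state, FLY)
        assert r_dd == pytest.approx(-7.77800, rel=1e-4)
        assert th_dd == pytest.approx(204.43, rel=1e-4)

    def test_slip_reduction(self):
        state = CoMState(r=1.8e-3, theta=0.1, r_dot=0.0, theta_dot=10.0)
        slip = ARSLIPParams(k_s=FLY.k_s, k_a=0.0, R=FLY.R, m=FLY.m, g=FLY.g)
        _, th_dd = arslip_derivatives(state, slip)
        assert th_dd == pytest.approx(543.94, rel=1e-4)


class TestEnergy:
    def test_static_energy(self):
        r_star = FLY.R - FLY.m * FLY.g / FLY.k_s
        e = total_energy(CoMState(r=r_star, theta=0.0), FLY)
        expected = 0.5 * FLY.k_s * (FLY.R - r_star) ** 2 \
            + FLY.m * FLY.g * r_star
        assert e == pytest.approx(expected, rel=1e-12)

    def test_term_by_term_value(self):
        state = CoMState(r=1.8e-3, theta=0.1, r_dot=0.0, theta_dot=10.0)
        assert total_energy(state, FLY) == pytest.approx(1.7960e-8, rel=1e-3)

    def test_conserved_along_trajectory(self):
        ic = InitialConditions(alpha=0.3, r0=1.9e-3, r_dot0=-2e-3,
                               theta_dot0=15.0)
        traj = simulate_step(FLY, ic, np.linspace(0.0, 0.05, 101))
        assert energy_drift(traj, FLY) <= 1e-8


class TestSimulateStep:
    def test_static_fixed_point_stays_put(self):
        r_star = FLY.R - FLY.m * FLY.g / FLY.k_s
        traj = simulate_step(FLY, InitialConditions(alpha=0.0, r0=r_star),
                             np.linspace(0.0, 0.05, 21))
        assert np.ptp(traj.x) == 0.0
        assert np.allclose(traj.z, r_star, rtol=0, atol=1e-15)

    def test_radial_oscillation_period(self):
        """Small vertical oscillation at theta = 0 has the linearized
        period 2 pi sqrt(m / k_s) = 0.06623 s."""
        slip = ARSLIPParams(k_s=0.009, k_a=0.0, R=2e-3, m=1e-6)
        r_star = slip.R - slip.m * slip.g / slip.k_s
        t = np.linspace(0.0, 0.2, 4001)
        traj = simulate_step(slip, InitialConditions(alpha=0.0,
                                                     r0=0.99 * r_star), t)
        z = traj.z
        peaks = t[1:-1][(z[1:-1] > z[:-2]) & (z[1:-1] > z[2:])]
        assert np.mean(np.diff(peaks)) == pytest.approx(0.06623, abs=1e-4)

    def test_stiff_limit_matches_rigid_pendulum(self):
        """As gamma_s -> infinity the leg length freezes and the model is a
        rigid inverted pendulum, integrated independently as the oracle."""
        gamma_s = 1e4
        R, m, g = 2e-3, 1e-6, 9.807
        stiff = ARSLIPParams(k_s=gamma_s * m * g / R, k_a=0.0, R=R, m=m, g=g)
        ell = R - m * g / stiff.k_s
        ic = InitialConditions(alpha=0.25, r0=ell, r_dot0=0.0,
                               theta_dot0=40.0)
        t = np.linspace(0.0, 0.015, 61)
        traj = simulate_step(stiff, ic, t)
        theta = np.arctan2(traj.x, traj.z)

        def pendulum(t, y):
            return [y[1], (g / ell) * math.sin(y[0])]

        sol = solve_ivp(pendulum, (0, t[-1]), [-0.25, 40.0], t_eval=t,
                        rtol=1e-12, atol=1e-14)
        assert np.max(np.abs(theta - sol.y[0])) <= 1e-4

    def test_dense_output_grid_independent(self):
        ic = InitialConditions(alpha=0.3, r0=1.9e-3, theta_dot0=15.0)
        coarse = simulate_step(FLY, ic, np.linspace(0.0, 0.05, 26))
        fine = simulate_step(FLY, ic, np.linspace(0.0, 0.05, 51))
        assert np.max(np.abs(fine.x[::2] - coarse.x)) <= 1e-9
        assert np.max(np.abs(fine.z[::2] - coarse.z)) <= 1e-9

    def test_nondimensional_scaling(self):
        """Systems sharing (gamma_s, gamma_a, r_bar0, Omega) produce the
        same nondimensional trajectory r_bar(tau), theta(tau)."""
        base = FLY
        scale_R, scale_m = 3.7, 250.0
        big = ARSLIPParams(k_s=base.k_s * scale_m / scale_R,
                           k_a=base.k_a * scale_m * scale_R,
                           R=base.R * scale_R, m=base.m * scale_m, g=base.g)
        tau = np.linspace(0.0, 2.0, 51)  # nondimensional times
        ic_b = InitialConditions(alpha=0.3, r0=0.95 * base.R,
                                 r_dot0=-0.01 * math.sqrt(base.g * base.R),
                                 theta_dot0=0.5 * math.sqrt(base.g / base.R))
        ic_B = InitialConditions(alpha=0.3, r0=0.95 * big.R,
                                 r_dot0=-0.01 * math.sqrt(big.g * big.R),
                                 theta_dot0=0.5 * math.sqrt(big.g / big.R))
        t_b = tau * math.sqrt(base.R / base.g)
        t_B = tau * math.sqrt(big.R / big.g)
        tr_b = simulate_step(base, ic_b, t_b)
        tr_B = simulate_step(big, ic_B, t_B)
        r_bar_b = np.hypot(tr_b.x, tr_b.z) / base.R
        r_bar_B = np.hypot(tr_B.x, tr_B.z) / big.R
        th_b = np.arctan2(tr_b.x, tr_b.z)
        th_B = np.arctan2(tr_B.x, tr_B.z)
        assert np.max(np.abs(r_bar_b - r_bar_B)) <= 1e-9
        assert np.max(np.abs(th_b - th_B)) <= 1e-9

    def test_fall_reported_with_time(self):
        soft = ARSLIPParams(k_s=0.002, k_a=0.0, R=2e-3, m=1e-6)
        with pytest.raises(FallError) as err:
            simulate_step(soft, InitialConditions(alpha=0.1, r0=1.5e-3),
                          np.linspace(0.0, 0.2, 101))
        assert 0.0 < err.value.t_fall < 0.2


class TestSymmetricStep:
    def test_time_reversal_symmetry(self):
        traj = simulate_symmetric_step(FLY, 1.1e-3, 0.3,
                                       half_duration=0.02, n_samples=101)
        assert np.max(np.abs(traj.z - traj.z[::-1])) <= 1e-9 * 1.1e-3
        assert np.max(np.abs(traj.v - traj.v[::-1])) <= \
            1e-9 * np.max(np.abs(traj.v))
        assert np.max(np.abs(traj.x + traj.x[::-1])) <= 1e-9 * 1.1e-3

    def test_explicit_grid_matches_symmetric_grid(self):
        t_grid = np.array([-0.015, -0.007, 0.0, 0.004, 0.015])
        a = simulate_symmetric_step(FLY, 1.1e-3, 0.3, t_grid=t_grid)
        b = simulate_symmetric_step(FLY, 1.1e-3, 0.3, half_duration=0.015,
                                    n_samples=3001)
        for i, t in enumerate(t_grid):
            j = np.argmin(np.abs(b.t - t))
            assert a.z[i] == pytest.approx(b.z[j], abs=1e-9)

    def test_fly_like_speed_maximum_and_slip_minimum(self):
        """A fly-like leg (gamma_s = 2, angular spring above the
        speed-curvature boundary k_a = m g r_m, i.e. gamma_a > r_m/R = 0.5)
        shows a mid-stance speed maximum; a stiff angular-spring-free leg
        shows the classic walking SLIP minimum."""
        m, R, g = 1e-6, 2e-3, 9.807
        fly = ARSLIPParams(k_s=2 * m * g / R, k_a=0.6 * m * g * R,
                           R=R, m=m, g=g)
        r_m = fly.R - m * g / fly.k_s
        Fr = 0.01
        Omega = math.sqrt(Fr) * R / r_m
        half = 0.5 * math.pi * math.sqrt(m / fly.k_s)
        dt = 0.02 * half
        traj = simulate_symmetric_step(fly, r_m, Omega,
                                       t_grid=np.array([0.0, dt]))
        assert traj.v[1] < traj.v[0]

        slip = ARSLIPParams(k_s=20 * m * g / R, k_a=0.0, R=R, m=m, g=g)
        r_m_s = slip.R - m * g / slip.k_s
        Omega_s = math.sqrt(Fr) * R / r_m_s
        half_s = 0.5 * math.pi * math.sqrt(m / slip.k_s)
        traj_s = simulate_symmetric_step(
            slip, r_m_s, Omega_s, t_grid=np.array([0.0, 0.02 * half_s]))
        assert traj_s.v[1] > traj_s.v[0]
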