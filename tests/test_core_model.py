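"""Potentials, the tripod -> ARSLIP mapping, and nondimensionalization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arslip.core_model import (ARSLIPParams, CoMState, GeometryError,
                               TripodParams, arslip_potential,
                               dimensionalize, nondimensionalize,
                               tripod_potential, tripod_to_arslip)

params_st = st.builds(
    TripodParams,
    k=st.floats(0.1, 10.0),
    R_tri=st.floats(0.5, 2.0),
    L=st.floats(0.0, 2.0),
    r_m=st.floats(0.5, 2.0),
    m=st.floats(0.5, 2.0),
)


def numeric_derivatives(p: TripodParams, h_rel: float = 3e-3):
    """Five-point central-difference 1st/2nd derivatives of the tripod
    potential at mid-stance (r = r_m, theta = 0) -- the independent oracle
    for the quadratic-expansion mapping.  Fourth-order stencils allow a
    large h (truncation ~ h^4) while keeping the roundoff eps/h^2 far below
    even very small angular stiffnesses."""
    h_r = h_rel * p.r_m
    h_th = h_rel

    def V(r, th):
        return tripod_potential(CoMState(r=r, theta=th), p)

    v0 = V(p.r_m, 0.0)

    def d1(f, h):
        return (-f(2 * h) + 8 * f(h) - 8 * f(-h) + f(-2 * h)) / (12 * h)

    def d2(f, h):
        return (-f(2 * h) + 16 * f(h) - 30 * v0 + 16 * f(-h)
                - f(-2 * h)) / (12 * h ** 2)

    dV_dr = d1(lambda d: V(p.r_m + d, 0.0), h_r)
    d2V_dr2 = d2(lambda d: V(p.r_m + d, 0.0), h_r)
    d2V_dth2 = d2(lambda d: V(p.r_m, d), h_th)
    d2V_drdth = (V(p.r_m + h_r, h_th) - V(p.r_m + h_r, -h_th)
                 - V(p.r_m - h_r, h_th) + V(p.r_m - h_r, -h_th)) \
        / (4 * h_r * h_th)
    return dV_dr, d2V_dr2, d2V_dth2, d2V_drdth


class TestTripodPotential:
    @pytest.mark.parametrize("L, r, theta, expected", [
        (0.0, 1.0, 0.0, 0.0),          # all three legs at natural length
        (1.0, 1.0, 0.0, 0.171573),     # (1 - sqrt(2))^2 by substitution
        (1.0, 1.0, 0.2, 0.185703),     # l_minus=1.265962, l_plus=1.548334
    ])
    def test_worked_values(self, L, r, theta, expected):
        p = TripodParams(k=1.0, R_tri=1.0, L=L, r_m=1.0, m=1.0)
        v = tripod_potential(CoMState(r=r, theta=theta), p)
        assert v == pytest.approx(expected, abs=1e-6)
        assert v >= 0

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            CoMState(r=-1.0, theta=0.0)
        with pytest.raises(ValueError):
            CoMState(r=float("nan"), theta=0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(params_st, st.floats(0.3, 2.5), st.floats(0.0, 1.0))
    def test_mirror_symmetry(self, p, r, theta):
        left = tripod_potential(CoMState(r=r, theta=-theta), p)
        right = tripod_potential(CoMState(r=r, theta=theta), p)
        assert left == right  # exact: only sin(theta) enters, squared terms


class TestArslipPotential:
    def test_relaxed_springs(self):
        p = ARSLIPParams(k_s=3.0, k_a=2.0, R=1.5, m=1.0)
        assert arslip_potential(CoMState(r=1.5, theta=0.0), p) == 0.0

    def test_pure_angular_term(self):
        p = ARSLIPParams(k_s=1e-12, k_a=2.0, R=1.0, m=1.0)
        v = arslip_potential(CoMState(r=1.0, theta=0.5), p)
        assert v == pytest.approx(0.25, rel=1e-9)

    def test_fly_scale_value(self):
        p = ARSLIPParams(k_s=0.009, k_a=1.1e-8, R=2e-3, m=1e-6)
        v = arslip_potential(CoMState(r=1.9e-3, theta=0.3), p)
        assert v == pytest.approx(5.40e-10, rel=1e-3)

    def test_slip_reduction(self):
        p = ARSLIPParams(k_s=0.009, k_a=0.0, R=2e-3, m=1e-6)
        v = arslip_potential(CoMState(r=1.9e-3, theta=0.3), p)
        assert v == pytest.approx(0.5 * 0.009 * (1e-4) ** 2, rel=1e-12)


class TestTripodToArslip:
    def test_parallel_legs(self):
        # L = 0: three parallel vertical springs
        p = tripod_to_arslip(TripodParams(k=1.3, R_tri=1.1, L=0.0, r_m=0.9,
                                          m=1.0))
        assert p.k_a == 0.0
        assert p.k_s == pytest.approx(3 * 1.3, rel=1e-12)
        assert p.R == pytest.approx(1.1, rel=1e-12)

    @pytest.mark.parametrize("k, R_tri, L, r_m, ks, ka, R", [
        (1.0, 1.0, 1.0, 1.0, 2.292893, 0.707107, 0.744521),
        (1.0, 1.2, 0.5, 1.0, 2.570675, 0.429325, 1.134838),
    ])
    def test_worked_values(self, k, R_tri, L, r_m, ks, ka, R):
        p = tripod_to_arslip(TripodParams(k=k, R_tri=R_tri, L=L, r_m=r_m,
                                          m=1.0))
        assert p.k_s == pytest.approx(ks, abs=2e-6)
        assert p.k_a == pytest.approx(ka, abs=2e-6)
        assert p.R == pytest.approx(R, abs=2e-5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(params_st)
    def test_matches_numerical_derivatives(self, p):
        """The mapped constants equal the tripod potential's derivatives at
        mid-stance, and the cross term vanishes (spring independence)."""
        try:
            eff = tripod_to_arslip(p)
        except GeometryError:
            return
        dV_dr, d2V_dr2, d2V_dth2, d2V_drdth = numeric_derivatives(p)
        scale = p.k * max(p.R_tri, p.r_m) ** 2
        assert eff.k_s == pytest.approx(d2V_dr2, rel=2e-6, abs=1e-8 * p.k)
        assert eff.k_a == pytest.approx(d2V_dth2, rel=2e-6, abs=1e-8 * scale)
        # first derivative: -dV/dr at r_m equals k_s (R - r_m)
        assert eff.k_s * (eff.R - p.r_m) == pytest.approx(
            -dV_dr, rel=2e-5, abs=1e-7 * p.k * p.r_m)
        assert abs(d2V_drdth) <= 1e-6 * scale

    def test_invalid_geometry_rejected(self):
        # wide, low tripod with long natural legs: mapped k_s <= 0
        with pytest.raises(GeometryError):
            tripod_to_arslip(TripodParams(k=1.0, R_tri=2.0, L=1.0, r_m=0.01,
                                          m=1.0))

    def test_gammas_decrease_with_tripod_spread(self):
        """Narrow and high tripods are stiffer: with a fly's fixed per-leg
        constants (k, R_tri) and the mid-stance height set by static
        balance, both mapped stiffnesses strictly decrease over
        L/r_m in [1, 2]."""
        k, R_tri, m, g = 0.008, 2.042e-3, 1.123e-6, 9.807
        ratios = np.linspace(1.0, 2.0, 21)
        gammas = []
        for ratio in ratios:
            s_hat = math.hypot(ratio, 1.0)
            r_m = (R_tri * (1 + 2 / s_hat) - m * g / k) / 3  # force balance
            eff = tripod_to_arslip(TripodParams(k=k, R_tri=R_tri,
                                                L=ratio * r_m, r_m=r_m,
                                                m=m, g=g))
            q = nondimensionalize(eff)
            gammas.append((q.gamma_a, q.gamma_s))
        ga, gs = np.array(gammas).T
        assert np.all(np.diff(gs) < 0)
        # gamma_a has a very shallow maximum near L/r_m ~ 1.05 and falls
        # steadily beyond it
        assert ga[-1] < ga[0]
        assert np.all(np.diff(ga[ratios >= 1.1]) < 0)


class TestNondimensionalization:
    def test_fly_values(self):
        # median fitted stiffnesses with W1118 morphometrics
        p = ARSLIPParams(k_s=0.009, k_a=1.1e-8, R=2.042e-3, m=1.123e-6,
                         g=9.807)
        q = nondimensionalize(p)
        assert q.gamma_s == pytest.approx(1.669, abs=2e-3)
        assert round(q.gamma_s) == 2
        assert q.gamma_a == pytest.approx(0.489, abs=2e-3)
        assert round(q.gamma_a, 1) == 0.5

    def test_zero_speed_froude(self):
        p = ARSLIPParams(k_s=1.0, k_a=0.0, R=1.0, m=1.0)
        assert nondimensionalize(p, v=0.0).Fr == 0.0

    def test_froude_consistency(self):
        """Fr = r_bar_m^2 Omega^2 at a shared mid-stance state."""
        p = ARSLIPParams(k_s=0.01, k_a=1e-8, R=2e-3, m=1e-6)
        r_m, theta_dot = 1.1e-3, 20.0
        v = r_m * theta_dot
        q = nondimensionalize(p, v=v, r_m=r_m,
                              state=CoMState(r=r_m, theta=0.0,
                                             theta_dot=theta_dot))
        assert q.Fr == pytest.approx(q.r_bar_m ** 2 * q.Omega ** 2,
                                     rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(1e-3, 1e2), st.floats(0.0, 1e2), st.floats(1e-4, 1.0),
           st.floats(1e-7, 1.0))
    def test_round_trip(self, k_s, k_a, R, m):
        p = ARSLIPParams(k_s=k_s, k_a=k_a, R=R, m=m)
        back = dimensionalize(nondimensionalize(p), m=m, R=R, g=p.g)
        assert back.k_s == pytest.approx(p.k_s, rel=1e-12)
        assert back.k_a == pytest.approx(p.k_a, rel=1e-12, abs=1e-300)
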