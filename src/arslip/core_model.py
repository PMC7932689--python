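"""Mechanical parameterizations of the springy tripod and the ARSLIP model.

An insect standing on the three legs of a tripod can be idealized as a point
mass supported by three linear springs ("springy tripod"): a middle leg of
length ``r`` directly under the body, and a front and a hind leg whose
footholds sit a distance ``L`` ahead of and behind the middle foothold along
the walking direction.  Expanding the tripod's elastic energy to quadratic
order about mid-stance (``r = r_m``, ``theta = 0``) yields the angular and
radial spring-loaded inverted pendulum (ARSLIP): a single effective leg with
a radial spring ``k_s`` and an angular spring ``k_a``.  This module houses
both potentials, the geometry-to-effective-spring mapping, and the
nondimensionalization used throughout the package.

Sign convention: ``theta`` is the angle of the effective leg from the
vertical, negative before mid-stance and positive after; walking direction
is +x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "CoMState",
    "ARSLIPParams",
    "TripodParams",
    "NondimQuantities",
    "InitialConditions",
    "GeometryError",
    "tripod_potential",
    "arslip_potential",
    "tripod_to_arslip",
    "nondimensionalize",
    "dimensionalize",
]

G_DEFAULT = 9.807  # m/s^2


class GeometryError(ValueError):
    """Tripod geometry outside the quadratic-expansion validity range."""


def _check_finite(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value):
            raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class CoMState:
    """Polar mechanical state of the center of mass about the foothold.

    r : radial leg length (m, > 0)
    theta : angle from vertical (rad, positive in the walking direction)
    r_dot : radial speed (m/s)
    theta_dot : angular speed (rad/s)
    """

    r: float
    theta: float
    r_dot: float = 0.0
    theta_dot: float = 0.0

    def __post_init__(self) -> None:
        _check_finite(r=self.r, theta=self.theta, r_dot=self.r_dot,
                      theta_dot=self.theta_dot)
        if self.r <= 0:
            raise ValueError(f"r must be > 0, got {self.r}")


@dataclass(frozen=True)
class ARSLIPParams:
    """Effective-leg constants: radial spring k_s (N/m), angular spring k_a
    (N*m/rad), natural length R (m), mass m (kg), gravity g (m/s^2).

    ``k_a = 0`` is exactly the SLIP model.
    """

    k_s: float
    k_a: float
    R: float
    m: float
    g: float = G_DEFAULT

    def __post_init__(self) -> None:
        _check_finite(k_s=self.k_s, k_a=self.k_a, R=self.R, m=self.m, g=self.g)
        if self.k_s <= 0 or self.R <= 0 or self.m <= 0 or self.g <= 0:
            raise ValueError("k_s, R, m, g must be > 0")
        if self.k_a < 0:
            raise ValueError("k_a must be >= 0")


@dataclass(frozen=True)
class TripodParams:
    """Springy-tripod constants.

    k : per-leg spring constant (N/m); R_tri : per-leg natural length (m);
    L : half tripod spread along the walking direction (m); r_m : mid-stance
    height (m); m : mass (kg); g : gravity (m/s^2).
    """

    k: float
    R_tri: float
    L: float
    r_m: float
    m: float
    g: float = G_DEFAULT

    def __post_init__(self) -> None:
        _check_finite(k=self.k, R_tri=self.R_tri, L=self.L, r_m=self.r_m,
                      m=self.m, g=self.g)
        if self.k <= 0 or self.R_tri <= 0 or self.r_m <= 0 or self.m <= 0 \
                or self.g <= 0:
            raise ValueError("k, R_tri, r_m, m, g must be > 0")
        if self.L < 0:
            raise ValueError("L must be >= 0")


@dataclass(frozen=True)
class NondimQuantities:
    """Dimensionless stiffnesses and speeds.

    gamma_s = k_s R / (m g); gamma_a = k_a / (m g R); r_bar = r / R;
    Omega = theta_dot * sqrt(R / g); Fr = v^2 / (g R).
    """

    gamma_s: float
    gamma_a: float
    r_bar: float | None = None
    r_bar_m: float | None = None
    Omega: float | None = None
    Fr: float | None = None


@dataclass(frozen=True)
class InitialConditions:
    """Step-start state: angle of attack alpha = |theta(0)| (rad), leg
    length r0 (m), radial speed r_dot0 (m/s), angular speed theta_dot0
    (rad/s).  theta(0) = -alpha (the leg points backward at touch-down)."""

    alpha: float
    r0: float
    r_dot0: float = 0.0
    theta_dot0: float = 0.0

    def __post_init__(self) -> None:
        _check_finite(alpha=self.alpha, r0=self.r0, r_dot0=self.r_dot0,
                      theta_dot0=self.theta_dot0)
        if self.r0 <= 0:
            raise ValueError("r0 must be > 0")


def _leg_lengths(r: float, L: float, theta: float) -> tuple[float, float]:
    """Front (+) and hind (-) leg lengths of the tripod at (r, theta)."""
    s2_minus = r * r + L * L - 2.0 * r * L * math.sin(theta)
    s2_plus = r * r + L * L + 2.0 * r * L * math.sin(theta)
    if s2_minus < 0 or s2_plus < 0:
        raise ValueError("negative squared leg length; inputs out of domain")
    return math.sqrt(s2_minus), math.sqrt(s2_plus)


def tripod_potential(state: CoMState, p: TripodParams) -> float:
    """Total elastic energy (J) of the three tripod legs at ``state``.

    V = 1/2 k (R_tri - l_minus)^2 + 1/2 k (R_tri - l_plus)^2
        + 1/2 k (R_tri - r)^2,   l_pm = sqrt(r^2 + L^2 +- 2 r L sin(theta))
    """
    l_minus, l_plus = _leg_lengths(state.r, p.L, state.theta)
    return 0.5 * p.k * ((p.R_tri - l_minus) ** 2 + (p.R_tri - l_plus) ** 2
                        + (p.R_tri - state.r) ** 2)


def arslip_potential(state: CoMState, p: ARSLIPParams) -> float:
    """Elastic energy (J) of the ARSLIP effective leg:
    1/2 k_s (R - r)^2 + 1/2 k_a theta^2.  With k_a = 0 this is the SLIP
    elastic energy."""
    return 0.5 * p.k_s * (p.R - state.r) ** 2 + 0.5 * p.k_a * state.theta ** 2


def tripod_radial_force(p: TripodParams, r: float | None = None) -> float:
    """Net upward radial force -dV_tri/dr (N) of the tripod at theta = 0.

    At ``r = r_m`` this equals the mapped ARSLIP spring force
    k_s (R - r_m); setting it to ``m g`` expresses mid-stance static
    balance.
    """
    if r is None:
        r = p.r_m
    s = math.hypot(p.L, r)
    return p.k * (p.R_tri - r * (3.0 - 2.0 * p.R_tri / s))


def tripod_to_arslip(p: TripodParams) -> ARSLIPParams:
    """Map springy-tripod constants to the equivalent ARSLIP constants.

    The effective springs are fixed by matching first and second
    derivatives of the two potentials at mid-stance (r = r_m, theta = 0):

        k_a = 2 k L^2 r_m^2 R_tri / (L^2 + r_m^2)^(3/2)
        k_s = k [3 - 2 L^2 R_tri / (L^2 + r_m^2)^(3/2)]
        k_s (R - r_m) = k (R_tri - r_m [3 - 2 R_tri / sqrt(L^2 + r_m^2)])

    Raises GeometryError when the mapped k_s would be <= 0 (very wide, low
    tripods with a long natural leg length, outside the validity of the
    quadratic expansion).
    """
    s = math.hypot(p.L, p.r_m)
    if s <= 0:
        raise ValueError("L and r_m cannot both be zero")
    s3 = s ** 3
    k_a = 2.0 * p.k * p.L ** 2 * p.r_m ** 2 * p.R_tri / s3
    k_s = p.k * (3.0 - 2.0 * p.L ** 2 * p.R_tri / s3)
    if k_s <= 0:
        raise GeometryError(
            f"mapped k_s = {k_s:.3g} <= 0 for L/r_m = {p.L / p.r_m:.3g}, "
            f"R_tri/r_m = {p.R_tri / p.r_m:.3g}: geometry outside "
            "quadratic-expansion validity")
    R = p.r_m + tripod_radial_force(p) / k_s
    if R <= 0:
        raise GeometryError(f"mapped R = {R:.3g} <= 0")
    return ARSLIPParams(k_s=k_s, k_a=k_a, R=R, m=p.m, g=p.g)


def nondimensionalize(p: ARSLIPParams, v: float | None = None,
                      state: CoMState | None = None,
                      r_m: float | None = None) -> NondimQuantities:
    """Nondimensionalize spring constants (and optionally speed and state)
    using body mass m, natural leg length R and gravity g as the units."""
    mg = p.m * p.g
    gamma_s = p.k_s * p.R / mg
    gamma_a = p.k_a / (mg * p.R)
    Fr = v ** 2 / (p.R * p.g) if v is not None else None
    r_bar = state.r / p.R if state is not None else None
    Omega = (state.theta_dot * math.sqrt(p.R / p.g)
             if state is not None else None)
    r_bar_m = r_m / p.R if r_m is not None else None
    return NondimQuantities(gamma_s=gamma_s, gamma_a=gamma_a, r_bar=r_bar,
                            r_bar_m=r_bar_m, Omega=Omega, Fr=Fr)


def dimensionalize(q: NondimQuantities, m: float, R: float,
                   g: float = G_DEFAULT) -> ARSLIPParams:
    """Inverse of :func:`nondimensionalize` given the unit scales (m, R, g)."""
    return ARSLIPParams(k_s=q.gamma_s * m * g / R, k_a=q.gamma_a * m * g * R,
                        R=R, m=m, g=g)


def slip_params(p: ARSLIPParams) -> ARSLIPParams:
    """The SLIP member of the family: same radial spring, k_a = 0."""
    return replace(p, k_a=0.0)
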