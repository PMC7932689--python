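"""Fly-like vs cockroach-like kinematic regimes of the springy tripod.

Whether a walker shows a mid-stance *maximum* in horizontal speed (fly-like)
or a mid-stance *minimum* (cockroach-like, the classic stiff-SLIP walking
signature) depends on the interplay between the angular spring, which
accelerates the body into mid-stance, and the radial spring plus gravity,
which decelerate it.  Both effective stiffnesses derive from the per-leg
stiffness and the tripod geometry, so the regime is decided by two
dimensionless numbers: gamma_leg = k R_tri / (m g) and the geometry ratio
L / r_m (plus, weakly, the dimensionless speed Fr).

The classifier is fully numerical: it builds the tripod at a given
(gamma_leg, L/r_m), maps it to ARSLIP, simulates a mid-stance-anchored
symmetric step and compares the speed just after mid-stance with the
mid-stance speed.  The per-point natural length R_tri is fixed by mid-stance
static balance (the mapped radial spring force at r_m equals the weight), a
convention that makes the label depend only on (gamma_leg, L/r_m, Fr);
alternative conventions can be supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_model import GeometryError, TripodParams, nondimensionalize, \
    tripod_to_arslip
from .dynamics import FallError, simulate_symmetric_step

__all__ = [
    "RegimePoint",
    "balanced_tripod",
    "classify_kinematics",
    "boundary_curve",
    "gamma_s_vs_geometry",
]


@dataclass
class RegimePoint:
    """Classification of one (stiffness, geometry) combination.

    margin = v(dt) - v(0) (m/s in the working units); negative margin means
    the mid-stance speed is a local maximum (fly-like)."""

    gamma_leg: float
    L_over_rm: float
    Fr: float
    label: str  # "fly_like" or "cockroach_like"
    margin: float


def balanced_tripod(gamma_leg: float, L_over_rm: float, r_m: float = 1.0,
                    m: float = 1.0, g: float = 1.0) -> TripodParams:
    """Tripod at the given nondimensional stiffness and geometry whose
    mapped radial spring force balances gravity at mid-stance.

    With the balance condition k [R_tri - r_m (3 - 2 R_tri / s)] = m g
    (s = sqrt(L^2 + r_m^2)) and the definition gamma_leg = k R_tri / (m g),
    both k and R_tri are determined in closed form:

        k = m g [gamma_leg (1 + 2 r_m / s) - 1] / (3 r_m)
        R_tri = gamma_leg m g / k

    Legs softer than gamma_leg (1 + 2 r_m / s) <= 1 cannot hold the body at
    that height and are rejected.
    """
    if gamma_leg <= 0 or L_over_rm <= 0:
        raise ValueError("gamma_leg and L_over_rm must be positive")
    L = L_over_rm * r_m
    s = math.hypot(L, r_m)
    denom = gamma_leg * (1.0 + 2.0 * r_m / s) - 1.0
    if denom <= 0:
        raise GeometryError(
            f"gamma_leg = {gamma_leg:.3g} too soft to support the body at "
            f"L/r_m = {L_over_rm:.3g}")
    k = m * g * denom / (3.0 * r_m)
    R_tri = gamma_leg * m * g / k
    return TripodParams(k=k, R_tri=R_tri, L=L, r_m=r_m, m=m, g=g)


def classify_kinematics(gamma_leg: float, L_over_rm: float, Fr: float = 0.01,
                        force_slip: bool = False,
                        dt_fraction: float = 0.02) -> RegimePoint:
    """Label one (gamma_leg, L/r_m) point at dimensionless speed Fr.

    Builds the statically balanced tripod, maps it to ARSLIP (k_a forced to
    zero when ``force_slip``), simulates a symmetric step from the
    mid-stance state at the angular speed implied by Fr over a quarter of
    the radial oscillation period each way, and labels the point fly_like
    iff the speed shortly after mid-stance (at dt = ``dt_fraction`` of the
    half-duration) is below the mid-stance speed.
    """
    r_m = 1.0
    tri = balanced_tripod(gamma_leg, L_over_rm, r_m=r_m)
    eff = tripod_to_arslip(tri)  # raises GeometryError outside validity
    if force_slip:
        from dataclasses import replace
        eff = replace(eff, k_a=0.0)
    # Fr = v^2/(g R) with v = r_m * theta_dot at mid-stance
    Omega = math.sqrt(Fr) * eff.R / r_m
    half = 0.5 * math.pi * math.sqrt(eff.m / eff.k_s)  # quarter radial period
    t_probe = dt_fraction * half
    # sample mid-stance and the probe time exactly (the margin is O(dt^2)
    # and must not be polluted by interpolation over a coarse grid)
    traj = simulate_symmetric_step(eff, r_m, Omega,
                                   t_grid=np.array([0.0, t_probe]))
    v = traj.v
    margin = float(v[1] - v[0])
    label = "fly_like" if margin < 0 else "cockroach_like"
    return RegimePoint(gamma_leg=gamma_leg, L_over_rm=L_over_rm, Fr=Fr,
                       label=label, margin=margin)


def _margin(gamma: float, ratio: float, Fr: float) -> float:
    return classify_kinematics(gamma, ratio, Fr).margin


def boundary_curve(L_over_rm_grid: np.ndarray, Fr: float = 0.01,
                   tol: float = 1e-3, gamma_lo: float = 0.1,
                   gamma_hi: float = 1e3) -> np.ndarray:
    """Critical per-leg stiffness gamma_crit(L/r_m) separating the regimes.

    Per grid point, bisects gamma_leg between a cockroach_like and a
    fly_like bracket until the interval is narrower than ``tol`` (relative),
    expanding the bracket upward geometrically when the initial one does not
    straddle the boundary.  Points with no sign change within
    (gamma_lo, gamma_hi] are reported as ``inf`` (unbounded: no leg
    stiffness makes that geometry fly-like at this Fr).
    """
    grid = np.asarray(L_over_rm_grid, dtype=float)
    out = np.empty(len(grid))
    for i, ratio in enumerate(grid):
        s = math.hypot(ratio, 1.0)
        feasible = 1.0 / (1.0 + 2.0 / s)  # static-balance feasibility
        lo = max(gamma_lo, feasible * 1.01)

        def margin_or_nan(gamma: float) -> float:
            try:
                return _margin(gamma, ratio, Fr)
            except (GeometryError, FallError, RuntimeError):
                return np.nan

        m_lo = margin_or_nan(lo)
        # walk lo up past any infeasible/falling region
        while not np.isfinite(m_lo) and lo < gamma_hi:
            lo *= 1.5
            m_lo = margin_or_nan(lo)
        if not np.isfinite(m_lo) or m_lo < 0:
            # already fly-like at the softest feasible leg: boundary at/below
            out[i] = lo if np.isfinite(m_lo) else np.inf
            continue
        hi = lo * 2.0
        m_hi = margin_or_nan(hi)
        while (not np.isfinite(m_hi) or m_hi > 0) and hi < gamma_hi:
            hi *= 2.0
            m_hi = margin_or_nan(hi)
        if not np.isfinite(m_hi) or m_hi > 0:
            out[i] = np.inf  # cockroach-like at every stiffness tried
            continue
        while (hi - lo) / hi > tol:
            mid = math.sqrt(lo * hi)
            m_mid = margin_or_nan(mid)
            if not np.isfinite(m_mid) or m_mid > 0:
                lo = mid
            else:
                hi = mid
        out[i] = math.sqrt(lo * hi)
    return out


def gamma_s_vs_geometry(gamma_leg: float, L_over_rm_grid: np.ndarray
                        ) -> np.ndarray:
    """Mapped nondimensional radial stiffness gamma_s over a geometry grid
    at fixed per-leg stiffness, under the static-balance R_tri convention."""
    grid = np.asarray(L_over_rm_grid, dtype=float)
    out = np.empty(len(grid))
    for i, ratio in enumerate(grid):
        try:
            eff = tripod_to_arslip(balanced_tripod(gamma_leg, ratio))
            out[i] = nondimensionalize(eff).gamma_s
        except (GeometryError, ValueError):
            out[i] = np.nan
    return out
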