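"""Integration of the SLIP/ARSLIP equations of motion.

The effective leg obeys the Euler-Lagrange equations in polar coordinates
(r, theta) about the foothold:

    r''     = r theta'^2 + (k_s/m) (R - r) - g cos(theta)
    theta'' = -2 theta' r' / r - k_a theta / (m r^2) + (g / r) sin(theta)

SLIP is the exact k_a = 0 special case.  The system is conservative; the
total energy (kinetic + elastic + gravitational, reference at the foothold)
is the integration-accuracy watchdog: every simulated step must conserve it
to ~1e-8 relative, which drives the default solver tolerances
(rtol = 1e-10, atol = 1e-12, dense output).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .core_model import ARSLIPParams, CoMState, InitialConditions

__all__ = [
    "CoMTrajectory",
    "FallError",
    "arslip_derivatives",
    "total_energy",
    "simulate_step",
    "simulate_symmetric_step",
]

RTOL_DEFAULT = 1e-10
ATOL_DEFAULT = 1e-12


class FallError(RuntimeError):
    """The model fell during integration (leg fully compressed or the body
    swung past horizontal)."""

    def __init__(self, message: str, t_fall: float):
        super().__init__(message)
        self.t_fall = t_fall


@dataclass
class CoMTrajectory:
    """Time-sampled sagittal CoM track relative to the effective foothold.

    t : time samples (s, strictly increasing); x : horizontal position (m);
    z : height (m); v : horizontal speed (m/s); states : the underlying
    polar states for model-generated tracks (x = r sin(theta),
    z = r cos(theta)).
    """

    t: np.ndarray
    x: np.ndarray
    z: np.ndarray
    v: np.ndarray | None = None
    states: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.z)):
            raise ValueError("t, x, z must have equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")

    @property
    def speed(self) -> np.ndarray:
        """Horizontal speed; exact for model tracks, finite-difference
        otherwise."""
        if self.v is not None:
            return np.asarray(self.v, dtype=float)
        return np.gradient(self.x, self.t)


def arslip_derivatives(state: CoMState, p: ARSLIPParams) -> tuple[float, float]:
    """(r'', theta'') of the ARSLIP system at ``state``.  k_a = 0 gives the
    SLIP system exactly."""
    if state.r <= 0:
        raise ValueError("r must be > 0 (singularity at r = 0)")
    r, th, rd, thd = state.r, state.theta, state.r_dot, state.theta_dot
    r_dd = r * thd ** 2 + (p.k_s / p.m) * (p.R - r) - p.g * math.cos(th)
    th_dd = (-2.0 * thd * rd / r - p.k_a * th / (p.m * r ** 2)
             + (p.g / r) * math.sin(th))
    return r_dd, th_dd


def total_energy(state: CoMState, p: ARSLIPParams) -> float:
    """Conserved energy E = 1/2 m (r'^2 + r^2 theta'^2)
    + 1/2 k_s (R - r)^2 + 1/2 k_a theta^2 + m g r cos(theta),
    gravitational reference at the foothold."""
    kinetic = 0.5 * p.m * (state.r_dot ** 2
                           + (state.r * state.theta_dot) ** 2)
    elastic = (0.5 * p.k_s * (p.R - state.r) ** 2
               + 0.5 * p.k_a * state.theta ** 2)
    gravity = p.m * p.g * state.r * math.cos(state.theta)
    return kinetic + elastic + gravity


def _rhs(p: ARSLIPParams):
    k_s, k_a, R, m, g = p.k_s, p.k_a, p.R, p.m, p.g

    def rhs(t: float, y: np.ndarray) -> list[float]:
        r, th, rd, thd = y
        r_dd = r * thd * thd + (k_s / m) * (R - r) - g * math.cos(th)
        th_dd = (-2.0 * thd * rd / r - k_a * th / (m * r * r)
                 + (g / r) * math.sin(th))
        return [rd, thd, r_dd, th_dd]

    return rhs


def _fall_events(p: ARSLIPParams):
    r_floor = 0.05 * p.R

    def leg_collapse(t, y):
        return y[0] - r_floor

    def overswing(t, y):
        return abs(y[1]) - math.pi / 2

    leg_collapse.terminal = True
    leg_collapse.direction = -1
    overswing.terminal = True
    overswing.direction = 1
    return [leg_collapse, overswing]


def _integrate(p: ARSLIPParams, y0: np.ndarray, t_grid: np.ndarray,
               rtol: float, atol: float) -> np.ndarray:
    """Integrate from t_grid[0] to t_grid[-1]; return states (4, n)."""
    sol = solve_ivp(_rhs(p), (t_grid[0], t_grid[-1]), y0, method="DOP853",
                    t_eval=t_grid, rtol=rtol, atol=atol,
                    events=_fall_events(p))
    if sol.status == 1:  # terminated by a fall event
        t_fall = min(float(te[0]) for te in sol.t_events if len(te))
        raise FallError(f"model fell at t = {t_fall:.6g} s", t_fall)
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    return sol.y


def _to_trajectory(t_grid: np.ndarray, states: np.ndarray) -> CoMTrajectory:
    r, th, rd, thd = states
    x = r * np.sin(th)
    z = r * np.cos(th)
    v = rd * np.sin(th) + r * thd * np.cos(th)  # exact horizontal speed
    return CoMTrajectory(t=t_grid, x=x, z=z, v=v, states=states)


def simulate_step(p: ARSLIPParams, ic: InitialConditions,
                  t_grid: np.ndarray, rtol: float = RTOL_DEFAULT,
                  atol: float = ATOL_DEFAULT) -> CoMTrajectory:
    """Integrate one stance from touch-down state theta(0) = -alpha,
    sampling exactly at ``t_grid`` (dense output of an adaptive DOP853 run).

    Raises :class:`FallError` if the leg collapses (r <= 0.05 R) or the body
    swings past |theta| = pi/2.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or not np.all(np.diff(t_grid) > 0):
        raise ValueError("t_grid must be 1-D, increasing, length >= 2")
    if ic.r0 <= 0:
        raise ValueError("r0 must be > 0")
    y0 = np.array([ic.r0, -ic.alpha, ic.r_dot0, ic.theta_dot0])
    states = _integrate(p, y0, t_grid, rtol, atol)
    return _to_trajectory(t_grid, states)


def simulate_symmetric_step(p: ARSLIPParams, r_m: float, Omega: float,
                            half_duration: float | None = None,
                            n_samples: int = 201,
                            t_grid: np.ndarray | None = None,
                            rtol: float = RTOL_DEFAULT,
                            atol: float = ATOL_DEFAULT) -> CoMTrajectory:
    """Mid-stance-anchored run: start at theta = 0, r = r_m, r' = 0,
    theta' = Omega sqrt(g/R); integrate +-half_duration and concatenate.

    The backward half is obtained by time reflection (negating the rates),
    valid because the system is autonomous and reversible; the output
    therefore satisfies z(t) = z(-t) and v(t) = v(-t) exactly up to solver
    tolerance.  Time t = 0 is mid-stance.  An explicit ``t_grid`` (strictly
    increasing, straddling or touching 0) overrides the symmetric
    ``n_samples`` grid, e.g. to sample at camera frame times.
    """
    if r_m <= 0:
        raise ValueError("r_m must be > 0")
    theta_dot0 = Omega * math.sqrt(p.g / p.R)
    y0 = np.array([r_m, 0.0, 0.0, theta_dot0])
    y0_rev = np.array([r_m, 0.0, 0.0, -theta_dot0])

    if t_grid is None:
        if half_duration is None or half_duration <= 0:
            raise ValueError("half_duration must be > 0")
        n_half = max(2, (n_samples + 1) // 2)
        t_grid = np.concatenate(
            [-np.linspace(0.0, half_duration, n_half)[::-1][:-1],
             np.linspace(0.0, half_duration, n_half)])
    else:
        t_grid = np.asarray(t_grid, dtype=float)
        if t_grid.ndim != 1 or len(t_grid) < 2 \
                or not np.all(np.diff(t_grid) > 0):
            raise ValueError("t_grid must be 1-D, increasing, length >= 2")

    pos = t_grid[t_grid >= 0]
    neg = t_grid[t_grid < 0]
    parts = []
    if len(neg):
        # integrate the past as a forward run with reversed rates; the state
        # at -t is [r, theta, -r_dot, -theta_dot] of that run
        grid_b = np.concatenate([[0.0], -neg[::-1]])
        bwd = _integrate(p, y0_rev, grid_b, rtol, atol)[:, 1:]
        bwd_states = np.vstack([bwd[0], bwd[1], -bwd[2], -bwd[3]])
        parts.append(bwd_states[:, ::-1])
    if len(pos) == 1 and pos[0] == 0.0:
        parts.append(y0[:, None])
    elif len(pos):
        prepended = pos[0] > 0
        grid_f = np.concatenate([[0.0], pos]) if prepended else pos
        fwd = _integrate(p, y0, grid_f, rtol, atol)
        parts.append(fwd[:, 1:] if prepended else fwd)
    states = np.concatenate(parts, axis=1)
    return _to_trajectory(t_grid, states)


def energy_drift(traj: CoMTrajectory, p: ARSLIPParams) -> float:
    """max |E(t) - E(0)| / |E(0)| along a model-generated trajectory."""
    if traj.states is None:
        raise ValueError("trajectory has no stored states")
    r, th, rd, thd = traj.states
    kinetic = 0.5 * p.m * (rd ** 2 + (r * thd) ** 2)
    elastic = 0.5 * p.k_s * (p.R - r) ** 2 + 0.5 * p.k_a * th ** 2
    gravity = p.m * p.g * r * np.cos(th)
    E = kinetic + elastic + gravity
    return float(np.max(np.abs(E - E[0])) / abs(E[0]))
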