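"""Synthetic walking datasets with embedded ground truth.

Emulates the tabular output of a high-speed (380 Hz) recording of a fly
walking straight: a sagittal CoM track with Gaussian measurement noise
(vertical sigma ~ 20 um), an M-tripod footfall schedule whose stance
durations scale as the reciprocal of speed and swing durations shrink
weakly and linearly with speed, per-step tripod geometry following the
fly-typical L/r_m in [1, 2] (narrower and taller tripods at higher Fr), and
body-frame leg tracks.  The CoM within each tripod stance is generated by
the springy-tripod -> ARSLIP mapping and the ARSLIP equations of motion, so
every downstream stage (gait, step kinematics, fitting, regime) can be
tested against recorded truth.

All randomness flows from a single seed; equal seeds give identical data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_model import (ARSLIPParams, InitialConditions, TripodParams,
                         tripod_to_arslip)
from .dynamics import CoMTrajectory, FallError, simulate_step, \
    simulate_symmetric_step
from .gait import LEGS, TRIPOD_1, TRIPOD_2, FootfallSequence, LegTracks

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "tripod_for_geometry",
    "generate_step",
    "generate_fly_dataset",
]


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic walker (SI units).

    Speed laws (v in m/s): stance duration = stance_coeff / v with
    stance_coeff in metres (the CoM path length covered during a leg's
    stance), swing duration = swing_intercept + swing_slope * v.  The
    equivalent of the field-conventional mm/s form (slope -0.00018 s per
    mm/s, intercept 0.03 s) is the default.  Per-step geometry follows
    L/r_m = clip(lr_intercept + lr_slope * Fr, lr_range), decreasing with
    Fr within the fly-typical [1, 2].  The per-fly ground truth is a single
    per-leg stiffness k_leg and natural leg length R_tri; the mid-stance
    height of each step follows from static balance at its geometry.
    """

    n_steps: int = 20
    speed_range: tuple[float, float] = (8e-3, 30e-3)   # m/s
    frame_rate: float = 380.0                          # Hz
    sigma_z: float = 20e-6                             # m
    sigma_x: float = 20e-6                             # m
    delta_meso_pro: float = 0.05                       # cycle fraction
    delta_meta_meso: float = 0.05                      # cycle fraction
    duty: float = 0.6                # for fixed-period fixtures only
    stance_coeff: float = 0.75e-3                      # m
    swing_slope: float = -0.18                         # s per m/s
    swing_intercept: float = 0.03                      # s
    lr_intercept: float = 2.1
    lr_slope: float = -24.0                            # per unit Fr
    lr_range: tuple[float, float] = (1.0, 2.0)
    mass: float = 1.123e-6                             # kg
    R_real: float = 2.042e-3                           # m
    k_leg: float = 0.008                               # N/m
    R_tri: float | None = None                         # default: R_real
    g: float = 9.807
    fly_id: str = "synthfly"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if not 0.0 < self.duty < 1.0:
            raise ValueError("duty must be in (0, 1)")
        if not (0.5 <= self.lr_range[0] <= self.lr_range[1] <= 8.0):
            raise ValueError("lr_range must lie within [0.5, 8]")
        if self.R_tri is None:
            self.R_tri = self.R_real

    def stance_duration(self, v: float) -> float:
        return self.stance_coeff / v

    def swing_duration(self, v: float) -> float:
        return self.swing_intercept + self.swing_slope * v

    def l_over_rm(self, Fr: float) -> float:
        raw = self.lr_intercept + self.lr_slope * Fr
        return float(np.clip(raw, *self.lr_range))


@dataclass
class SyntheticDataset:
    """Generated bundle: world-frame CoM (noisy), footfalls, leg tracks, and
    the per-step/ per-fly ground truth."""

    com: CoMTrajectory
    com_clean: CoMTrajectory
    footfalls: FootfallSequence
    leg_tracks: LegTracks
    truth: dict
    config: SyntheticConfig


def tripod_for_geometry(cfg: SyntheticConfig, l_over_rm: float
                        ) -> TripodParams:
    """True tripod at one step's geometry: r_m from mid-stance static
    balance (linear in r_m for fixed L/r_m), L = (L/r_m) * r_m."""
    s_hat = math.hypot(l_over_rm, 1.0)
    mg = cfg.mass * cfg.g
    r_m = (cfg.R_tri * (1.0 + 2.0 / s_hat) - mg / cfg.k_leg) / 3.0
    if r_m <= 0:
        raise ValueError("configured k_leg/R_tri cannot support the body")
    return TripodParams(k=cfg.k_leg, R_tri=cfg.R_tri, L=l_over_rm * r_m,
                        r_m=r_m, m=cfg.mass, g=cfg.g)


def generate_step(p_true: ARSLIPParams, ic: InitialConditions,
                  cfg: SyntheticConfig, seed: int, duration: float
                  ) -> tuple[CoMTrajectory, dict]:
    """One noisy CoM step from known ARSLIP parameters, sampled at the
    configured frame rate, plus its embedded ground truth.

    If the simulated step falls, the angle of attack is reduced by 30% and
    the step regenerated, up to 5 attempts.
    """
    rng = np.random.default_rng(seed)
    n = max(5, int(math.floor(duration * cfg.frame_rate)) + 1)
    t_grid = np.arange(n) / cfg.frame_rate
    alpha = ic.alpha
    last_err: FallError | None = None
    for _ in range(5):
        try:
            clean = simulate_step(p_true, InitialConditions(
                alpha=alpha, r0=ic.r0, r_dot0=ic.r_dot0,
                theta_dot0=ic.theta_dot0), t_grid)
            break
        except FallError as err:
            last_err = err
            alpha *= 0.7
    else:
        raise last_err
    x = clean.x + rng.normal(0.0, cfg.sigma_x, n)
    z = clean.z + rng.normal(0.0, cfg.sigma_z, n)
    noisy = CoMTrajectory(t=t_grid, x=x, z=z)
    truth = {"params": p_true, "alpha": alpha, "r0": ic.r0,
             "r_dot0": ic.r_dot0, "theta_dot0": ic.theta_dot0,
             "clean": clean, "seed": seed}
    return noisy, truth


def _build_schedule(cfg: SyntheticConfig, speeds: np.ndarray
                    ) -> tuple[dict, dict, list[dict]]:
    """Per-cycle M-tripod schedule with speed-dependent durations.

    Returns (intervals, cycle map) where intervals is {leg: (n, 2)} and the
    cycle map lists, per tripod event in time order, its tripod, cycle index
    and commanded speed.
    """
    offsets = {
        "R1": 0.0, "L2": cfg.delta_meso_pro,
        "R3": cfg.delta_meso_pro + cfg.delta_meta_meso,
        "L1": 0.5, "R2": 0.5 + cfg.delta_meso_pro,
        "L3": 0.5 + cfg.delta_meso_pro + cfg.delta_meta_meso,
    }
    intervals: dict[str, list] = {leg: [] for leg in LEGS}
    events = []
    t0 = 0.0
    for j, v in enumerate(speeds):
        stance = cfg.stance_duration(v)
        swing = cfg.swing_duration(v)
        if swing <= 0:
            continue  # infeasible speed/duration combination: skip cycle
        T = stance + swing
        for leg in LEGS:
            td = t0 + offsets[leg] * T
            intervals[leg].append((td, td + stance))
        for tripod in (TRIPOD_1, TRIPOD_2):
            first_td = t0 + min(offsets[leg] for leg in tripod) * T
            events.append({"tripod": tripod, "cycle": j, "speed": v,
                           "t0": first_td})
        t0 += T
    # abrupt slow-downs could otherwise make a long stance run into the same
    # leg's next touch-down; keep a one-frame swing at minimum
    gap = 1.0 / cfg.frame_rate
    iv = {}
    for leg, rows in intervals.items():
        arr = np.asarray(rows)
        arr[:-1, 1] = np.minimum(arr[:-1, 1], arr[1:, 0] - gap)
        iv[leg] = arr
    events.sort(key=lambda e: e["t0"])
    return iv, offsets, events


def generate_fly_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Full synthetic walking bout.

    Per-cycle speeds are drawn uniformly from ``cfg.speed_range``; footfall
    timing follows the M-tripod offsets with the speed-law durations; each
    tripod stance window (defined exactly as in the analysis: midpoints
    between adjacent tripods' touch-downs and lift-offs) carries an
    ARSLIP-generated CoM piece anchored at its mid-time, with geometry from
    the L/r_m-vs-Fr law and the per-fly (k_leg, R_tri) truth; pieces are
    stitched with position continuity (velocity jumps at boundaries are
    allowed, as the effective-leg model is per-step).  Gaussian measurement
    noise is added to the CoM; leg tracks are body-frame foothold-minus-CoM
    positions in stance with linear return ramps in swing.
    """
    from .step_kinematics import tripod_step_windows

    rng = np.random.default_rng(cfg.seed)
    n_cycles = (cfg.n_steps + 2 + 1) // 2 + 1
    # bounded random walk over the speed range: flies modulate their speed
    # gradually, and gentle cycle-to-cycle changes keep the footfall
    # schedule self-consistent
    lo, hi = cfg.speed_range
    dv = 0.2 * (hi - lo)
    speeds = np.empty(n_cycles)
    speeds[0] = rng.uniform(lo, hi)
    for j in range(1, n_cycles):
        step = rng.uniform(-dv, dv)
        v = speeds[j - 1] + step
        if v > hi:
            v = hi - (v - hi)
        elif v < lo:
            v = lo + (lo - v)
        speeds[j] = float(np.clip(v, lo, hi))
    intervals, _, events = _build_schedule(cfg, speeds)
    span = (0.0, float(max(iv[-1, 1] for iv in intervals.values())))
    placeholder = {leg: np.zeros((len(intervals[leg]), 2)) for leg in LEGS}
    footfalls = FootfallSequence(intervals=intervals, footholds=placeholder,
                                 span=span)
    windows = tripod_step_windows(footfalls)[:cfg.n_steps]
    if not windows:
        raise ValueError("configuration produced no complete tripod stances")

    frame_dt = 1.0 / cfg.frame_rate
    t_start = windows[0].window[0]
    t_end = windows[-1].window[1]
    t = t_start + np.arange(int((t_end - t_start) / frame_dt) + 1) * frame_dt

    x_world = np.full(len(t), np.nan)
    z_world = np.full(len(t), np.nan)
    v_world = np.full(len(t), np.nan)
    truth_steps = []
    x_cursor = 0.0
    half_width = 1.0e-3

    for idx, step in enumerate(windows):
        w0, w1 = step.window
        t_mid = 0.5 * (w0 + w1)
        ev = min(events, key=lambda e: abs(e["t0"] - w0))
        v_cmd = ev["speed"]
        Fr = v_cmd ** 2 / (cfg.g * cfg.R_real)
        ratio = cfg.l_over_rm(Fr)
        tri = tripod_for_geometry(cfg, ratio)
        eff = tripod_to_arslip(tri)
        theta_dot_mid = v_cmd / tri.r_m
        Omega = theta_dot_mid * math.sqrt(eff.R / eff.g)

        sel = (t >= w0 - 1e-12) & (t <= w1 + 1e-12)
        tau = t[sel] - t_mid
        tau_lo, tau_hi = w0 - t_mid, w1 - t_mid
        grid = np.unique(np.concatenate([[tau_lo, tau_hi], tau]))
        traj = simulate_symmetric_step(eff, tri.r_m, Omega, t_grid=grid)
        x_lo = float(np.interp(tau_lo, traj.t, traj.x))
        x_hi = float(np.interp(tau_hi, traj.t, traj.x))
        foothold_x = x_cursor - x_lo
        x_cursor = foothold_x + x_hi

        keep = np.isin(grid, tau)
        x_world[sel] = foothold_x + traj.x[keep]
        z_world[sel] = traj.z[keep]
        v_world[sel] = traj.v[keep]

        # place the tripod's footholds: front/hind straddle the effective
        # foothold by +-L, middle at the foothold (sagittal projection)
        front, middle, hind = step.tripod
        leg_x = {front: foothold_x + tri.L, middle: foothold_x,
                 hind: foothold_x - tri.L}
        for leg in step.tripod:
            iv = footfalls.intervals[leg]
            j = int(np.argmin(np.abs(iv[:, 0] - w0)))
            y = half_width if leg.startswith("R") else -half_width
            footfalls.footholds[leg][j] = (leg_x[leg], y)

        truth_steps.append({
            "step": idx, "window": (w0, w1), "tripod": step.tripod,
            "speed": v_cmd, "Fr": Fr, "L_over_rm": ratio, "L": tri.L,
            "r_m": tri.r_m, "foothold_x": foothold_x,
            "k_s": eff.k_s, "k_a": eff.k_a, "R": eff.R,
            "theta_dot_mid": theta_dot_mid,
        })

    # flanking footholds (no window of their own): extend the pattern so
    # leg tracks are well-defined at the bout edges
    stride = np.median([s["foothold_x"] for s in truth_steps[1:]]) \
        - np.median([s["foothold_x"] for s in truth_steps[:-1]]) \
        if len(truth_steps) > 1 else 1e-3
    for leg in LEGS:
        fh = footfalls.footholds[leg]
        placed = np.flatnonzero(np.any(fh != 0, axis=1))
        if len(placed) == 0:
            continue
        for j in range(len(fh)):
            if not np.any(fh[j] != 0):
                ref = placed[np.argmin(np.abs(placed - j))]
                fh[j] = fh[ref] + ((j - ref) * stride, 0.0)

    com_clean = CoMTrajectory(t=t, x=x_world.copy(), z=z_world.copy(),
                              v=v_world)
    x_noisy = x_world + rng.normal(0.0, cfg.sigma_x, len(t))
    z_noisy = z_world + rng.normal(0.0, cfg.sigma_z, len(t))
    com = CoMTrajectory(t=t, x=x_noisy, z=z_noisy)

    leg_tracks = _leg_tracks_from(footfalls, com_clean)

    truth = {
        "fly": {"fly_id": cfg.fly_id, "k_leg": cfg.k_leg,
                "R_tri": cfg.R_tri, "mass": cfg.mass, "R_real": cfg.R_real,
                "g": cfg.g},
        "steps": truth_steps,
        "seed": cfg.seed,
    }
    return SyntheticDataset(com=com, com_clean=com_clean,
                            footfalls=footfalls, leg_tracks=leg_tracks,
                            truth=truth, config=cfg)


def _leg_tracks_from(f: FootfallSequence, com: CoMTrajectory) -> LegTracks:
    """Body-frame leg positions: foothold minus CoM while in stance (the
    leg tip sweeps anterior -> posterior), linear AEP return ramps in
    swing, constant extrapolation at the edges."""
    t = com.t
    y: dict[str, np.ndarray] = {}
    stance: dict[str, np.ndarray] = {}
    for leg in f.intervals:
        iv = f.intervals[leg]
        fh = f.footholds[leg]
        yy = np.full(len(t), np.nan)
        st = np.zeros(len(t), dtype=bool)
        for (td, lo), (fx, _) in zip(iv, fh):
            sel = (t >= td) & (t < lo)
            yy[sel] = fx - com.x[sel]
            st[sel] = True
        known = np.isfinite(yy)
        if known.any():
            yy[~known] = np.interp(t[~known], t[known], yy[known])
        else:
            yy[:] = 0.0
        y[leg] = yy
        stance[leg] = st
    return LegTracks(t=t, y=y, stance=stance)
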