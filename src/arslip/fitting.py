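"""Constrained fitting of SLIP/ARSLIP to per-step CoM trajectories, and the
per-fly prediction of spring constants from tripod geometry.

Per step, the free parameters are the spring constants (k_s, and k_a for
ARSLIP), the natural leg length R (within +-10% of the fly's measured leg
length R_real) and the initial rates (within +-10% of their measured
values); the initial r and theta are fixed from the data.  The objective is
the sum of the height and horizontal-position RMSEs between the simulated
and measured CoM.  The global search is a seeded Latin-hypercube multi-start
with bounded least-squares refinement and a final derivative-free polish of
the exact objective; the ARSLIP search can be seeded with the SLIP optimum
(k_a = 0), which makes the model-nesting inequality hold by construction.

Per fly, a single per-leg stiffness k and natural leg length R_tri are found
whose springy-tripod mapping at each step's measured geometry (L, r_m) best
reproduces the per-step fitted (k_s, k_a) in relative terms; comparing the
predicted and fitted nondimensional stiffnesses tests whether tripod
geometry alone explains the step-to-step stiffness variation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize
from scipy.stats import qmc

from .core_model import (ARSLIPParams, GeometryError, InitialConditions,
                         TripodParams, nondimensionalize, tripod_to_arslip)
from .dynamics import CoMTrajectory, FallError, simulate_step

__all__ = [
    "KS_MAX",
    "KA_MAX",
    "FitResult",
    "FlyTripodFit",
    "estimate_initial_conditions",
    "fit_step",
    "fit_both_models",
    "compare_models",
    "fit_fly_tripod",
]

KS_MAX = 0.050   # N/m   (search range 0 < k_s < 50e-3 N/m)
KA_MAX = 50e-9   # N*m   (search range 0 <= k_a < 50e-9 N*m)
KS_MIN = 1e-4 * KS_MAX
FIT_RTOL = 1e-8
FIT_ATOL = 1e-12


@dataclass
class FitResult:
    """Best fit of one model to one step."""

    model: str                      # "SLIP" or "ARSLIP"
    k_s: float
    k_a: float | None               # None for SLIP
    R: float
    r_dot0: float
    theta_dot0: float
    r0: float
    theta0: float
    rmse_z: float
    rmse_x: float
    n_starts: int
    converged: bool
    seed: int
    mass: float = np.nan
    g: float = 9.807

    @property
    def objective(self) -> float:
        return self.rmse_z + self.rmse_x

    def params(self) -> ARSLIPParams:
        """The fitted constants as ARSLIP parameters (k_a = 0 for SLIP)."""
        return ARSLIPParams(k_s=self.k_s, k_a=self.k_a or 0.0, R=self.R,
                            m=self.mass, g=self.g)


@dataclass
class FlyTripodFit:
    """Single per-fly (k, R_tri) and the per-step predicted vs fitted
    nondimensional spring constants."""

    k: float
    R_tri: float
    gamma_a_pred: np.ndarray
    gamma_a_fit: np.ndarray
    gamma_s_pred: np.ndarray
    gamma_s_fit: np.ndarray
    R_pred: np.ndarray
    residual: float
    corr_gamma_a: float
    corr_gamma_s: float
    n_steps: int
    excluded: list[int] = field(default_factory=list)


def estimate_initial_conditions(com: CoMTrajectory,
                                window: tuple[float, float],
                                foothold_x: float,
                                n_frames: int = 5
                                ) -> tuple[float, float, float, float, bool]:
    """(r0, theta0, r_dot0_meas, theta_dot0_meas, flagged) at window start.

    r and theta come from the first frame's CoM relative to the effective
    foothold; the rates are the time derivatives, evaluated at the first
    frame, of local least-squares quadratics through the first ``n_frames``
    frames of r(t) and theta(t) (the trajectory curves appreciably within a
    few frames, so a straight-line slope would estimate the rate a couple
    of frames in, not at the window start).  Falls back to a 3-frame linear
    fit, flagged, when fewer frames are available.
    """
    sel = (com.t >= window[0]) & (com.t <= window[1])
    t = com.t[sel]
    x = com.x[sel] - foothold_x
    z = com.z[sel]
    if len(t) < 3:
        raise ValueError("need at least 3 samples at window start")
    flagged = len(t) < n_frames
    n = n_frames if not flagged else 3
    deg = 2 if n >= 5 else 1
    r = np.hypot(x[:n], z[:n])
    theta = np.arctan2(x[:n], z[:n])
    tt = t[:n] - t[0]
    r_dot = float(np.polyval(np.polyder(np.polyfit(tt, r, deg)), 0.0))
    theta_dot = float(np.polyval(np.polyder(np.polyfit(tt, theta, deg)), 0.0))
    return float(r[0]), float(theta[0]), r_dot, theta_dot, flagged


def _noise_sigma(y: np.ndarray) -> float:
    """Robust per-sample noise estimate from fourth differences.

    For white noise sigma on a smooth signal, Var(fourth difference) =
    70 sigma^2, while a smooth trajectory contributes only
    O(d4y/dt4 * dt^4) -- negligible at 380 Hz even for the fastest
    fly-scale steps, so tracking noise separates cleanly from dynamics.
    """
    d4 = np.diff(y, n=4)
    if len(d4) == 0:
        return 0.0
    mad = np.median(np.abs(d4 - np.median(d4)))
    return float(1.4826 * mad / math.sqrt(70.0))


def _rate_bounds(v: float, frac: float = 0.10,
                 floor: float = 1e-9) -> tuple[float, float]:
    """+-frac band about a measured rate (tiny symmetric band at zero)."""
    if abs(v) < floor:
        return (-floor, floor)
    lo, hi = sorted(((1 - frac) * v, (1 + frac) * v))
    return (lo, hi)


class _StepObjective:
    """Maps a unit-box parameter vector to (rmse_z, rmse_x) for one step."""

    def __init__(self, t: np.ndarray, x: np.ndarray, z: np.ndarray,
                 r0: float, theta0: float, bounds: list[tuple[float, float]],
                 model: str, mass: float, g: float):
        self.t = t - t[0]
        self.x = x
        self.z = z
        self.r0 = r0
        self.theta0 = theta0
        self.lo = np.array([b[0] for b in bounds])
        self.hi = np.array([b[1] for b in bounds])
        self.model = model
        self.mass = mass
        self.g = g
        self.scale = math.hypot(float(np.std(z)) + 1e-12,
                                float(np.std(x)) + 1e-12)

    def unmap(self, u: np.ndarray) -> np.ndarray:
        return self.lo + np.clip(u, 0.0, 1.0) * (self.hi - self.lo)

    def _unpack(self, u: np.ndarray) -> tuple[ARSLIPParams, InitialConditions]:
        p = self.unmap(u)
        if self.model == "ARSLIP":
            k_s, k_a, R, r_dot0, theta_dot0 = p
        else:
            k_s, R, r_dot0, theta_dot0 = p
            k_a = 0.0
        params = ARSLIPParams(k_s=k_s, k_a=k_a, R=R, m=self.mass, g=self.g)
        ic = InitialConditions(alpha=-self.theta0, r0=self.r0,
                               r_dot0=r_dot0, theta_dot0=theta_dot0)
        return params, ic

    def simulate(self, u: np.ndarray) -> CoMTrajectory:
        params, ic = self._unpack(u)
        return simulate_step(params, ic, self.t, rtol=FIT_RTOL,
                             atol=FIT_ATOL)

    def residuals(self, u: np.ndarray) -> np.ndarray:
        try:
            traj = self.simulate(u)
        except (FallError, RuntimeError, ValueError):
            return np.full(2 * len(self.t), 10.0 * self.scale + 1e-3)
        n = len(self.t)
        return np.concatenate([(traj.z - self.z) / math.sqrt(n),
                               (traj.x - self.x) / math.sqrt(n)])

    def rmse(self, u: np.ndarray) -> tuple[float, float]:
        try:
            traj = self.simulate(u)
        except (FallError, RuntimeError, ValueError):
            return (10.0 * self.scale + 1e-3, 10.0 * self.scale + 1e-3)
        rmse_z = float(np.sqrt(np.mean((traj.z - self.z) ** 2)))
        rmse_x = float(np.sqrt(np.mean((traj.x - self.x) ** 2)))
        return rmse_z, rmse_x

    def objective(self, u: np.ndarray) -> float:
        rz, rx = self.rmse(u)
        return rz + rx


def fit_step(com: CoMTrajectory, window: tuple[float, float], model: str,
             R_real: float, mass: float, foothold_x: float = 0.0,
             g: float = 9.807, seed: int = 0, n_starts: int = 8,
             extra_starts: list[dict] | None = None,
             polish: bool = True) -> FitResult:
    """Fit one model ("SLIP" or "ARSLIP") to the CoM over one step window.

    Multi-start global search (seeded Latin hypercube over the bounded box,
    bounded least-squares refinement, derivative-free polish of the exact
    rmse_z + rmse_x objective), deterministic under a fixed seed.
    ``extra_starts`` entries (dicts with k_s, k_a, R, r_dot0, theta_dot0)
    are both used as additional local-search starts and evaluated verbatim,
    so a SLIP optimum passed to an ARSLIP fit bounds the result from above.
    Returns a non-converged result with infinite RMSEs if every start falls.
    """
    model = model.upper()
    if model not in ("SLIP", "ARSLIP"):
        raise ValueError("model must be 'SLIP' or 'ARSLIP'")
    sel = (com.t >= window[0]) & (com.t <= window[1])
    t, z = com.t[sel], com.z[sel]
    x = com.x[sel] - foothold_x
    if len(t) < 5:
        raise ValueError("window must contain at least 5 samples")
    # measured rates anchor +-10% box constraints; an edge derivative
    # amplifies measurement noise by ~1/dt, so under measurable tracking
    # noise estimate over a wider quadratic window (variance down ~n^3)
    # at the cost of some curvature bias
    sigma_hat = math.hypot(_noise_sigma(z), _noise_sigma(x))
    n_rate = 5 if sigma_hat < 6e-6 else int(min(13, max(5, len(t) // 2)))
    r0, theta0, rd0_m, thd0_m, _ = estimate_initial_conditions(
        com, window, foothold_x, n_frames=n_rate)

    bounds = [(KS_MIN, KS_MAX)]
    if model == "ARSLIP":
        bounds.append((0.0, KA_MAX))
    bounds += [(0.90 * R_real, 1.10 * R_real),
               _rate_bounds(rd0_m), _rate_bounds(thd0_m)]
    obj = _StepObjective(t, x, z, r0, theta0, bounds, model, mass, g)
    d = len(bounds)

    # spread starts over the stiffness dimensions only: the rate boxes are
    # narrow (+-10% of the measurement), so every start begins at the
    # measured rates and lets the local refinement adjust them
    starts = []
    for u in qmc.LatinHypercube(d=d - 2, seed=seed).random(n_starts):
        starts.append(np.concatenate([u, [0.5, 0.5]]))
    starts.append(np.full(d, 0.5))  # data-informed center start

    candidates: list[tuple[float, np.ndarray]] = []
    for extra in extra_starts or []:
        p = [extra["k_s"]]
        if model == "ARSLIP":
            p.append(extra.get("k_a", 0.0))
        p += [extra["R"], extra["r_dot0"], extra["theta_dot0"]]
        u = (np.array(p) - obj.lo) / (obj.hi - obj.lo)
        u = np.clip(u, 0.0, 1.0)
        candidates.append((obj.objective(u), u))
        starts.append(u)

    # cheap first pass over all starts; stop early if a start reaches the
    # numerical floor of the objective
    floor = 1e-5 * obj.scale
    center_idx = len(starts) - 1  # the data-informed center start
    center_candidates = []
    for j, u0 in enumerate(starts):
        u0 = np.asarray(u0, dtype=float)
        f0 = obj.objective(u0)
        if not np.isfinite(f0) or f0 >= 10.0 * obj.scale:
            candidates.append((f0, u0))
            continue
        try:
            res = least_squares(obj.residuals, u0, bounds=(0.0, 1.0),
                                diff_step=1e-6, xtol=1e-10, ftol=1e-10,
                                gtol=1e-12, max_nfev=40)
            candidates.append((obj.objective(res.x), res.x))
        except Exception:
            candidates.append((f0, u0))
        if j == center_idx:
            center_candidates.append(candidates[-1])
        if candidates[-1][0] < floor:
            break

    candidates.sort(key=lambda c: c[0])
    best_f, best_u = candidates[0]
    converged = np.isfinite(best_f) and best_f < 10.0 * obj.scale
    if not converged:
        # every start fell: probe a deterministic coarse grid over the
        # stiffness dimensions (rates at the measured centers) for any
        # surviving parameter set before giving up
        # dense along k_s (the survival-critical dimension), coarse in the
        # others
        import itertools as _it
        ks_levels = np.linspace(0.03, 0.97, 16)
        other = [(0.1, 0.5, 0.9)] * (d - 3)
        probes = []
        for combo in _it.product(ks_levels, *other):
            u0 = np.concatenate([combo, [0.5, 0.5]])
            f0 = obj.objective(u0)
            if np.isfinite(f0) and f0 < 10.0 * obj.scale:
                probes.append((f0, u0))
        probes.sort(key=lambda c: c[0])
        for f0, u0 in probes[:2]:
            try:
                res = least_squares(obj.residuals, u0, bounds=(0.0, 1.0),
                                    diff_step=1e-6, xtol=1e-12, ftol=1e-12,
                                    gtol=1e-13, max_nfev=200)
                f = obj.objective(res.x)
            except Exception:
                f = f0
                res = None
            if f < best_f:
                best_f, best_u = f, (res.x if res is not None else u0)
        converged = np.isfinite(best_f) and best_f < 10.0 * obj.scale
    if converged:
        # tight refinement of the leading candidates plus the data-informed
        # center start (the capped first pass can leave the true basin's
        # start ranked behind a shallow decoy)
        for f0, u0 in candidates[:3] + center_candidates:
            if not np.isfinite(f0) or f0 >= 10.0 * obj.scale:
                continue
            try:
                res = least_squares(obj.residuals, u0, bounds=(0.0, 1.0),
                                    diff_step=1e-6, xtol=1e-13, ftol=1e-13,
                                    gtol=1e-14, max_nfev=300)
                f = obj.objective(res.x)
                if f <= best_f:
                    best_f, best_u = f, res.x
            except Exception:
                pass
            if best_f < floor:
                break
    if converged and polish:
        # derivative-free polish of the exact rmse_z + rmse_x objective
        try:
            res = minimize(obj.objective, best_u, method="Powell",
                           bounds=[(0.0, 1.0)] * d,
                           options={"xtol": 1e-9, "ftol": 1e-11,
                                    "maxfev": 30 * d})
            if res.fun <= best_f:
                best_f, best_u = float(res.fun), res.x
        except Exception:
            pass

    p = obj.unmap(best_u)
    if model == "ARSLIP":
        k_s, k_a, R, rd0, thd0 = p
    else:
        (k_s, R, rd0, thd0), k_a = p, None
    rmse_z, rmse_x = obj.rmse(best_u) if converged else (np.inf, np.inf)
    result = FitResult(model=model, k_s=float(k_s),
                       k_a=(float(k_a) if k_a is not None else None),
                       R=float(R), r_dot0=float(rd0), theta_dot0=float(thd0),
                       r0=r0, theta0=theta0, rmse_z=rmse_z, rmse_x=rmse_x,
                       n_starts=len(starts), converged=bool(converged),
                       seed=seed, mass=mass, g=g)
    return result


def fit_both_models(com: CoMTrajectory, window: tuple[float, float],
                    R_real: float, mass: float, foothold_x: float = 0.0,
                    g: float = 9.807, seed: int = 0, n_starts: int = 8
                    ) -> tuple[FitResult, FitResult]:
    """Fit SLIP, then ARSLIP seeded with the SLIP optimum (k_a = 0), so the
    nested-model inequality objective(ARSLIP) <= objective(SLIP) holds."""
    slip = fit_step(com, window, "SLIP", R_real, mass, foothold_x, g,
                    seed=seed, n_starts=n_starts)
    extra = [{"k_s": slip.k_s, "k_a": 0.0, "R": slip.R,
              "r_dot0": slip.r_dot0, "theta_dot0": slip.theta_dot0}]
    arslip = fit_step(com, window, "ARSLIP", R_real, mass, foothold_x, g,
                      seed=seed, n_starts=n_starts, extra_starts=extra)
    return slip, arslip


def compare_models(pairs: list[tuple[FitResult, FitResult]]):
    """Paired per-step RMSE table for (SLIP, ARSLIP) fits with medians and
    the fraction of steps on which ARSLIP wins (ties split 50/50)."""
    import pandas as pd

    rows = []
    wins = 0.0
    for i, (slip, arslip) in enumerate(pairs):
        rows.append({"step": i,
                     "rmse_slip": slip.objective,
                     "rmse_arslip": arslip.objective,
                     "rmse_z_slip": slip.rmse_z,
                     "rmse_z_arslip": arslip.rmse_z,
                     "rmse_x_slip": slip.rmse_x,
                     "rmse_x_arslip": arslip.rmse_x})
        if arslip.objective < slip.objective:
            wins += 1.0
        elif arslip.objective == slip.objective:
            wins += 0.5
    table = pd.DataFrame(rows)
    summary = {
        "median_slip": float(table["rmse_slip"].median()) if len(table)
        else np.nan,
        "median_arslip": float(table["rmse_arslip"].median()) if len(table)
        else np.nan,
        "fraction_arslip_wins": wins / len(pairs) if pairs else np.nan,
        "n_steps": len(pairs),
    }
    return table, summary


def fit_fly_tripod(steps: list[dict], R_real: float, mass: float,
                   g: float = 9.807, seed: int = 0, n_starts: int = 8,
                   k_max: float = KS_MAX) -> FlyTripodFit:
    """Single (k, R_tri) for one fly from its per-step ARSLIP fits.

    ``steps`` entries need k_s, k_a, R (fitted) and L, r_m (measured
    geometry).  Minimizes the summed squared *relative* errors of the
    tripod-mapped k_a and k_s against the fitted values (relative errors so
    that k_a ~ 1e-8 and k_s ~ 1e-2 contribute comparably); bounds
    k in (0, k_max], R_tri in [0.75, 1.5] R_real.  Steps with degenerate
    geometry or non-positive fitted constants are excluded and logged.
    Requires at least 6 usable steps.
    """
    usable, excluded = [], []
    for i, s in enumerate(steps):
        ok = all(np.isfinite(s[key]) for key in
                 ("k_s", "k_a", "R", "L", "r_m")) \
            and s["k_s"] > 0 and s["k_a"] > 0 and s["r_m"] > 0 \
            and s["L"] >= 0
        if ok:
            usable.append(s)
        else:
            excluded.append(i)
            warnings.warn(f"step {i}: degenerate geometry or fit, excluded",
                          stacklevel=2)
    if len(usable) < 6:
        raise ValueError(f"need >= 6 usable steps, got {len(usable)}")

    lo = np.array([1e-4 * k_max, 0.75 * R_real])
    hi = np.array([k_max, 1.50 * R_real])

    def mapped(params: np.ndarray, s: dict) -> ARSLIPParams:
        k, R_tri = params
        return tripod_to_arslip(TripodParams(k=k, R_tri=R_tri, L=s["L"],
                                             r_m=s["r_m"], m=mass, g=g))

    def residuals(params: np.ndarray) -> np.ndarray:
        out = np.empty(2 * len(usable))
        for j, s in enumerate(usable):
            try:
                eff = mapped(params, s)
                out[2 * j] = (eff.k_a - s["k_a"]) / s["k_a"]
                out[2 * j + 1] = (eff.k_s - s["k_s"]) / s["k_s"]
            except (GeometryError, ValueError):
                out[2 * j] = out[2 * j + 1] = 1e3
        return out

    starts = qmc.LatinHypercube(d=2, seed=seed).random(n_starts)
    best = None
    for u0 in starts:
        x0 = lo + u0 * (hi - lo)
        try:
            res = least_squares(residuals, x0, bounds=(lo, hi),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("per-fly tripod fit failed from every start")

    k, R_tri = best.x
    mg = mass * g
    ga_p, gs_p, ga_f, gs_f, R_p = [], [], [], [], []
    for s in usable:
        eff = mapped(best.x, s)
        q = nondimensionalize(eff)
        ga_p.append(q.gamma_a)
        gs_p.append(q.gamma_s)
        R_p.append(eff.R)
        ga_f.append(s["k_a"] / (mg * s["R"]))
        gs_f.append(s["k_s"] * s["R"] / mg)
    ga_p, gs_p = np.array(ga_p), np.array(gs_p)
    ga_f, gs_f = np.array(ga_f), np.array(gs_f)

    def _corr(a, b):
        if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
            return np.nan
        return float(np.corrcoef(a, b)[0, 1])

    return FlyTripodFit(k=float(k), R_tri=float(R_tri),
                        gamma_a_pred=ga_p, gamma_a_fit=ga_f,
                        gamma_s_pred=gs_p, gamma_s_fit=gs_f,
                        R_pred=np.array(R_p),
                        residual=float(2.0 * best.cost),
                        corr_gamma_a=_corr(ga_p, ga_f),
                        corr_gamma_s=_corr(gs_p, gs_f),
                        n_steps=len(usable), excluded=excluded)
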