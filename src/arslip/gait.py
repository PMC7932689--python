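"""Interleg-coordination (gait) analysis.

Walking insects are described by the six canonical legs R1, L1, R2, L2, R3,
L3 (front to back; R/L = right/left).  A tripod gait alternates support
between the leg triplets R1-L2-R3 and L1-R2-L3.  Flies walk with a modified
tripod ("M-tripod") in which the front leg of each tripod touches down
slightly before its middle leg, which leads the rear leg.

Two estimators of coordination are provided: normalized stance-start delays
(event-based) and instantaneous leg phases from the analytic signal of the
leg-tip position along the body axis (Hilbert transform), with the
convention that stance runs from phase 0 to pi and swing from -pi to 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "LEGS",
    "TRIPOD_1",
    "TRIPOD_2",
    "FootfallSequence",
    "LegTracks",
    "CoordinationResult",
    "stance_swing_durations",
    "normalized_stance_delays",
    "leg_phases",
    "phase_delays",
    "classify_step_gait",
    "make_m_tripod",
]

LEGS = ("R1", "L1", "R2", "L2", "R3", "L3")
TRIPOD_1 = ("R1", "L2", "R3")
TRIPOD_2 = ("L1", "R2", "L3")


@dataclass
class FootfallSequence:
    """Per-leg stance intervals with ground-plane foothold coordinates.

    intervals : {leg: array (n, 2) of (touch-down, lift-off) times, s}
    footholds : {leg: array (n, 2) of (x, y) foothold positions, m}
    span : recording span (s)
    """

    intervals: dict[str, np.ndarray]
    footholds: dict[str, np.ndarray]
    span: tuple[float, float]

    def __post_init__(self) -> None:
        for leg in self.intervals:
            if leg not in LEGS:
                raise ValueError(f"unknown leg label {leg!r}; expected one "
                                 f"of {LEGS}")
            iv = np.asarray(self.intervals[leg], dtype=float).reshape(-1, 2)
            self.intervals[leg] = iv
            if np.any(iv[:, 1] <= iv[:, 0]):
                raise ValueError(f"leg {leg}: lift-off must follow "
                                 "touch-down")
            if np.any(np.diff(iv[:, 0]) <= 0) or \
                    np.any(iv[1:, 0] < iv[:-1, 1]):
                raise ValueError(f"leg {leg}: intervals must be sorted and "
                                 "disjoint")
            fh = np.asarray(self.footholds.get(leg, np.zeros((len(iv), 2))),
                            dtype=float).reshape(-1, 2)
            if len(fh) != len(iv):
                raise ValueError(f"leg {leg}: one foothold per interval "
                                 "required")
            self.footholds[leg] = fh

    def touch_downs(self, leg: str) -> np.ndarray:
        return self.intervals[leg][:, 0]

    def lift_offs(self, leg: str) -> np.ndarray:
        return self.intervals[leg][:, 1]

    def in_stance(self, leg: str, t: np.ndarray) -> np.ndarray:
        """Boolean stance flag for leg at times t."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        iv = self.intervals[leg]
        out = np.zeros(len(t), dtype=bool)
        for td, lo in iv:
            out |= (t >= td) & (t < lo)
        return out

    def shifted(self, dt: float) -> "FootfallSequence":
        """Same sequence with all times translated by dt."""
        return FootfallSequence(
            intervals={leg: iv + dt for leg, iv in self.intervals.items()},
            footholds={leg: fh.copy() for leg, fh in self.footholds.items()},
            span=(self.span[0] + dt, self.span[1] + dt))


@dataclass
class LegTracks:
    """Per-leg leg-tip position along the body axis (anterior positive).

    t : shared time samples (s, strictly increasing)
    y : {leg: position samples (m)}
    stance : {leg: boolean stance flag per sample}
    """

    t: np.ndarray
    y: dict[str, np.ndarray]
    stance: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        for leg, yy in self.y.items():
            yy = np.asarray(yy, dtype=float)
            if len(yy) != len(self.t):
                raise ValueError(f"leg {leg}: y length mismatch")
            if not np.all(np.isfinite(yy)):
                raise ValueError(f"leg {leg}: y must be finite")
            self.y[leg] = yy


@dataclass
class CoordinationResult:
    """Per-cycle normalized delays (cycle fraction in [-0.5, 0.5]) of each
    leg relative to the reference leg, with cycle periods and duty factor."""

    reference: str
    cycle_starts: np.ndarray
    periods: np.ndarray
    delays: dict[str, np.ndarray]
    duty_factor: np.ndarray | None = None
    low_confidence: bool = False

    def median_delays(self) -> dict[str, float]:
        """Per-leg circular median: delays near the +-0.5 wrap boundary
        flip sign stochastically, so the median is taken on residuals
        about the circular mean and rotated back."""
        out: dict[str, float] = {}
        for leg, d in self.delays.items():
            d = np.asarray(d, dtype=float)
            d = d[np.isfinite(d)]
            if len(d) == 0:
                out[leg] = float("nan")
                continue
            mu = circular_mean_fraction(d)
            resid = wrap_cycle_fraction(d - mu)
            out[leg] = float(wrap_cycle_fraction(mu + np.median(resid)))
        return out


def wrap_cycle_fraction(d: np.ndarray | float) -> np.ndarray | float:
    """Map a cycle fraction into (-0.5, 0.5]."""
    return 0.5 - np.mod(0.5 - np.asarray(d, dtype=float), 1.0)


# ---------------------------------------------------------------------------
# stance/swing durations vs speed


def stance_swing_durations(f: FootfallSequence, com=None) -> "pd.DataFrame":
    """Per-interval stance and swing durations with concurrent body speed.

    Stance duration = lift-off - touch-down; swing duration = next
    touch-down - lift-off (same leg; NaN for the last interval).  If a CoM
    trajectory (with absolute time base and ``x`` in metres) is given, the
    mean horizontal speed over each stance is attached; intervals without
    CoM overlap get speed NaN and ``flagged=True`` rather than an error.
    """
    import pandas as pd

    rows = []
    for leg, iv in f.intervals.items():
        for i, (td, lo) in enumerate(iv):
            swing = iv[i + 1, 0] - lo if i + 1 < len(iv) else np.nan
            speed = np.nan
            flagged = False
            if com is not None:
                sel = (com.t >= td) & (com.t <= lo)
                if np.count_nonzero(sel) >= 2:
                    speed = float((com.x[sel][-1] - com.x[sel][0])
                                  / (com.t[sel][-1] - com.t[sel][0]))
                else:
                    flagged = True
            rows.append({"leg": leg, "t_down": td, "t_up": lo,
                         "stance_s": lo - td, "swing_s": swing,
                         "speed_m_s": speed, "flagged": flagged})
    return pd.DataFrame(rows).sort_values(["leg", "t_down"],
                                          ignore_index=True)


# ---------------------------------------------------------------------------
# event-based delays


def normalized_stance_delays(f: FootfallSequence,
                             reference: str = "R1") -> CoordinationResult:
    """Normalized stance-start delays of every leg relative to the
    reference leg, per reference cycle.

    The cycle period is the time between consecutive reference touch-downs;
    each other leg contributes its touch-down nearest to the cycle start
    (so legs that enter stance slightly *before* the reference produce
    negative delays), divided by the period and wrapped to (-0.5, 0.5].
    """
    ref_td = f.touch_downs(reference)
    if len(ref_td) < 2:
        return CoordinationResult(reference=reference,
                                  cycle_starts=np.empty(0),
                                  periods=np.empty(0), delays={})
    periods = np.diff(ref_td)
    starts = ref_td[:-1]
    delays: dict[str, np.ndarray] = {}
    for leg in f.intervals:
        if leg == reference:
            continue
        td = f.touch_downs(leg)
        vals = np.full(len(starts), np.nan)
        if len(td):
            for i, (t0, T) in enumerate(zip(starts, periods)):
                j = np.argmin(np.abs(td - t0))
                vals[i] = wrap_cycle_fraction((td[j] - t0) / T)
        delays[leg] = vals
    ref_lo = f.lift_offs(reference)
    duty = np.array([
        (ref_lo[np.searchsorted(ref_lo, t0)] - t0) / T
        if np.searchsorted(ref_lo, t0) < len(ref_lo) else np.nan
        for t0, T in zip(starts, periods)])
    return CoordinationResult(reference=reference, cycle_starts=starts,
                              periods=periods, delays=delays,
                              duty_factor=duty)


# ---------------------------------------------------------------------------
# phase-based delays


def _swing_interpolated(t: np.ndarray, y: np.ndarray,
                        stance: np.ndarray) -> np.ndarray:
    """Replace swing samples by linear interpolation between the flanking
    stance samples (leg position is only physically meaningful in stance)."""
    if stance.all() or not stance.any():
        return y.copy()
    out = y.copy()
    idx = np.flatnonzero(stance)
    out[~stance] = np.interp(t[~stance], t[idx], y[idx])
    return out


def _median_cycle_period(t: np.ndarray, stance: np.ndarray,
                         y: np.ndarray | None = None) -> float:
    td = t[1:][stance[1:] & ~stance[:-1]]  # touch-down sample times
    if len(td) >= 2:
        return float(np.median(np.diff(td)))
    if y is not None:
        # no stance transitions (e.g. a continuous oscillation): two
        # mean-crossings per cycle
        yc = y - np.mean(y)
        n_cross = int(np.count_nonzero(np.sign(yc[1:]) * np.sign(yc[:-1])
                                       < 0))
        if n_cross >= 4:
            return float(2.0 * (t[-1] - t[0]) / n_cross)
    return float(t[-1] - t[0])


def leg_phases(tracks: LegTracks, edge_fraction: float = 0.1
               ) -> dict[str, np.ndarray]:
    """Instantaneous phase per leg per sample, in [-pi, pi].

    The phase is the argument of the analytic signal (Hilbert transform) of
    the swing-interpolated leg position, detrended by a sliding mean over
    two median cycle periods.  Sign convention: stance runs 0 -> pi, swing
    -pi -> 0 (anterior-positive tracks satisfy this naturally since the leg
    tip moves backward in the body frame during stance).

    Tracks covering fewer than two full cycles are processed but a warning
    is emitted (analytic-signal edge effects make them low-confidence).
    """
    phases: dict[str, np.ndarray] = {}
    for leg, y in tracks.y.items():
        stance = np.asarray(tracks.stance.get(leg,
                                              np.ones(len(y), bool)), bool)
        yi = _swing_interpolated(tracks.t, y, stance)
        period = _median_cycle_period(tracks.t, stance, yi)
        span = tracks.t[-1] - tracks.t[0]
        if span < 2 * period or (stance[1:] & ~stance[:-1]).sum() < 2:
            warnings.warn(f"leg {leg}: track shorter than two cycles; "
                          "phases are low-confidence", stacklevel=2)
        dt = float(np.median(np.diff(tracks.t)))
        win = max(3, int(round(2 * period / dt)) | 1)  # odd window
        kernel = np.ones(win) / win
        pad = win // 2
        ypad = np.pad(yi, pad, mode="reflect")
        trend = np.convolve(ypad, kernel, mode="valid")
        analytic = hilbert(yi - trend)
        ph = np.angle(analytic)
        # enforce forward-advancing phase regardless of track sign convention
        dph = np.diff(np.unwrap(ph))
        if np.median(dph) < 0:
            ph = np.angle(np.conj(analytic))
        phases[leg] = ph
    return phases


def circular_mean_fraction(frac: np.ndarray) -> float:
    """Vector mean of cycle fractions, wrapped to (-0.5, 0.5]."""
    ang = 2.0 * math.pi * np.asarray(frac, dtype=float)
    mean = math.atan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
    return float(wrap_cycle_fraction(mean / (2.0 * math.pi)))


def phase_delays(phases: dict[str, np.ndarray], tracks: LegTracks,
                 f: FootfallSequence,
                 reference: str = "R1") -> CoordinationResult:
    """Normalized phase delays relative to the reference leg, one value per
    reference stance: the circular mean of (phi_leg - phi_ref)/2pi over the
    reference stance samples (touch-down to lift-off), in (-0.5, 0.5]."""
    ref_iv = f.intervals[reference]
    starts, periods, rows = [], [], []
    ref_td = ref_iv[:, 0]
    for i, (td, lo) in enumerate(ref_iv):
        sel = (tracks.t >= td) & (tracks.t <= lo)
        if not sel.any():
            continue  # no overlap: skip this stance
        period = (ref_td[i + 1] - td if i + 1 < len(ref_td)
                  else (td - ref_td[i - 1] if i > 0 else np.nan))
        starts.append(td)
        periods.append(period)
        row = {}
        for leg in phases:
            if leg == reference:
                continue
            # positive = leg lags the reference, matching the sign of
            # stance-start delays (a leg whose events come later has a
            # smaller instantaneous phase)
            dphi = (phases[reference][sel] - phases[leg][sel]) / (2 * math.pi)
            row[leg] = circular_mean_fraction(dphi)
        rows.append(row)
    delays = {leg: np.array([r.get(leg, np.nan) for r in rows])
              for leg in phases if leg != reference}
    return CoordinationResult(reference=reference,
                              cycle_starts=np.asarray(starts),
                              periods=np.asarray(periods), delays=delays)


# ---------------------------------------------------------------------------
# gait classification


def _wrapped_dist(a: float, b: float) -> float:
    return abs(float(wrap_cycle_fraction(a - b)))


def classify_step_gait(delays: dict[str, float],
                       tol: float = 0.125) -> str:
    """Classify one cycle's delays (relative to R1) as ``tripod``,
    ``tetrapod`` or ``noncanonical``.

    Tripod template: the delays along each tripod's front-middle-rear chain
    (R1-L2, L2-R3 and, half a cycle later, L1-R2, R2-L3, with L1 itself at
    0.5) are each within ``tol``.  Chain (consecutive-leg) delays are used
    because in an M-tripod the rear leg's delay relative to the front leg
    is the *sum* of two small within-tripod delays.  Tetrapod: the six legs
    pair into three contralateral pairs whose delays sit at 0, 1/3 and 2/3
    of a cycle (either chirality), each leg within ``tol`` of its group.
    The tolerance is a package choice, configurable.
    """
    needed = [leg for leg in LEGS if leg != "R1"]
    if any(leg not in delays or not np.isfinite(delays[leg])
           for leg in needed):
        return "noncanonical"
    d = {leg: float(delays[leg]) for leg in needed}
    d["R1"] = 0.0

    chain = (_wrapped_dist(d["L2"], 0.0) <= tol
             and _wrapped_dist(d["R3"], d["L2"]) <= tol
             and _wrapped_dist(d["L1"], 0.5) <= tol
             and _wrapped_dist(d["R2"], d["L1"]) <= tol
             and _wrapped_dist(d["L3"], d["R2"]) <= tol)
    if chain:
        return "tripod"

    # tetrapod: three contralateral pairs at mutual offsets {0, 1/3, 2/3},
    # anchored at R1's group
    import itertools
    rights = ["R1", "R2", "R3"]
    lefts = ["L1", "L2", "L3"]
    groups = (0.0, 1.0 / 3.0, 2.0 / 3.0)
    for perm in itertools.permutations(lefts):
        pairs = list(zip(rights, perm))
        for offsets in itertools.permutations(groups):
            if offsets[0] != 0.0:  # R1's pair anchors the pattern at 0
                continue
            ok = all(_wrapped_dist(d[r], off) <= tol
                     and _wrapped_dist(d[l], off) <= tol
                     for (r, l), off in zip(pairs, offsets))
            if ok:
                return "tetrapod"
    return "noncanonical"


# ---------------------------------------------------------------------------
# M-tripod synthesis


def make_m_tripod(delta_meso_pro: float, delta_meta_meso: float,
                  period: float, duty: float, n_cycles: int,
                  t0: float = 0.0, step_length: float | None = None,
                  spread: float = 2.0e-3, half_width: float = 1.0e-3
                  ) -> FootfallSequence:
    """Synthesize an M-tripod footfall schedule.

    The front leg of each tripod touches down ``delta_meso_pro * period``
    before its middle leg, which leads the rear leg by
    ``delta_meta_meso * period``; the opposing tripod is shifted by half a
    period.  Stance lasts ``duty * period``.  Footholds advance by
    ``step_length`` (default: half the spread) per cycle at the canonical
    body stations (front/middle/hind at +-spread/2, y = +-half_width).
    """
    if not 0.0 < duty < 1.0:
        raise ValueError("duty must be in (0, 1)")
    if period <= 0 or n_cycles < 1:
        raise ValueError("period must be > 0 and n_cycles >= 1")
    for name, val in (("delta_meso_pro", delta_meso_pro),
                      ("delta_meta_meso", delta_meta_meso)):
        if abs(val) >= 0.5:
            raise ValueError(f"{name} must have |delta| < 0.5 cycles")

    if step_length is None:
        step_length = spread / 2.0
    # per-leg touch-down offset within the cycle (front leads)
    offsets = {
        "R1": 0.0, "L2": delta_meso_pro,
        "R3": delta_meso_pro + delta_meta_meso,
        "L1": 0.5, "R2": 0.5 + delta_meso_pro,
        "L3": 0.5 + delta_meso_pro + delta_meta_meso,
    }
    station_x = {"R1": spread / 2, "L1": spread / 2, "R2": 0.0, "L2": 0.0,
                 "R3": -spread / 2, "L3": -spread / 2}
    station_y = {leg: (half_width if leg.startswith("R") else -half_width)
                 for leg in LEGS}
    intervals: dict[str, np.ndarray] = {}
    footholds: dict[str, np.ndarray] = {}
    stance = duty * period
    for leg in LEGS:
        tds = t0 + (np.arange(n_cycles) + offsets[leg]) * period
        intervals[leg] = np.column_stack([tds, tds + stance])
        xs = station_x[leg] + np.arange(n_cycles) * step_length
        footholds[leg] = np.column_stack(
            [xs, np.full(n_cycles, station_y[leg])])
    t_end = t0 + (n_cycles - 1 + max(offsets.values())) * period + stance
    return FootfallSequence(intervals=intervals, footholds=footholds,
                            span=(t0, t_end))
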