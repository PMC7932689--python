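"""Tripod-stance segmentation and per-step CoM descriptors.

A "step" is one tripod stance: because the three legs of a tripod do not
land in perfect synchrony, the stance start is the halfway time point
between the first touch-down of the current tripod and the last lift-off of
the preceding tripod, and the end is the corresponding midpoint with the
following tripod.  Consecutive step windows therefore tile the walking bout.

Each step carries the tripod geometry that sets the effective stiffness:
half spread L (half the anterior-posterior foothold distance of the tripod,
measured along the walking direction) and mid-stance height r_m (CoM height
when it crosses vertically above the effective foothold, the midpoint of the
front and hind footholds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dynamics import CoMTrajectory
from .gait import TRIPOD_1, TRIPOD_2, FootfallSequence

__all__ = [
    "StepRecord",
    "tripod_step_windows",
    "step_geometry",
    "detrended_change",
    "step_summary",
    "filter_steps",
]


@dataclass
class StepRecord:
    """One tripod stance and its kinematic descriptors (SI units)."""

    window: tuple[float, float]
    tripod: tuple[str, str, str]
    single_support_fraction: float = np.nan
    L: float = np.nan
    r_m: float = np.nan
    foothold_x: float = np.nan
    mid_stance_time: float = np.nan
    v_mean: float = np.nan
    v_initial: float = np.nan
    distance: float = np.nan
    duration: float = np.nan
    delta_v: float = np.nan
    delta_z: float = np.nan
    Fr: float = np.nan
    flags: list[str] = field(default_factory=list)
    fly_id: str | None = None
    step_id: int | None = None
    footholds: dict | None = field(default=None, repr=False)

    @property
    def L_over_rm(self) -> float:
        return self.L / self.r_m

    def __post_init__(self) -> None:
        if self.window[1] <= self.window[0]:
            raise ValueError("window end must exceed start")


def _tripod_events(f: FootfallSequence) -> list[dict]:
    """Group each tripod's stance intervals into cycles, ordered by first
    touch-down.  Cycles are indexed by the tripod's front leg; the other
    two legs contribute their touch-down nearest to the front leg's."""
    events = []
    for tripod in (TRIPOD_1, TRIPOD_2):
        front = tripod[0]
        if any(leg not in f.intervals or len(f.intervals[leg]) == 0
               for leg in tripod):
            continue
        for td_front in f.touch_downs(front):
            tds, los, fhs = [], [], {}
            ok = True
            for leg in tripod:
                iv = f.intervals[leg]
                j = int(np.argmin(np.abs(iv[:, 0] - td_front)))
                period_guess = np.median(np.diff(f.touch_downs(front))) \
                    if len(f.touch_downs(front)) > 1 else np.inf
                if abs(iv[j, 0] - td_front) > 0.5 * period_guess:
                    ok = False
                    break
                tds.append(iv[j, 0])
                los.append(iv[j, 1])
                fhs[leg] = f.footholds[leg][j]
            if ok:
                events.append({"tripod": tripod, "first_td": min(tds),
                               "last_lo": max(los), "footholds": fhs})
    events.sort(key=lambda e: e["first_td"])
    return events


def _occupancy_fraction(f: FootfallSequence, tripod: tuple[str, ...],
                        start: float, end: float) -> float:
    """Fraction of [start, end] during which only the given tripod's legs
    are in stance (single support), by interval arithmetic on the other
    legs' stance intervals."""
    others = [leg for leg in f.intervals if leg not in tripod]
    busy: list[tuple[float, float]] = []
    for leg in others:
        for td, lo in f.intervals[leg]:
            a, b = max(td, start), min(lo, end)
            if b > a:
                busy.append((a, b))
    if not busy:
        return 1.0
    busy.sort()
    merged = [list(busy[0])]
    for a, b in busy[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    occupied = sum(b - a for a, b in merged)
    return 1.0 - occupied / (end - start)


def tripod_step_windows(f: FootfallSequence) -> list[StepRecord]:
    """Segment the bout into tripod stances (windows tile the bout).

    Each window requires a complete preceding and following opposing-tripod
    event; boundary tripods are dropped.  The single-support fraction (share
    of the window with only the current tripod's legs grounded) is attached.
    """
    events = _tripod_events(f)
    records = []
    for i in range(1, len(events) - 1):
        prev, cur, nxt = events[i - 1], events[i], events[i + 1]
        if prev["tripod"] == cur["tripod"] or nxt["tripod"] == cur["tripod"]:
            continue  # incomplete alternation
        start = 0.5 * (cur["first_td"] + prev["last_lo"])
        end = 0.5 * (nxt["first_td"] + cur["last_lo"])
        if end <= start:
            continue
        ssf = _occupancy_fraction(f, cur["tripod"], start, end)
        records.append(StepRecord(window=(start, end), tripod=cur["tripod"],
                                  single_support_fraction=ssf, step_id=i,
                                  footholds=cur["footholds"]))
    return records


def _walking_direction(x: np.ndarray, y: np.ndarray | None) -> np.ndarray:
    """Unit vector of the principal axis of horizontal CoM displacement,
    oriented along the net displacement."""
    if y is None:
        return np.array([1.0, 0.0]) if x[-1] >= x[0] else np.array([-1.0, 0.0])
    pts = np.column_stack([x, y])
    pts = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    u = vt[0]
    net = np.array([x[-1] - x[0], (y[-1] - y[0])])
    if np.dot(u, net) < 0:
        u = -u
    return u


def step_geometry(step: StepRecord, f: FootfallSequence, com: CoMTrajectory,
                  com_y: np.ndarray | None = None) -> StepRecord:
    """Fill in (L, r_m, effective foothold, mid-stance time) for one step.

    2L is the front-hind foothold distance projected on the walking
    direction (the principal axis of horizontal CoM displacement); the
    effective foothold is the midpoint of the front and hind footholds; the
    mid-stance time is when the projected CoM crosses the projected
    foothold, and r_m the interpolated CoM height there.  If the CoM never
    crosses the foothold within the window, the time of maximum height is
    used and the record flagged.
    """
    footholds = getattr(step, "footholds", None)
    if footholds is None:
        raise ValueError("step has no footholds; produce it with "
                         "tripod_step_windows")
    front, _, hind = step.tripod
    u = _walking_direction(com.x, com_y)
    p_front = np.dot(footholds[front], u)
    p_hind = np.dot(footholds[hind], u)
    step.L = 0.5 * abs(p_front - p_hind)
    p_foot = 0.5 * (p_front + p_hind)
    step.foothold_x = p_foot

    sel = (com.t >= step.window[0]) & (com.t <= step.window[1])
    t = com.t[sel]
    z = com.z[sel]
    if com_y is None:
        p = com.x[sel] * u[0]
    else:
        p = com.x[sel] * u[0] + com_y[sel] * u[1]
    if len(t) < 2:
        step.flags.append("no_com_overlap")
        return step
    rel = p - p_foot
    crossings = np.flatnonzero(np.sign(rel[:-1]) * np.sign(rel[1:]) <= 0)
    crossings = crossings[(rel[crossings] != 0) | (rel[crossings + 1] != 0)]
    if len(crossings):
        j = crossings[0]
        frac = -rel[j] / (rel[j + 1] - rel[j]) if rel[j + 1] != rel[j] else 0.0
        step.mid_stance_time = float(t[j] + frac * (t[j + 1] - t[j]))
        step.r_m = float(z[j] + frac * (z[j + 1] - z[j]))
    else:
        j = int(np.argmax(z))
        step.mid_stance_time = float(t[j])
        step.r_m = float(z[j])
        step.flags.append("no_midstance_crossing")
    return step


def detrended_change(series: np.ndarray) -> float:
    """Total excursion of a series about the line through its endpoints.

    The series is detrended by the straight line connecting its first and
    last samples; the change is max - min of the residual.  (For a residual
    that stays one-signed this equals its peak; for one that straddles zero
    it is peak + |trough|, so a pure oscillation reports its full
    peak-to-peak amplitude rather than cancelling to zero.)
    """
    y = np.asarray(series, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 samples")
    line = y[0] + (y[-1] - y[0]) * np.linspace(0.0, 1.0, len(y))
    resid = y - line
    return float(resid.max() - resid.min())


def step_summary(step: StepRecord, com: CoMTrajectory,
                 leg_length: float | None = None,
                 g: float = 9.807) -> StepRecord:
    """Fill speed/distance/height descriptors of one step from the CoM.

    v_mean = distance/duration; v_initial from the first 5 frames; delta_v
    and delta_z are detrended total excursions of speed and height over the
    window; Fr = v_mean^2 / (g * leg_length) (leg_length defaults to the
    step's r_m when no measured natural leg length is supplied).
    """
    sel = (com.t >= step.window[0]) & (com.t <= step.window[1])
    t, x, z = com.t[sel], com.x[sel], com.z[sel]
    if len(t) < 3:
        step.flags.append("too_few_samples")
        return step
    step.duration = float(t[-1] - t[0])
    step.distance = float(x[-1] - x[0])
    step.v_mean = step.distance / step.duration
    v = com.speed[sel]
    n0 = min(5, len(t))
    step.v_initial = float(np.polyfit(t[:n0], x[:n0], 1)[0])
    step.delta_v = detrended_change(v)
    step.delta_z = detrended_change(z)
    ell = leg_length if leg_length is not None else step.r_m
    if ell and np.isfinite(ell) and ell > 0:
        step.Fr = step.v_mean ** 2 / (g * ell)
    return step


def filter_steps(records: list[StepRecord],
                 min_single_support: float = 0.25,
                 min_steps_per_fly: int = 6) -> list[StepRecord]:
    """Apply the step-eligibility filters used for model fitting.

    Keeps steps whose single-support fraction is at least
    ``min_single_support`` (a single effective leg is only a fair model when
    one tripod carries the body for a substantial share of the stance), then
    drops all steps of any fly contributing fewer than ``min_steps_per_fly``
    eligible steps (per-fly spring-constant fits need a minimum sample).
    """
    eligible = [r for r in records
                if r.single_support_fraction >= min_single_support]
    counts: dict[str | None, int] = {}
    for r in eligible:
        counts[r.fly_id] = counts.get(r.fly_id, 0) + 1
    return [r for r in eligible if counts[r.fly_id] >= min_steps_per_fly]
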