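"""Interleg coordination: delays, phases, classification, M-tripod."""

import collections

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from arslip.dynamics import CoMTrajectory
from arslip.gait import (LegTracks, classify_step_gait, leg_phases,
                         make_m_tripod, normalized_stance_delays,
                         phase_delays, stance_swing_durations,
                         wrap_cycle_fraction, FootfallSequence)


def ideal_tripod(n_cycles=10, period=0.1, duty=0.5):
    return make_m_tripod(0.0, 0.0, period=period, duty=duty,
                         n_cycles=n_cycles)


class TestStanceSwingDurations:
    def test_single_interval(self):
        f = FootfallSequence(
            intervals={"R1": np.array([[0.10, 0.18], [0.21, 0.30]])},
            footholds={"R1": np.zeros((2, 2))}, span=(0.0, 0.3))
        table = stance_swing_durations(f)
        assert table.loc[0, "stance_s"] == pytest.approx(0.08)
        assert table.loc[0, "swing_s"] == pytest.approx(0.03)
        assert np.isnan(table.loc[1, "swing_s"])

    def test_speed_law_recovery(self):
        """Swing durations generated as 0.03 - 0.00018 v (v in mm/s) with
        2 ms jitter regress back to the configured slope within 30%, and a
        reciprocal fit to the stance durations explains >95% of variance."""
        rng = np.random.default_rng(0)
        n = 200
        speeds = rng.uniform(8.0, 30.0, n)          # mm/s
        swing = 0.03 - 0.00018 * speeds + rng.normal(0.0, 2e-3, n)
        stance = 1.2 / speeds + rng.normal(0.0, 1e-3, n)
        slope = np.polyfit(speeds, swing, 1)[0]
        assert slope == pytest.approx(-0.00018, rel=0.30)
        recip = np.polyfit(1.0 / speeds, stance, 1)
        pred = np.polyval(recip, 1.0 / speeds)
        ss_res = np.sum((stance - pred) ** 2)
        ss_tot = np.sum((stance - stance.mean()) ** 2)
        assert 1.0 - ss_res / ss_tot > 0.95

    def test_speed_attached_from_com(self):
        f = ideal_tripod(4)
        t = np.arange(0.0, 1.0, 1e-3)
        com = CoMTrajectory(t=t, x=0.02 * t, z=np.full(len(t), 1e-3))
        table = stance_swing_durations(f, com)
        good = table.dropna(subset=["speed_m_s"])
        assert np.allclose(good["speed_m_s"], 0.02, rtol=1e-6)


class TestStanceDelays:
    def test_ideal_tripod_delays(self):
        med = normalized_stance_delays(ideal_tripod()).median_delays()
        assert med["L2"] == pytest.approx(0.0, abs=1e-12)
        assert med["R3"] == pytest.approx(0.0, abs=1e-12)
        for leg in ("L1", "R2", "L3"):
            assert abs(med[leg]) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("offset, expected", [(0.010, 0.10),
                                                  (-0.010, -0.10)])
    def test_small_offsets_signed(self, offset, expected):
        f = ideal_tripod()
        f.intervals["L2"] = f.intervals["L2"] + offset
        med = normalized_stance_delays(f).median_delays()
        assert med["L2"] == pytest.approx(expected, abs=1e-9)

    def test_no_complete_cycle_gives_empty(self):
        f = FootfallSequence(intervals={"R1": np.array([[0.0, 0.06]])},
                             footholds={"R1": np.zeros((1, 2))},
                             span=(0.0, 0.1))
        assert len(normalized_stance_delays(f).cycle_starts) == 0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(-5.0, 5.0), st.floats(0.2, 5.0))
    def test_translation_and_rescale_invariance(self, dt, scale):
        f = make_m_tripod(0.04, 0.06, period=0.1, duty=0.6, n_cycles=6)
        base = normalized_stance_delays(f).median_delays()
        shifted = normalized_stance_delays(f.shifted(dt)).median_delays()
        rescaled = FootfallSequence(
            intervals={leg: iv * scale for leg, iv in f.intervals.items()},
            footholds=f.footholds, span=(f.span[0] * scale,
                                         f.span[1] * scale))
        res = normalized_stance_delays(rescaled).median_delays()
        for leg in base:
            # circular comparison: +0.5 and -0.5 are the same delay
            assert abs(float(wrap_cycle_fraction(
                shifted[leg] - base[leg]))) <= 1e-9
            assert abs(float(wrap_cycle_fraction(
                res[leg] - base[leg]))) <= 1e-9


class TestLegPhases:
    def test_cosine_phase_advances_linearly(self):
        freq = 10.0
        t = np.arange(0.0, 2.0, 1 / 380.0)
        y = np.cos(2 * np.pi * freq * t)
        tracks = LegTracks(t=t, y={"R1": y},
                           stance={"R1": np.ones(len(t), bool)})
        ph = np.unwrap(leg_phases(tracks)["R1"])
        n_edge = int(0.1 * len(t))
        core = slice(n_edge, len(t) - n_edge)
        fit = np.polyfit(t[core], ph[core], 1)
        assert fit[0] == pytest.approx(2 * np.pi * freq, rel=0.01)
        resid = ph[core] - np.polyval(fit, t[core])
        assert np.max(np.abs(resid)) <= 0.05

    def test_quarter_period_offset(self):
        t = np.arange(0.0, 2.0, 1 / 380.0)
        y1 = np.cos(2 * np.pi * 10 * t)
        y2 = np.cos(2 * np.pi * 10 * (t - 0.025))
        tracks = LegTracks(t=t, y={"R1": y1, "L2": y2},
                           stance={"R1": np.ones(len(t), bool),
                                   "L2": np.ones(len(t), bool)})
        ph = leg_phases(tracks)
        n_edge = int(0.1 * len(t))
        dphi = (ph["R1"] - ph["L2"])[n_edge:-n_edge] / (2 * np.pi)
        dphi = wrap_cycle_fraction(dphi)
        assert np.median(dphi) == pytest.approx(0.25, abs=0.01)

    def test_touchdown_phase_convention(self):
        """Triangle-wave leg track (linear AEP->PEP in stance, return in
        swing): the analytic-signal phase at touch-down samples is ~0."""
        period, duty = 0.1, 0.6
        t = np.arange(0.0, 1.0, 1 / 380.0)
        tau = (t / period) % 1.0
        y = np.where(tau < duty, 1.0 - 2.0 * tau / duty,
                     -1.0 + 2.0 * (tau - duty) / (1 - duty)) * 1e-3
        stance = tau < duty
        tracks = LegTracks(t=t, y={"R1": y}, stance={"R1": stance})
        ph = leg_phases(tracks)["R1"]
        tds = np.flatnonzero(stance[1:] & ~stance[:-1]) + 1
        tds = tds[(tds > 0.1 * len(t)) & (tds < 0.9 * len(t))]
        assert np.all(np.abs(ph[tds]) <= 0.3)


class TestPhaseDelays:
    def _tracks_and_footfalls(self, offset_cycles=0.0):
        f = make_m_tripod(0.0, 0.0, period=0.1, duty=0.5, n_cycles=10)
        t = np.arange(0.0, 1.0, 1 / 380.0)
        y = {}
        stance = {}
        base = np.cos(2 * np.pi * 10 * t)
        for leg in ("R1", "L2"):
            shift = offset_cycles if leg == "L2" else 0.0
            y[leg] = np.cos(2 * np.pi * 10 * t - 2 * np.pi * shift)
            stance[leg] = np.ones(len(t), bool)
        return LegTracks(t=t, y=y, stance=stance), f

    def test_identical_traces_zero_delay(self):
        tracks, f = self._tracks_and_footfalls(0.0)
        res = phase_delays(leg_phases(tracks), tracks, f)
        assert np.nanmedian(res.delays["L2"]) == pytest.approx(0.0,
                                                               abs=0.01)

    def test_antiphase_half_cycle(self):
        tracks, f = self._tracks_and_footfalls(0.5)
        res = phase_delays(leg_phases(tracks), tracks, f)
        assert abs(np.nanmedian(res.delays["L2"])) == pytest.approx(0.5,
                                                                    abs=0.01)

    def test_m_tripod_round_trip(self, clean_dataset):
        """Configured within-tripod deltas are recovered by the phase
        estimator on generator leg tracks, and agree with the stance-start
        estimator within 0.05 cycles."""
        ds = clean_dataset
        ph = leg_phases(ds.leg_tracks)
        p_med = phase_delays(ph, ds.leg_tracks, ds.footfalls).median_delays()
        s_med = normalized_stance_delays(ds.footfalls).median_delays()
        for leg in p_med:
            diff = abs(float(wrap_cycle_fraction(p_med[leg] - s_med[leg])))
            assert diff <= 0.05


class TestClassification:
    def test_ideal_tripod(self):
        med = normalized_stance_delays(ideal_tripod()).median_delays()
        assert classify_step_gait(med) == "tripod"

    def test_m_tripod_up_to_delta_01(self):
        for d1, d2 in [(0.05, 0.08), (0.1, 0.1), (0.02, 0.0)]:
            f = make_m_tripod(d1, d2, period=0.1, duty=0.6, n_cycles=10)
            med = normalized_stance_delays(f).median_delays()
            assert classify_step_gait(med) == "tripod", (d1, d2)

    def test_canonical_tetrapod(self):
        delays = {"L2": 0.0, "R2": 1 / 3, "L3": 1 / 3, "R3": 2 / 3,
                  "L1": 2 / 3}
        assert classify_step_gait(delays) == "tetrapod"

    def test_missing_leg_noncanonical(self):
        assert classify_step_gait({"L2": 0.0}) == "noncanonical"

    def test_random_delays_mostly_noncanonical(self):
        rng = np.random.default_rng(0)
        legs = ("L1", "L2", "L3", "R2", "R3")
        labels = collections.Counter(
            classify_step_gait({leg: rng.uniform(-0.5, 0.5)
                                for leg in legs})
            for _ in range(1000))
        assert labels["noncanonical"] >= 900


class TestMakeMTripod:
    def test_duty_sets_stance_length(self):
        f = make_m_tripod(0.0, 0.0, period=0.1, duty=0.6, n_cycles=5)
        for leg, iv in f.intervals.items():
            assert np.allclose(iv[:, 1] - iv[:, 0], 0.06)

    def test_delta_round_trip(self):
        f = make_m_tripod(0.05, 0.08, period=0.1, duty=0.6, n_cycles=10)
        med = normalized_stance_delays(f).median_delays()
        assert med["L2"] == pytest.approx(0.05, abs=1e-9)
        assert med["R3"] == pytest.approx(0.13, abs=1e-9)

    def test_invalid_deltas_rejected(self):
        with pytest.raises(ValueError):
            make_m_tripod(0.5, 0.0, period=0.1, duty=0.6, n_cycles=5)
        with pytest.raises(ValueError):
            make_m_tripod(0.0, 0.0, period=0.1, duty=1.2, n_cycles=5)
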