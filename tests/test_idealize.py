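"""Single-channel idealization: 50% rule, dead time, P_o, i-V slopes."""

import numpy as np
import pytest

from trpckit import idealize as chid
from trpckit import synthetic as syn


FS = 10_000.0


def make_trace(samples, fc=1000.0):
    return chid.RawTrace(np.asarray(samples, float), sampling_rate=FS,
                         filter_cutoff=fc)


class TestDeadTime:
    @pytest.mark.parametrize("fc, expected_ms", [
        (1000.0, 0.15915),   # the recording cutoff: ~0.16 ms
        (500.0, 0.31831),
        (1e9, 1.59e-7),
    ])
    def test_closed_form(self, fc, expected_ms):
        assert chid.dead_time(fc) * 1e3 == pytest.approx(expected_ms, rel=1e-3)

    def test_rounds_to_printed_value(self):
        assert round(chid.dead_time(1000.0) * 1e3, 2) == 0.16

    @pytest.mark.parametrize("fc", [0.0, -100.0])
    def test_invalid_cutoff(self, fc):
        with pytest.raises(ValueError):
            chid.dead_time(fc)


class TestAssignLevels:
    def test_square_wave(self):
        # closed (baseline) occupies most of the record, as in a
        # low-Po patch, so the taller histogram mode is the closed level
        x = np.tile([0.0] * 70 + [-2.0] * 30, 20)
        lv = chid.assign_levels(make_trace(x))
        assert lv.closed_level == pytest.approx(0.0, abs=0.05)
        assert lv.open_level == pytest.approx(-2.0, abs=0.05)

    def test_flat_trace_has_no_open_level(self):
        lv = chid.assign_levels(make_trace(np.zeros(1000)))
        assert lv.open_level is None

    def test_levels_match_generator_truth(self, gating_model):
        trace, _ = syn.gen_gating_trace(gating_model)
        lv = chid.assign_levels(trace)
        assert lv.closed_level == pytest.approx(0.0, abs=gating_model.noise_sd)
        assert lv.open_level == pytest.approx(
            gating_model.unitary_current, abs=gating_model.noise_sd)


class TestIdealize50pct:
    LEVELS = chid.Levels(0.0, -2.0)

    def test_square_pulse(self):
        n_open = int(0.005 * FS)  # 5 ms
        x = np.concatenate([np.zeros(100), -2.0 * np.ones(n_open), np.zeros(100)])
        dw = chid.idealize_50pct(make_trace(x), self.LEVELS)
        opens = [(s, d) for s, d in dw.events if s == "open"]
        assert len(opens) == 1
        assert opens[0][1] == pytest.approx(0.005, abs=1.5 / FS)

    def test_sub_dead_time_blip_ignored(self):
        n_open = int(0.005 * FS)
        base = np.concatenate([np.zeros(100), -2.0 * np.ones(n_open), np.zeros(100)])
        blipped = base.copy()
        blipped[50] = -2.0  # 0.1 ms closed-side blip, below the 0.16 ms dead time
        ref = chid.idealize_50pct(make_trace(base), self.LEVELS)
        got = chid.idealize_50pct(make_trace(blipped), self.LEVELS)
        assert [s for s, _ in got.events] == [s for s, _ in ref.events]
        assert got.T_m == ref.T_m

    def test_flat_trace_single_closed_event(self):
        dw = chid.idealize_50pct(make_trace(np.zeros(500)),
                                 chid.Levels(0.0, None))
        assert dw.events == [("closed", 500 / FS)]

    def test_noiseless_markov_dwells_recovered(self):
        model = syn.GatingModel(opening_rate=5.0, closing_rate=5.0,
                                noise_sd=0.0, duration=20.0, seed=7)
        trace, truth = syn.gen_gating_trace(model)
        dw = chid.idealize_50pct(trace, self.LEVELS)
        td = chid.dead_time(trace.filter_cutoff)
        truth_events = [(s, d) for s, d in truth.events if d >= td]
        assert len(dw.events) == len(truth_events)
        for (s1, d1), (s2, d2) in zip(dw.events, truth_events):
            assert s1 == s2
            assert d1 == pytest.approx(d2, abs=2.0 / FS)

    def test_sign_flip_invariance(self, gating_model):
        trace, _ = syn.gen_gating_trace(gating_model)
        flipped = chid.RawTrace(-trace.samples, trace.sampling_rate,
                                trace.filter_cutoff)
        dw = chid.idealize_50pct(trace, chid.Levels(0.0, -2.0))
        dw_f = chid.idealize_50pct(flipped, chid.Levels(0.0, 2.0))
        assert dw.events == dw_f.events

    def test_dwell_times_partition_the_record(self, gating_model):
        trace, _ = syn.gen_gating_trace(gating_model)
        dw = chid.idealize_50pct(trace, chid.Levels(0.0, -2.0))
        assert dw.total_open + dw.total_closed == pytest.approx(
            dw.T_m, abs=1.0 / FS)


class TestOpenProbability:
    def test_direct_ratio(self):
        dw = chid.DwellSequence([("open", 1.0), ("closed", 3.0)])
        assert chid.open_probability(dw) == pytest.approx(0.25)

    def test_no_open_events(self):
        dw = chid.DwellSequence([("closed", 4.0)])
        assert chid.open_probability(dw) == 0.0

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            chid.open_probability(chid.DwellSequence([], T_m=0.0))

    def test_markov_stationary_probability_recovered(self):
        model = syn.GatingModel(opening_rate=20.0, closing_rate=30.0,
                                noise_sd=0.2, duration=60.0, seed=5)
        trace, _ = syn.gen_gating_trace(model)
        dw = chid.idealize_50pct(trace, chid.Levels(0.0, -2.0))
        po = chid.open_probability(dw)
        # ~1400 gating cycles: 3 standard errors of the stationary Po
        n_cycles = model.duration / (1 / 20 + 1 / 30)
        se = np.sqrt(2.0 / n_cycles) * model.stationary_po * (1 - model.stationary_po)
        assert abs(po - model.stationary_po) < 3 * se + 0.01


class TestWindowConsistency:
    def test_full_window_ratio_is_one(self):
        dw = chid.DwellSequence([("open", 10.0), ("closed", 20.0)])
        rep = chid.window_consistency(dw, window=30.0)
        assert len(rep) == 1
        assert rep["ratio"].iloc[0] == pytest.approx(1.0)

    def test_silent_second_half_flagged(self):
        # 30 s of 50% activity, then a 30.5-s silent tail
        events = ([("open", 0.5), ("closed", 0.5)] * 29
                  + [("open", 0.5), ("closed", 30.5)])
        dw = chid.DwellSequence(events)
        rep = chid.window_consistency(dw, window=30.0)
        assert not rep["passes"].iloc[-1]
        assert rep["ratio"].iloc[0] > rep["ratio"].iloc[-1]

    def test_stationary_record_mostly_passes(self):
        model = syn.GatingModel(opening_rate=400.0, closing_rate=400.0,
                                noise_sd=0.0, duration=120.0, seed=3)
        _, truth = syn.gen_gating_trace(model)
        rep = chid.window_consistency(truth, window=30.0)
        assert rep["passes"].mean() >= 0.7

    def test_window_longer_than_record_errors(self):
        dw = chid.DwellSequence([("open", 1.0), ("closed", 1.0)])
        with pytest.raises(ValueError):
            chid.window_consistency(dw, window=30.0)


class TestMembranePotential:
    @pytest.mark.parametrize("vrev, vcmd, ljp, expected", [
        (0.0, -60.0, 0.0, 60.0),
        (0.0, -60.0, 2.0, 60.0),     # small LJP neglected
        (-10.0, -10.0, 0.0, 0.0),
        (0.0, -60.0, 5.0, 55.0),     # large LJP subtracted
    ])
    def test_values(self, vrev, vcmd, ljp, expected):
        ctx = chid.VoltageContext(V_rev=vrev, V_cmd=vcmd, LJP=ljp)
        assert chid.membrane_potential(ctx) == pytest.approx(expected)


class TestUnitaryIV:
    def test_exact_line(self):
        v = np.array([-100, -80, -60, -40, 40, 60, 80, 100], float)
        pts = list(zip(v, 0.05 * v))
        out = chid.unitary_iv(pts)
        assert out["negative"]["slope_pS"] == pytest.approx(50.0)
        assert out["positive"]["slope_pS"] == pytest.approx(50.0)

    def test_noisy_line_within_stderr(self, rng):
        v = np.linspace(-120, -20, 8)
        i = 0.04 * v + rng.normal(0, 0.05, v.size)
        out = chid.unitary_iv(list(zip(v, i)) + [(50.0, 2.0), (60.0, 2.4)])
        neg = out["negative"]
        assert abs(neg["slope_pS"] - 40.0) < 4 * neg["stderr_pS"]

    def test_single_point_branch_omitted(self):
        with pytest.warns(UserWarning):
            out = chid.unitary_iv([(-60.0, -3.0), (-40.0, -2.0), (40.0, 2.0)])
        assert out["positive"] is None
        assert out["negative"] is not None
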