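"""Baseline fitting, active/inactive classification and burst calling."""

import dataclasses

import numpy as np
import pytest

from ms2burst.kinetics import KineticParams
from ms2burst.simulator import FluorescenceTrace, SimulationConfig, simulate_ensemble
from ms2burst.traces import (
    AllMissingTraceError,
    BaselineModel,
    annotate_ensemble,
    annotate_trace,
    call_bursts,
    classify_active,
    filter_tracked,
    fit_baseline,
    median_filter3,
    normalize_trace,
    summarize_bursting,
)

from conftest import mixed_cohort, truth_on_mask

DT = 15.0


def make_trace(signal, cell_id="c0", region="ME", dt=DT):
    signal = np.asarray(signal, dtype=float)
    return FluorescenceTrace(
        cell_id=cell_id,
        allele_id="a1",
        region_label=region,
        times=np.arange(len(signal)) * dt,
        signal=signal,
    )


def pulse_trace(n_frames, pulses, base=10.0, level=30.0, **kw):
    """Constant background with rectangular pulses given as (start, length)."""
    sig = np.full(n_frames, base)
    for start, length in pulses:
        sig[start : start + length] = level
    return make_trace(sig, **kw)


class TestMedianFilter:
    def test_removes_single_spike(self):
        x = np.array([1.0, 1.0, 9.0, 1.0, 1.0])
        np.testing.assert_array_equal(median_filter3(x), np.ones(5))

    def test_missing_frames_stay_missing(self):
        x = np.array([1.0, np.nan, 3.0, 4.0])
        out = median_filter3(x)
        assert np.isnan(out[1])
        # neighbours of the gap use the available values only
        assert out[2] == pytest.approx(3.5)


class TestBaseline:
    def test_constant_traces(self):
        traces = [make_trace(np.full(30, 7.0)) for _ in range(4)]
        base = fit_baseline(traces)
        assert base.intercept == pytest.approx(7.0)
        assert base.slope == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_recovered(self):
        t = np.arange(40) * DT
        traces = [make_trace(5.0 + 0.01 * t) for _ in range(3)]
        base = fit_baseline(traces)
        assert base.intercept == pytest.approx(5.0, abs=1e-9)
        assert base.slope == pytest.approx(0.01, abs=1e-12)

    def test_two_pass_recovers_background_floor_under_bleaching(self):
        ens = mixed_cohort(noise_sd=2.0, seed=31, bleaching_rate=1e-5,
                           background=100.0)
        base = fit_baseline(ens)
        assert base.n_inactive > 0
        # SE of the intercept from 60 silent nuclei x 241 frames of SD-2 noise
        se = 2.0 / np.sqrt(60 * 241) * 2
        assert abs(base.intercept - 100.0) < max(2 * se, 0.5)

    def test_fallback_when_everything_active(self):
        t = np.arange(30) * DT
        traces = [make_trace(100.0 + 0.0 * t), make_trace(200.0 + 0.0 * t)]
        # each trace sits far from the joint mean; one will be "active"
        base = fit_baseline(traces)
        assert isinstance(base, BaselineModel)


class TestClassifyActive:
    BASE = BaselineModel(intercept=10.0, slope=0.0)

    def test_trace_at_baseline_is_inactive(self):
        active, _ = classify_active(make_trace(np.full(30, 10.0)), self.BASE)
        assert not active

    def test_four_frame_pulse_is_inactive(self):
        trace = pulse_trace(30, [(10, 4)], base=10.0, level=20.0)
        active, _ = classify_active(trace, self.BASE)
        assert not active

    def test_exact_threshold_counts_as_off(self):
        trace = make_trace(np.full(30, 12.0))  # exactly 1.2 x baseline
        active, mask = classify_active(trace, self.BASE)
        assert not active and not mask.any()

    def test_twenty_frame_pulse_detected_within_one_frame(self):
        trace = pulse_trace(60, [(20, 20)], base=10.0, level=30.0)
        active, mask = classify_active(trace, self.BASE)
        assert active
        on = np.flatnonzero(mask)
        assert abs(on.min() - 20) <= 1 and abs(on.max() - 39) <= 1

    def test_all_missing_rejected_with_distinct_error(self):
        with pytest.raises(AllMissingTraceError):
            classify_active(make_trace(np.full(30, np.nan)), self.BASE)

    def test_short_tracks_filtered_upstream(self):
        short = make_trace(np.r_[np.full(8, 20.0), np.full(22, np.nan)])
        long = make_trace(np.full(30, 20.0))
        assert filter_tracked([short, long]) == [long]


class TestNormalize:
    def test_inactive_trace_near_zero(self):
        base = BaselineModel(intercept=10.0, slope=0.0)
        out = normalize_trace(make_trace(np.full(30, 10.0)), base)
        np.testing.assert_allclose(out.signal, 0.0, atol=1e-12)

    def test_zero_bleaching_reduces_to_subtraction(self):
        base = BaselineModel(intercept=10.0, slope=0.0)
        out = normalize_trace(make_trace(np.full(30, 25.0)), base)
        np.testing.assert_allclose(out.signal, 15.0)

    def test_bleached_plateau_flattened(self):
        # always-ON gene under bleaching: normalized plateau has ~zero slope
        params = KineticParams(r=0.5, k_on=1.0, k_off=0.0, T=120.0)
        ens = mixed_cohort(
            noise_sd=1.0, seed=33, params=params, bleaching_rate=5e-5,
            background=50.0, n_active=30, n_inactive=30,
        )
        base = fit_baseline(ens)
        active = [t for t in ens if t.truth["counts"].max() > 0][0]
        out = normalize_trace(active, base)
        window = out.times >= 300.0  # plateau after the elongation fill-in
        slope = np.polyfit(out.times[window], out.signal[window], 1)[0]
        raw_slope = np.polyfit(active.times[window], active.signal[window], 1)[0]
        assert abs(slope) < abs(raw_slope) / 3


class TestCallBursts:
    BASE = BaselineModel(intercept=10.0, slope=0.0)

    def test_two_pulses_and_off_period(self):
        trace = pulse_trace(40, [(5, 10), (25, 10)])
        bursts = call_bursts(trace, self.BASE, analysis_start=0.0)
        assert len(bursts) == 2
        assert bursts[0].duration == pytest.approx(10 * DT)
        assert bursts[1].off_period_before == pytest.approx(10 * DT)
        assert bursts[0].off_period_before is None

    def test_sub_minimum_runs_dropped_not_merged(self):
        trace = pulse_trace(40, [(5, 10), (18, 3), (25, 10)])
        bursts = call_bursts(trace, self.BASE, analysis_start=0.0)
        assert len(bursts) == 2

    def test_pulse_straddling_analysis_start(self):
        # 6-frame pulse with only 4 frames inside the window -> rejected
        trace = pulse_trace(40, [(8, 6)])
        start = 10 * DT
        assert call_bursts(trace, self.BASE, analysis_start=start) == []
        # 9-frame pulse with 5 frames inside -> accepted, clipped at start
        trace = pulse_trace(40, [(6, 9)])
        bursts = call_bursts(trace, self.BASE, analysis_start=start)
        assert len(bursts) == 1
        assert bursts[0].start_time == pytest.approx(start)

    def test_scale_invariance(self):
        trace = pulse_trace(40, [(5, 10), (25, 8)])
        ref = call_bursts(trace, self.BASE, analysis_start=0.0)
        for c in (0.2, 7.0):
            scaled_trace = make_trace(trace.signal * c)
            scaled_base = BaselineModel(
                intercept=self.BASE.intercept * c, slope=0.0
            )
            got = call_bursts(scaled_trace, scaled_base, analysis_start=0.0)
            assert [(b.start_time, b.end_time) for b in got] == [
                (b.start_time, b.end_time) for b in ref
            ]

    def test_frame_bookkeeping_conserved(self):
        trace = pulse_trace(60, [(10, 8), (30, 12)])
        start = 5 * DT
        bursts = call_bursts(trace, self.BASE, analysis_start=start)
        span_end = trace.times[-1] + DT
        total = sum(b.duration for b in bursts)
        total += sum(
            b.off_period_before for b in bursts if b.off_period_before is not None
        )
        lead = bursts[0].start_time - start
        trail = span_end - bursts[-1].end_time
        assert total + lead + trail == pytest.approx(span_end - start)

    def test_short_off_gaps_unresolvable(self):
        # With T = 120 s the nascent signal cannot clear within an OFF gap
        # shorter than ~2 min, so such gaps must NOT be recovered: fast
        # OFF excursions are bridged into single called bursts.
        params = KineticParams(r=0.5, k_on=0.02, k_off=0.01, T=120.0)
        ens = mixed_cohort(noise_sd=0.0, seed=35, params=params,
                           n_active=40, n_inactive=40)
        anns = annotate_ensemble(ens, analysis_start=0.0)
        n_called = sum(len(a.bursts) for a in anns)
        n_true_off_gaps = 0
        for trace in filter_tracked(ens):
            traj = trace.truth.get("trajectory")
            if traj is None:
                continue
            ivals = traj.on_intervals(3600.0)
            n_true_off_gaps += max(len(ivals) - 1, 0)
        # mean OFF dwell is 1/k_on = 50 s << resolution: bursts merge
        assert n_true_off_gaps > 2 * n_called


class TestSummaries:
    def test_single_long_burst_is_sustained(self):
        trace = pulse_trace(80, [(10, 48)])  # 48 frames = 12 min
        ann = annotate_trace(trace, self.base(), analysis_start=0.0)
        assert ann.sustained and ann.active
        summary = summarize_bursting([ann])
        assert summary.loc[0, "fraction_sustained"] == 1.0

    def test_all_inactive_gives_zero_active_fraction(self):
        anns = [
            annotate_trace(make_trace(np.full(40, 10.0), cell_id=f"c{i}"),
                           self.base(), analysis_start=0.0)
            for i in range(5)
        ]
        summary = summarize_bursting(anns)
        assert summary.loc[0, "fraction_active"] == 0.0
        assert summary.loc[0, "n_bursts"] == 0

    def test_onset_and_end_bracket_bursts(self):
        trace = pulse_trace(60, [(10, 8), (30, 12)])
        ann = annotate_trace(trace, self.base(), analysis_start=0.0)
        assert ann.onset_time == pytest.approx(10 * DT)
        assert ann.end_time == pytest.approx((30 + 12) * DT)

    def test_halving_koff_lengthens_bursts_not_off_periods(self):
        slow = KineticParams(r=0.5, k_on=0.002, k_off=0.004, T=120.0)
        slower_off = dataclasses.replace(slow, k_off=0.002)
        durations, offs = {}, {}
        for name, params in (("base", slow), ("half_koff", slower_off)):
            ens = mixed_cohort(noise_sd=1.0, seed=37, params=params,
                               n_active=80, n_inactive=40, duration=5400.0)
            anns = annotate_ensemble(ens, analysis_start=0.0)
            durations[name] = [b.duration for a in anns for b in a.bursts]
            offs[name] = [
                b.off_period_before
                for a in anns
                for b in a.bursts
                if b.off_period_before is not None
            ]
        assert np.median(durations["half_koff"]) > 1.3 * np.median(durations["base"])
        # off periods are governed by k_on alone: medians within bootstrap CI
        rng = np.random.default_rng(0)
        boots = [
            np.median(rng.choice(offs["base"], len(offs["base"])))
            - np.median(rng.choice(offs["half_koff"], len(offs["half_koff"])))
            for _ in range(200)
        ]
        lo, hi = np.percentile(boots, [2.5, 97.5])
        assert lo <= 0.0 <= hi or abs(np.median(boots)) < 2 * DT

    @staticmethod
    def base():
        return BaselineModel(intercept=10.0, slope=0.0)
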