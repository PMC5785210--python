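"""Detrending, noise estimation, event segmentation and binned
time-in-event statistics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from slicephys import (
    CalciumSimConfig, DetectionParams, FluorescenceTrace,
    detect_events, detrend, estimate_noise, generate_dff_trace,
    run_slice_pipeline, time_in_sle,
)
from slicephys.sle import (
    DetectionError, SleEventTrain, interval_overlap, merge_intervals,
)


def dff(values, fr=10.0, **kw):
    return FluorescenceTrace(values=np.asarray(values, float),
                             frame_rate=fr, kind="dff", **kw)


def brute_force_merge(intervals, max_gap, resolution=0.01):
    """Oracle: paint intervals onto a fine grid, dilate gaps, re-read runs."""
    if not intervals:
        return []
    hi = max(e for _, e in intervals) + max_gap + 1
    n = int(hi / resolution) + 1
    mask = np.zeros(n, bool)
    for s, e in intervals:
        mask[int(round(s / resolution)):int(round(e / resolution))] = True
    out = []
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append([i * resolution, j * resolution])
            i = j
        else:
            i += 1
    merged = []
    for s, e in out:
        if merged and s - merged[-1][1] < max_gap - resolution / 2:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


class TestDetrend:
    def test_constant_trace_residual_zero(self):
        out = detrend(dff(np.full(3000, 0.3)))
        assert np.abs(out.values).max() < 1e-9

    def test_linear_drift_removed(self):
        """A 0.2 ΔF/F ramp over 30 min leaves residual bounded by
        slope × (window offset of the rolling percentile)."""
        n = 18000
        ramp = np.linspace(0, 0.2, n)
        out = detrend(dff(ramp))
        assert np.abs(out.values).max() < 0.02

    def test_event_height_preserved_under_drift(self):
        n = 18000
        fr = 10.0
        t = np.arange(n) / fr
        event = np.where((t >= 900) & (t < 910), 1.0, 0.0)
        drift = np.linspace(0, 0.2, n)
        clean = detrend(dff(event))
        drifty = detrend(dff(event + drift))
        sel = (t >= 900) & (t < 910)
        peak_clean = clean.values[sel].max()
        peak_drifty = drifty.values[sel].max()
        assert abs(peak_drifty - peak_clean) / peak_clean < 0.10

    def test_short_trace_rejected(self):
        with pytest.raises(DetectionError, match="shorter"):
            detrend(dff(np.zeros(100)))  # 10 s < 60 s window


class TestNoise:
    def test_gaussian_noise_recovered(self, rng):
        x = rng.normal(0.0, 0.01, 36000)
        est = estimate_noise(dff(x))
        assert 0.009 <= est <= 0.011

    def test_zero_trace_gives_zero(self):
        assert estimate_noise(dff(np.zeros(1000))) == 0.0

    def test_robust_to_event_contamination(self, rng):
        x = rng.normal(0.0, 0.01, 36000)
        clean = estimate_noise(dff(x))
        contaminated = x.copy()
        contaminated[:3600] += 0.5  # 10% of samples inside large events
        est = estimate_noise(dff(contaminated))
        assert abs(est - clean) / clean < 0.15

    def test_all_nan_rejected(self):
        with pytest.raises(DetectionError):
            estimate_noise(dff(np.full(100, np.nan)))


class TestDetect:
    def test_never_above_threshold_is_empty(self):
        train = detect_events(dff(np.zeros(6000)), threshold=0.1)
        assert train.intervals == []

    def test_exact_interval_by_construction(self):
        fr = 10.0
        t = np.arange(6000) / fr
        x = np.where((t >= 100) & (t < 160), 1.0, 0.0)
        train = detect_events(dff(x), threshold=0.5)
        assert train.intervals == [(100.0, 160.0)]

    def test_one_second_gap_merged_with_two_second_rule(self):
        fr = 10.0
        t = np.arange(3000) / fr
        x = (((t >= 100) & (t < 110)) | ((t >= 111) & (t < 120))).astype(float)
        train = detect_events(dff(x), threshold=0.5)
        assert train.intervals == [(100.0, 120.0)]

    def test_short_events_discarded(self):
        fr = 10.0
        x = np.zeros(3000)
        x[1000:1005] = 1.0  # 0.5 s < min_event_s = 1 s
        train = detect_events(dff(x), threshold=0.5)
        assert train.intervals == []

    def test_auto_threshold_is_k_times_noise(self, rng):
        x = rng.normal(0.0, 0.02, 36000)
        train = detect_events(dff(x))
        assert train.threshold == pytest.approx(4.0 * train.noise_sd)

    def test_nonfinite_threshold_rejected(self):
        with pytest.raises(DetectionError, match="finite"):
            detect_events(dff(np.zeros(3000)), threshold=np.inf)

    @given(st.lists(st.tuples(st.floats(0, 500), st.floats(0.5, 30)),
                    min_size=0, max_size=12),
           st.floats(0.5, 5.0))
    def test_merge_rule_matches_brute_force(self, raw, max_gap):
        intervals = sorted((round(s, 2), round(s, 2) + round(d, 2))
                           for s, d in raw)
        # drop overlapping inputs; merge_intervals expects disjoint sorted
        clean = []
        for s, e in intervals:
            if not clean or s >= clean[-1][1]:
                clean.append((s, e))
        got = merge_intervals(clean, max_gap)
        expect = brute_force_merge(clean, max_gap)
        assert len(got) == len(expect)
        for (gs, ge), (es, ee) in zip(got, expect):
            assert gs == pytest.approx(es, abs=0.02)
            assert ge == pytest.approx(ee, abs=0.02)


class TestTimeInSle:
    def _train(self, intervals):
        return SleEventTrain(intervals=intervals, trace_id="t",
                             params_used=DetectionParams(), noise_sd=0.01,
                             threshold=0.04)

    def test_empty_train_all_zero(self):
        out = time_in_sle(self._train([]), duration=4800.0)
        assert np.all(out.fraction == 0.0)
        assert out.plateau_percent == 0.0

    def test_full_bin(self):
        out = time_in_sle(self._train([(600.0, 900.0)]), duration=4800.0)
        frac = out.fraction
        assert frac[2] == pytest.approx(1.0)
        assert frac.sum() == pytest.approx(1.0)

    def test_plateau_percent_from_interval_arithmetic(self):
        intervals = [(2500.0, 2800.0), (3000.0, 3300.0)]  # 600 s in window
        out = time_in_sle(self._train(intervals), duration=4800.0)
        assert out.plateau_percent == pytest.approx(25.0)
        assert not out.plateau_truncated

    def test_truncated_recording_flagged(self):
        out = time_in_sle(self._train([(2500.0, 2800.0)]), duration=3600.0)
        assert out.plateau_truncated
        # 300 s of events over the 1200-s truncated window
        assert out.plateau_percent == pytest.approx(25.0)

    @given(st.lists(st.tuples(st.floats(0, 4700), st.floats(1, 90)),
                    min_size=0, max_size=20))
    def test_mask_conservation(self, raw):
        intervals = []
        for s, d in sorted(raw):
            s, e = round(s, 1), round(s + d, 1)
            e = min(e, 4800.0)
            if not intervals or s >= intervals[-1][1]:
                intervals.append((s, e))
        out = time_in_sle(self._train(intervals), duration=4800.0)
        total = sum(e - s for s, e in intervals)
        assert out.fraction.sum() * 300.0 == pytest.approx(total, abs=1e-9)


class TestDetectorProperties:
    @pytest.mark.parametrize("seed", range(5))
    def test_threshold_scale_equivariance(self, seed):
        cfg = CalciumSimConfig(duration=1200.0, seed=seed)
        trace, _ = generate_dff_trace(cfg)
        flat = detrend(trace)
        c = 3.7
        scaled = flat.with_values(c * flat.values)
        t1 = detect_events(flat)
        t2 = detect_events(scaled)
        assert t2.noise_sd == pytest.approx(c * t1.noise_sd, rel=1e-9)
        assert t2.threshold == pytest.approx(c * t1.threshold, rel=1e-9)
        assert t1.intervals == t2.intervals

    @pytest.mark.parametrize("seed", range(5))
    def test_lower_threshold_k_detects_superset(self, seed):
        cfg = CalciumSimConfig(duration=1200.0, seed=seed)
        trace, _ = generate_dff_trace(cfg)
        flat = detrend(trace)
        low = detect_events(flat, DetectionParams(threshold_k=3.0))
        high = detect_events(flat, DetectionParams(threshold_k=5.0))
        for s, e in high.intervals:
            assert any(ls <= s and e <= le for ls, le in low.intervals)


class TestPipeline:
    def test_all_zero_regions_give_zero_rows(self):
        traces = [dff(np.zeros(36000), region=r)
                  for r in ("DGH", "CA3", "CA1", "MEC", "LEC")]
        trains, table = run_slice_pipeline(traces)
        assert len(trains) == 5
        assert (table["fraction"] == 0.0).all()
        assert (table["plateau_percent"] == 0.0).all()

    def test_recovers_truth_plateau(self):
        cfg = CalciumSimConfig(seed=4)
        trace, truth = generate_dff_trace(cfg)
        trace.region = "DGH"
        params = DetectionParams()
        _, table = run_slice_pipeline([trace], params)
        lo, hi = params.plateau_window
        truth_pct = 100 * interval_overlap(truth.event_intervals, lo, hi) / (hi - lo)
        got = table["plateau_percent"].iloc[0]
        assert abs(got - truth_pct) <= 5.0

    def test_order_independence(self):
        params = DetectionParams(plateau_window=(600.0, 1200.0))
        traces = []
        for i, seed in enumerate([1, 2, 3]):
            tr, _ = generate_dff_trace(CalciumSimConfig(duration=1200.0,
                                                        seed=seed))
            tr.region = f"r{i}"
            tr.trace_id = f"r{i}"
            traces.append(tr)
        _, fwd = run_slice_pipeline(traces, params)
        _, rev = run_slice_pipeline(traces[::-1], params)
        fwd = fwd.sort_values(["trace_id", "bin_start_s"]).reset_index(drop=True)
        rev = rev.sort_values(["trace_id", "bin_start_s"]).reset_index(drop=True)
        assert fwd.equals(rev)

    def test_mismatched_durations_listed(self):
        a = dff(np.zeros(36000)); a.trace_id = "ok"
        b = dff(np.zeros(24000)); b.trace_id = "short"
        with pytest.raises(DetectionError, match="short"):
            run_slice_pipeline([a, b])
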