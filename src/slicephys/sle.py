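"""Seizure-like-event (SLE) detection and time-in-event statistics.

The pipeline for one ΔF/F trace is:

1. :func:`detrend` — subtract a rolling lower-percentile baseline to remove
   slow drift and photobleaching without flattening sustained events;
2. :func:`estimate_noise` — robust per-trace noise SD from sub-median
   samples, so the detection threshold scales with each trace's
   signal-to-noise ratio;
3. :func:`detect_events` — threshold at ``k × noise SD``, merge brief gaps,
   discard brief events;
4. :func:`time_in_sle` — fraction of time in SLEs per 5-min bin, and the
   percent time in SLEs over the 40–80-min plateau window.

:func:`run_slice_pipeline` applies all four stages to every region of a
slice and emits a tidy table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import percentile_filter

from slicephys.trace import FluorescenceTrace, TraceError


class DetectionError(ValueError):
    """Invalid detection input or parameters."""


@dataclass
class DetectionParams:
    """Tunable parameters of the SLE detector.

    All times are seconds.  ``threshold_k`` is the detection threshold in
    multiples of the robust noise SD; ``baseline_window_s`` and
    ``baseline_percentile`` define the rolling-percentile drift baseline;
    ``merge_gap_s`` and ``min_event_s`` post-process the thresholded mask;
    ``bin_width_s`` (5 min) and ``plateau_window`` (40–80 min) control the
    summary statistics.
    """

    baseline_window_s: float = 60.0
    baseline_percentile: float = 10.0
    threshold_k: float = 4.0
    min_event_s: float = 1.0
    merge_gap_s: float = 2.0
    bin_width_s: float = 300.0
    plateau_window: Tuple[float, float] = (2400.0, 4800.0)

    def validate(self) -> None:
        for name in ("baseline_window_s", "threshold_k", "min_event_s",
                     "merge_gap_s", "bin_width_s"):
            if not getattr(self, name) > 0:
                raise DetectionError(f"{name} must be positive")
        if not 0 < self.baseline_percentile < 100:
            raise DetectionError("baseline_percentile must be in (0, 100)")
        if not self.plateau_window[0] < self.plateau_window[1]:
            raise DetectionError("plateau_window start must precede end")


@dataclass
class SleEventTrain:
    """Detected SLE intervals for one trace (seconds, half-open, sorted)."""

    intervals: List[Tuple[float, float]]
    trace_id: Optional[str]
    params_used: DetectionParams
    noise_sd: float
    threshold: float
    region: Optional[str] = None
    condition: Optional[str] = None

    def total_event_time(self) -> float:
        return float(sum(e - s for s, e in self.intervals))


@dataclass
class BinnedSleFraction:
    """Fraction of time in SLEs per time bin, plus the plateau summary.

    ``fraction[i]`` is the overlap of detected events with
    ``[bin_edges[i], bin_edges[i+1])`` divided by the nominal bin width,
    so ``sum(fraction) × bin_width`` equals total event time exactly.
    ``plateau_percent`` is computed from the raw intervals over the
    plateau window (not from bin averages).  ``plateau_truncated`` flags a
    recording shorter than the plateau window's end.
    """

    bin_edges: np.ndarray
    fraction: np.ndarray
    plateau_percent: float
    plateau_window: Tuple[float, float]
    plateau_truncated: bool = False


# --------------------------------------------------------------------------
# Stage 1: drift removal
# --------------------------------------------------------------------------

def _fill_short_nan_runs(trace: FluorescenceTrace) -> np.ndarray:
    """Linearly interpolate dropped frames; error on runs longer than the
    tolerated maximum."""
    values = trace.values
    if not np.isnan(values).any():
        return values
    trace.check_dropped_frames()
    idx = np.arange(values.size)
    good = ~np.isnan(values)
    if not good.any():
        raise DetectionError("trace is entirely dropped frames")
    return np.interp(idx, idx[good], values[good])


def detrend(trace: FluorescenceTrace, params: Optional[DetectionParams] = None) -> FluorescenceTrace:
    """Remove slow baseline drift by subtracting a rolling lower-percentile
    baseline.

    A centered window of ``baseline_window_s`` seconds slides over the
    trace and its ``baseline_percentile``-th percentile forms the
    baseline.  A low percentile tracks the inter-event floor of the signal
    and is insensitive to sustained supra-threshold events, so event
    amplitude is preserved while drift and bleach are removed.
    """
    params = params or DetectionParams()
    params.validate()
    if trace.duration < params.baseline_window_s:
        raise DetectionError(
            f"trace duration {trace.duration:.1f} s is shorter than the "
            f"baseline window ({params.baseline_window_s:.1f} s)")
    values = _fill_short_nan_runs(trace)
    win = int(round(params.baseline_window_s * trace.frame_rate))
    win = max(win | 1, 3)  # odd, centered
    baseline = percentile_filter(values, params.baseline_percentile,
                                 size=win, mode="nearest")
    out = trace.values - baseline  # preserve NaNs at dropped frames
    return trace.with_values(out)


# --------------------------------------------------------------------------
# Stage 2: noise estimation
# --------------------------------------------------------------------------

def estimate_noise(trace: FluorescenceTrace) -> float:
    """Robust noise SD of a detrended trace, in ΔF/F units.

    ``1.4826 × median(|x − median(x)|)`` computed over the samples at or
    below the trace median.  Restricting to the lower half makes the
    estimate insensitive to events, which only push samples upward; for
    pure Gaussian noise it equals the usual MAD estimate of σ.
    """
    x = trace.values
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise DetectionError("cannot estimate noise: no finite samples")
    med = float(np.median(x))
    lower = x[x <= med]
    mad = float(np.median(np.abs(lower - med)))
    return 1.4826 * mad


# --------------------------------------------------------------------------
# Stage 3: thresholding and segmentation
# --------------------------------------------------------------------------

def _mask_to_intervals(mask: np.ndarray, frame_rate: float) -> List[Tuple[float, float]]:
    """Contiguous True runs of a frame mask as half-open second intervals."""
    if not mask.any():
        return []
    padded = np.r_[0, mask.astype(np.int8), 0]
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [(s / frame_rate, e / frame_rate) for s, e in zip(starts, ends)]


def merge_intervals(intervals: Sequence[Tuple[float, float]], max_gap: float) -> List[Tuple[float, float]]:
    """Merge sorted half-open intervals separated by gaps shorter than
    ``max_gap`` seconds."""
    merged: List[Tuple[float, float]] = []
    for s, e in intervals:
        if merged and s - merged[-1][1] < max_gap:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def detect_events(
    trace: FluorescenceTrace,
    params: Optional[DetectionParams] = None,
    threshold: Optional[float] = None,
    noise_sd: Optional[float] = None,
) -> SleEventTrain:
    """Segment SLEs from a detrended trace.

    Samples strictly above the threshold form the event mask; gaps shorter
    than ``merge_gap_s`` are merged, then events shorter than
    ``min_event_s`` are discarded.  If no explicit ``threshold`` is given
    it is set to ``threshold_k × noise_sd`` with the noise SD estimated
    from the trace (per-trace SNR scaling).
    """
    params = params or DetectionParams()
    params.validate()
    if noise_sd is None:
        noise_sd = estimate_noise(trace)
    if threshold is None:
        if noise_sd <= 0:
            raise DetectionError(
                "noise SD is zero and no explicit threshold was supplied")
        threshold = params.threshold_k * noise_sd
    if not np.isfinite(threshold):
        raise DetectionError(f"threshold must be finite, got {threshold}")

    with np.errstate(invalid="ignore"):
        mask = trace.values > threshold
    mask[~np.isfinite(trace.values)] = False
    intervals = _mask_to_intervals(mask, trace.frame_rate)
    intervals = merge_intervals(intervals, params.merge_gap_s)
    intervals = [(s, e) for s, e in intervals if e - s >= params.min_event_s]
    return SleEventTrain(
        intervals=intervals, trace_id=trace.trace_id, params_used=params,
        noise_sd=float(noise_sd), threshold=float(threshold),
        region=trace.region, condition=trace.condition)


# --------------------------------------------------------------------------
# Stage 4: binned time-in-event statistics
# --------------------------------------------------------------------------

def interval_overlap(intervals: Sequence[Tuple[float, float]], lo: float, hi: float) -> float:
    """Total overlap in seconds of half-open intervals with ``[lo, hi)``."""
    return float(sum(max(0.0, min(e, hi) - max(s, lo)) for s, e in intervals))


def time_in_sle(
    train: SleEventTrain,
    duration: float,
    params: Optional[DetectionParams] = None,
) -> BinnedSleFraction:
    """Binned fraction of time in SLEs plus the plateau-window percentage.

    Bins of ``bin_width_s`` are anchored at t = 0 and tile ``[0,
    duration)``; each bin's fraction is event overlap divided by the
    nominal bin width.  ``plateau_percent`` is 100 × (event time within
    the plateau window) / (window length), computed from the raw
    intervals.  If the recording ends before the window does, the percent
    is computed over the overlapping part and flagged as truncated.
    """
    params = params or train.params_used or DetectionParams()
    params.validate()
    if train.intervals and duration < train.intervals[-1][1]:
        raise DetectionError(
            f"duration {duration:.1f} s precedes the last event end "
            f"({train.intervals[-1][1]:.1f} s)")
    n_bins = int(np.ceil(duration / params.bin_width_s))
    edges = np.arange(n_bins + 1) * params.bin_width_s
    edges[-1] = min(edges[-1], duration)
    fraction = np.array([
        interval_overlap(train.intervals, edges[i], edges[i + 1]) / params.bin_width_s
        for i in range(n_bins)
    ])
    p_lo, p_hi = params.plateau_window
    truncated = duration < p_hi
    eff_hi = min(p_hi, duration)
    window_len = eff_hi - p_lo
    if window_len <= 0:
        raise DetectionError(
            "recording ends before the plateau window starts")
    plateau = 100.0 * interval_overlap(train.intervals, p_lo, eff_hi) / window_len
    return BinnedSleFraction(
        bin_edges=edges, fraction=fraction, plateau_percent=float(plateau),
        plateau_window=(p_lo, p_hi), plateau_truncated=truncated)


# --------------------------------------------------------------------------
# Whole-slice pipeline
# --------------------------------------------------------------------------

def run_slice_pipeline(
    traces: Sequence[FluorescenceTrace],
    params: Optional[DetectionParams] = None,
) -> Tuple[Dict[str, SleEventTrain], pd.DataFrame]:
    """Detrend → estimate noise → detect → bin for every region of a slice.

    All traces must share duration and frame rate.  Returns the per-trace
    event trains and a tidy table with one row per (trace, bin):
    ``region, condition, trace_id, bin_start_s, bin_end_s, fraction,
    plateau_percent, threshold, noise_sd``.
    """
    params = params or DetectionParams()
    params.validate()
    if not traces:
        raise DetectionError("no traces supplied")
    ref = traces[0]
    bad = [t.trace_id or f"#{i}" for i, t in enumerate(traces)
           if t.n_frames != ref.n_frames or t.frame_rate != ref.frame_rate]
    if bad:
        raise DetectionError(
            "traces differ in duration or frame rate: " + ", ".join(bad))

    trains: Dict[str, SleEventTrain] = {}
    rows = []
    for i, trace in enumerate(traces):
        tid = trace.trace_id or trace.region or f"trace{i}"
        flat = detrend(trace, params)
        noise = estimate_noise(flat)
        # a noiseless trace (e.g. all-zero region) gets a zero threshold:
        # only strictly positive excursions count as events
        threshold = 0.0 if noise == 0 else None
        train = detect_events(flat, params, threshold=threshold,
                              noise_sd=noise)
        binned = time_in_sle(train, trace.duration, params)
        trains[tid] = train
        for b in range(binned.fraction.size):
            rows.append({
                "region": trace.region, "condition": trace.condition,
                "trace_id": tid,
                "bin_start_s": binned.bin_edges[b],
                "bin_end_s": binned.bin_edges[b + 1],
                "fraction": binned.fraction[b],
                "plateau_percent": binned.plateau_percent,
                "threshold": train.threshold, "noise_sd": train.noise_sd,
            })
    return trains, pd.DataFrame(rows)
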