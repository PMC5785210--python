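"""Patch-clamp analyses: ramp slope conductance, input resistance,
washdown time courses, action-potential counting and F–I curves.

The voltage-clamp side implements the running slope-conductance assay used
to follow K_ATP "washdown" after whole-cell break-in: each sweep holds
−70 mV, applies two 100-ms prepulse steps (−100 then −120 mV), then ramps
−120→−60 mV over 1 s; the ramp current is fitted with a straight line over
−120…−90 mV and the resulting conductance series is normalized to its
value 3 min after break-in.  The current-clamp side counts action
potentials during 1-s current pulses (50–200 pA) to build F–I curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np


class EphysError(ValueError):
    """Invalid electrophysiology data or analysis request."""


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------

@dataclass
class RampSweep:
    """One voltage-ramp sweep: command (mV) and recorded current (pA)."""

    time_from_breakin: float   # s
    command: np.ndarray        # mV
    current: np.ndarray        # pA
    sample_rate: float         # Hz

    def __post_init__(self) -> None:
        self.command = np.asarray(self.command, dtype=np.float64)
        self.current = np.asarray(self.current, dtype=np.float64)
        if self.command.shape != self.current.shape:
            raise EphysError("command and current traces differ in length")
        if self.sample_rate <= 0:
            raise EphysError("sample_rate must be positive")


@dataclass
class RampRecording:
    """A series of ramp sweeps (typically one every 10 s from break-in)."""

    sweeps: List[RampSweep]
    sample_rate: float

    def __post_init__(self) -> None:
        times = [s.time_from_breakin for s in self.sweeps]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise EphysError("sweep times must be strictly increasing")

    @property
    def sweep_times(self) -> np.ndarray:
        return np.array([s.time_from_breakin for s in self.sweeps])


@dataclass
class ConductanceTimeCourse:
    """Per-sweep slope conductance relative to break-in.

    ``normalized`` is conductance divided by its value at the anchor sweep
    (the sweep nearest 3 min after break-in by default), so the anchor
    entry is exactly 1.
    """

    times: np.ndarray            # s from break-in
    conductance: np.ndarray      # nS
    normalized: np.ndarray       # dimensionless
    input_resistance: np.ndarray  # MΩ per sweep
    anchor_time: float           # s; the anchor sweep's time
    anchor_index: int


@dataclass
class CurrentClampRecording:
    """Voltage responses to a family of current pulses.

    ``sweeps`` is a list of ``(amplitude_pA, voltage_trace_mV)``;
    ``pulse_window`` is the half-open ``(start_s, end_s)`` of the pulse
    within each sweep.
    """

    sweeps: List[Tuple[float, np.ndarray]]
    sample_rate: float
    pulse_window: Tuple[float, float]
    holding_current: float = 0.0   # pA

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise EphysError("sample_rate must be positive")
        if not self.sweeps:
            raise EphysError("recording has no sweeps")
        n = self.sweeps[0][1].size
        w0, w1 = self.pulse_window
        if not (0 <= w0 < w1 <= n / self.sample_rate + 1e-9):
            raise EphysError("pulse window must lie within the sweep")
        if abs(self.holding_current) >= 30.0:
            raise EphysError(
                f"holding current {self.holding_current:.1f} pA exceeds the "
                "30 pA bound for a cell held near rest")


@dataclass
class FICurve:
    """Action-potential count versus injected current amplitude."""

    amplitudes: np.ndarray       # pA, sorted ascending
    ap_counts: np.ndarray        # non-negative ints
    detection_rule: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64)
        self.ap_counts = np.asarray(self.ap_counts, dtype=np.int64)
        if self.amplitudes.shape != self.ap_counts.shape:
            raise EphysError("amplitudes and counts differ in length")
        if np.any(self.ap_counts < 0):
            raise EphysError("AP counts must be non-negative")


# --------------------------------------------------------------------------
# Ramp analysis
# --------------------------------------------------------------------------

def _ramp_segment(command: np.ndarray) -> slice:
    """Locate the voltage ramp as the longest strictly-increasing run of
    the command waveform."""
    dv = np.diff(command)
    rising = dv > 1e-12
    if not rising.any():
        raise EphysError("command waveform contains no rising ramp segment")
    # longest run of consecutive True
    edges = np.flatnonzero(np.diff(rising.astype(np.int8)))
    starts = np.r_[0, edges + 1]
    ends = np.r_[edges + 1, rising.size]
    run_lengths = ends - starts
    run_lengths[~rising[starts]] = 0
    k = int(np.argmax(run_lengths))
    return slice(int(starts[k]), int(ends[k]) + 1)


def slope_conductance(
    sweep: RampSweep,
    fit_range: Tuple[float, float] = (-120.0, -90.0),
) -> float:
    """Whole-cell slope conductance in nS from one ramp sweep.

    Ordinary-least-squares slope of recorded current (pA) versus commanded
    voltage (mV) over ramp samples whose command lies in ``fit_range``
    (inclusive); pA/mV = nS.
    """
    lo, hi = min(fit_range), max(fit_range)
    seg = _ramp_segment(sweep.command)
    v = sweep.command[seg]
    i = sweep.current[seg]
    mask = (v >= lo) & (v <= hi)
    if mask.sum() < 10:
        raise EphysError(
            f"only {int(mask.sum())} ramp samples in fit range "
            f"[{lo}, {hi}] mV; need at least 10")
    slope, _ = np.polyfit(v[mask], i[mask], 1)
    return float(slope)


def _constant_segments(command: np.ndarray, min_samples: int) -> list:
    """(start, stop, level) for maximal constant runs of the command."""
    dv = np.abs(np.diff(command)) < 1e-9
    edges = np.flatnonzero(np.diff(dv.astype(np.int8)))
    starts = np.r_[0, edges + 1]
    ends = np.r_[edges + 1, dv.size]
    out = []
    for a, b in zip(starts, ends):
        if dv[a] and (b + 1 - a) >= min_samples:
            out.append((int(a), int(b) + 1, float(command[a])))
    return out


def input_resistance(sweep: RampSweep, steady_state_s: float = 0.02) -> float:
    """Input resistance in MΩ from the two prepulse steps.

    ``R = ΔV/ΔI`` between the −100 and −120 mV steps, with each step's
    current taken as the mean over its last ``steady_state_s`` seconds
    (late window, after capacitive transients have settled).
    """
    min_samples = max(int(0.05 * sweep.sample_rate), 10)
    segments = _constant_segments(sweep.command, min_samples)
    if not segments:
        raise EphysError("no constant command segments found")
    holding = segments[0][2]
    steps = [(a, b, lvl) for a, b, lvl in segments if lvl < holding - 1e-6]
    levels = sorted({lvl for _, _, lvl in steps})
    if len(levels) < 2:
        raise EphysError(
            "prepulse steps missing: need two distinct step levels below "
            f"holding, found {len(levels)}")
    n_ss = max(int(steady_state_s * sweep.sample_rate), 1)
    means = {}
    for a, b, lvl in steps:
        if lvl in (levels[0], levels[1]) and lvl not in means:
            means[lvl] = float(np.mean(sweep.current[b - n_ss:b]))
    v1, v2 = levels[0], levels[1]
    di = means[v2] - means[v1]
    if di == 0:
        raise EphysError("zero current difference between prepulse steps")
    # mV/pA = GΩ → ×1000 MΩ
    return float(1000.0 * (v2 - v1) / di)


def washdown_timecourse(
    rec: RampRecording,
    anchor_s: float = 180.0,
    fit_range: Tuple[float, float] = (-120.0, -90.0),
    anchor_tolerance_s: float = 30.0,
) -> ConductanceTimeCourse:
    """Slope-conductance time course normalized to the value at the
    sweep nearest ``anchor_s`` (3 min after break-in by default).

    The anchor is the recorded sweep nearest the anchor time (ties go to
    the earlier sweep); no interpolation is performed, so the normalized
    series is exactly 1 at the anchor.
    """
    if not rec.sweeps:
        raise EphysError("recording has no sweeps")
    times = rec.sweep_times
    dist = np.abs(times - anchor_s)
    anchor_idx = int(np.argmin(dist))   # argmin takes the earlier of ties
    if dist[anchor_idx] > anchor_tolerance_s:
        raise EphysError(
            f"no sweep within {anchor_tolerance_s:.0f} s of the "
            f"{anchor_s:.0f} s anchor (nearest at {times[anchor_idx]:.0f} s)")
    g = np.array([slope_conductance(s, fit_range) for s in rec.sweeps])
    r_in = np.array([input_resistance(s) for s in rec.sweeps])
    g_anchor = g[anchor_idx]
    if g_anchor == 0:
        raise EphysError("anchor conductance is zero; cannot normalize")
    normalized = g / g_anchor
    normalized[anchor_idx] = 1.0   # exact by construction
    return ConductanceTimeCourse(
        times=times, conductance=g, normalized=normalized,
        input_resistance=r_in,
        anchor_time=float(times[anchor_idx]), anchor_index=anchor_idx)


# --------------------------------------------------------------------------
# Current-clamp analysis
# --------------------------------------------------------------------------

AP_RULES = ("zero_crossing", "dvdt")


def count_aps(
    voltage: np.ndarray,
    sample_rate: float,
    pulse_window: Tuple[float, float],
    rule: str = "zero_crossing",
    refractory_s: float = 0.002,
    dvdt_threshold: float = 20.0,
) -> int:
    """Count action potentials in one sweep within the half-open pulse
    window.

    ``zero_crossing``: upward crossings of 0 mV.  ``dvdt``: upward
    crossings of ``dV/dt ≥ dvdt_threshold`` mV/ms.  Both rules apply an
    absolute refractory period so one spike is never counted twice.
    """
    voltage = np.asarray(voltage, dtype=np.float64)
    if not np.isfinite(voltage).all():
        raise EphysError("voltage trace contains non-finite samples")
    w0, w1 = pulse_window
    n = voltage.size
    if not (0 <= w0 < w1 <= n / sample_rate + 1e-9):
        raise EphysError("pulse window lies outside the sweep")
    if rule == "zero_crossing":
        sig = voltage
        level = 0.0
    elif rule == "dvdt":
        sig = np.diff(voltage, prepend=voltage[0]) * sample_rate / 1000.0  # mV/ms
        level = dvdt_threshold
    else:
        raise EphysError(f"unknown AP rule {rule!r}; choose from {AP_RULES}")
    above = sig >= level
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    times = crossings / sample_rate
    times = times[(times >= w0) & (times < w1)]
    count = 0
    last = -np.inf
    for t in times:
        if t - last >= refractory_s:
            count += 1
            last = t
    return count


def fi_curve(
    rec: CurrentClampRecording,
    rule: str = "zero_crossing",
    refractory_s: float = 0.002,
    dvdt_threshold: float = 20.0,
) -> FICurve:
    """F–I curve: AP count per injected-current amplitude, sorted by
    amplitude.  Group aggregation (mean ± SEM across cells) is left to the
    statistics layer."""
    amps = [a for a, _ in rec.sweeps]
    if len(set(amps)) != len(amps):
        raise EphysError("duplicate pulse amplitudes in recording")
    order = np.argsort(amps)
    amplitudes = []
    counts = []
    for k in order:
        amp, v = rec.sweeps[k]
        amplitudes.append(amp)
        counts.append(count_aps(v, rec.sample_rate, rec.pulse_window,
                                rule=rule, refractory_s=refractory_s,
                                dvdt_threshold=dvdt_threshold))
    return FICurve(
        amplitudes=np.array(amplitudes), ap_counts=np.array(counts),
        detection_rule={"rule": rule, "refractory_s": refractory_s,
                        "dvdt_threshold_mv_per_ms": dvdt_threshold})
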