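"""Synthetic recordings with exact ground truth.

Three generators emulate the study's recording types:

- :func:`generate_dff_trace` — slice calcium-imaging ΔF/F traces in which
  seizure-like events (SLEs) appear after a convulsant-onset time, ride on a
  slowly drifting, photobleaching baseline, and plateau in rate late in the
  recording.
- :func:`generate_ramp_recording` — voltage-clamp ramp sweeps from a passive
  membrane with a time-varying K_ATP-like conductance ("washdown" decay,
  "run-up" growth, or constant).
- :func:`generate_current_clamp` — current-clamp voltage sweeps from a leaky
  integrate-and-fire (LIF) neuron under 1-s current pulses.

Every generator returns a :class:`SyntheticTruth` carrying the exact event
intervals, spike times or conductance function, so downstream detectors can
be scored against ground truth.  All randomness is drawn from a single
``numpy`` generator seeded from the config; equal configs give bit-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Tuple

import numpy as np

from slicephys.trace import FluorescenceTrace
from slicephys.ephys import RampSweep, RampRecording, CurrentClampRecording


class SimConfigError(ValueError):
    """A simulation config field is invalid; the message names the field."""


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise SimConfigError(f"{field_name}: {msg}")


# --------------------------------------------------------------------------
# Ground truth
# --------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Exact ground truth attached to a generated dataset.

    ``event_intervals`` are half-open ``(start_s, end_s)`` SLE intervals;
    ``spike_times`` are exact threshold-crossing times (current-clamp case);
    ``conductance_fn`` maps time-from-break-in to the true total slope
    conductance in nS (ramp case).  ``params`` is the generating config.
    """

    event_intervals: list = field(default_factory=list)
    spike_times: list = field(default_factory=list)
    spike_times_by_amplitude: dict = field(default_factory=dict)
    conductance_fn: Optional[Callable[[float], float]] = None
    params: object = None

    def validate(self, duration: Optional[float] = None) -> None:
        prev_end = -math.inf
        for start, end in self.event_intervals:
            if not (start < end):
                raise ValueError(f"degenerate interval ({start}, {end})")
            if start < prev_end:
                raise ValueError("event intervals overlap or are unsorted")
            if duration is not None and (start < 0 or end > duration):
                raise ValueError("event interval outside [0, duration)")
            prev_end = end
        if np.any(np.diff(self.spike_times) <= 0):
            raise ValueError("spike_times must be strictly increasing")


# --------------------------------------------------------------------------
# Calcium imaging
# --------------------------------------------------------------------------

@dataclass
class CalciumSimConfig:
    """Parameters of the synthetic ΔF/F trace generator.

    Defaults mirror the imaging protocol: 10 Hz frame rate, 10 min of
    baseline before drug onset, SLE rate rising after onset and plateauing
    by 2400 s, transient amplitude ~0.5 ΔF/F.

    ``sle_rate_profile`` is either a plateau rate in events/min (a sigmoid
    rise from drug onset reaching that plateau by ``rate_plateau_s``) or a
    callable mapping time in seconds to an instantaneous rate in events/min.
    ``forced_events`` inserts explicit ground-truth intervals regardless of
    the stochastic rate (useful for controlled tests).
    """

    duration: float = 4800.0          # s; 80-min recording
    frame_rate: float = 10.0          # Hz
    drug_onset: float = 600.0         # s
    latency_to_first_sle: float = 120.0   # s after onset before events may start
    sle_rate_profile: object = 0.75   # events/min at plateau, or callable t->rate
    rate_plateau_s: float = 2400.0    # s; rate reaches plateau by here
    event_duration_mean: float = 20.0  # s
    event_duration_sd: float = 5.0     # s
    transient_rise_tau: float = 0.05   # s
    transient_decay_tau: float = 0.4   # s
    transient_rate: float = 5.0        # Hz; within-event transient rate
    peak_dff: float = 0.5              # ΔF/F amplitude of one transient
    drift_amplitude: float = 0.05      # ΔF/F; SD of the slow drift process
    drift_tau: float = 120.0           # s; drift smoothness timescale
    bleach_amplitude: float = 0.1      # ΔF/F; asymptotic bleach loss
    bleach_tau: float = 1800.0         # s; may be math.inf for no bleach
    noise_sd: float = 0.02             # ΔF/F
    forced_events: Tuple[Tuple[float, float], ...] = ()
    seed: int = 0

    def validate(self) -> None:
        _require(self.drug_onset >= 0, "drug_onset", "must be >= 0")
        _require(self.duration > self.drug_onset, "duration",
                 "must exceed drug_onset")
        _require(self.frame_rate > 0, "frame_rate", "must be positive")
        _require(self.latency_to_first_sle >= 0, "latency_to_first_sle",
                 "must be >= 0")
        for name in ("transient_rise_tau", "transient_decay_tau",
                     "drift_tau", "bleach_tau"):
            _require(getattr(self, name) > 0, name, "must be positive")
        _require(self.transient_decay_tau > self.transient_rise_tau,
                 "transient_decay_tau", "must exceed transient_rise_tau")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(self.event_duration_mean > 0, "event_duration_mean",
                 "must be positive")
        _require(self.event_duration_sd >= 0, "event_duration_sd",
                 "must be >= 0")
        _require(self.peak_dff > 0, "peak_dff", "must be positive")
        _require(self.drift_amplitude >= 0, "drift_amplitude", "must be >= 0")
        _require(self.bleach_amplitude >= 0, "bleach_amplitude", "must be >= 0")
        _require(self.transient_rate > 0, "transient_rate", "must be positive")
        if not callable(self.sle_rate_profile):
            _require(float(self.sle_rate_profile) >= 0, "sle_rate_profile",
                     "plateau rate must be >= 0")
        for iv in self.forced_events:
            _require(0 <= iv[0] < iv[1] <= self.duration, "forced_events",
                     f"interval {iv} must lie in [0, duration]")

    def rate_at(self, t: np.ndarray) -> np.ndarray:
        """Instantaneous SLE rate in events/min at time(s) ``t`` seconds."""
        t = np.asarray(t, dtype=float)
        if callable(self.sle_rate_profile):
            return np.asarray(self.sle_rate_profile(t), dtype=float)
        r_max = float(self.sle_rate_profile)
        t_on = self.drug_onset
        t_plateau = max(self.rate_plateau_s, t_on + 1.0)
        mid = 0.5 * (t_on + t_plateau)
        width = (t_plateau - t_on) / 10.0
        rate = r_max / (1.0 + np.exp(-(t - mid) / width))
        return np.where(t < t_on, 0.0, rate)


def transient_kernel(t: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Difference-of-exponentials calcium transient, peak-normalized to 1.

    ``k(t) = (e^{-t/τ_d} - e^{-t/τ_r}) / k(t*)`` for ``t >= 0`` with the
    peak at ``t* = τ_r τ_d / (τ_d - τ_r) · ln(τ_d/τ_r)``.
    """
    t = np.asarray(t, dtype=float)
    t_peak = rise_tau * decay_tau / (decay_tau - rise_tau) * math.log(decay_tau / rise_tau)
    norm = math.exp(-t_peak / decay_tau) - math.exp(-t_peak / rise_tau)
    out = np.exp(-t / decay_tau) - np.exp(-t / rise_tau)
    out[t < 0] = 0.0
    return out / norm


def _sample_event_intervals(cfg: CalciumSimConfig, rng: np.random.Generator) -> list:
    """Draw SLE intervals from the inhomogeneous Poisson rate profile.

    Event starts are thinned against the peak rate; each start gets a
    truncated-normal duration.  Events overlapping an earlier one are
    dropped so truth intervals are disjoint.  Forced events are inserted
    first and always kept.
    """
    intervals = sorted((float(a), float(b)) for a, b in cfg.forced_events)
    earliest = cfg.drug_onset + cfg.latency_to_first_sle

    if callable(cfg.sle_rate_profile):
        grid = np.linspace(0.0, cfg.duration, 2049)
        r_max = float(np.max(cfg.rate_at(grid)))
    else:
        r_max = float(cfg.sle_rate_profile)
    if r_max <= 0:
        return intervals

    lam = r_max / 60.0  # events per second
    t = earliest
    candidates = []
    while True:
        t += rng.exponential(1.0 / lam)
        if t >= cfg.duration:
            break
        if rng.uniform() * r_max <= float(cfg.rate_at(t)):
            candidates.append(t)

    for start in candidates:
        dur = rng.normal(cfg.event_duration_mean, cfg.event_duration_sd)
        dur = max(dur, 1.0)
        end = min(start + dur, cfg.duration)
        if end <= start:
            continue
        # keep truth intervals disjoint with a small guard gap
        clash = any(start < e + 1.0 and end > s - 1.0 for s, e in intervals)
        if not clash:
            intervals.append((start, end))
            intervals.sort()
    return intervals


def generate_dff_trace(config: CalciumSimConfig) -> Tuple[FluorescenceTrace, SyntheticTruth]:
    """Simulate one region's ΔF/F trace plus exact SLE ground truth.

    The trace is ``baseline + events + noise`` where the baseline is a slow
    Gaussian-process drift plus an exponential photobleaching decay, and
    each SLE renders as a dense Poisson train of difference-of-exponential
    transients so the ΔF/F envelope stays elevated for the event's duration.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = round(config.duration * config.frame_rate)
    times = np.arange(n) / config.frame_rate

    intervals = _sample_event_intervals(config, rng)

    # --- baseline: smooth drift + photobleaching decay
    # The drift is white noise low-pass filtered at the drift timescale;
    # it is generated on a coarse grid (>= 20 points per drift_tau) and
    # interpolated, which is statistically equivalent at a fraction of the
    # cost of filtering at the full frame rate.
    baseline = np.zeros(n)
    grid_dt = max(1.0 / config.frame_rate, config.drift_tau / 40.0)
    n_grid = int(config.duration / grid_dt) + 2
    raw = rng.normal(0.0, 1.0, n_grid)  # drawn always, so the seed stream
    if config.drift_amplitude > 0:      # is layout-independent
        from scipy.ndimage import gaussian_filter1d

        smooth = gaussian_filter1d(raw, config.drift_tau / grid_dt,
                                   mode="reflect")
        smooth = np.interp(times, np.arange(n_grid) * grid_dt, smooth)
        sd = smooth.std()
        if sd > 0:
            baseline += config.drift_amplitude * smooth / sd
    if config.bleach_amplitude > 0 and math.isfinite(config.bleach_tau):
        baseline -= config.bleach_amplitude * (1.0 - np.exp(-times / config.bleach_tau))

    # --- events: one transient at each event start plus a Poisson train
    signal = np.zeros(n)
    kern_len = int(8 * config.transient_decay_tau * config.frame_rate) + 2
    kern_t = np.arange(kern_len) / config.frame_rate
    transient_times = []
    for start, end in intervals:
        transient_times.append(start)
        t = start
        while True:
            t += rng.exponential(1.0 / config.transient_rate)
            if t >= end:
                break
            transient_times.append(t)
    if transient_times:
        t_ev = np.asarray(transient_times)
        amps = config.peak_dff * rng.uniform(0.8, 1.0, t_ev.size)
        i0 = np.ceil(t_ev * config.frame_rate).astype(np.int64)
        keep = i0 < n
        t_ev, amps, i0 = t_ev[keep], amps[keep], i0[keep]
        # kernel sampled at each transient's (sub-frame) offset, vectorized
        offsets = i0 / config.frame_rate - t_ev
        tk = kern_t[None, :] + offsets[:, None]          # (n_transients, L)
        contrib = amps[:, None] * transient_kernel(
            tk, config.transient_rise_tau, config.transient_decay_tau)
        idx = i0[:, None] + np.arange(kern_len)[None, :]
        flat_ok = idx < n
        np.add.at(signal, idx[flat_ok], contrib[flat_ok])

    values = baseline + signal
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, n)

    trace = FluorescenceTrace(values=values, frame_rate=config.frame_rate,
                              kind="dff", drug_onset=config.drug_onset)
    truth = SyntheticTruth(event_intervals=intervals, params=config)
    truth.validate(duration=config.duration)
    return trace, truth


# --------------------------------------------------------------------------
# Voltage-clamp ramps
# --------------------------------------------------------------------------

@dataclass
class MembraneSimConfig:
    """Passive membrane with a time-varying K_ATP-like conductance.

    ``katp_mode`` selects the conductance time course (seconds from
    break-in):

    - ``washdown``: ``g(t) = g0 · e^{-t/τ}`` — an initially open K_ATP
      conductance closing as high-ATP pipette solution dialyzes the cell;
    - ``runup``: ``g(t) = g_inf · (1 - e^{-t/τ})`` — channels disinhibited
      as ATP washes out;
    - ``constant``: ``g(t) = g0``.
    """

    capacitance: float = 35.0          # pF (study cells: 30–40 pF)
    leak_conductance: float = 1.0      # nS
    leak_reversal: float = -70.0       # mV
    katp_conductance_t0: float = 3.0   # nS; g0
    katp_conductance_inf: float = 3.0  # nS; run-up asymptote
    katp_tau: float = 60.0             # s
    katp_mode: str = "washdown"        # washdown | runup | constant
    katp_reversal: float = -90.0       # mV
    noise_sd: float = 0.0              # pA
    sample_rate: float = 5000.0        # Hz
    seed: int = 0

    def validate(self) -> None:
        _require(0 < self.capacitance <= 1000, "capacitance",
                 "must be in (0, 1000] pF")
        _require(self.leak_conductance >= 0, "leak_conductance", "must be >= 0")
        _require(self.katp_conductance_t0 >= 0, "katp_conductance_t0",
                 "must be >= 0")
        _require(self.katp_conductance_inf >= 0, "katp_conductance_inf",
                 "must be >= 0")
        _require(self.katp_tau > 0, "katp_tau", "must be positive")
        _require(self.katp_mode in ("washdown", "runup", "constant"),
                 "katp_mode", "must be washdown, runup or constant")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(self.sample_rate > 0, "sample_rate", "must be positive")

    def katp_at(self, t: float) -> float:
        """K_ATP conductance in nS at time ``t`` seconds from break-in."""
        if self.katp_mode == "washdown":
            return self.katp_conductance_t0 * math.exp(-t / self.katp_tau)
        if self.katp_mode == "runup":
            return self.katp_conductance_inf * (1.0 - math.exp(-t / self.katp_tau))
        return self.katp_conductance_t0

    def total_conductance_at(self, t: float) -> float:
        """True total slope conductance (leak + K_ATP) in nS at time ``t``."""
        return self.leak_conductance + self.katp_at(t)


# ramp protocol segment durations, seconds
RAMP_HOLD_S = 0.1
RAMP_STEP_S = 0.1
RAMP_RAMP_S = 1.0
RAMP_TAIL_S = 0.1
RAMP_HOLD_MV = -70.0
RAMP_STEP1_MV = -100.0
RAMP_STEP2_MV = -120.0
RAMP_END_MV = -60.0


def ramp_command_waveform(sample_rate: float) -> np.ndarray:
    """Command voltage for one ramp sweep: hold −70 mV, 100-ms steps to
    −100 then −120 mV, a 1-s ramp −120→−60 mV, then back to hold."""
    return _ramp_command_and_dvdt(sample_rate)[0]


def _ramp_command_and_dvdt(sample_rate: float):
    """Command waveform plus its piecewise-analytic derivative (mV/s).

    The derivative is taken segment-wise (zero on holds and steps, the
    exact ramp slope on ramp samples) so the simulated capacitive current
    is constant within the ramp rather than smeared across segment edges.
    """
    def n_of(dur):
        return round(dur * sample_rate)

    hold = np.full(n_of(RAMP_HOLD_S), RAMP_HOLD_MV)
    step1 = np.full(n_of(RAMP_STEP_S), RAMP_STEP1_MV)
    step2 = np.full(n_of(RAMP_STEP_S), RAMP_STEP2_MV)
    n_ramp = n_of(RAMP_RAMP_S)
    ramp = RAMP_STEP2_MV + (RAMP_END_MV - RAMP_STEP2_MV) * np.arange(n_ramp) / n_ramp
    tail = np.full(n_of(RAMP_TAIL_S), RAMP_HOLD_MV)
    command = np.concatenate([hold, step1, step2, ramp, tail])
    dvdt = np.zeros_like(command)
    ramp_start = hold.size + step1.size + step2.size
    dvdt[ramp_start:ramp_start + n_ramp] = (RAMP_END_MV - RAMP_STEP2_MV) / RAMP_RAMP_S
    return command, dvdt


def generate_ramp_recording(
    config: MembraneSimConfig,
    n_sweeps: int = 30,
    sweep_interval: float = 10.0,
) -> Tuple[RampRecording, SyntheticTruth]:
    """Simulate a whole-cell ramp protocol run (one sweep every
    ``sweep_interval`` seconds from break-in).

    Per sweep the membrane current is the sum of ohmic leak and K_ATP
    components plus the capacitive current ``C·dV/dt``; the K_ATP
    conductance is frozen at its value at the sweep's start time, so
    ``truth.conductance_fn`` is exact for any within-sweep fit.
    """
    config.validate()
    if n_sweeps < 1:
        raise SimConfigError("n_sweeps: must be >= 1")
    if sweep_interval <= 0:
        raise SimConfigError("sweep_interval: must be positive")

    rng = np.random.default_rng(config.seed)
    command, dvdt = _ramp_command_and_dvdt(config.sample_rate)
    sweeps = []
    for i in range(n_sweeps):
        t_sweep = i * sweep_interval
        g_k = config.katp_at(t_sweep)
        current = (
            config.leak_conductance * (command - config.leak_reversal)
            + g_k * (command - config.katp_reversal)
            + config.capacitance * dvdt * 1e-3  # pF·mV/s → pA needs 1e-3
        )
        if config.noise_sd > 0:
            current = current + rng.normal(0.0, config.noise_sd, command.size)
        sweeps.append(RampSweep(time_from_breakin=t_sweep,
                                command=command.copy(), current=current,
                                sample_rate=config.sample_rate))
    rec = RampRecording(sweeps=sweeps, sample_rate=config.sample_rate)
    truth = SyntheticTruth(conductance_fn=config.total_conductance_at,
                           params=config)
    return rec, truth


# --------------------------------------------------------------------------
# Current clamp (leaky integrate-and-fire)
# --------------------------------------------------------------------------

@dataclass
class SpikingSimConfig:
    """Leaky integrate-and-fire neuron under the 1-s current-pulse protocol.

    Membrane: ``C dV/dt = -g_L(V-E_L) - g_K(V-E_K) + I_hold + I_inj``.
    A spike fires when V reaches ``threshold``; V then resets after an
    absolute refractory period.  Spikes are rendered with a stereotyped
    waveform that crosses 0 mV so amplitude-based counters see them.
    The holding current is whatever keeps the cell at ``holding_target``.
    """

    capacitance: float = 35.0        # pF
    leak_conductance: float = 2.0    # nS
    resting: float = -70.0           # mV; leak reversal
    threshold: float = -50.0         # mV
    reset: float = -62.0             # mV
    refractory_ms: float = 35.0      # ms; lumped refractory + AHP recovery
    katp_leak: float = 0.0           # nS; added K_ATP-like leak
    katp_reversal: float = -90.0     # mV
    holding_target: float = -70.0    # mV
    pulse_amplitudes: Tuple[float, ...] = (50.0, 100.0, 150.0, 200.0)  # pA
    pulse_duration: float = 1.0      # s
    inter_pulse: float = 10.0        # s (protocol cadence; sweeps stored per pulse)
    pre_s: float = 0.1               # s of holding before the pulse
    post_s: float = 0.4              # s after the pulse
    noise_sd: float = 0.0            # pA
    sample_rate: float = 20000.0     # Hz
    spike_peak_mv: float = 30.0      # rendered spike peak
    seed: int = 0

    def validate(self) -> None:
        _require(self.capacitance > 0, "capacitance", "must be positive")
        _require(self.leak_conductance > 0, "leak_conductance",
                 "must be positive")
        _require(self.threshold > self.reset, "threshold",
                 "must exceed reset")
        _require(self.refractory_ms >= 0, "refractory_ms", "must be >= 0")
        _require(self.katp_leak >= 0, "katp_leak", "must be >= 0")
        _require(len(self.pulse_amplitudes) > 0, "pulse_amplitudes",
                 "must be non-empty")
        amps = np.asarray(self.pulse_amplitudes, dtype=float)
        _require(bool(np.all(np.diff(amps) > 0)) or amps.size == 1,
                 "pulse_amplitudes", "must be strictly increasing")
        _require(self.pulse_duration > 0, "pulse_duration", "must be positive")
        _require(self.inter_pulse > 0, "inter_pulse", "must be positive")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(self.sample_rate > 0, "sample_rate", "must be positive")

    @property
    def total_leak(self) -> float:
        return self.leak_conductance + self.katp_leak

    @property
    def holding_current(self) -> float:
        """pA required to hold the membrane at ``holding_target``."""
        return (self.leak_conductance * (self.holding_target - self.resting)
                + self.katp_leak * (self.holding_target - self.katp_reversal))


def lif_spike_times(config: SpikingSimConfig, amplitude: float) -> list:
    """Closed-form spike times of the noiseless LIF during one pulse.

    With constant drive the membrane relaxes exponentially toward
    ``V∞ = (g_L E_L + g_K E_K + I_hold + I) / g_tot`` with ``τ = C/g_tot``.
    If ``V∞ > threshold`` the crossing from a start voltage V0 occurs at
    ``τ · ln((V∞ − V0)/(V∞ − θ))``; after each spike the cycle restarts
    from ``reset`` once the refractory period elapses.  Times are seconds
    from pulse onset, within ``[0, pulse_duration)``.
    """
    g = config.total_leak
    tau = config.capacitance / g / 1000.0  # pF/nS = ms → s
    v_inf = (config.leak_conductance * config.resting
             + config.katp_leak * config.katp_reversal
             + config.holding_current + amplitude) / g
    if v_inf <= config.threshold:
        return []
    t_ref = config.refractory_ms / 1000.0
    times = []
    v0 = config.holding_target
    t = 0.0
    while True:
        t_cross = tau * math.log((v_inf - v0) / (v_inf - config.threshold))
        t = t + t_cross
        if t >= config.pulse_duration:
            break
        times.append(t)
        t += t_ref
        v0 = config.reset
        if t >= config.pulse_duration:
            break
    return times


def _render_spike(v: np.ndarray, idx: int, t_cross: float,
                  config: SpikingSimConfig) -> int:
    """Overwrite a stereotyped AP waveform for a spike at ``t_cross``.

    The peak sample is placed at ``floor(t_cross × rate)`` so the
    voltage's upward 0-mV crossing falls on the sample grid at (or within
    one sample before) the exact threshold-crossing time; amplitude- and
    slope-based counters therefore see the spike at its true time.  The
    downstroke relaxes to reset over 0.75 ms.  Returns the first sample
    index after the waveform.
    """
    sr = config.sample_rate
    ic = int(math.floor(t_cross * sr))
    if ic >= v.size:
        return v.size
    # samples between the last integrated one and the peak sit just
    # below threshold (sub-sample remainder of the upstroke)
    v[idx:ic] = config.threshold
    n_down = max(int(0.00075 * sr), 2)
    down = np.linspace(config.spike_peak_mv, config.reset, n_down + 1)
    stop = min(ic + down.size, v.size)
    v[ic:stop] = down[: stop - ic]
    return max(stop, ic + 1)


def generate_current_clamp(config: SpikingSimConfig) -> Tuple[CurrentClampRecording, SyntheticTruth]:
    """Simulate one voltage sweep per pulse amplitude.

    Integration is exact between samples for piecewise-constant drive
    (exponential update), and threshold-crossing times are solved in
    continuous time, so with ``noise_sd=0`` the recorded spike times equal
    the closed form of :func:`lif_spike_times`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sr = config.sample_rate
    dt = 1.0 / sr
    n_pre = round(config.pre_s * sr)
    n_pulse = round(config.pulse_duration * sr)
    n_post = round(config.post_s * sr)
    n = n_pre + n_pulse + n_post
    pulse_window = (n_pre / sr, (n_pre + n_pulse) / sr)

    g = config.total_leak
    tau = config.capacitance / g / 1000.0  # s
    e_eff = (config.leak_conductance * config.resting
             + config.katp_leak * config.katp_reversal
             + config.holding_current) / g
    t_ref = config.refractory_ms / 1000.0

    sweeps = []
    spike_times_by_amp = {}
    all_spikes = []
    for sweep_idx, amp in enumerate(config.pulse_amplitudes):
        v = np.empty(n)
        v_now = config.holding_target
        t_now = 0.0          # continuous integration clock
        i = 0
        spikes = []
        while i < n:
            t_sample = (i + 1) * dt
            in_pulse = pulse_window[0] <= i * dt < pulse_window[1]
            drive = amp if in_pulse else 0.0
            if config.noise_sd > 0:
                drive += rng.normal(0.0, config.noise_sd)
            v_inf = e_eff + drive / g
            # exact exponential relaxation from (t_now, v_now) to t_sample
            v_next = v_inf + (v_now - v_inf) * math.exp(-(t_sample - t_now) / tau)
            if v_next >= config.threshold and v_inf > config.threshold:
                # exact crossing time within this step
                t_cross = t_now + tau * math.log(
                    (v_inf - v_now) / (v_inf - config.threshold))
                spikes.append(t_cross)
                i = _render_spike(v, i, t_cross, config)
                t_now = t_cross + t_ref
                v_now = config.reset
                # hold at reset until the refractory period has elapsed
                while i < n and i * dt < t_now:
                    v[i] = config.reset
                    i += 1
                continue
            v[i] = v_next
            v_now = v_next
            t_now = t_sample
            i += 1
        sweeps.append((float(amp), v))
        pulse_spikes = [t - pulse_window[0] for t in spikes
                        if pulse_window[0] <= t < pulse_window[1]]
        spike_times_by_amp[float(amp)] = pulse_spikes
        # global protocol time: sweeps are inter_pulse seconds apart
        all_spikes.extend(t + sweep_idx * config.inter_pulse for t in spikes)

    rec = CurrentClampRecording(sweeps=sweeps, sample_rate=sr,
                                pulse_window=pulse_window,
                                holding_current=config.holding_current)
    truth = SyntheticTruth(spike_times=sorted(all_spikes),
                           spike_times_by_amplitude=spike_times_by_amp,
                           params=config)
    return rec, truth
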