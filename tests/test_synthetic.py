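"""Generator correctness: ground truth, determinism, and closed-form
oracles for the calcium, ramp and current-clamp simulators."""

import math

import numpy as np
import pytest

from slicephys import (
    CalciumSimConfig, MembraneSimConfig, SpikingSimConfig,
    generate_dff_trace, generate_ramp_recording, generate_current_clamp,
)
from slicephys.synthetic import SimConfigError, transient_kernel


def lif_count_oracle(cfg, amplitude):
    """Closed-form LIF spike count over one pulse, written independently
    of the package's own spike-time function.

    Between spikes the membrane relaxes exponentially toward
    V_inf = E_eff + I/g with time constant tau = C/g; the time to reach
    threshold from V0 is tau*ln((V_inf-V0)/(V_inf-theta)).
    """
    g = cfg.leak_conductance + cfg.katp_leak
    tau = cfg.capacitance / g * 1e-3
    i_hold = (cfg.leak_conductance * (cfg.holding_target - cfg.resting)
              + cfg.katp_leak * (cfg.holding_target - cfg.katp_reversal))
    v_inf = (cfg.leak_conductance * cfg.resting
             + cfg.katp_leak * cfg.katp_reversal
             + i_hold + amplitude) / g
    if v_inf <= cfg.threshold:
        return 0
    t_ref = cfg.refractory_ms * 1e-3
    t, v0, count = 0.0, cfg.holding_target, 0
    while True:
        t += tau * math.log((v_inf - v0) / (v_inf - cfg.threshold))
        if t >= cfg.pulse_duration:
            return count
        count += 1
        t += t_ref
        v0 = cfg.reset
        if t >= cfg.pulse_duration:
            return count


class TestCalciumGenerator:
    def test_no_events_when_rate_zero(self):
        cfg = CalciumSimConfig(sle_rate_profile=0.0, noise_sd=0.0,
                               drift_amplitude=0.0, bleach_amplitude=0.0,
                               seed=5)
        trace, truth = generate_dff_trace(cfg)
        assert truth.event_intervals == []
        assert np.allclose(trace.values, 0.0)
        assert trace.n_frames == round(cfg.duration * cfg.frame_rate)

    def test_forced_event_confined_by_kernel_decay(self):
        """In a clean trace a single forced event's fluorescence exceeds
        half the transient amplitude only inside the event padded by five
        decay time constants."""
        cfg = CalciumSimConfig(
            sle_rate_profile=0.0, noise_sd=0.0, drift_amplitude=0.0,
            bleach_amplitude=0.0, forced_events=((700.0, 710.0),), seed=0)
        trace, truth = generate_dff_trace(cfg)
        assert truth.event_intervals == [(700.0, 710.0)]
        t = trace.times
        hot = trace.values > 0.5 * cfg.peak_dff
        pad = 5 * cfg.transient_decay_tau
        outside = (t < 700.0) | (t >= 710.0 + pad)
        assert not hot[outside].any()
        assert hot[(t >= 700.0) & (t < 710.0)].any()

    def test_events_start_after_onset_plus_latency(self):
        cfg = CalciumSimConfig(seed=9)
        _, truth = generate_dff_trace(cfg)
        earliest = cfg.drug_onset + cfg.latency_to_first_sle
        assert truth.event_intervals, "default config should produce events"
        assert all(s >= earliest for s, _ in truth.event_intervals)

    @pytest.mark.parametrize("seed", [0, 1, 17])
    def test_truth_intervals_sorted_disjoint_in_range(self, seed):
        cfg = CalciumSimConfig(seed=seed)
        _, truth = generate_dff_trace(cfg)
        iv = truth.event_intervals
        assert all(s < e for s, e in iv)
        assert all(iv[i][1] <= iv[i + 1][0] for i in range(len(iv) - 1))
        assert all(0 <= s and e <= cfg.duration for s, e in iv)

    def test_determinism(self):
        cfg = CalciumSimConfig(seed=3)
        t1, truth1 = generate_dff_trace(cfg)
        t2, truth2 = generate_dff_trace(CalciumSimConfig(seed=3))
        np.testing.assert_array_equal(t1.values, t2.values)
        assert truth1.event_intervals == truth2.event_intervals

    def test_invalid_config_names_field(self):
        with pytest.raises(SimConfigError, match="frame_rate"):
            generate_dff_trace(CalciumSimConfig(frame_rate=0))
        with pytest.raises(SimConfigError, match="duration"):
            generate_dff_trace(CalciumSimConfig(duration=300.0,
                                                drug_onset=600.0))
        with pytest.raises(SimConfigError, match="noise_sd"):
            generate_dff_trace(CalciumSimConfig(noise_sd=-1.0))

    def test_kernel_peaks_at_one(self):
        t = np.linspace(0, 5, 20001)
        k = transient_kernel(t, 0.05, 0.4)
        assert k.max() == pytest.approx(1.0, abs=1e-6)
        assert k[0] == 0.0


class TestRampGenerator:
    def test_ohms_law_at_step(self):
        """Pure 1-nS resistor with 0 mV reversal: steady current at the
        −100 mV prepulse is −100 pA."""
        cfg = MembraneSimConfig(leak_conductance=1.0, leak_reversal=0.0,
                                katp_conductance_t0=0.0, katp_mode="constant",
                                noise_sd=0.0)
        rec, _ = generate_ramp_recording(cfg, n_sweeps=1)
        sw = rec.sweeps[0]
        at_100 = np.abs(sw.command - (-100.0)) < 1e-9
        # skip the step edge (capacitive transient), use late samples
        idx = np.flatnonzero(at_100)[-20:]
        np.testing.assert_allclose(sw.current[idx], -100.0, atol=1e-9)

    def test_washdown_truth_decay(self):
        cfg = MembraneSimConfig(katp_mode="washdown", katp_conductance_t0=3.0,
                                katp_tau=60.0)
        _, truth = generate_ramp_recording(cfg, n_sweeps=2)
        drop = truth.conductance_fn(0.0) - truth.conductance_fn(300.0)
        assert drop == pytest.approx(3.0 - 3.0 * math.exp(-5.0), rel=1e-12)
        assert drop >= 2.9

    def test_constant_mode_truth_flat(self):
        cfg = MembraneSimConfig(katp_mode="constant")
        rec, truth = generate_ramp_recording(cfg, n_sweeps=5)
        g = [truth.conductance_fn(t) for t in rec.sweep_times]
        assert len(set(g)) == 1

    def test_determinism(self):
        cfg = MembraneSimConfig(noise_sd=3.0, seed=11)
        r1, _ = generate_ramp_recording(cfg, n_sweeps=3)
        r2, _ = generate_ramp_recording(MembraneSimConfig(noise_sd=3.0, seed=11),
                                        n_sweeps=3)
        for a, b in zip(r1.sweeps, r2.sweeps):
            np.testing.assert_array_equal(a.current, b.current)

    def test_bad_sweep_interval(self):
        with pytest.raises(SimConfigError, match="sweep_interval"):
            generate_ramp_recording(MembraneSimConfig(), sweep_interval=0.0)


class TestCurrentClampGenerator:
    def test_zero_amplitude_stays_at_holding(self):
        cfg = SpikingSimConfig(pulse_amplitudes=(0.0,), noise_sd=0.0)
        rec, truth = generate_current_clamp(cfg)
        assert truth.spike_times == []
        amp, v = rec.sweeps[0]
        np.testing.assert_allclose(v, cfg.holding_target, atol=1e-9)

    @pytest.mark.parametrize("amplitude", [50.0, 100.0, 150.0, 200.0])
    def test_spike_count_matches_closed_form(self, amplitude):
        cfg = SpikingSimConfig(noise_sd=0.0)
        _, truth = generate_current_clamp(cfg)
        assert len(truth.spike_times_by_amplitude[amplitude]) == \
            lif_count_oracle(cfg, amplitude)

    def test_spike_times_match_closed_form_exactly(self):
        cfg = SpikingSimConfig(pulse_amplitudes=(150.0,), noise_sd=0.0)
        _, truth = generate_current_clamp(cfg)
        g = cfg.total_leak
        tau = cfg.capacitance / g * 1e-3
        v_inf = (cfg.leak_conductance * cfg.resting + cfg.holding_current
                 ) / g + 150.0 / g
        t_first = tau * math.log((v_inf - cfg.holding_target)
                                 / (v_inf - cfg.threshold))
        assert truth.spike_times_by_amplitude[150.0][0] == \
            pytest.approx(t_first, rel=1e-9)

    def test_spike_count_monotone_in_current_and_leak(self):
        base = SpikingSimConfig(noise_sd=0.0)
        _, truth0 = generate_current_clamp(base)
        counts0 = [len(truth0.spike_times_by_amplitude[a])
                   for a in base.pulse_amplitudes]
        assert counts0 == sorted(counts0), "non-decreasing in current"
        leaky = SpikingSimConfig(noise_sd=0.0, katp_leak=0.75)
        _, truth1 = generate_current_clamp(leaky)
        counts1 = [len(truth1.spike_times_by_amplitude[a])
                   for a in leaky.pulse_amplitudes]
        assert all(c1 <= c0 for c0, c1 in zip(counts0, counts1))

    def test_rendered_spikes_cross_zero(self):
        cfg = SpikingSimConfig(pulse_amplitudes=(150.0,), noise_sd=0.0)
        rec, truth = generate_current_clamp(cfg)
        _, v = rec.sweeps[0]
        upward = np.flatnonzero((v[1:] >= 0) & (v[:-1] < 0))
        assert upward.size == len(truth.spike_times_by_amplitude[150.0])

    def test_determinism_with_noise(self):
        a, _ = generate_current_clamp(SpikingSimConfig(noise_sd=10.0, seed=2))
        b, _ = generate_current_clamp(SpikingSimConfig(noise_sd=10.0, seed=2))
        for (_, va), (_, vb) in zip(a.sweeps, b.sweeps):
            np.testing.assert_array_equal(va, vb)

    def test_empty_amplitudes_rejected(self):
        with pytest.raises(SimConfigError, match="pulse_amplitudes"):
            generate_current_clamp(SpikingSimConfig(pulse_amplitudes=()))

    def test_global_spike_times_strictly_increasing(self):
        _, truth = generate_current_clamp(SpikingSimConfig(noise_sd=0.0))
        truth.validate()
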