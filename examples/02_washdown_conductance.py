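"""Voltage-ramp slope conductance and the K_ATP 'washdown' time course.

Simulates a whole-cell recording in which an initially open 3-nS
K_ATP-like conductance decays with a 60-s time constant after break-in
(high-ATP pipette solution), fits each ramp sweep with a line over
-120..-90 mV, and normalizes the conductance series to the sweep
nearest 3 min after break-in.
"""

import math

from slicephys import MembraneSimConfig, generate_ramp_recording, washdown_timecourse

cfg = MembraneSimConfig(leak_conductance=1.0, katp_conductance_t0=3.0,
                        katp_tau=60.0, katp_mode="washdown", noise_sd=2.0,
                        seed=4)
rec, truth = generate_ramp_recording(cfg, n_sweeps=30, sweep_interval=10.0)
tc = washdown_timecourse(rec)

closed_form_t0 = (1.0 + 3.0) / (1.0 + 3.0 * math.exp(-180.0 / 60.0))
print(f"sweeps: {len(rec.sweeps)}, anchor sweep at {tc.anchor_time:.0f} s")
print(f"conductance at t=0: {tc.conductance[0]:.2f} nS "
      f"(truth {truth.conductance_fn(0.0):.2f} nS)")
print(f"normalized at t=0: {tc.normalized[0]:.3f} "
      f"(noiseless closed form {closed_form_t0:.3f})")
print(f"normalized at anchor: {tc.normalized[tc.anchor_index]:.3f} (exact 1 "
      "by construction)")
print(f"input resistance, first/last sweep: "
      f"{tc.input_resistance[0]:.0f} / {tc.input_resistance[-1]:.0f} MOhm")
# Washdown: normalized conductance starts ~3.5x the 3-min value and decays
# toward 1 as the pipette ATP closes the K_ATP channels; input resistance
# rises correspondingly.
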