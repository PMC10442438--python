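"""Whole-cell intrinsic properties and short-term synaptic dynamics.

Simulates the standard slice-physiology protocols on a known RC cell and a
depressing synapse, and recovers the generating parameters.
"""

import numpy as np

import fiberphot as fp
from fiberphot.synth import RCCell, gen_ephys

cell = RCCell(rm_mohm=120.0, cm_pf=90.0, rs_mohm=12.0)
protocols = {
    "seal_test": gen_ephys("seal_test", cell, noise_sigma=2.0, seed=1),
    "iv_steps": gen_ephys("iv_steps", cell, noise_sigma=2.0, seed=2),
    "ramp": gen_ephys("ramp", cell, seed=3),
    "fi_steps": gen_ephys("fi_steps", cell, seed=4),
}
props = fp.intrinsic_properties(protocols)
print(f"Rm  = {props.membrane_resistance_mohm:6.1f} MOhm (truth 120)")
print(f"Cm  = {props.membrane_capacitance_pf:6.1f} pF   (truth 90)")
print(f"Rs  = {props.series_resistance_mohm:6.1f} MOhm (truth 12)")
print(f"Rin = {props.input_resistance_mohm:6.1f} MOhm (truth 120)")
print(f"rheobase = {props.rheobase_pa:.0f} pA, "
      f"spike threshold = {props.spike_threshold_mv:.1f} mV")
print(f"F-I curve: {props.fi_rates_hz[-1]:.1f} Hz at "
      f"{props.fi_currents_pa[-1]:.0f} pA")

# short-term depression: paired pulses and a 10-pulse train at 50 ms interval
pair = gen_ephys("opto_paired", amplitudes_pa=(100.0, 50.0), noise_sigma=1.0,
                 seed=5)
dyn = fp.paired_pulse_ratio(pair, pair.meta["pulse_times_s"])
print(f"\npaired-pulse ratio = {dyn.ppr:.2f} (commanded 0.50; "
      f"PPR < 1 = depression)")

train = gen_ephys("opto_train", noise_sigma=1.0, seed=6)  # 0.8^k amplitudes
tdyn = fp.train_dynamics(train, train.meta["pulse_times_s"])
print("train amplitudes normalized to pulse 1:")
print("  " + " ".join(f"{v:.2f}" for v in tdyn.normalized))
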