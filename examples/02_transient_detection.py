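"""Detect calcium transients with the two-pass sliding MAD threshold.

Generates a 15-minute session with a known 0.3 Hz transient train, runs the
full chain (normalize -> correct -> band-pass -> detect) and compares the
detected rate and amplitudes with the generating truth.
"""

import numpy as np

import fiberphot as fp

session, truth = fp.gen_photometry(duration=900, transient_rate=0.3,
                                   amp_mean=5.0, noise_sigma=0.05, seed=3)

dff470, dff405 = fp.normalize_session(session)
global_signal = fp.motion_correct(dff470, fp.fit_isosbestic(dff405, dff470))
filtered = fp.bandpass_filter(global_signal)            # 0.2-6 Hz, zero phase
transients = fp.detect_transients(filtered)             # 2-MAD two-pass rule

duration = len(global_signal) / global_signal.rate
true_in_window = np.sum(truth.transient_times > 60)

print(f"generated transients (after trim): {true_in_window}")
print(f"detected transients              : {len(transients)}")
print(f"detected frequency               : {len(transients) / duration:.3f} Hz"
      f"  (generating rate 0.300 Hz)")
print(f"mean peak amplitude              : "
      f"{transients.peak_amplitudes.mean():.2f} %dF/F")
print("-> frequency estimates phasic activity; counts exceed the generated")
print("   train slightly because the noise-adaptive threshold also reports")
print("   small noise excursions, and near-coincident events merge.")
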