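"""Normalize a two-channel photometry session and remove motion artifacts.

Generates a 5-minute synthetic session with photobleaching, a shared motion
artifact and noise, runs the dF/F + isosbestic-correction chain, and prints
how much of the artifact the correction removed.
"""

import numpy as np

import fiberphot as fp

# a session with three square motion-artifact pulses shared by both channels
pulses = [(80.0, 2.0, 4.0), (150.0, 1.0, 3.0), (220.0, 2.5, 5.0)]
session, truth = fp.gen_photometry(duration=300, transient_rate=0.3,
                                   artifact=pulses, noise_sigma=0.2, seed=11)

dff470, dff405 = fp.normalize_session(session)          # trim 60 s, 60 s window
fit = fp.fit_isosbestic(dff405, dff470)                 # OLS 405 -> 470
global_signal = fp.motion_correct(dff470, fit)          # the corrected dF/F

truth_dff = truth.clean_dff470()                        # artifact-free target
rmse_raw = np.sqrt(np.mean((dff470.values - truth_dff.values) ** 2))
rmse_corr = np.sqrt(np.mean((global_signal.values - truth_dff.values) ** 2))

print(f"isosbestic fit: slope={fit.slope:.3f}, intercept={fit.intercept:.3f}")
print(f"RMS error vs calcium truth, uncorrected : {rmse_raw:.3f} %dF/F")
print(f"RMS error vs calcium truth, corrected   : {rmse_corr:.3f} %dF/F")
print("-> the corrected global signal is closer to the artifact-free truth;")
print("   the slope rescales the isosbestic channel before subtraction.")
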