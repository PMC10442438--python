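"""Peri-event analysis around footshocks and lick-bout onsets.

Builds a session with a step increase in signal after each footshock,
groups a bursty lick train into bouts with the 10-s rule, and prints the
baseline-vs-response contrasts.
"""

import numpy as np

import fiberphot as fp
from fiberphot.behavior import detect_bouts
from fiberphot.photometry import DffTrace
from fiberphot.spatial import peri_event

# footshocks: one per minute, 1 s each
shocks = fp.gen_events("shock", n=5, start=90.0)

# a signal that jumps by +2 %dF/F for 3 s after each shock
rate = 20.0
t = np.arange(0, 420, 1 / rate)
values = np.random.default_rng(0).normal(0, 0.1, len(t))
for onset in shocks.times:
    values[(t >= onset) & (t < onset + 3.0)] += 2.0
signal = DffTrace(t=t, values=values, rate=rate)

pe = peri_event(signal, shocks, pre=5, post=5,
                baseline_window=(-5, -1), response_window=(0, 3))
print(f"peri-shock matrix: {pe.matrix.shape[0]} events x "
      f"{pe.matrix.shape[1]} samples ([-5, +5] s at 20 Hz)")
print(f"mean response - baseline contrast: {pe.mean_contrast:.2f} %dF/F "
      f"(construction: +2)")

# lick bouts: licks separated by >= 10 s start a new bout
licks = fp.gen_events("lick_sucrose", n_bouts=4, gap=15.0, jitter=False)
bouts = detect_bouts(licks, min_gap=10.0)
print(f"licks: {len(licks)}, bouts: {len(bouts)} "
      f"(counts per bout: {[int(c) for c in bouts.counts]})")
print("-> peri-event rows are aligned at the event onset; the contrast is")
print("   the response-window mean minus the baseline-window mean per event.")
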