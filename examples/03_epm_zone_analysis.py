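"""Zone analysis of a synchronized EPM session.

Generates a 15-minute elevated-plus-maze session whose transient rate is
higher in the open arms (0.5 Hz) than the closed arms (0.2 Hz), then
recovers per-zone signal means, transient frequencies and the differential
frequency, plus occupancy/signal maps and the open-arm positional profile.
"""

import numpy as np

import fiberphot as fp
from fiberphot.behavior import (MazeGeometry, TrackingTrace, ZoneLabels,
                                classify_direction, compute_velocity,
                                linearize_arm)
from fiberphot.spatial import build_maps, positional_profile, zone_summary

maze = MazeGeometry("EPM")
bundle = fp.gen_session(maze, duration=900,
                        zone_rates={"open": 0.5, "closed": 0.2, "center": 0.3},
                        photometry_kwargs={"noise_sigma": 0.05}, seed=7)

dff470, dff405 = fp.normalize_session(bundle["session"])
gs = fp.motion_correct(dff470, fp.fit_isosbestic(dff405, dff470))
transients = fp.detect_transients(fp.bandpass_filter(gs))

# align behavior with the trimmed signal
n_trim = len(bundle["track"]) - len(gs)
track = TrackingTrace(x=bundle["track"].x[n_trim:],
                      y=bundle["track"].y[n_trim:], rate=20.0, t0=gs.t[0])
zones = ZoneLabels(labels=bundle["zones"].labels[n_trim:], maze=maze,
                   rate=20.0, t0=gs.t[0])

summary = zone_summary(gs, zones, transients)
ts = summary.transient_stats
print("per-zone transient frequency (Hz):")
for z in ("open", "closed", "center"):
    print(f"  {z:7s} {ts.frequency_hz[z]:.3f}  (dwell {ts.dwell_s[z]:.0f} s)")
print(f"differential frequency (open - closed): {ts.differential_hz:.3f} Hz")
print("  -> generating rates were 0.5 / 0.2 Hz (true differential 0.3 Hz);")
print("     the contrast is compressed because noise-excursion detections")
print("     add a uniform rate to every zone and coincident events merge")

maps = build_maps(gs, track, extent=(0, 0, maze.size, maze.size))
print(f"occupancy map: {maps.n_frames} frames over "
      f"{np.count_nonzero(maps.occupancy)} visited 0.5 cm bins")

armpos = linearize_arm(track, maze)
direction = classify_direction(armpos, compute_velocity(track))
profile = positional_profile(gs, armpos, direction)
print(f"open-arm signal, beginning (0-10 cm): {profile.beginning_mean:.3f} %")
print(f"open-arm signal, end (25-35 cm)     : {profile.end_mean:.3f} %")
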