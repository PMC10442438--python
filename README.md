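# fiberphot

Analysis of in-vivo fiber-photometry recordings and the behavioral,
anatomical and slice-physiology measurements that accompany them in
anxiety/valence experiments — with a ground-truthed synthetic-data
generator so every stage can be validated end to end without any
recording.

## Who this is for

Labs recording bulk GCaMP fluorescence from a brain region (insular
cortex, amygdala, ...) while a mouse explores an elevated plus maze (EPM),
an open field (OFT) or a place-preference box, consumes sucrose/quinine, or
receives footshocks / tail lifts — and who additionally quantify axonal
projections in fluorescence images and characterize neurons in whole-cell
slice recordings.

## The core signal model

Two excitation wavelengths are sampled simultaneously at 20 Hz: 470 nm
(calcium-dependent GCaMP fluorescence) and 405 nm (the isosbestic point,
calcium-independent, carrying only motion and other non-neuronal
artifacts). The pipeline:

1. discards the first minute (LED stabilization);
2. normalizes each channel to ΔF/F (%) against a 60 s sliding-window mean,
   `ΔF/F = (F − F̄)/F̄ × 100`, which removes slow photobleaching;
3. fits the normalized 405 trace to the 470 trace by ordinary least squares
   and subtracts the fitted trace:
   `ΔF/F = ΔF/F₄₇₀ − ΔF/F_fitted405` — the **global signal**, a tonic
   activity estimate;
4. band-passes the global signal (0.2–6 Hz, zero-phase) and detects
   **calcium transients** with a two-pass sliding median/MAD rule: flag
   samples above `median + 2·MAD`, recompute median and MAD with flagged
   samples excluded, and report one transient (the local maximum) per
   excursion above the recomputed threshold — a phasic activity estimate.

Around this sit: zone assignment and occupancy-normalized signal maps on a
0.5 cm grid; linearized open-arm position (70 half-centimeter bins over
0–35 cm) with OUT/BACK direction segmentation gated at 3.75 mm/frame;
peri-event alignment (lick-bout onsets with the 10 s bout rule, footshocks,
tail lifts); one-tailed Pearson correlations across subjects; the place
preference index `PPI% = (T_stim − T_nonstim)/(T_stim + T_nonstim) × 100`;
pixel-fraction projection densities at fixed thresholds (0.5, or 0.04/0.06
for two-channel collateral mapping) normalized to a reference region; and
intrinsic/synaptic property extraction from seal-test, I–V, ramp, F–I and
paired/train stimulation sweeps.

## A worked example

`examples/03_epm_zone_analysis.py` generates a 15-minute EPM session whose
transient rate is 0.5 Hz in the open arms and 0.2 Hz in the closed arms,
then runs the full chain:

```
per-zone transient frequency (Hz):
  open    0.434  (dwell 240 s)
  closed  0.289  (dwell 450 s)
  center  0.331  (dwell 151 s)
differential frequency (open - closed): 0.145 Hz
  -> generating rates were 0.5 / 0.2 Hz (true differential 0.3 Hz);
     the contrast is compressed because noise-excursion detections
     add a uniform rate to every zone and coincident events merge
occupancy map: 16800 frames over 2145 visited 0.5 cm bins
open-arm signal, beginning (0-10 cm): 0.347 %
open-arm signal, end (25-35 cm)     : 0.488 %
```

The per-zone frequencies are transient counts divided by dwell time; the
differential frequency (open − closed) is the per-animal anxiety-related
readout; the beginning/end aggregates compare the signal at the start vs
the far end of the open arms. The other example scripts cover
preprocessing and motion correction (`01`), transient detection (`02`),
peri-event contrasts and lick bouts (`04`), cohort correlations and the
PPI (`05`), projection densities (`06`) and whole-cell properties (`07`);
each prints the numbers it computes and what they mean.

There is also a thin CLI (`fiberphot run|simulate|preprocess|transients|
cohort|quantify-image|ephys --help`) over the same library functions,
driven by a YAML config whose defaults are the protocol values above.

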