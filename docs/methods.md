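# Methods

This note documents the models implemented in `fiberphot`, the defaults
and their rationale, what the synthetic-data generator does and does not
emulate, and the numerical choices a user should know before trusting a
number.

## Photometry preprocessing

**ΔF/F normalization.** Each channel is normalized as
`(F − F̄)/F̄ × 100` with `F̄` the mean over a **centered** 60 s window,
truncated at the recording edges (no padding). A centered window avoids
the phase lag a trailing window would inject into peri-event analyses.
The window mean is computed per window by direct summation of deviations
from the first sample, which makes constant traces map to exactly 0 and
matches a per-sample loop to ~1e-13. The first 60 s of the recording are
discarded before normalization. Within a 60 s window, an exponential
bleach of time constant τ ≫ 60 s leaves a residual of order `(60/τ)²/24`
(~0.015% for τ = 1000 s) in the window interior; the first and last half
windows are one-sided and carry a first-order residual up to ~1.5%, so
edge-adjacent analyses should be treated with care.

**Isosbestic correction.** The normalized 405 trace is regressed onto the
normalized 470 trace by OLS over the whole trimmed recording and the
fitted trace subtracted. OLS on ΔF/F (rather than moment matching of the
raw traces) is the default because it minimizes the residual artifact
power under the affine-sharing assumption; when the artifact really is
affine across the two normalized channels and noise-free, the subtraction
is exact (the generator provides this construction for testing). With raw
additive artifacts the correction is approximate — the calcium signal
leaks into the regression — but it reliably reduces the RMS error against
the artifact-free truth (measured: 100/100 seeds at the default artifact
and noise levels).

**Band-pass.** A second-order Butterworth band-pass (0.2–6 Hz) applied
forward-backward (`sosfiltfilt`), i.e. zero-phase, so transient peak times
are not shifted. Measured gains: |H|² ≈ 1.0 at 1 Hz, ≤ 1e-5 at 0.01 Hz,
DC fully rejected.

**Transient detection.** Two passes over the band-passed global signal
with a sliding 60 s window (the ΔF/F window length is reused; the
protocol leaves the MAD window unspecified, so it is a configurable
assumption): pass 1 flags samples above `median + k·MAD` (k = 2); pass 2
recomputes the sliding median and MAD with flagged samples excluded and
thresholds at `median + k·MAD` of that peak-excluded trace. One transient
is reported per contiguous supra-threshold excursion, located at the
excursion maximum — the "local maxima" reading that avoids double
counting. A flat trace returns an empty set flagged `degenerate` rather
than raising. Sliding medians are computed exactly (NaN-padded strided
windows + `nanmedian`, verified sample-for-sample against an explicit
loop).

**Known limitation — the threshold is noise-adaptive.** Because the MAD
tracks whatever spread is present, the threshold sits ~2 robust SDs above
the local median *of the residual trace*. Under white measurement noise
this admits noise excursions at a nearly scale-free rate (~0.1–0.2 Hz at
our default conditions), regardless of how small the noise is relative to
the transients; conversely, near-coincident true events merge into one
excursion (~9% at 0.3 Hz). Consequences, measured on synthetic sessions
(amplitude 5% ΔF/F, 0.3 Hz, 900 s): detection F1 against the generating
train is ≈ 0.94 with zero noise (merging-limited), ≈ 0.88 at 0.05% ΔF/F
noise, ≈ 0.66 at the 0.2% default, and degrades steeply below peak SNR
~25. Zone-wise frequency estimates inherit a roughly time-uniform false
rate (~0.04 Hz at 0.05% noise) that inflates low-rate zones
proportionally more, plus a small boundary flux because the detected peak
lags the generating event by the kernel peak delay (~0.13 s). Frequency
*contrasts* between zones and their ordering are much more robust than
absolute rates (ordering recovered in 50/50 seeds at the 0.5 vs 0.2 Hz
conditions). Users comparing groups should compare like with like (same
noise floor, same settings) rather than read absolute frequencies as
event rates.

**Zone statistics.** A transient is assigned to the zone of the frame
nearest its peak time; `frequency = count / dwell time`. Zones with zero
dwell are reported NaN and flagged, never silently 0. The differential
frequency is open − closed (EPM) or center − border (OFT); the EPM center
platform is its own zone and never enters the contrast.

## Behavior

**Geometry.** EPM: 75 × 75 cm plus shape, 5 cm arm width, 5 × 5 cm center
platform, arm length (75 − 5)/2 = 35 cm; open arms run along x. OFT:
60 × 60 cm; the "center = 50% of the arena" is read as 50% of the *area*
(concentric square of side 60/√2 ≈ 42.4 cm) by default, with the
50%-of-linear-dimension reading (30 cm square) available as
`oft_center_mode="linear"` — the definition is ambiguous and the choice
is recorded in every output via the config hash. RTPP: two 30 × 60 cm
chambers. The edge shared by the center platform and an arm belongs to
the arm, so the arm-position origin (0 cm) is an arm frame.

**Calibration and dropouts.** Pixel coordinates map to cm by a per-axis
linear map (from arena corners). Missing frames are linearly interpolated
across gaps ≤ 0.5 s and kept missing beyond (standard tracking-dropout
handling); coordinates more than 1 cm outside the arena raise, smaller
excursions are clipped onto the maze.

**Velocity and direction.** Displacement is the per-frame Euclidean step
(mm/frame; 3.75 mm/frame at 20 Hz = 7.5 cm/s). Direction labeling keeps
only in-arm frames at or above the velocity gate; each retained frame is
labeled by the sign of the arm-axis change from the previous retained
frame (positive → OUT, negative → BACK), zero changes (pure transverse
movement) inherit the previous label, and the first frame of a run takes
the label of the move it starts. A velocity-passing extremum frame is
assigned to its incoming run, which is the one single-frame convention in
the otherwise exact time-reversal symmetry (reversing a trajectory swaps
OUT and BACK). Optional 5-frame median smoothing of position before
segmentation is off by default.

**Arm linearization.** In-arm frames project onto the arm's long axis,
distance measured from the center-platform edge (0) to the arm end (35),
binned half-open at 0.5 cm (70 bins; the 35 cm endpoint folds into bin
69). The transverse coordinate is discarded, so the projection is
invariant under reflection across the arm midline.

**Bouts and approaches.** Licks separated by ≥ 10 s start a new bout
(onset = first lick, offset = last). Port-approach onsets are an
operational definition of "movement initiation toward the port": the
first frame of a maximal strictly-decreasing run of distance-to-port that
starts outside the approach radius (5 cm default), ends inside it, and
begins at or above the speed floor (2 cm/s default); both parameters are
exposed because no standard definition exists.

## Spatial and statistical analysis

Occupancy, cumulative-signal and average maps share a 0.5 cm grid;
`average = cumulative / occupancy` exactly on visited bins and NaN
elsewhere (note a float `cum/occ·occ` round-trip is only ulp-exact, which
is why the identity is stated in division form). Positional profiles
average the signal per 0.5 cm bin; the beginning (0–10 cm) and end
(25–35 cm) aggregates weight bins equally, not by occupancy, matching the
per-bin-average-then-average-bins order. Peri-event rows cover
[−pre, +post] at the native 20 Hz grid; events without full coverage are
dropped and counted, never padded (padding would import the edge bias of
the truncated ΔF/F windows). Default windows — baseline [−5, −1] s,
response [0, +5] s — are assumptions (the protocol does not state
lengths) and are configurable per event type; per-event baseline
re-zeroing is off by default. Correlations are plain product-moment r
with a one-tailed p from the t transform; aggregation is always average
within subject first, correlate across subjects second. The PPI is
antisymmetric and bounded by construction. No multiple-comparison
correction is applied; each correlation is reported raw.

## Imaging quantification

Images are normalized by the max code value (255 for 8-bit, 65535 for
16-bit); stacks are max-intensity projected before scoring. Density is
the fraction of pixels **strictly** above the fixed threshold (ties
excluded; an inclusive mode exists), with 0.5 the default single-channel
threshold and 0.04 (red) / 0.06 (green) for two-channel collateral
scoring. Relative densities divide by the mean fraction of a reference
region (typically BLA), whose mean maps to exactly 1. Density at a fixed
threshold is *not* invariant to intensity rescaling — only to rescaling
threshold and image together — which the tests demonstrate rather than
hide. ROI cropping is the caller's responsibility; whole provided images
are scored.

## Electrophysiology

The seal-test transient is fit with `I(t) = A·exp(−t/τ) + I_ss` (SciPy
`curve_fit`, initialized from the 1/e crossing); for an RC membrane
behind a series resistance, `Rs = ΔV/I(0)`, `Rm = ΔV/I_ss − Rs`,
`Cm = τ·(Rs+Rm)/(Rs·Rm)`. Input resistance is the slope of the
steady-state I–V relation (last 20% of each step) over subthreshold
steps. Spike threshold uses a dV/dt ≥ 20 mV/ms criterion (configurable;
the measure is standard, the criterion value is a choice); rheobase is
the commanded ramp current at that sample, so it is quantized to one
ramp sample (0.03 pA at 10 kHz). PSC amplitudes are measured from a
local baseline (mean of the 5 ms before each pulse) to the extremum in a
40 ms post-pulse window — sized to the 50 ms inter-pulse interval — so a
response riding on the previous decay is still referenced locally
(recovers a commanded ratio of 0.5 within ~4% even with a 18 ms decay).
EPSCs are negative-going at −70 mV, IPSCs positive-going at 0 mV; both
are reported as magnitudes. Train outputs are always 10 amplitudes
normalized to pulse 1 (first entry exactly 1). Measured recovery on the
simulated grid (Rm 50–500 MΩ × Cm 20–200 pF, 2 pA noise): median
absolute relative error well under 1% for Rm, Cm and Rin.

## The synthetic-data generator

The generator is the package's validation instrument; its defaults define
the study conditions and every generated bundle carries its ground truth.

* **Photometry**: `F470 = bleach(t)·(B₄₇₀ + s(t)) + a(t) + ε`,
  `F405 = bleach(t)·B₄₀₅ + c·a(t) + ε'`, with `s` a Poisson train
  (0.3 Hz default) of double-exponential kernels (rise 50 ms, decay
  500 ms — a generic GCaMP6-like shape; the kernel peaks ~128 ms after
  the event time), gamma-distributed amplitudes (mean 5 a.u. on a 100
  a.u. baseline ≈ 5% ΔF/F, CV 0.3), single-exponential bleaching
  (τ = 1000 s), square-pulse artifacts shared across channels with scale
  c = 0.8, and white Gaussian noise (0.2 a.u. ≈ 0.2% ΔF/F — a realistic
  rig noise floor). A separate constructor builds ΔF/F-domain traces
  whose artifact is *exactly* affine across channels (orthogonalized
  against the calcium truth), the idealized case in which the isosbestic
  subtraction is provably exact.
* **Trajectories**: a semi-Markov chain over zones (exponential visit
  durations, embedded jump matrix; EPM arms connect only through the
  center) with a Gaussian-step random walk clipped inside the current
  zone. Defaults (EPM: open 5 s, closed 15 s, center 2 s mean visits)
  give ~21% open-arm time. The realized dwell fractions match the
  closed-form semi-Markov stationary law (tested against a brute-force
  chain simulation).
* **Zone-dependent transients**: an inhomogeneous Poisson process with
  per-frame rate `λ(zone)`, realized by per-frame Poisson counts.
* **Cohorts**: per-subject open-arm time drawn uniformly on 5–40%;
  true differential frequency = slope·pct + intercept + N(0, σ)
  (defaults slope −0.01 Hz/%, intercept 0.5 Hz, closed baseline
  0.25 Hz); `residual_sigma_for_r2` converts a target population R² into
  σ. Metric-level cohorts (no session simulation) drive the inference
  tests; full per-subject sessions are available.
* **Images**: exactly `round(f·n)` pixels receive 8-bit codes strictly
  above the threshold, the rest at or below — the true fraction is exact
  by construction.
* **Ephys**: seal-test and I–V responses are analytic RC solutions
  (I–V steps are generated series-resistance-compensated, so the I–V
  slope is Rm); ramp and F–I use an Euler-integrated
  leaky-integrate-and-fire cell with a stereotyped spike waveform
  injected at threshold; PSCs are difference-of-exponential kernels
  (rise 1 ms, decay 15 ms) with commanded per-pulse amplitudes.

**What the generator does not emulate** — hemodynamic or pH artifacts,
indicator nonlinearity and saturation, interleaved two-channel
acquisition, video tracking errors beyond dropouts, spike-shape
diversity, stochastic synaptic release. Passing tests therefore show that
the *pipeline math* recovers known ground truth under this model, not
that the model captures every property of real recordings; in particular
the transient-detector limitations quantified above are properties the
method would also exhibit on real data.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use 5–15 min sessions, 100
random traces/images for oracle-equality checks, 25–50 seeded sessions
for rate-recovery statistics, 1000 metric-level null cohorts for the
type-I check and 100 for power, and a 12-cell RC grid — sizes chosen so
the full validation runs on one CPU in a few minutes while keeping the
Monte-Carlo error well below the tolerances being tested.
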