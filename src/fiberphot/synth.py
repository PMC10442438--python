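"""Ground-truthed synthetic data for every pipeline stage.

This module is first-class, tested code: it generates two-channel
photometry sessions (Poisson transient trains convolved with a
fast-rise/exponential-decay calcium kernel, exponential photobleaching, a
motion artifact shared across the 405/470 channels with a channel scale
factor, Gaussian noise), maze-constrained random-walk trajectories with
zone-dependent transient rates, behavioral event schedules, cohorts whose
true differential transient frequency is a noisy linear function of time
in the open arms, binary-patterned test images with an exactly known
above-threshold pixel fraction, and RC-membrane / synaptic-current sweep
sets with known parameters.

Every generator takes a seed and is bit-for-bit reproducible; every
generator returns the ground truth alongside the observable so downstream
recovery can be tested without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .behavior import EventTrain, MazeGeometry, TrackingTrace, ZoneLabels
from .ephys import EphysSweepSet
from .errors import ParameterError
from .imaging import ImagePlane
from .photometry import DffTrace, PhotometrySession

__all__ = [
    "PhotometryTruth",
    "TrackingTruth",
    "CohortTruth",
    "RCCell",
    "calcium_kernel",
    "gen_photometry",
    "gen_shared_artifact_dff",
    "gen_tracking",
    "gen_session",
    "gen_events",
    "gen_cohort",
    "residual_sigma_for_r2",
    "gen_image",
    "gen_ephys",
]


# ---------------------------------------------------------------------------
# truth records
# ---------------------------------------------------------------------------

@dataclass
class PhotometryTruth:
    """Generating parameters of a synthetic photometry session."""

    transient_times: np.ndarray        # s, strictly increasing
    transient_amplitudes: np.ndarray   # a.u.
    kernel_rise: float                 # s
    kernel_decay: float                # s
    bleach_tau: float | None           # s, None = no bleaching
    artifact_trace: np.ndarray         # a.u. per sample (470 channel)
    artifact_scale_405: float
    noise_sigma: float                 # a.u.
    baseline470: float
    baseline405: float
    rate: float
    duration: float
    seed: int

    def __post_init__(self) -> None:
        t = np.asarray(self.transient_times, float)
        if len(t) and (np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] > self.duration):
            raise ParameterError("transient times must be strictly increasing "
                                 "and inside the session")
        if not self.kernel_decay > self.kernel_rise > 0:
            raise ParameterError("need kernel_decay > kernel_rise > 0")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")

    def clean_dff470(self, trim: float = 60.0, window: float = 60.0) -> DffTrace:
        """Pipeline dF/F of the artifact-free, noise-free 470 channel.

        This is the ground-truth calcium dF/F a perfect motion correction
        should recover.
        """
        from .photometry import normalize_session

        n = int(round(self.duration * self.rate))
        t = np.arange(n) / self.rate
        bleach = _bleach(t, self.bleach_tau)
        s = _transient_signal(t, self.transient_times,
                              self.transient_amplitudes,
                              self.kernel_rise, self.kernel_decay)
        clean = PhotometrySession(
            t=t, f470=bleach * (self.baseline470 + s),
            f405=bleach * self.baseline405, rate=self.rate)
        dff470, _ = normalize_session(clean, trim=trim, window=window)
        return dff470


@dataclass
class TrackingTruth:
    """Generating parameters (and realized zone path) of a trajectory."""

    dwell_means: dict                  # zone -> mean visit duration (s)
    transition: dict                   # zone -> {zone: prob}, rows normalized
    step_sigma: float                  # cm per frame
    zone_per_frame: np.ndarray         # realized zone of every frame
    zone_rates: dict = field(default_factory=dict)  # Hz per zone (if used)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.dwell_means.values()):
            raise ParameterError("dwell durations must be positive")
        for z, row in self.transition.items():
            s = sum(row.values())
            if not np.isclose(s, 1.0):
                raise ParameterError(f"transition row {z!r} does not sum to 1")
        if any(v < 0 for v in self.zone_rates.values()):
            raise ParameterError("zone rates must be >= 0")

    def stationary_time_fraction(self) -> dict:
        """Expected long-run dwell fraction per zone.

        Stationary distribution of the embedded jump chain weighted by the
        mean visit duration (semi-Markov stationary law).
        """
        zones = sorted(self.dwell_means)
        P = np.array([[self.transition[a].get(b, 0.0) for b in zones]
                      for a in zones])
        w, v = np.linalg.eig(P.T)
        pi = np.real(v[:, np.argmin(np.abs(w - 1))])
        pi = np.abs(pi) / np.abs(pi).sum()
        weight = pi * np.array([self.dwell_means[z] for z in zones])
        weight /= weight.sum()
        return dict(zip(zones, weight))


@dataclass
class CohortTruth:
    """Linear model tying differential transient frequency to open-arm time."""

    n_subjects: int
    generating_slope: float       # Hz per % time in open arms
    generating_intercept: float   # Hz
    residual_sigma: float         # Hz
    seed: int

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ParameterError("need at least 3 subjects")
        if self.residual_sigma < 0:
            raise ParameterError("residual_sigma must be >= 0")


# ---------------------------------------------------------------------------
# photometry
# ---------------------------------------------------------------------------

def _bleach(t: np.ndarray, tau: float | None) -> np.ndarray:
    if tau is None:
        return np.ones_like(t)
    if tau <= 0:
        raise ParameterError("bleach_tau must be positive")
    return np.exp(-t / tau)


def calcium_kernel(t: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Double-exponential calcium kernel normalized to unit peak.

    A generic GCaMP6-like impulse response: difference of exponentials with
    a fast rise and slower decay, zero for t < 0.
    """
    if not decay > rise > 0:
        raise ParameterError("need decay > rise > 0 (non-empty kernel support)")
    t = np.asarray(t, float)
    t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
    peak = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
    out = np.zeros_like(t)
    pos = t >= 0
    out[pos] = np.exp(-t[pos] / decay) - np.exp(-t[pos] / rise)
    return out / peak


def _transient_signal(t, times, amps, rise, decay) -> np.ndarray:
    s = np.zeros_like(t)
    if len(times) == 0:
        return s
    rate = 1.0 / (t[1] - t[0]) if len(t) > 1 else 1.0
    # kernel support long enough that the truncated tail is < 1e-14 of peak
    support = int(np.ceil(33 * decay * rate))
    ker_t = np.arange(support + 1) / rate
    for tk, ak in zip(times, amps):
        i0 = int(np.ceil((tk - t[0]) * rate))
        if i0 >= len(t):
            continue
        offs = t[i0:i0 + support + 1] - tk
        s[i0:i0 + len(offs)] += ak * calcium_kernel(offs, rise, decay)
    return s


def _artifact_trace(t, artifact, rate) -> np.ndarray:
    if artifact is None:
        return np.zeros_like(t)
    arr = np.asarray(artifact, dtype=object)
    if arr.ndim == 1 and len(arr) == len(t) and not isinstance(artifact[0], (tuple, list)):
        return np.asarray(artifact, float)
    out = np.zeros_like(t)
    for onset, dur, amp in artifact:  # square pulses
        out[(t >= onset) & (t < onset + dur)] += amp
    return out


def gen_photometry(
    duration: float = 900.0,
    rate: float = 20.0,
    *,
    transient_rate: float = 0.3,
    transient_times=None,
    amp_mean: float = 5.0,
    amp_cv: float = 0.3,
    kernel_rise: float = 0.05,
    kernel_decay: float = 0.5,
    baseline470: float = 100.0,
    baseline405: float = 50.0,
    bleach_tau: float | None = 1000.0,
    artifact=None,
    artifact_scale_405: float = 0.8,
    noise_sigma: float = 0.2,
    high_cutoff: float = 6.0,
    seed: int = 0,
) -> tuple[PhotometrySession, PhotometryTruth]:
    """Generate a two-channel photometry session with known ground truth.

    The calcium-dependent channel is
    ``F470 = bleach(t) * (baseline470 + s(t)) + artifact(t) + noise`` where
    ``s`` is the Poisson transient train convolved with the calcium kernel;
    the isosbestic channel carries no calcium:
    ``F405 = bleach(t) * baseline405 + artifact_scale_405 * artifact(t) + noise``.

    ``artifact`` is either a per-sample array or a list of
    ``(onset_s, duration_s, amplitude)`` square pulses. ``transient_times``
    overrides the homogeneous Poisson train (used by :func:`gen_session`
    for zone-dependent rates).
    """
    if duration <= 60.0:
        raise ParameterError("duration must exceed 60 s so the first-minute "
                             "trim leaves data")
    if rate <= 2 * high_cutoff:
        raise ParameterError("rate must exceed twice the detection high cutoff")
    if transient_rate < 0 or amp_mean <= 0:
        raise ParameterError("transient_rate must be >= 0 and amp_mean > 0")

    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate

    if transient_times is None:
        n_ev = rng.poisson(transient_rate * duration)
        times = np.sort(rng.uniform(0, duration, n_ev))
    else:
        times = np.asarray(transient_times, float)
    times = np.unique(times)
    if amp_cv > 0:
        shape = 1.0 / amp_cv**2
        amps = rng.gamma(shape, amp_mean / shape, len(times))
    else:
        amps = np.full(len(times), amp_mean)

    art = _artifact_trace(t, artifact, rate)
    bleach = _bleach(t, bleach_tau)
    s = _transient_signal(t, times, amps, kernel_rise, kernel_decay)
    noise470 = rng.normal(0, noise_sigma, n) if noise_sigma else np.zeros(n)
    noise405 = rng.normal(0, noise_sigma, n) if noise_sigma else np.zeros(n)

    f470 = bleach * (baseline470 + s) + art + noise470
    f405 = bleach * baseline405 + artifact_scale_405 * art + noise405
    session = PhotometrySession(t=t, f470=f470, f405=f405, rate=rate)
    truth = PhotometryTruth(
        transient_times=times, transient_amplitudes=amps,
        kernel_rise=kernel_rise, kernel_decay=kernel_decay,
        bleach_tau=bleach_tau, artifact_trace=art,
        artifact_scale_405=artifact_scale_405, noise_sigma=noise_sigma,
        baseline470=baseline470, baseline405=baseline405,
        rate=rate, duration=duration, seed=seed)
    return session, truth


def gen_shared_artifact_dff(
    n: int = 12000,
    rate: float = 20.0,
    slope: float = 1.25,
    intercept: float = 0.2,
    transient_rate: float = 0.3,
    amp_pct: float = 5.0,
    n_pulses: int = 8,
    pulse_amp_pct: float = 3.0,
    seed: int = 0,
) -> tuple[DffTrace, DffTrace, np.ndarray]:
    """Normalized traces with an *exactly* affine shared artifact.

    Builds a calcium dF/F truth ``d`` and an artifact trace ``a`` directly
    in the normalized (%) domain, then sets ``dff405 = a`` and
    ``dff470 = d + slope * a + intercept`` after orthogonalizing and
    centering ``d`` against ``a``. Under this construction the OLS
    isosbestic fit recovers (slope, intercept) exactly and the corrected
    global signal equals ``d`` to float precision — the idealized case the
    subtraction targets. Returns ``(dff470, dff405, d)``.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n) / rate
    # artifact: random square pulses
    a = np.zeros(n)
    for _ in range(n_pulses):
        onset = rng.uniform(0, t[-1] - 5)
        dur = rng.uniform(0.5, 3.0)
        a[(t >= onset) & (t < onset + dur)] += rng.normal(pulse_amp_pct,
                                                          pulse_amp_pct / 4)
    # calcium truth
    n_ev = rng.poisson(transient_rate * n / rate)
    times = np.sort(rng.uniform(0, t[-1], n_ev))
    d = _transient_signal(t, times, np.full(n_ev, amp_pct), 0.05, 0.5)
    # make the affine relation exact in-sample
    va = np.var(a)
    if va > 0:
        d = d - np.cov(d, a, bias=True)[0, 1] / va * (a - a.mean())
    d = d - d.mean()
    dff405 = DffTrace(t=t, values=a, rate=rate)
    dff470 = DffTrace(t=t, values=d + slope * a + intercept, rate=rate)
    return dff470, dff405, d


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------

def _default_dwell_model(maze: MazeGeometry) -> tuple[dict, dict]:
    if maze.kind == "EPM":
        dwell = {"open": 5.0, "closed": 15.0, "center": 2.0}
        trans = {"open": {"center": 1.0}, "closed": {"center": 1.0},
                 "center": {"open": 0.5, "closed": 0.5}}
    elif maze.kind == "OFT":
        dwell = {"center": 3.0, "border": 12.0}
        trans = {"center": {"border": 1.0}, "border": {"center": 1.0}}
    else:
        dwell = {"stim": 10.0, "nonstim": 10.0}
        trans = {"stim": {"nonstim": 1.0}, "nonstim": {"stim": 1.0}}
    return dwell, trans


def _zone_rects(maze: MazeGeometry, zone: str, rng) -> tuple:
    """(x0, x1, y0, y1) of a rectangle inside the zone (EPM picks one arm)."""
    s = maze.size
    if maze.kind == "EPM":
        lo, hi = maze._band
        if zone == "center":
            return lo, hi, lo, hi
        if zone == "open":  # arms along x
            return (hi, s, lo, hi) if rng.random() < 0.5 else (0.0, lo, lo, hi)
        return (lo, hi, hi, s) if rng.random() < 0.5 else (lo, hi, 0.0, lo)
    if maze.kind == "OFT":
        half = maze.oft_center_side / 2
        c = s / 2
        if zone == "center":
            return c - half, c + half, c - half, c + half
        return 0.0, s, 0.0, s  # border handled by push-out
    if zone == "stim":
        return (0.0, s / 2, 0.0, s) if maze.rtpp_stim_side == "left" \
            else (s / 2, s, 0.0, s)
    return (s / 2, s, 0.0, s) if maze.rtpp_stim_side == "left" \
        else (0.0, s / 2, 0.0, s)


def _oft_push_out(x, y, maze: MazeGeometry):
    """Move a point out of the OFT center square to its nearest edge."""
    half = maze.oft_center_side / 2
    c = maze.size / 2
    dx, dy = x - c, y - c
    if abs(dx) > half or abs(dy) > half:
        return x, y
    eps = 1e-6
    if abs(dx) >= abs(dy):
        x = c + np.sign(dx or 1.0) * (half + eps)
    else:
        y = c + np.sign(dy or 1.0) * (half + eps)
    return min(max(x, 0.0), maze.size), min(max(y, 0.0), maze.size)


def gen_tracking(
    maze: MazeGeometry,
    duration: float = 900.0,
    rate: float = 20.0,
    dwell_means: dict | None = None,
    transition: dict | None = None,
    step_sigma: float = 1.0,
    zone_rates: dict | None = None,
    seed: int = 0,
) -> tuple[TrackingTrace, TrackingTruth]:
    """Maze-constrained random walk with a semi-Markov zone dwell model.

    Zone visits alternate according to ``transition`` (embedded jump chain)
    with exponentially distributed visit durations of mean
    ``dwell_means[zone]``; within a visit the position performs a Gaussian
    random walk clipped to the zone. Every frame lies inside the maze.
    """
    if maze.size <= 0:
        raise ParameterError("zero-area maze")
    dw, tr = _default_dwell_model(maze)
    dwell_means = dwell_means or dw
    transition = transition or tr

    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    x = np.empty(n)
    y = np.empty(n)
    zone_pf = np.empty(n, dtype=object)

    zones = list(dwell_means)
    zone = zones[int(rng.integers(len(zones)))]
    rect = _zone_rects(maze, zone, rng)
    px = rng.uniform(rect[0], rect[1])
    py = rng.uniform(rect[2], rect[3])
    if maze.kind == "OFT" and zone == "border":
        px, py = _oft_push_out(px, py, maze)
    i = 0
    while i < n:
        visit = max(1, int(round(rng.exponential(dwell_means[zone]) * rate)))
        for _ in range(min(visit, n - i)):
            px = min(max(px + rng.normal(0, step_sigma), rect[0]), rect[1])
            py = min(max(py + rng.normal(0, step_sigma), rect[2]), rect[3])
            if maze.kind == "OFT" and zone == "border":
                px, py = _oft_push_out(px, py, maze)
            x[i], y[i], zone_pf[i] = px, py, zone
            i += 1
        # jump to the next zone; continue from the nearest point of its rect
        row = transition[zone]
        nxt = rng.choice(list(row), p=np.array(list(row.values())) / sum(row.values()))
        zone = str(nxt)
        rect = _zone_rects(maze, zone, rng)
        px = min(max(px, rect[0]), rect[1])
        py = min(max(py, rect[2]), rect[3])
        if maze.kind == "OFT" and zone == "border":
            px, py = _oft_push_out(px, py, maze)

    track = TrackingTrace(x=x, y=y, rate=rate)
    truth = TrackingTruth(dwell_means=dict(dwell_means),
                          transition={k: dict(v) for k, v in transition.items()},
                          step_sigma=step_sigma, zone_per_frame=zone_pf,
                          zone_rates=dict(zone_rates or {}), seed=seed)
    return track, truth


def gen_session(
    maze: MazeGeometry,
    duration: float = 900.0,
    rate: float = 20.0,
    zone_rates: dict | None = None,
    tracking_kwargs: dict | None = None,
    photometry_kwargs: dict | None = None,
    seed: int = 0,
) -> dict:
    """One synchronized photometry + tracking session with zone-dependent
    transient rates.

    Transients form an inhomogeneous Poisson process whose rate at each
    frame is ``zone_rates[zone-of-frame]``; the realized times are fed to
    :func:`gen_photometry`. Returns a bundle dict with keys ``session``,
    ``track``, ``photometry_truth``, ``tracking_truth``, ``zones`` (truth
    zone labels as a :class:`ZoneLabels`).
    """
    zone_rates = zone_rates or ({"open": 0.5, "closed": 0.2, "center": 0.3}
                                if maze.kind == "EPM"
                                else {z: 0.3 for z in maze.zone_names})
    rng = np.random.default_rng(seed)
    track, ttruth = gen_tracking(maze, duration, rate, seed=int(rng.integers(2**31)),
                                 zone_rates=zone_rates,
                                 **(tracking_kwargs or {}))
    lam = np.array([zone_rates[z] for z in ttruth.zone_per_frame])
    dt = 1.0 / rate
    counts = rng.poisson(lam * dt)
    times = np.concatenate([
        (i + rng.random(c)) * dt for i, c in enumerate(counts) if c
    ]) if counts.sum() else np.empty(0)
    session, ptruth = gen_photometry(
        duration, rate, transient_times=np.sort(times),
        seed=int(rng.integers(2**31)), **(photometry_kwargs or {}))
    zones = ZoneLabels(labels=ttruth.zone_per_frame, maze=maze, rate=rate)
    return {"session": session, "track": track, "zones": zones,
            "photometry_truth": ptruth, "tracking_truth": ttruth}


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

def gen_events(kind: str, seed: int = 0, **params) -> EventTrain:
    """Behavioral event schedules.

    * ``shock`` — n (default 10) footshock onsets, one per minute, 1 s each;
    * ``lift`` — tail-suspension epochs of 1 min separated by 1 min rest;
    * ``lick_sucrose`` / ``lick_quinine`` — bursty lick trains: ``n_bouts``
      bouts of ``licks_per_bout`` licks at ``within_ili`` s spacing, bouts
      separated by ``gap`` s (>= 10 s by construction when gap >= 10).
    """
    if kind == "shock":
        n = params.get("n", 10)
        period = params.get("period", 60.0)
        start = params.get("start", 60.0)
        return EventTrain(times=start + period * np.arange(n), label="shock",
                          meta={"duration_s": params.get("duration", 1.0)})
    if kind == "lift":
        n = params.get("n", 3)
        epoch = params.get("epoch", 60.0)
        period = params.get("period", 120.0)
        start = params.get("start", 60.0)
        if epoch > period:
            raise ParameterError("lift epochs overlap (epoch > period)")
        return EventTrain(times=start + period * np.arange(n), label="lift",
                          meta={"duration_s": epoch})
    if kind in ("lick_sucrose", "lick_quinine"):
        n_bouts = params.get("n_bouts", 17 if kind == "lick_sucrose" else 13)
        per_bout = params.get("licks_per_bout", 8)
        ili = params.get("within_ili", 0.15)
        gap = params.get("gap", 20.0)
        start = params.get("start", 30.0)
        rng = np.random.default_rng(seed)
        times = []
        t0 = start
        for _ in range(n_bouts):
            k = max(1, int(rng.poisson(per_bout))) if params.get("jitter", True) \
                else per_bout
            licks = t0 + np.arange(k) * ili
            times.append(licks)
            t0 = licks[-1] + gap
        return EventTrain(times=np.concatenate(times), label=kind)
    if kind == "empty":
        return EventTrain(times=np.empty(0), label="empty")
    raise ParameterError(f"unknown event kind {kind!r}")


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def residual_sigma_for_r2(
    slope: float, r2: float, open_pct_range: tuple = (5.0, 40.0)
) -> float:
    """Residual sigma giving an expected population R^2 for the cohort model.

    With open-arm time drawn uniformly on ``open_pct_range``, the signal
    variance is ``slope^2 * range^2 / 12``; solving R^2 = signal/(signal +
    noise) for the noise SD.
    """
    if not 0 < r2 <= 1:
        raise ParameterError("r2 must lie in (0, 1]")
    sd_x = (open_pct_range[1] - open_pct_range[0]) / np.sqrt(12.0)
    return abs(slope) * sd_x * np.sqrt((1 - r2) / r2)


def gen_cohort(
    n_subjects: int = 20,
    generating_slope: float = -0.01,
    generating_intercept: float = 0.5,
    residual_sigma: float = 0.0,
    open_pct_range: tuple = (5.0, 40.0),
    base_closed_rate: float = 0.25,
    simulate_sessions: bool = False,
    duration: float = 900.0,
    rate: float = 20.0,
    seed: int = 0,
    session_kwargs: dict | None = None,
) -> tuple[list[dict], CohortTruth]:
    """Cohort of subjects whose true differential transient frequency
    (open - closed) is linear in their open-arm time percentage, plus noise.

    Each subject draws ``open_time_pct`` uniformly, gets
    ``true_differential = slope * pct + intercept + N(0, residual_sigma)``,
    and zone rates ``closed = base_closed_rate``,
    ``open = closed + differential`` (clipped at 0, clipping recorded).
    With ``simulate_sessions=True`` a full EPM session bundle is generated
    per subject via :func:`gen_session`.
    """
    truth = CohortTruth(n_subjects=n_subjects, generating_slope=generating_slope,
                        generating_intercept=generating_intercept,
                        residual_sigma=residual_sigma, seed=seed)
    rng = np.random.default_rng(seed)
    subjects = []
    maze = MazeGeometry("EPM")
    for i in range(n_subjects):
        pct = rng.uniform(*open_pct_range)
        diff = generating_slope * pct + generating_intercept
        if residual_sigma > 0:
            diff += rng.normal(0, residual_sigma)
        open_rate = base_closed_rate + diff
        clipped = open_rate < 0
        open_rate = max(open_rate, 0.0)
        rec = {"subject": i, "open_time_pct": pct,
               "true_differential_hz": diff if not clipped
               else open_rate - base_closed_rate,
               "open_rate_hz": open_rate, "closed_rate_hz": base_closed_rate,
               "rate_clipped": clipped}
        if simulate_sessions:
            # steer the dwell model toward the drawn open-arm percentage
            open_frac = pct / 100.0
            closed_frac = max(1.0 - open_frac - 0.15, 0.05)
            dwell = {"center": 2.0,
                     "open": 4.0 * open_frac / 0.15,
                     "closed": 4.0 * closed_frac / 0.15}
            rec["bundle"] = gen_session(
                maze, duration, rate,
                zone_rates={"open": open_rate, "closed": base_closed_rate,
                            "center": base_closed_rate},
                tracking_kwargs={"dwell_means": dwell},
                seed=int(rng.integers(2**31)),
                **(session_kwargs or {}))
        subjects.append(rec)
    return subjects, truth


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def gen_image(
    shape: tuple = (100, 100),
    target_fraction: float = 0.25,
    threshold: float = 0.5,
    seed: int = 0,
) -> tuple[ImagePlane, float]:
    """8-bit test image with an exactly known above-threshold pixel fraction.

    Exactly ``round(target_fraction * n_pixels)`` pixels receive 8-bit codes
    strictly above the threshold after /255 normalization; the rest stay at
    or below it. Returns the normalized image and the exact true fraction.
    """
    if not 0 <= target_fraction <= 1:
        raise ParameterError("target_fraction must lie in [0, 1]")
    if not 0 <= threshold <= 1:
        raise ParameterError("threshold must lie in [0, 1]")
    n = int(np.prod(shape))
    k = int(round(target_fraction * n))
    hi_code = int(np.floor(threshold * 255)) + 1
    lo_code = int(np.floor(threshold * 255))
    if k > 0 and hi_code > 255:
        raise ParameterError("threshold too high for an 8-bit code above it")
    rng = np.random.default_rng(seed)
    flat = np.empty(n, dtype=np.uint8)
    flat[:k] = rng.integers(hi_code, 256, k, dtype=np.uint8, endpoint=False) \
        if hi_code < 255 else 255
    flat[k:] = rng.integers(0, lo_code + 1, n - k, dtype=np.uint8,
                            endpoint=False) if lo_code > 0 else 0
    rng.shuffle(flat)
    return ImagePlane.from_array(flat.reshape(shape)), k / n


# ---------------------------------------------------------------------------
# electrophysiology
# ---------------------------------------------------------------------------

@dataclass
class RCCell:
    """Single-compartment RC membrane accessed through a series resistance."""

    rm_mohm: float = 100.0
    cm_pf: float = 100.0
    rs_mohm: float = 10.0
    e_rest_mv: float = -70.0
    v_thresh_mv: float = -45.0
    v_reset_mv: float = -60.0
    refractory_s: float = 0.004

    def __post_init__(self) -> None:
        if self.rm_mohm <= 0 or self.cm_pf <= 0 or self.rs_mohm <= 0:
            raise ParameterError("Rm, Cm and Rs must be positive")


def _psc_kernel(t, rise=0.001, decay=0.015):
    k = np.where(t >= 0, np.exp(-t / decay) - np.exp(-t / rise), 0.0)
    t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
    return k / (np.exp(-t_peak / decay) - np.exp(-t_peak / rise))


def gen_ephys(
    protocol: str,
    cell: RCCell | None = None,
    rate: float = 10000.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    **params,
) -> EphysSweepSet:
    """Synthetic whole-cell sweeps for one protocol with known parameters.

    Protocols: ``seal_test`` (5 mV / 1 s voltage step), ``iv_steps``
    (-140..-80 mV, 10 mV step), ``ramp`` (0-300 pA / 1 s), ``fi_steps``
    (0-300 pA / 2 s, 20 pA step) on a leaky-integrate-and-fire version of
    the cell, and ``opto_paired`` / ``opto_train`` postsynaptic-current
    sweeps with commanded per-pulse amplitudes (2 ms pulses, 50 ms apart).
    Generating parameters are recorded under ``meta['truth']``.
    """
    cell = cell or RCCell()
    rng = np.random.default_rng(seed)
    rm = cell.rm_mohm * 1e6
    rs = cell.rs_mohm * 1e6
    cm = cell.cm_pf * 1e-12

    if protocol == "seal_test":
        dv = params.get("step_mv", 5.0) * 1e-3
        onset, dur, total = 0.1, params.get("duration_s", 1.0), None
        total = onset + dur + 0.1
        t = np.arange(int(round(total * rate))) / rate
        tau = cm * rs * rm / (rs + rm)
        i_ss = dv / (rs + rm)
        i_peak = dv / rs
        i = np.zeros_like(t)
        on = t >= onset
        i[on] = (i_peak - i_ss) * np.exp(-(t[on] - onset) / tau) + i_ss
        off = t >= onset + dur
        i[off] = -((i_peak - i_ss) * np.exp(-(t[off] - onset - dur) / tau))
        i_pa = i * 1e12 + (rng.normal(0, noise_sigma, len(t)) if noise_sigma else 0)
        return EphysSweepSet(
            time=t, response=i_pa, protocol="seal_test", rate=rate,
            meta={"step_mv": dv * 1e3, "step_onset_s": onset,
                  "step_duration_s": dur,
                  "truth": {"rm_mohm": cell.rm_mohm, "rs_mohm": cell.rs_mohm,
                            "cm_pf": cell.cm_pf, "tau_s": tau}})

    if protocol == "iv_steps":
        steps = np.asarray(params.get("step_values_mv",
                                      np.arange(-140.0, -70.0, 10.0)))
        onset, dur = 0.1, params.get("duration_s", 1.0)
        t = np.arange(int(round((onset + dur + 0.1) * rate))) / rate
        tau = cm * rs * rm / (rs + rm)
        sweeps = []
        for v in steps:
            dv = (v - cell.e_rest_mv) * 1e-3
            i_ss = dv / rm          # series resistance compensated
            i_tr = dv / rs
            i = np.zeros_like(t)
            on = t >= onset
            i[on] = (i_tr - i_ss) * np.exp(-(t[on] - onset) / tau) + i_ss
            i[t >= onset + dur] = 0.0
            sweeps.append(i * 1e12 + (rng.normal(0, noise_sigma, len(t))
                                      if noise_sigma else 0))
        return EphysSweepSet(
            time=t, response=np.array(sweeps), protocol="iv_steps", rate=rate,
            meta={"step_values_mv": steps, "step_onset_s": onset,
                  "step_duration_s": dur,
                  "truth": {"rin_mohm": cell.rm_mohm}})

    if protocol in ("ramp", "fi_steps"):
        return _gen_current_clamp(protocol, cell, rate, noise_sigma, rng, params)

    if protocol in ("opto_paired", "opto_train"):
        n_pulses = 2 if protocol == "opto_paired" else 10
        default = ((100.0, 50.0) if n_pulses == 2
                   else tuple(100.0 * 0.8**k for k in range(10)))
        amps = np.asarray(params.get("amplitudes_pa", default), float)
        if len(amps) != n_pulses:
            raise ParameterError(f"{protocol} needs {n_pulses} amplitudes")
        interval = params.get("interval_s", 0.05)
        start = params.get("start_s", 0.1)
        pulses = start + interval * np.arange(n_pulses)
        total = pulses[-1] + 0.2
        t = np.arange(int(round(total * rate))) / rate
        sign = -1 if params.get("psc_kind", "EPSC").upper() == "EPSC" else +1
        rise = params.get("psc_rise_s", 0.001)
        decay = params.get("psc_decay_s", 0.015)
        resp = np.zeros_like(t)
        for tp, a in zip(pulses, amps):
            resp += sign * a * _psc_kernel(t - tp, rise, decay)
        resp += params.get("holding_pa", 0.0)
        if noise_sigma:
            resp += rng.normal(0, noise_sigma, len(t))
        return EphysSweepSet(
            time=t, response=resp, protocol=protocol, rate=rate,
            meta={"pulse_times_s": pulses, "psc_kind": params.get("psc_kind", "EPSC"),
                  "truth": {"amplitudes_pa": amps, "psc_rise_s": rise,
                            "psc_decay_s": decay}})

    raise ParameterError(f"unknown protocol {protocol!r}")


def _gen_current_clamp(protocol, cell: RCCell, rate, noise_sigma, rng, params):
    """Euler-integrated leaky-integrate-and-fire responses with a stereotyped
    action-potential waveform injected at threshold crossings."""
    rm = cell.rm_mohm * 1e6
    cm = cell.cm_pf * 1e-12
    e = cell.e_rest_mv * 1e-3
    vth = cell.v_thresh_mv * 1e-3
    vreset = cell.v_reset_mv * 1e-3
    dt = 1.0 / rate
    # AP shape: 0.5 ms rise to +30 mV, 1.5 ms fall to reset
    n_rise = max(int(round(0.0005 * rate)), 1)
    n_fall = max(int(round(0.0015 * rate)), 1)

    if protocol == "ramp":
        onset, dur = 0.1, params.get("duration_s", 1.0)
        i_max = params.get("max_pa", 300.0) * 1e-12
        n = int(round((onset + dur + 0.1) * rate))
        t = np.arange(n) / rate
        cmd = np.zeros(n)
        on = (t >= onset) & (t < onset + dur)
        cmd[on] = i_max * (t[on] - onset) / dur
        sweeps_cmd = [cmd]
    else:
        steps = np.asarray(params.get("step_values_pa",
                                      np.arange(0.0, 320.0, 20.0)))
        onset, dur = 0.1, params.get("duration_s", 2.0)
        n = int(round((onset + dur + 0.1) * rate))
        t = np.arange(n) / rate
        sweeps_cmd = []
        for s in steps:
            cmd = np.zeros(n)
            cmd[(t >= onset) & (t < onset + dur)] = s * 1e-12
            sweeps_cmd.append(cmd)

    sweeps = []
    truth_rheo = np.nan
    truth_counts = []
    for cmd in sweeps_cmd:
        v = np.empty(n)
        v[0] = e
        spikes = 0
        first_cross = None
        i = 1
        while i < n:
            dv = ((e - v[i - 1]) / rm + cmd[i - 1]) / cm * dt
            v[i] = v[i - 1] + dv
            if v[i] >= vth:
                if first_cross is None:
                    first_cross = i
                spikes += 1
                peak = 0.03
                rise = np.linspace(v[i], peak, n_rise + 1)[1:]
                fall = np.linspace(peak, vreset, n_fall + 1)[1:]
                wave = np.r_[rise, fall]
                j = min(i + len(wave), n)
                v[i:j] = wave[:j - i]
                i = j
                # refractory hold at reset
                k = min(i + int(round(cell.refractory_s * rate)), n)
                v[i:k] = vreset
                i = k
                if i < n:
                    v[i - 1] = vreset
                continue
            i += 1
        truth_counts.append(spikes)
        if protocol == "ramp" and first_cross is not None and np.isnan(truth_rheo):
            truth_rheo = cmd[first_cross] * 1e12
        v_mv = v * 1e3
        if noise_sigma:
            v_mv = v_mv + rng.normal(0, noise_sigma, n)
        sweeps.append(v_mv)

    if protocol == "ramp":
        meta = {"command_pa": sweeps_cmd[0] * 1e12, "step_onset_s": onset,
                "step_duration_s": dur,
                "truth": {"rheobase_pa": truth_rheo,
                          "v_thresh_mv": cell.v_thresh_mv}}
        return EphysSweepSet(time=t, response=sweeps[0], protocol="ramp",
                             rate=rate, meta=meta)
    meta = {"step_values_pa": steps, "step_onset_s": onset,
            "step_duration_s": dur, "spike_detect_mv": 0.0,
            "truth": {"spike_counts": np.asarray(truth_counts)}}
    return EphysSweepSet(time=t, response=np.array(sweeps),
                         protocol="fi_steps", rate=rate, meta=meta)
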