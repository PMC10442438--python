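"""Spatial maps, zone/positional summaries, peri-event analysis and cohort
correlations for synchronized photometry + tracking sessions.

The occupancy map counts frames per 0.5 cm spatial bin; the cumulative map
sums the global signal per bin; the average map is their ratio. Zone
summaries average the global signal over the frames spent in each zone, the
positional profile averages it per 0.5 cm arm bin (with beginning 0-10 cm
and end 25-35 cm aggregates), and peri-event analysis aligns signal windows
on discrete events (lick-bout onsets, footshocks, tail lifts). Cohort-level
inference uses one-tailed Pearson correlations of per-subject metrics, and
closed-loop place-preference sessions are scored with

    PPI% = (T_stim - T_nonstim) / (T_stim + T_nonstim) * 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .behavior import ArmPositionSeries, DirectionSegments, EventTrain, TrackingTrace, ZoneLabels
from .errors import AlignmentError, DataError, DegenerateFitError, ParameterError
from .photometry import DffTrace, TransientSet, ZoneTransientStats, transient_zone_stats

__all__ = [
    "SpatialMaps",
    "ZoneSummary",
    "PositionalProfile",
    "PeriEventResult",
    "CorrelationResult",
    "PlacePreferenceResult",
    "CohortResult",
    "build_maps",
    "zone_summary",
    "positional_profile",
    "peri_event",
    "pearson_one_tailed",
    "place_preference_index",
    "cohort_analysis",
]


@dataclass
class SpatialMaps:
    """Occupancy / cumulative-signal / average-signal maps on a cm grid.

    ``average`` is NaN on bins that were never visited; on visited bins
    ``average * occupancy == cumulative`` exactly.
    """

    occupancy: np.ndarray     # frames per bin
    cumulative: np.ndarray    # summed dF/F (%) per bin
    average: np.ndarray       # % per bin, NaN where occupancy == 0
    bin_size: float
    extent: tuple             # (x0, y0, x1, y1) in cm
    n_frames: int


@dataclass
class ZoneSummary:
    """Per-zone mean global signal plus transient statistics."""

    mean_signal_pct: dict
    transient_stats: ZoneTransientStats | None
    differential_signal_pct: float
    undefined_zones: tuple = ()


@dataclass
class PositionalProfile:
    """Mean global signal per 0.5 cm arm bin with beginning/end aggregates."""

    bin_means: np.ndarray
    bin_counts: np.ndarray
    bin_width: float
    beginning_mean: float     # bins covering [0, 10) cm
    end_mean: float           # bins covering [25, 35] cm
    restricted_to: str | None = None
    undefined: bool = False


@dataclass
class PeriEventResult:
    """Event-aligned signal matrix and baseline/response contrasts."""

    matrix: np.ndarray        # n_events x n_samples
    rel_time: np.ndarray      # seconds, 0 at event onset
    event_times: np.ndarray
    baselines: np.ndarray
    responses: np.ndarray
    contrasts: np.ndarray     # response - baseline per event
    mean_contrast: float
    n_dropped: int
    baseline_window: tuple
    response_window: tuple


@dataclass
class CorrelationResult:
    """One-tailed Pearson correlation between per-subject metrics."""

    r: float
    r2: float
    p: float
    n: int
    tail: str


@dataclass
class PlacePreferenceResult:
    t_stim_s: float
    t_nonstim_s: float
    ppi_pct: float


@dataclass
class CohortResult:
    table: pd.DataFrame
    correlations: dict = field(default_factory=dict)
    n_dropped: int = 0


# ---------------------------------------------------------------------------

def build_maps(
    global_signal: DffTrace,
    track: TrackingTrace,
    bin_size: float = 0.5,
    extent: tuple | None = None,
) -> SpatialMaps:
    """Accumulate occupancy and signal maps frame by frame.

    Frames with missing coordinates are skipped (and not counted in
    ``n_frames``). ``extent`` defaults to the track's bounding box snapped
    to the bin grid.
    """
    if bin_size <= 0:
        raise ParameterError("bin_size must be positive")
    if len(global_signal) != len(track):
        raise AlignmentError("signal and track must be frame-aligned")
    ok = np.isfinite(track.x) & np.isfinite(track.y) & np.isfinite(global_signal.values)
    x, y, v = track.x[ok], track.y[ok], global_signal.values[ok]
    if extent is None:
        x0 = np.floor(x.min() / bin_size) * bin_size if len(x) else 0.0
        y0 = np.floor(y.min() / bin_size) * bin_size if len(y) else 0.0
        x1 = x.max() if len(x) else bin_size
        y1 = y.max() if len(y) else bin_size
        extent = (x0, y0, x1, y1)
    x0, y0, x1, y1 = extent
    nx = max(int(np.ceil((x1 - x0) / bin_size)), 1)
    ny = max(int(np.ceil((y1 - y0) / bin_size)), 1)
    ix = np.clip(np.floor((x - x0) / bin_size).astype(int), 0, nx - 1)
    iy = np.clip(np.floor((y - y0) / bin_size).astype(int), 0, ny - 1)

    occ = np.zeros((ny, nx))
    cum = np.zeros((ny, nx))
    np.add.at(occ, (iy, ix), 1.0)
    np.add.at(cum, (iy, ix), v)
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = np.where(occ > 0, cum / occ, np.nan)
    return SpatialMaps(occupancy=occ, cumulative=cum, average=avg,
                       bin_size=bin_size, extent=(x0, y0, x0 + nx * bin_size,
                                                  y0 + ny * bin_size),
                       n_frames=int(ok.sum()))


def zone_summary(
    global_signal: DffTrace,
    zones: ZoneLabels,
    transients: TransientSet | None = None,
) -> ZoneSummary:
    """Average the global signal per zone and attach transient statistics.

    The differential signal is anxiogenic minus safe zone (open - closed on
    the EPM, center - border in the OFT); the EPM center platform is its own
    zone and never enters that contrast.
    """
    if len(global_signal) != len(zones):
        raise AlignmentError("signal and zone labels must be frame-aligned")
    labels = zones.labels
    means: dict = {}
    undefined = []
    for z in zones.zone_names:
        sel = labels == z
        if not sel.any():
            means[z] = np.nan
            undefined.append(z)
        else:
            means[z] = float(np.mean(global_signal.values[sel]))
    a, b = zones.contrast_pair
    diff = means.get(a, np.nan) - means.get(b, np.nan)
    tstats = transient_zone_stats(transients, zones) if transients is not None else None
    return ZoneSummary(mean_signal_pct=means, transient_stats=tstats,
                       differential_signal_pct=float(diff),
                       undefined_zones=tuple(undefined))


def positional_profile(
    global_signal: DffTrace,
    armpos: ArmPositionSeries,
    direction: DirectionSegments | None = None,
    restrict: str | None = None,
    arms: str = "open",
    beginning_cm: tuple = (0.0, 10.0),
    end_cm: tuple = (25.0, 35.0),
) -> PositionalProfile:
    """Mean global signal per 0.5 cm arm bin, with positional aggregates.

    ``arms`` selects which arms contribute (``"open"``, ``"closed"`` or
    ``"all"``); ``restrict`` optionally keeps only OUT or BACK frames.
    Aggregates are unweighted means over the bins inside ``[0, 10)`` cm
    (beginning) and ``[25, 35]`` cm (end). An empty restriction yields NaN
    aggregates flagged ``undefined``.
    """
    if len(global_signal) != len(armpos):
        raise AlignmentError("signal and arm positions must be frame-aligned")
    sel = armpos.bin_index >= 0
    if arms != "all":
        in_arm = np.array([a is not None and a.startswith(arms)
                           for a in armpos.arm])
        sel &= in_arm
    if restrict is not None:
        if direction is None:
            raise ParameterError("restrict requires direction segments")
        sel &= direction.labels == restrict

    nb = armpos.n_bins
    sums = np.zeros(nb)
    counts = np.zeros(nb)
    np.add.at(sums, armpos.bin_index[sel], global_signal.values[sel])
    np.add.at(counts, armpos.bin_index[sel], 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / counts, np.nan)

    centers = (np.arange(nb) + 0.5) * armpos.bin_width
    beg_sel = (centers >= beginning_cm[0]) & (centers < beginning_cm[1]) & (counts > 0)
    end_sel = (centers >= end_cm[0]) & (centers <= end_cm[1]) & (counts > 0)
    beg = float(np.mean(means[beg_sel])) if beg_sel.any() else np.nan
    end = float(np.mean(means[end_sel])) if end_sel.any() else np.nan
    return PositionalProfile(bin_means=means, bin_counts=counts,
                             bin_width=armpos.bin_width,
                             beginning_mean=beg, end_mean=end,
                             restricted_to=restrict,
                             undefined=not sel.any())


def peri_event(
    global_signal: DffTrace,
    events: EventTrain,
    pre: float = 5.0,
    post: float = 5.0,
    baseline_window: tuple = (-5.0, -1.0),
    response_window: tuple = (0.0, 5.0),
) -> PeriEventResult:
    """Align signal windows on event onsets and contrast response vs baseline.

    Each retained event contributes one row covering ``[-pre, +post]`` s on
    the native sampling grid; events without full coverage are dropped and
    counted. The per-event contrast is mean(response window) minus
    mean(baseline window).
    """
    if pre < 0 or post < 0:
        raise ParameterError("pre and post must be non-negative")
    rate = global_signal.rate
    npre = int(round(pre * rate))
    npost = int(round(post * rate))
    t0 = global_signal.t[0]
    n = len(global_signal)

    rows, kept = [], []
    dropped = 0
    for te in events.times:
        i = int(round((te - t0) * rate))
        if i - npre < 0 or i + npost >= n:
            dropped += 1
            continue
        rows.append(global_signal.values[i - npre:i + npost + 1])
        kept.append(te)
    if not rows:
        raise DataError("no event has full pre/post coverage in the recording")
    matrix = np.vstack(rows)
    rel = (np.arange(-npre, npost + 1)) / rate

    bsel = (rel >= baseline_window[0]) & (rel <= baseline_window[1])
    rsel = (rel >= response_window[0]) & (rel <= response_window[1])
    if not bsel.any() or not rsel.any():
        raise ParameterError("baseline/response windows fall outside [-pre, post]")
    baselines = matrix[:, bsel].mean(axis=1)
    responses = matrix[:, rsel].mean(axis=1)
    contrasts = responses - baselines
    return PeriEventResult(matrix=matrix, rel_time=rel,
                           event_times=np.asarray(kept),
                           baselines=baselines, responses=responses,
                           contrasts=contrasts,
                           mean_contrast=float(contrasts.mean()),
                           n_dropped=dropped,
                           baseline_window=baseline_window,
                           response_window=response_window)


def pearson_one_tailed(x, y, tail: str = "positive") -> CorrelationResult:
    """Pearson product-moment correlation with a one-tailed p value.

    ``tail="positive"`` tests r > 0, ``tail="negative"`` tests r < 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise AlignmentError("x and y must have equal length")
    if len(x) < 3:
        raise ParameterError("need at least 3 subjects")
    if np.var(x) == 0 or np.var(y) == 0:
        raise DegenerateFitError("zero-variance input; correlation undefined")
    if tail not in ("positive", "negative"):
        raise ParameterError("tail must be 'positive' or 'negative'")
    alt = "greater" if tail == "positive" else "less"
    res = _stats.pearsonr(x, y, alternative=alt)
    r = float(res.statistic)
    return CorrelationResult(r=r, r2=r * r, p=float(res.pvalue),
                             n=len(x), tail=tail)


def place_preference_index(t_stim: float, t_nonstim: float) -> PlacePreferenceResult:
    """PPI% = (T_stim - T_nonstim) / (T_stim + T_nonstim) * 100."""
    if t_stim < 0 or t_nonstim < 0:
        raise ParameterError("chamber times must be non-negative")
    total = t_stim + t_nonstim
    if total == 0:
        raise DataError("zero total chamber time; index undefined")
    return PlacePreferenceResult(
        t_stim_s=float(t_stim), t_nonstim_s=float(t_nonstim),
        ppi_pct=float((t_stim - t_nonstim) / total * 100.0))


def cohort_analysis(
    subjects: list[dict] | pd.DataFrame,
    correlations: dict[str, tuple[str, str, str]] | None = None,
) -> CohortResult:
    """Tidy per-subject metric table plus requested one-tailed correlations.

    ``correlations`` maps a result name to ``(x_metric, y_metric, tail)``.
    Subjects missing a metric are dropped from that correlation (count
    reported in ``n_dropped``, the maximum over correlations).
    """
    table = pd.DataFrame(subjects)
    if len(table) < 3:
        raise ParameterError("need at least 3 subjects")
    results = {}
    max_dropped = 0
    for name, (cx, cy, tail) in (correlations or {}).items():
        sub = table[[cx, cy]].dropna()
        max_dropped = max(max_dropped, len(table) - len(sub))
        results[name] = pearson_one_tailed(sub[cx].to_numpy(),
                                           sub[cy].to_numpy(), tail=tail)
    return CohortResult(table=table, correlations=results, n_dropped=max_dropped)
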