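"""Two-channel fiber-photometry preprocessing and calcium-transient detection.

The processing chain turns raw 470 nm (calcium-dependent) and 405 nm
(isosbestic, calcium-independent) fluorescence into a motion-corrected
"global signal" and a set of discrete calcium transients:

1.  trim the first minute of the recording (LED stabilisation),
2.  normalise each channel to dF/F (%) against a 60 s sliding-window mean,
    which also removes slow photobleaching,
3.  regress the normalised 405 nm trace onto the 470 nm trace (OLS) and
4.  subtract the fitted 405 nm trace — the result is the global signal,
5.  band-pass the global signal (0.2-6 Hz) and detect transients with a
    two-pass sliding median/MAD threshold: samples more than ``k_mad`` MADs
    above the sliding median are flagged, median and MAD are recomputed
    with the flagged samples excluded, and one transient is reported per
    contiguous excursion above the recomputed threshold (peak = maximum).

dF/F is expressed in percent of the local mean fluorescence: 100% means the
instantaneous fluorescence is twice the 60 s local average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .errors import AlignmentError, DataError, DegenerateFitError, ParameterError

__all__ = [
    "PhotometrySession",
    "DffTrace",
    "IsosbesticFit",
    "TransientSet",
    "normalize_session",
    "fit_isosbestic",
    "motion_correct",
    "bandpass_filter",
    "detect_transients",
    "transient_zone_stats",
    "ZoneTransientStats",
    "sliding_window_mean",
    "sliding_median_mad",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class PhotometrySession:
    """Raw two-channel fluorescence recording on a uniform time grid.

    Parameters
    ----------
    t : array of float
        Sample times in seconds, strictly increasing and uniform.
    f470, f405 : array of float
        Raw fluorescence (arbitrary units) of the calcium-dependent and
        isosbestic channels, sampled simultaneously.
    rate : float
        Sampling rate in Hz (20 Hz in the acquisition this models).
    """

    t: np.ndarray
    f470: np.ndarray
    f405: np.ndarray
    rate: float = 20.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f470 = np.asarray(self.f470, dtype=float)
        self.f405 = np.asarray(self.f405, dtype=float)
        if self.rate <= 0:
            raise ParameterError("sampling rate must be positive")
        if not (len(self.t) == len(self.f470) == len(self.f405)):
            raise AlignmentError("t, f470 and f405 must have equal length")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0) or np.ptp(dt) > 1e-9:
                raise DataError("time grid must be strictly increasing and uniform")

    @property
    def duration(self) -> float:
        """Recording span in seconds (n_samples / rate)."""
        return len(self.t) / self.rate

    @classmethod
    def from_csv(cls, path, rate: float | None = None) -> "PhotometrySession":
        """Read a session from CSV with columns ``time_s, f470, f405``."""
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(float)
        if rate is None:
            rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 20.0
        return cls(t=t, f470=df["f470"].to_numpy(float),
                   f405=df["f405"].to_numpy(float), rate=float(rate))

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.t, "f470": self.f470,
                      "f405": self.f405}).to_csv(path, index=False)


@dataclass
class DffTrace:
    """A dF/F trace in percent on a uniform timebase."""

    t: np.ndarray
    values: np.ndarray
    rate: float
    window: float = 60.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.t) != len(self.values):
            raise AlignmentError("t and values must have equal length")
        if self.window <= 0:
            raise ParameterError("window must be positive")

    def __len__(self) -> int:
        return len(self.values)

    def with_values(self, values: np.ndarray) -> "DffTrace":
        """Copy of this trace with ``values`` replaced (same timebase)."""
        return DffTrace(t=self.t, values=np.asarray(values, float),
                        rate=self.rate, window=self.window)


@dataclass
class IsosbesticFit:
    """OLS fit of the normalised 405 nm trace to the 470 nm trace."""

    slope: float
    intercept: float
    fitted405: np.ndarray


@dataclass
class TransientSet:
    """Detected calcium transients (one per supra-threshold excursion)."""

    peak_times: np.ndarray
    peak_amplitudes: np.ndarray
    params: dict = field(default_factory=dict)
    degenerate: bool = False  # True when MAD was zero everywhere (flat input)

    def __len__(self) -> int:
        return len(self.peak_times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"peak_time_s": self.peak_times,
                             "amplitude_pct": self.peak_amplitudes})


# ---------------------------------------------------------------------------
# sliding-window primitives
# ---------------------------------------------------------------------------

def _window_bounds(n: int, half: int) -> tuple[np.ndarray, np.ndarray]:
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return lo, hi


def sliding_window_mean(x: np.ndarray, half: int) -> np.ndarray:
    """Centered sliding mean with edge truncation.

    Window for sample ``i`` is ``x[max(0, i-half) : min(n, i+half+1)]``;
    edge windows are shorter, never padded. Sums are taken per window
    (``np.add.reduceat``) so the result matches a direct per-sample loop to
    float round-off.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n == 0:
        return x.copy()
    # summing deviations from x[0] keeps constant traces exact (their
    # deviations are identically zero) and improves conditioning generally
    shift = x[0]
    xs = x - shift
    lo, hi = _window_bounds(n, half)
    # reduceat over interleaved [lo0, hi0, lo1, hi1, ...]; window sums land at
    # even slots. A zero sentinel keeps the final hi == n index legal.
    bounds = np.empty(2 * n, dtype=np.intp)
    bounds[0::2] = lo
    bounds[1::2] = hi
    sums = np.add.reduceat(np.r_[xs, 0.0], bounds)[0::2]
    return sums / (hi - lo) + shift


def _nan_window_view(x: np.ndarray, half: int):
    """NaN-padded sliding windows of width ``2*half + 1`` (one row per sample)."""
    pad = np.full(half, np.nan)
    xp = np.concatenate([pad, x, pad])
    return np.lib.stride_tricks.sliding_window_view(xp, 2 * half + 1)


def sliding_median_mad(
    x: np.ndarray,
    half: int,
    exclude: np.ndarray | None = None,
    chunk: int = 2048,
) -> tuple[np.ndarray, np.ndarray]:
    """Centered sliding median and MAD with edge truncation.

    For every sample the median and the median absolute deviation are taken
    over the window ``[i-half, i+half]`` clipped to the trace, optionally
    excluding samples where ``exclude`` is True. Windows with no retained
    sample yield NaN. Equivalent to an explicit per-sample loop; implemented
    with NaN padding + ``nanmedian`` over strided windows, in chunks to bound
    memory.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    med = np.empty(n)
    mad = np.empty(n)
    if n == 0:
        return med, mad
    xm = x.copy()
    if exclude is not None:
        xm[np.asarray(exclude, bool)] = np.nan
    win = _nan_window_view(xm, half)
    with np.errstate(invalid="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for s in range(0, n, chunk):
                e = min(s + chunk, n)
                w = win[s:e]
                m = np.nanmedian(w, axis=1)
                med[s:e] = m
                mad[s:e] = np.nanmedian(np.abs(w - m[:, None]), axis=1)
    return med, mad


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def normalize_session(
    session: PhotometrySession,
    trim: float = 60.0,
    window: float = 60.0,
) -> tuple[DffTrace, DffTrace]:
    """Trim the recording start and normalise both channels to dF/F (%).

    The first ``trim`` seconds are discarded. Each remaining sample is
    normalised as ``(F - Fmean) / Fmean * 100`` where ``Fmean`` is the mean
    over a window of ``window`` seconds centered on the sample and truncated
    at the recording edges. Slow exponential trends (photobleaching) much
    longer than the window are removed by construction.

    Returns ``(dff470, dff405)``.
    """
    if window <= 0 or trim < 0:
        raise ParameterError("trim must be >= 0 and window > 0")
    if session.duration <= trim + window / 2:
        raise DataError("recording too short for the requested trim and window")
    if np.any(session.f470 <= 0) or np.any(session.f405 <= 0):
        raise DataError("fluorescence must be strictly positive (a.u. counts)")

    rel = session.t - session.t[0]
    keep = rel >= trim
    t = session.t[keep]
    half = int(round(window * session.rate / 2))

    out = []
    for f in (session.f470[keep], session.f405[keep]):
        m = sliding_window_mean(f, half)
        out.append(DffTrace(t=t, values=(f - m) / m * 100.0,
                            rate=session.rate, window=window))
    return out[0], out[1]


def fit_isosbestic(dff405: DffTrace, dff470: DffTrace) -> IsosbesticFit:
    """OLS regression of the normalised 470 trace on the 405 trace.

    Standardises the mean and amplitude of the calcium-independent channel
    so it can be subtracted from the calcium channel.
    """
    if len(dff405) != len(dff470):
        raise AlignmentError("dff405 and dff470 must be aligned")
    x = dff405.values
    y = dff470.values
    vx = np.var(x)
    if vx == 0:
        raise DegenerateFitError("dff405 has zero variance; cannot fit")
    slope = float(np.cov(x, y, bias=True)[0, 1] / vx)
    intercept = float(np.mean(y) - slope * np.mean(x))
    return IsosbesticFit(slope=slope, intercept=intercept,
                         fitted405=slope * x + intercept)


def motion_correct(dff470: DffTrace, fit: IsosbesticFit) -> DffTrace:
    """Subtract the fitted isosbestic trace: the motion-corrected global signal."""
    if len(fit.fitted405) != len(dff470):
        raise AlignmentError("fit and dff470 lengths differ")
    return dff470.with_values(dff470.values - fit.fitted405)


def bandpass_filter(
    trace: DffTrace, low: float = 0.2, high: float = 6.0, order: int = 2
) -> DffTrace:
    """Zero-phase Butterworth band-pass of the global signal.

    A second-order design applied forward and backward (``sosfiltfilt``), so
    transient peak times are not shifted. Rejects the DC component and
    frequencies well outside [low, high].
    """
    if not 0 < low < high:
        raise ParameterError("need 0 < low < high")
    if high >= trace.rate / 2:
        raise ParameterError("high cutoff must be below the Nyquist frequency")
    sos = _signal.butter(order, [low, high], btype="bandpass",
                         fs=trace.rate, output="sos")
    return trace.with_values(_signal.sosfiltfilt(sos, trace.values))


def detect_transients(
    filtered: DffTrace, k_mad: float = 2.0, mad_window: float = 60.0
) -> TransientSet:
    """Two-pass sliding median/MAD transient detection.

    Pass 1 flags samples exceeding ``median + k_mad * MAD`` within a sliding
    window; pass 2 recomputes the sliding median and MAD with the flagged
    samples excluded, and every contiguous excursion above the recomputed
    threshold becomes one transient located at its maximum.

    A flat trace (MAD zero everywhere) returns an empty set flagged
    ``degenerate=True`` rather than raising.
    """
    if k_mad <= 0 or mad_window <= 0:
        raise ParameterError("k_mad and mad_window must be positive")
    x = filtered.values
    half = int(round(mad_window * filtered.rate / 2))

    med1, mad1 = sliding_median_mad(x, half)
    with np.errstate(invalid="ignore"):
        flagged = x > med1 + k_mad * mad1
    med2, mad2 = sliding_median_mad(x, half, exclude=flagged)
    with np.errstate(invalid="ignore"):
        above = x > med2 + k_mad * mad2
    above &= np.isfinite(med2)

    params = {"band_low": None, "band_high": None, "k_mad": k_mad,
              "mad_window": mad_window}
    finite_mad = mad2[np.isfinite(mad2)]
    if finite_mad.size and np.all(finite_mad == 0) and not above.any():
        return TransientSet(np.empty(0), np.empty(0), params, degenerate=True)

    # one transient per contiguous run of supra-threshold samples
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above.size and above[0]:
        starts = np.r_[0, starts]
    if above.size and above[-1]:
        ends = np.r_[ends, above.size]
    peaks = np.array([s + int(np.argmax(x[s:e])) for s, e in zip(starts, ends)],
                     dtype=int)
    return TransientSet(
        peak_times=filtered.t[peaks] if peaks.size else np.empty(0),
        peak_amplitudes=x[peaks] if peaks.size else np.empty(0),
        params=params,
    )


@dataclass
class ZoneTransientStats:
    """Per-zone transient frequency/amplitude and the differential frequency."""

    frequency_hz: dict
    mean_amplitude_pct: dict
    dwell_s: dict
    differential_hz: float
    undefined_zones: tuple = ()


def transient_zone_stats(transients: TransientSet, zones) -> ZoneTransientStats:
    """Per-zone transient frequency (Hz) and mean amplitude (%).

    Each transient is assigned to the zone of the frame nearest its peak
    time. ``frequency = count / dwell time``; zones with zero dwell are
    reported NaN and listed in ``undefined_zones``. The differential
    frequency is open - closed for the EPM and center - border for the OFT.
    """
    labels = np.asarray(zones.labels)
    t = np.asarray(zones.t, float)
    if len(labels) != len(t):
        raise AlignmentError("zone labels and timebase lengths differ")
    if len(transients) and (transients.peak_times.min() < t[0] - 0.5 / zones.rate
                            or transients.peak_times.max() > t[-1] + 0.5 / zones.rate):
        raise AlignmentError("transient peak times fall outside the zone timebase")

    idx = np.clip(np.round((transients.peak_times - t[0]) * zones.rate).astype(int),
                  0, len(t) - 1) if len(transients) else np.empty(0, int)
    peak_zone = labels[idx] if len(transients) else np.empty(0, dtype=labels.dtype)

    freq, amp, dwell = {}, {}, {}
    undefined = []
    for z in zones.zone_names:
        n_frames = int(np.sum(labels == z))
        dz = n_frames / zones.rate
        dwell[z] = dz
        in_z = peak_zone == z
        if dz == 0:
            freq[z] = np.nan
            amp[z] = np.nan
            undefined.append(z)
        else:
            freq[z] = float(np.sum(in_z)) / dz
            amp[z] = (float(np.mean(transients.peak_amplitudes[in_z]))
                      if np.any(in_z) else np.nan)

    a, b = zones.contrast_pair
    diff = freq.get(a, np.nan) - freq.get(b, np.nan)
    return ZoneTransientStats(frequency_hz=freq, mean_amplitude_pct=amp,
                              dwell_s=dwell, differential_hz=float(diff),
                              undefined_zones=tuple(undefined))
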