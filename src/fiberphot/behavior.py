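"""Maze geometry, zone assignment and trajectory-derived behavioral series.

Covers the behavioral definitions used with synchronized photometry:

* elevated plus maze (EPM): plus-shaped 75 x 75 cm arena, arm width 5 cm,
  5 x 5 cm center platform, so each arm is (75 - 5) / 2 = 35 cm long; open
  arms are anxiogenic, closed arms safe;
* open field (OFT): 60 x 60 cm square whose anxiogenic "center" covers 50%
  of the arena (by default 50% of the *area*, a concentric square of side
  60 / sqrt(2) ~ 42.4 cm; a 50%-of-linear-dimension reading is available);
* real-time place preference arena (RTPP): a 60 x 60 cm box split into two
  equal 30 x 60 cm chambers.

Also: per-frame velocity with the 3.75 mm/frame movement gate, linearized
arm position in 0.5 cm bins (70 bins over 0-35 cm), OUT/BACK direction
segmentation, lick-bout grouping (10 s rule) and port-approach onsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, DataError, ParameterError

__all__ = [
    "MazeGeometry",
    "PixelCalibration",
    "TrackingTrace",
    "ZoneLabels",
    "VelocitySeries",
    "ArmPositionSeries",
    "DirectionSegments",
    "EventTrain",
    "BoutSet",
    "calibrate_and_assign_zones",
    "assign_zones",
    "compute_velocity",
    "linearize_arm",
    "classify_direction",
    "detect_bouts",
    "detect_port_approach",
]

OUT = "OUT"
BACK = "BACK"
MISSING = "missing"


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass
class MazeGeometry:
    """Arena definition with zone assignment.

    ``kind`` is one of ``"EPM"``, ``"OFT"``, ``"RTPP"``. EPM open arms run
    along the x axis, closed arms along y; the origin is the arena's lower
    left corner in cm.
    """

    kind: str
    size: float = None  # overall extent (cm); default set per kind
    arm_width: float = 5.0  # EPM
    oft_center_mode: str = "area"  # "area" (50% of area) or "linear"
    rtpp_stim_side: str = "left"  # which 30x60 chamber is the stim chamber

    def __post_init__(self) -> None:
        if self.kind not in ("EPM", "OFT", "RTPP"):
            raise ParameterError(f"unknown maze kind {self.kind!r}")
        if self.size is None:
            self.size = 75.0 if self.kind == "EPM" else 60.0
        if self.size <= 0 or (self.kind == "EPM" and self.arm_width <= 0):
            raise ParameterError("maze has zero area")
        if self.kind == "EPM" and self.arm_width >= self.size:
            raise ParameterError("arm width must be smaller than the maze size")

    # -- derived EPM quantities --------------------------------------------
    @property
    def arm_length(self) -> float:
        """EPM arm length: (size - arm_width) / 2 (35 cm at the defaults)."""
        return (self.size - self.arm_width) / 2

    @property
    def _band(self) -> tuple[float, float]:
        c = self.size / 2
        return c - self.arm_width / 2, c + self.arm_width / 2

    @property
    def oft_center_side(self) -> float:
        if self.oft_center_mode == "area":
            return self.size / np.sqrt(2.0)
        return self.size / 2

    @property
    def zone_names(self) -> tuple[str, ...]:
        return {"EPM": ("open", "closed", "center"),
                "OFT": ("center", "border"),
                "RTPP": ("stim", "nonstim")}[self.kind]

    @property
    def contrast_pair(self) -> tuple[str, str]:
        """(anxiogenic, safe) zone pair used for differential statistics."""
        return {"EPM": ("open", "closed"),
                "OFT": ("center", "border"),
                "RTPP": ("stim", "nonstim")}[self.kind]

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        return 0.0, 0.0, self.size, self.size

    def contains(self, x, y, tol: float = 0.0) -> np.ndarray:
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if self.kind == "EPM":
            lo, hi = self._band
            in_x_arm = (y >= lo - tol) & (y <= hi + tol) & \
                       (x >= -tol) & (x <= self.size + tol)
            in_y_arm = (x >= lo - tol) & (x <= hi + tol) & \
                       (y >= -tol) & (y <= self.size + tol)
            return in_x_arm | in_y_arm
        return ((x >= -tol) & (x <= self.size + tol) &
                (y >= -tol) & (y <= self.size + tol))

    def zone_of(self, x, y):
        """Zone label(s) for coordinates inside the maze.

        The edge shared by the center platform and an arm belongs to the
        arm, so the arm-position origin (0 cm) is an arm frame.
        """
        scalar = np.isscalar(x) and np.isscalar(y)
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        out = np.full(np.broadcast(x, y).shape, "", dtype=object)
        if self.kind == "EPM":
            lo, hi = self._band
            in_band_y = (y >= lo) & (y <= hi)
            in_band_x = (x >= lo) & (x <= hi)
            is_open = in_band_y & ((x >= hi) | (x <= lo))    # arms along x
            is_closed = in_band_x & ((y >= hi) | (y <= lo))  # arms along y
            out[in_band_x & in_band_y] = "center"
            out[is_open] = "open"
            out[is_closed] = "closed"
        elif self.kind == "OFT":
            half = self.oft_center_side / 2
            c = self.size / 2
            in_center = (np.abs(x - c) <= half) & (np.abs(y - c) <= half)
            out[:] = "border"
            out[in_center] = "center"
        else:  # RTPP: split at x = size/2
            left = x <= self.size / 2
            stim_left = self.rtpp_stim_side == "left"
            out[left] = "stim" if stim_left else "nonstim"
            out[~left] = "nonstim" if stim_left else "stim"
        return out[0] if scalar else out


@dataclass
class PixelCalibration:
    """Per-axis linear pixel -> cm map: ``cm = (px - origin) * cm_per_px``."""

    origin_px: tuple
    cm_per_px: tuple

    @classmethod
    def from_corners(cls, px_lower_left, px_upper_right, maze: MazeGeometry):
        """Build a calibration from the arena's lower-left/upper-right corners."""
        x0, y0 = px_lower_left
        x1, y1 = px_upper_right
        if x1 == x0 or y1 == y0:
            raise ParameterError("degenerate corner calibration")
        return cls(origin_px=(x0, y0),
                   cm_per_px=(maze.size / (x1 - x0), maze.size / (y1 - y0)))

    def apply(self, x_px, y_px) -> tuple[np.ndarray, np.ndarray]:
        x = (np.asarray(x_px, float) - self.origin_px[0]) * self.cm_per_px[0]
        y = (np.asarray(y_px, float) - self.origin_px[1]) * self.cm_per_px[1]
        return x, y


# ---------------------------------------------------------------------------
# per-frame series containers
# ---------------------------------------------------------------------------

@dataclass
class TrackingTrace:
    """Calibrated per-frame coordinates in cm."""

    x: np.ndarray
    y: np.ndarray
    rate: float = 20.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        if len(self.x) != len(self.y):
            raise AlignmentError("x and y must have equal length")
        if self.rate <= 0:
            raise ParameterError("rate must be positive")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.x)) / self.rate

    @classmethod
    def from_csv(cls, path, rate: float = 20.0, t0: float = 0.0):
        df = pd.read_csv(path)
        xcol = "x_cm" if "x_cm" in df else "x"
        ycol = "y_cm" if "y_cm" in df else "y"
        return cls(x=df[xcol].to_numpy(float), y=df[ycol].to_numpy(float),
                   rate=rate, t0=t0)

    def to_csv(self, path) -> None:
        pd.DataFrame({"frame": np.arange(len(self)), "x_cm": self.x,
                      "y_cm": self.y}).to_csv(path, index=False)


@dataclass
class ZoneLabels:
    """One zone label per frame (``'missing'`` where tracking dropped out)."""

    labels: np.ndarray
    maze: MazeGeometry
    rate: float = 20.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.labels)) / self.rate

    @property
    def zone_names(self) -> tuple[str, ...]:
        return self.maze.zone_names

    @property
    def contrast_pair(self) -> tuple[str, str]:
        return self.maze.contrast_pair

    def dwell_s(self, zone: str) -> float:
        return float(np.sum(self.labels == zone)) / self.rate


@dataclass
class VelocitySeries:
    """Per-frame displacement (mm/frame) and speed (cm/s)."""

    displacement_mm: np.ndarray
    rate: float

    @property
    def speed_cm_s(self) -> np.ndarray:
        return self.displacement_mm * self.rate / 10.0

    def __len__(self) -> int:
        return len(self.displacement_mm)


@dataclass
class ArmPositionSeries:
    """Linearized EPM arm position: distance (cm) from the center platform.

    ``pos_cm`` is NaN and ``arm`` is ``None`` for frames in the center or off
    the maze. Bins are half-open ``[k*0.5, (k+1)*0.5)`` with the arm end
    (35 cm) folded into the last bin; 70 bins per arm at the defaults.
    """

    arm: np.ndarray          # object array: arm name or None
    pos_cm: np.ndarray       # NaN outside arms
    bin_index: np.ndarray    # -1 outside arms
    bin_width: float = 0.5
    n_bins: int = 70

    def __len__(self) -> int:
        return len(self.pos_cm)


@dataclass
class DirectionSegments:
    """OUT/BACK labeling of velocity-gated in-arm frames.

    ``labels`` holds ``'OUT'``, ``'BACK'`` or ``None`` per frame; ``include``
    marks frames that passed the velocity gate and lie in an arm. Segments
    are (start_frame, end_frame_inclusive, label) tuples.
    """

    labels: np.ndarray
    include: np.ndarray
    segments: list = field(default_factory=list)


@dataclass
class EventTrain:
    """Sorted discrete event timestamps with a label."""

    times: np.ndarray
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        if np.any(np.diff(self.times) < 0):
            raise DataError("event times must be sorted")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class BoutSet:
    """Lick bouts: onset/offset of groups of licks separated by >= min_gap."""

    onsets: np.ndarray
    offsets: np.ndarray
    counts: np.ndarray
    min_gap: float = 10.0

    def __len__(self) -> int:
        return len(self.onsets)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def calibrate_and_assign_zones(
    x_px,
    y_px,
    maze: MazeGeometry,
    calibration: PixelCalibration,
    rate: float = 20.0,
    t0: float = 0.0,
    tol_cm: float = 1.0,
    max_gap_s: float = 0.5,
) -> tuple[TrackingTrace, ZoneLabels]:
    """Map pixel coordinates to cm, fill short dropouts, and label zones.

    Missing coordinates (NaN) are linearly interpolated across gaps of at
    most ``max_gap_s``; longer gaps stay missing and are labeled
    ``'missing'``. Coordinates outside the arena by more than ``tol_cm``
    raise; small excursions are clipped onto the maze.
    """
    x, y = calibration.apply(x_px, y_px)
    x = _fill_short_gaps(x, int(round(max_gap_s * rate)))
    y = _fill_short_gaps(y, int(round(max_gap_s * rate)))
    valid = np.isfinite(x) & np.isfinite(y)

    inside = np.zeros(len(x), bool)
    inside[valid] = maze.contains(x[valid], y[valid], tol=tol_cm)
    if np.any(valid & ~inside):
        raise DataError(
            f"{int(np.sum(valid & ~inside))} frames fall outside the arena "
            f"by more than {tol_cm} cm after calibration")
    xc, yc = _clip_to_maze(x, y, maze)

    labels = np.full(len(x), MISSING, dtype=object)
    labels[valid] = maze.zone_of(xc[valid], yc[valid])
    track = TrackingTrace(x=xc, y=yc, rate=rate, t0=t0)
    return track, ZoneLabels(labels=labels, maze=maze, rate=rate, t0=t0)


def assign_zones(track: TrackingTrace, maze: MazeGeometry) -> ZoneLabels:
    """Zone labels for an already-calibrated track (NaN frames -> 'missing')."""
    valid = np.isfinite(track.x) & np.isfinite(track.y)
    labels = np.full(len(track), MISSING, dtype=object)
    labels[valid] = maze.zone_of(track.x[valid], track.y[valid])
    return ZoneLabels(labels=labels, maze=maze, rate=track.rate, t0=track.t0)


def _fill_short_gaps(v: np.ndarray, max_gap: int) -> np.ndarray:
    v = np.asarray(v, float).copy()
    bad = ~np.isfinite(v)
    if not bad.any() or bad.all():
        return v
    idx = np.arange(len(v))
    # interpolate everything, then re-blank gaps longer than max_gap
    filled = np.interp(idx, idx[~bad], v[~bad])
    edges = np.diff(bad.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if bad[0]:
        starts = np.r_[0, starts]
    if bad[-1]:
        ends = np.r_[ends, len(v)]
    out = filled
    for s, e in zip(starts, ends):
        if e - s > max_gap or s == 0 or e == len(v):  # no extrapolation
            out[s:e] = np.nan
    return out


def _clip_to_maze(x: np.ndarray, y: np.ndarray, maze: MazeGeometry):
    """Snap slightly-outside coordinates onto the maze."""
    xc = np.clip(x, 0.0, maze.size)
    yc = np.clip(y, 0.0, maze.size)
    if maze.kind == "EPM":
        lo, hi = maze._band
        # pull the transverse coordinate into the nearest arm band
        in_x_arm = np.abs(yc - maze.size / 2) <= np.abs(xc - maze.size / 2)
        yb = np.clip(yc, lo, hi)
        xb = np.clip(xc, lo, hi)
        xc = np.where(in_x_arm, xc, xb)
        yc = np.where(in_x_arm, yb, yc)
    return xc, yc


def compute_velocity(track: TrackingTrace) -> VelocitySeries:
    """Euclidean per-frame displacement (mm); the first frame is 0.

    3.75 mm/frame at 20 Hz corresponds to 7.5 cm/s.
    """
    if len(track) < 2:
        raise DataError("need at least two frames")
    dx = np.diff(track.x)
    dy = np.diff(track.y)
    disp_cm = np.hypot(dx, dy)
    disp = np.r_[0.0, disp_cm * 10.0]
    return VelocitySeries(displacement_mm=disp, rate=track.rate)


def linearize_arm(
    track: TrackingTrace, maze: MazeGeometry, bin_width: float = 0.5
) -> ArmPositionSeries:
    """Project in-arm frames onto the arm's long axis.

    Distance is measured from the edge of the center platform (0 cm) to the
    arm end (``arm_length`` cm); the transverse coordinate is discarded.
    Frames in the center or off the maze get NaN / bin -1.
    """
    if maze.kind != "EPM":
        raise ParameterError("arm linearization is defined for the EPM only")
    lo, hi = maze._band
    L = maze.arm_length
    n_bins = int(round(L / bin_width))
    labels = maze.zone_of(track.x, track.y)

    arm = np.full(len(track), None, dtype=object)
    pos = np.full(len(track), np.nan)
    x, y = track.x, track.y
    specs = [  # (arm name, axis coord, outward direction)
        ("open_right", x, +1), ("open_left", x, -1),
        ("closed_top", y, +1), ("closed_bottom", y, -1),
    ]
    for name, coord, sign in specs:
        zone = "open" if name.startswith("open") else "closed"
        if sign > 0:
            sel = (labels == zone) & (coord >= hi)
            d = coord - hi
        else:
            sel = (labels == zone) & (coord <= lo)
            d = lo - coord
        sel &= np.isfinite(d)
        arm[sel] = name
        pos[sel] = np.clip(d[sel], 0.0, L)

    with np.errstate(invalid="ignore"):
        bins = np.where(np.isnan(pos), -1,
                        np.minimum(np.floor(pos / bin_width), n_bins - 1)).astype(int)
    return ArmPositionSeries(arm=arm, pos_cm=pos, bin_index=bins,
                             bin_width=bin_width, n_bins=n_bins)


def classify_direction(
    armpos: ArmPositionSeries,
    velocity: VelocitySeries,
    threshold_mm_per_frame: float = 3.75,
) -> DirectionSegments:
    """Label velocity-gated in-arm movement OUT (away from center) or BACK.

    Frames with displacement below the threshold are excluded. Among the
    remaining frames of one arm visit, each frame is labeled by the sign of
    the arm-axis change from the previous retained frame (positive -> OUT,
    negative -> BACK); zero changes inherit the previous label, and the
    first frame of a run inherits the label of the move it starts.
    Segments are maximal runs of one label.
    """
    n = len(armpos)
    if len(velocity) != n:
        raise AlignmentError("armpos and velocity must be aligned")
    include = (velocity.displacement_mm >= threshold_mm_per_frame) & \
              np.isfinite(armpos.pos_cm)
    labels = np.full(n, None, dtype=object)

    kept = np.flatnonzero(include)
    prev_label = None
    move_label = np.full(len(kept), None, dtype=object)
    for j in range(1, len(kept)):
        i0, i1 = kept[j - 1], kept[j]
        if armpos.arm[i0] != armpos.arm[i1]:
            prev_label = None
            continue
        d = armpos.pos_cm[i1] - armpos.pos_cm[i0]
        if d > 0:
            prev_label = OUT
        elif d < 0:
            prev_label = BACK
        # d == 0 (transverse move): inherit prev_label
        move_label[j] = prev_label
    for j in range(len(kept)):
        lab = move_label[j]
        if lab is None and j + 1 < len(kept):
            # first retained frame of an arm visit: take the label of the
            # move it starts (lookahead)
            lab = move_label[j + 1]
        labels[kept[j]] = lab

    segments = []
    start = None
    cur = None
    for i in range(n):
        lab = labels[i]
        if lab != cur:
            if cur is not None:
                segments.append((start, i - 1, cur))
            start = i if lab is not None else None
            cur = lab
    if cur is not None:
        segments.append((start, n - 1, cur))
    return DirectionSegments(labels=labels, include=include, segments=segments)


def detect_bouts(licks: EventTrain, min_gap: float = 10.0) -> BoutSet:
    """Group licks into bouts separated by at least ``min_gap`` seconds."""
    if min_gap <= 0:
        raise ParameterError("min_gap must be positive")
    t = licks.times
    if len(t) == 0:
        z = np.empty(0)
        return BoutSet(onsets=z, offsets=z.copy(),
                       counts=np.empty(0, int), min_gap=min_gap)
    new_bout = np.r_[True, np.diff(t) >= min_gap]
    starts = np.flatnonzero(new_bout)
    ends = np.r_[starts[1:] - 1, len(t) - 1]
    return BoutSet(onsets=t[starts], offsets=t[ends],
                   counts=(ends - starts + 1).astype(int), min_gap=min_gap)


def detect_port_approach(
    track: TrackingTrace,
    port_xy: tuple,
    speed_floor_cm_s: float = 2.0,
    approach_radius_cm: float = 5.0,
) -> EventTrain:
    """Movement-initiation onsets of approaches toward a reward port.

    An approach is a maximal run of strictly decreasing distance to the port
    that starts outside ``approach_radius_cm``, ends within it, and whose
    first frame has speed at least ``speed_floor_cm_s``. One onset (the
    run's first frame time) is emitted per approach.
    """
    px, py = port_xy
    d = np.hypot(track.x - px, track.y - py)
    speed = compute_velocity(track).speed_cm_s
    dec = np.diff(d) < 0
    onsets = []
    i = 0
    t = track.t
    while i < len(dec):
        if dec[i]:
            j = i
            while j < len(dec) and dec[j]:
                j += 1
            # run of decreasing distance covers frames i .. j
            if d[i] > approach_radius_cm and d[j] <= approach_radius_cm \
                    and speed[i + 1] >= speed_floor_cm_s:
                onsets.append(t[i])
            i = j
        else:
            i += 1
    return EventTrain(times=np.asarray(onsets), label="port_approach")
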