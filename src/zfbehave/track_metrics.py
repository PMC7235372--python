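"""Free-swim and tap-evoked escape endpoints from centroid tracks.

Tracks are uniformly sampled (typically 25 fps) centroid positions in mm.
Speeds come from central differences of position, accelerations from
central differences of speed; both are one-sided at the track ends.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CentroidTrack",
    "MovementEvent",
    "FreeSwimMetrics",
    "EscapeMetrics",
    "kinematics",
    "detect_movements",
    "freeswim_summary",
    "escape_summary",
]

#: hysteresis defaults (the commercial tracker's values are not published)
START_THRESHOLD_MM_S = 2.0
STOP_THRESHOLD_MM_S = 1.6


@dataclass
class CentroidTrack:
    """Uniformly sampled centroid positions of one subject."""

    frame_rate: float
    x: np.ndarray  # mm
    y: np.ndarray  # mm
    subject_id: str = "subject"
    arena_id: str = "arena"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")

    @property
    def n_frames(self) -> int:
        return self.x.size

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": np.arange(self.n_frames),
            "time_s": self.time,
            "x_mm": self.x,
            "y_mm": self.y,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, frame_rate: Optional[float] = None,
                 subject_id: str = "subject") -> "CentroidTrack":
        df = pd.read_csv(path)
        required = {"frame", "x_mm", "y_mm"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"track CSV missing columns: {sorted(missing)}")
        df = df.sort_values("frame")
        frames = df["frame"].to_numpy()
        if np.unique(frames).size != frames.size:
            raise ValueError("duplicate frames in track CSV")
        gaps = np.diff(frames)
        if gaps.size and (gaps != 1).any():
            logger.warning("track %s has %d frame gap(s); gaps are not interpolated",
                           subject_id, int((gaps != 1).sum()))
        if frame_rate is None:
            if "time_s" not in df.columns or len(df) < 2:
                raise ValueError("frame_rate not given and not inferrable")
            t = df["time_s"].to_numpy()
            frame_rate = float((frames[-1] - frames[0]) / (t[-1] - t[0]))
        return cls(frame_rate=frame_rate, x=df["x_mm"].to_numpy(),
                   y=df["y_mm"].to_numpy(), subject_id=subject_id)


@dataclass
class MovementEvent:
    """A detected movement: half-open frame interval with travel distance."""

    start_frame: int
    end_frame: int
    duration: float  # s
    distance: float  # mm

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.distance < 0:
            raise ValueError("distance must be non-negative")


@dataclass
class FreeSwimMetrics:
    total_displacement: float
    n_movements: int
    mean_movement_duration: Optional[float]
    mean_time_per_acceleration: Optional[float]
    mean_velocity_moving: Optional[float]
    max_acceleration: float
    max_velocity: float
    bins: pd.DataFrame = field(repr=False, default=None)


@dataclass
class EscapeMetrics:
    per_tap: pd.DataFrame = field(repr=False, default=None)
    average: dict = None          # mean over responded taps
    response_rate: float = 0.0
    bins: pd.DataFrame = field(repr=False, default=None)  # per tap x 40 ms bin


# ---------------------------------------------------------------------------

def kinematics(track: CentroidTrack) -> tuple[np.ndarray, np.ndarray]:
    """Speed (mm/s) and acceleration (mm/s^2) series.

    Velocity uses central differences of position at interior frames and
    one-sided differences at the ends; acceleration is the same scheme
    applied to the speed series (exact on quadratic trajectories).
    """
    if track.n_frames < 3:
        raise ValueError("need at least 3 samples for kinematics")
    dt = 1.0 / track.frame_rate
    pos = np.stack([track.x, track.y], axis=1)
    vel = np.gradient(pos, dt, axis=0)       # central interior, one-sided ends
    speed = np.linalg.norm(vel, axis=1)
    accel = np.gradient(speed, dt)
    return speed, accel


def _step_displacements(track: CentroidTrack) -> np.ndarray:
    """Per-step travel |p[i+1]-p[i]|; step i is attributed to sample i."""
    return np.hypot(np.diff(track.x), np.diff(track.y))


def detect_movements(speed: np.ndarray, frame_rate: float,
                     start_thr: float = START_THRESHOLD_MM_S,
                     stop_thr: float = STOP_THRESHOLD_MM_S,
                     displacements: Optional[np.ndarray] = None,
                     min_frames: int = 2) -> list[MovementEvent]:
    """Hysteresis movement detection on a speed series.

    An event opens when speed >= ``start_thr`` and closes when speed drops
    below ``stop_thr``; events shorter than ``min_frames`` are discarded.
    """
    if stop_thr > start_thr:
        raise ValueError("stop_thr must not exceed start_thr")
    events: list[MovementEvent] = []
    open_at: Optional[int] = None
    n = speed.size
    for i in range(n):
        if open_at is None:
            if speed[i] >= start_thr:
                open_at = i
        elif speed[i] < stop_thr:
            events.append((open_at, i))
            open_at = None
    if open_at is not None:
        events.append((open_at, n))
    out = []
    for s, e in events:
        if e - s < min_frames:
            continue
        if displacements is not None:
            dist = float(displacements[s:min(e, displacements.size)].sum())
        else:
            dist = 0.0
        out.append(MovementEvent(start_frame=s, end_frame=e,
                                 duration=(e - s) / frame_rate, distance=dist))
    return out


def _positive_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index ranges of maximal True runs."""
    if not mask.any():
        return []
    padded = np.diff(np.concatenate([[0], mask.astype(int), [0]]))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return [(int(s), int(e)) for s, e in zip(starts, ends)]


def freeswim_summary(track: CentroidTrack, events: Sequence[MovementEvent],
                     bin_length: float = 600.0) -> FreeSwimMetrics:
    """Whole-trial free-swimming endpoints plus fixed-length time bins.

    mean_time_per_acceleration is the mean duration of maximal runs of
    strictly positive acceleration that fall inside movement events;
    mean_velocity_moving is distance-in-events over time-in-events.
    """
    speed, accel = kinematics(track)
    steps = _step_displacements(track)
    total = float(steps.sum())

    in_event = np.zeros(track.n_frames, dtype=bool)
    for ev in events:
        in_event[ev.start_frame:ev.end_frame] = True
    accel_runs = [r for r in _positive_runs(accel > 0)
                  if in_event[r[0]:r[1]].all()]
    fr = track.frame_rate
    mean_tpa = (float(np.mean([(e - s) / fr for s, e in accel_runs]))
                if accel_runs else None)

    if events:
        dist_in = sum(ev.distance for ev in events)
        time_in = sum(ev.duration for ev in events)
        mvm = dist_in / time_in if time_in > 0 else None
        mmd = float(np.mean([ev.duration for ev in events]))
    else:
        mvm = None
        mmd = None

    # bins: samples (and their outgoing steps) are assigned by sample time
    bin_idx = np.floor(track.time / bin_length).astype(int)
    n_bins = int(bin_idx.max()) + 1 if track.n_frames else 0
    rows = []
    for b in range(n_bins):
        sel = bin_idx == b
        step_sel = sel[:-1]  # step i belongs to sample i's bin
        ev_in_bin = [ev for ev in events if bin_idx[ev.start_frame] == b]
        dist_in = sum(ev.distance for ev in ev_in_bin)
        time_in = sum(ev.duration for ev in ev_in_bin)
        rows.append({
            "bin": b,
            "bin_start_s": b * bin_length,
            "total_displacement": float(steps[step_sel].sum()),
            "n_movements": len(ev_in_bin),
            "mean_movement_duration": (float(np.mean([ev.duration for ev in ev_in_bin]))
                                       if ev_in_bin else np.nan),
            "mean_velocity_moving": (dist_in / time_in if time_in > 0 else np.nan),
            "max_acceleration": float(accel[sel].max()) if sel.any() else np.nan,
            "max_velocity": float(speed[sel].max()) if sel.any() else np.nan,
        })
    bins = pd.DataFrame(rows)

    return FreeSwimMetrics(
        total_displacement=total,
        n_movements=len(events),
        mean_movement_duration=mmd,
        mean_time_per_acceleration=mean_tpa,
        mean_velocity_moving=mvm,
        max_acceleration=float(accel.max()),
        max_velocity=float(speed.max()),
        bins=bins,
    )


_ESCAPE_FIELDS = ("max_acceleration", "max_velocity",
                  "cumulative_time_accelerating", "total_displacement",
                  "cumulative_velocity")


def escape_summary(track: CentroidTrack, tap_times: Sequence[float],
                   window: float = 0.280, bin_length: float = 0.040,
                   response_thr: float = STOP_THRESHOLD_MM_S) -> EscapeMetrics:
    """Per-tap escape endpoints over a fixed post-tap window, plus bins.

    The window excludes the tap frame itself and covers the following
    ``window * frame_rate`` samples (7 at 25 fps / 280 ms).  A tap whose
    window never exceeds ``response_thr`` counts as a non-response and is
    excluded from the tap average; the response rate is reported.
    """
    speed, accel = kinematics(track)
    steps = _step_displacements(track)
    fr = track.frame_rate
    n_win = int(round(window * fr))
    n_per_bin = bin_length * fr
    if abs(n_per_bin - round(n_per_bin)) > 1e-9:
        raise ValueError("bin_length must be an integer number of frames")
    n_per_bin = int(round(n_per_bin))
    n_bins = n_win // n_per_bin

    rows = []
    bin_rows = []
    for k, tt in enumerate(tap_times):
        tap_frame = int(round(tt * fr))
        lo, hi = tap_frame + 1, tap_frame + n_win  # inclusive sample range
        if tap_frame < 0 or hi >= track.n_frames:
            logger.warning("tap %d at %.3f s has a truncated window; excluded", k, tt)
            continue
        sl = slice(lo, hi + 1)
        responded = bool((speed[sl] > response_thr).any())
        rows.append({
            "tap": k,
            "tap_time_s": tt,
            "responded": responded,
            "max_acceleration": float(accel[sl].max()),
            "max_velocity": float(speed[sl].max()),
            "cumulative_time_accelerating": float((accel[sl] > 0).sum()) / fr,
            # steps tap_frame..hi-1: travel from the tap sample through the window
            "total_displacement": float(steps[tap_frame:hi].sum()),
            "cumulative_velocity": float(speed[sl].sum()),
        })
        for b in range(n_bins):
            bsl = slice(lo + b * n_per_bin, lo + (b + 1) * n_per_bin)
            bin_rows.append({
                "tap": k, "bin": b,
                "bin_start_ms": b * bin_length * 1e3,
                "mean_speed": float(speed[bsl].mean()),
                "mean_acceleration": float(accel[bsl].mean()),
                "displacement": float(steps[bsl.start - 1:bsl.stop - 1].sum()),
            })
    per_tap = pd.DataFrame(rows)
    bins = pd.DataFrame(bin_rows)
    if len(per_tap):
        responded = per_tap[per_tap["responded"]]
        rate = len(responded) / len(per_tap)
        avg = ({f: float(responded[f].mean()) for f in _ESCAPE_FIELDS}
               if len(responded) else {f: 0.0 for f in _ESCAPE_FIELDS})
    else:
        rate = 0.0
        avg = {f: 0.0 for f in _ESCAPE_FIELDS}
    return EscapeMetrics(per_tap=per_tap, average=avg,
                         response_rate=rate, bins=bins)
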