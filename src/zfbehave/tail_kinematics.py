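"""Tail-kinematics scoring from tracked multi-point tail traces.

The pipeline mirrors the high-speed (1000 fps) semi-constrained larva
preparation: a fixed number of points tracked from tail base to tip at
every frame.  Scoring proceeds through

1. :func:`smooth_trace`       -- moving-average denoising in time and space,
2. :func:`compute_series`     -- deflection / curvature / tip-excursion series,
3. :func:`segment_bouts`      -- active-movement episodes,
4. :func:`segment_halfbeats`  -- zero-crossing delimited half-beats,
5. :func:`classify_halfbeat`  -- swim/escape and slow/fast class labels,
6. :func:`bout_metrics`       -- per-bout summaries split by speed class.

Angles are reported in degrees throughout.  Image coordinates are assumed
(y increasing downward); positive deflection means the tip lies to the
animal's left of the resting body axis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TailTrace",
    "KinematicSeries",
    "HalfBeat",
    "BoutMetrics",
    "KinematicThresholds",
    "smooth_trace",
    "compute_series",
    "segment_bouts",
    "segment_halfbeats",
    "classify_halfbeat",
    "bout_metrics",
    "score_trace",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TailTrace:
    """Time-indexed polyline of tracked tail points.

    ``x`` and ``y`` are ``(n_frames, n_points)`` arrays; point index 0 is
    the tail base (most rostral tracked point), the last index the tip.
    """

    frame_rate: float
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.x.ndim != 2 or self.x.shape != self.y.shape:
            raise ValueError("x and y must be 2-D arrays of identical shape")
        if self.n_frames < 1:
            raise ValueError("trace must contain at least one frame")
        if self.n_points < 3:
            raise ValueError("trace must contain at least three tail points")

    @property
    def n_frames(self) -> int:
        return self.x.shape[0]

    @property
    def n_points(self) -> int:
        return self.x.shape[1]

    @property
    def time(self) -> np.ndarray:
        """Seconds per frame, frame 0 at t = 0."""
        return np.arange(self.n_frames) / self.frame_rate

    # -- CSV round trip ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long-format table: frame, time_s, point_index, x, y."""
        nf, npnt = self.x.shape
        frames = np.repeat(np.arange(nf), npnt)
        points = np.tile(np.arange(npnt), nf)
        return pd.DataFrame(
            {
                "frame": frames,
                "time_s": frames / self.frame_rate,
                "point_index": points,
                "x": self.x.ravel(),
                "y": self.y.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, frame_rate: Optional[float] = None) -> "TailTrace":
        required = {"frame", "point_index", "x", "y"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"tail table is missing columns: {sorted(missing)}")
        df = df.sort_values(["frame", "point_index"])
        npnt = df["point_index"].nunique()
        counts = df.groupby("frame")["point_index"].count()
        if not (counts == npnt).all():
            raise ValueError("point count varies across frames")
        nf = counts.size
        if frame_rate is None:
            if "time_s" not in df.columns or nf < 2:
                raise ValueError("frame_rate not given and not inferrable")
            t = df.drop_duplicates("frame")["time_s"].to_numpy()
            frame_rate = 1.0 / float(np.mean(np.diff(t)))
        return cls(
            frame_rate=frame_rate,
            x=df["x"].to_numpy().reshape(nf, npnt),
            y=df["y"].to_numpy().reshape(nf, npnt),
        )

    @classmethod
    def from_csv(cls, path, frame_rate: Optional[float] = None,
                 dialect: str = "long") -> "TailTrace":
        """Read a tail trace.

        ``dialect='long'`` expects columns frame/time_s/point_index/x/y;
        ``dialect='wide'`` expects x0..x{n-1}, y0..y{n-1} one row per frame.
        """
        df = pd.read_csv(path)
        if dialect == "long":
            return cls.from_frame(df, frame_rate=frame_rate)
        if dialect == "wide":
            xcols = sorted((c for c in df.columns if c.startswith("x") and c[1:].isdigit()),
                           key=lambda c: int(c[1:]))
            ycols = sorted((c for c in df.columns if c.startswith("y") and c[1:].isdigit()),
                           key=lambda c: int(c[1:]))
            if not xcols or len(xcols) != len(ycols):
                raise ValueError("wide tail CSV needs matching x0..xN / y0..yN columns")
            if frame_rate is None:
                raise ValueError("frame_rate is required for the wide dialect")
            return cls(frame_rate=frame_rate,
                       x=df[xcols].to_numpy(float),
                       y=df[ycols].to_numpy(float))
        raise ValueError(f"unknown dialect {dialect!r}")


@dataclass
class KinematicSeries:
    """Per-frame kinematic scalars derived from a (smoothed) trace."""

    frame_rate: float
    deflection: np.ndarray   # signed, degrees
    curvature: np.ndarray    # non-negative, degrees
    tip_x: np.ndarray        # tip excursion along the axis normal, coord units
    body_axis: np.ndarray    # unit vector of the resting base->tip direction

    def __post_init__(self) -> None:
        if np.any(np.abs(self.deflection) > 180.0 + 1e-9):
            raise ValueError("deflection outside [-180, 180] degrees")
        if np.any(self.curvature < -1e-9):
            raise ValueError("curvature must be non-negative")


@dataclass
class HalfBeat:
    """One lateral tail excursion between successive midline crossings."""

    start_frame: int
    end_frame: int
    period: float            # s
    frequency: float         # Hz, 1 / (2 * period)
    peak_deflection: float   # degrees, max |deflection|
    peak_curvature: float    # degrees
    trajectory: float        # total variation of tip_x (headline value)
    net_trajectory: float    # |tip_x(end) - tip_x(start)|
    velocity: float          # trajectory / period
    response_class: Optional[str] = None  # "swim" | "escape"
    speed_class: Optional[str] = None     # "slow" | "fast"
    incomplete: bool = False  # True when a bout had no zero crossing

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValueError("end_frame must exceed start_frame")


@dataclass
class ClassMetrics:
    n_halfbeats: int
    bout_duration: float
    cumulative_trajectory: Optional[float]
    mean_trajectory: Optional[float]
    mean_velocity: Optional[float]
    max_deflection: Optional[float]
    max_curvature: Optional[float]
    period_variance: Optional[float]


@dataclass
class BoutMetrics:
    """Per-bout summaries, computed separately for slow and fast half-beats."""

    start_frame: int
    end_frame: int
    bout_duration: float
    per_class: dict  # speed_class -> ClassMetrics


@dataclass
class KinematicThresholds:
    """Tunable constants of the scoring pipeline (defaults as published)."""

    deflection_split: float = 35.0     # degrees: swim vs escape
    frequency_split: float = 60.0      # Hz: slow vs fast
    smooth_frames: int = 15            # temporal moving-average window
    smooth_points: int = 3             # spatial moving-average window
    min_active_deflection: float = 3.0  # degrees; bout detection threshold
    min_quiescence: float = 0.05       # s; gaps shorter than this are merged
    body_axis: Optional[Sequence[float]] = None  # override resting axis

    def __post_init__(self) -> None:
        for name in ("deflection_split", "frequency_split", "smooth_frames",
                     "smooth_points", "min_active_deflection", "min_quiescence"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.smooth_frames % 2 == 0:
            raise ValueError("smooth_frames must be odd (centred window)")
        if self.smooth_points % 2 == 0:
            raise ValueError("smooth_points must be odd (centred window)")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _sliding_mean(arr: np.ndarray, window: int, axis: int) -> np.ndarray:
    """Centred moving average with symmetrically shrinking edge windows.

    At index i the half-width is min((window-1)//2, i, n-1-i), so edge
    samples are averaged over a shorter but still centred window.
    """
    if window == 1:
        return arr.copy()
    arr = np.moveaxis(arr, axis, 0)
    n = arr.shape[0]
    h = (window - 1) // 2
    idx = np.arange(n)
    k = np.minimum(h, np.minimum(idx, n - 1 - idx))
    csum = np.cumsum(arr, axis=0)
    zero = np.zeros((1,) + arr.shape[1:])
    csum = np.concatenate([zero, csum], axis=0)  # csum[i] = sum of arr[:i]
    lo = idx - k
    hi = idx + k + 1
    counts = (hi - lo).reshape((-1,) + (1,) * (arr.ndim - 1))
    out = (csum[hi] - csum[lo]) / counts
    return np.moveaxis(out, 0, axis)


def smooth_trace(trace: TailTrace, t: KinematicThresholds) -> TailTrace:
    """Moving-average smoothing over frames and adjacent tail points.

    Each coordinate is replaced by the mean over a centred window of
    ``t.smooth_frames`` frames and ``t.smooth_points`` adjacent points;
    windows shrink symmetrically at the boundaries.
    """
    x = _sliding_mean(trace.x, t.smooth_frames, axis=0)
    y = _sliding_mean(trace.y, t.smooth_frames, axis=0)
    x = _sliding_mean(x, t.smooth_points, axis=1)
    y = _sliding_mean(y, t.smooth_points, axis=1)
    return TailTrace(frame_rate=trace.frame_rate, x=x, y=y)


def _estimate_body_axis(chords: np.ndarray, n_frames_used: int = 100) -> np.ndarray:
    """Resting base->tip direction from the quietest frames.

    A provisional axis (mean chord) yields provisional deflections; the
    axis is then re-estimated from the ``n_frames_used`` frames with the
    smallest |deflection|.
    """
    mean_chord = chords.mean(axis=0)
    norm = np.linalg.norm(mean_chord)
    if norm == 0:
        raise ValueError("degenerate trace: mean base->tip chord has zero length")
    axis = mean_chord / norm
    cross = axis[0] * chords[:, 1] - axis[1] * chords[:, 0]
    dot = chords @ axis
    prov = np.abs(np.degrees(np.arctan2(cross, dot)))
    quiet = np.argsort(prov, kind="stable")[:n_frames_used]
    refined = chords[quiet].mean(axis=0)
    norm = np.linalg.norm(refined)
    return axis if norm == 0 else refined / norm


def compute_series(trace: TailTrace,
                   body_axis: Optional[Sequence[float]] = None) -> KinematicSeries:
    """Deflection, curvature and tip-excursion series for a smoothed trace.

    Deflection is the signed angle (degrees) between the base->tip chord
    and the resting body axis; curvature the sum of absolute angles between
    consecutive tail segments; tip_x the tip coordinate along the axis
    normal, measured relative to the tail base.
    """
    base = np.stack([trace.x[:, 0], trace.y[:, 0]], axis=1)
    tip = np.stack([trace.x[:, -1], trace.y[:, -1]], axis=1)
    chords = tip - base
    if body_axis is None:
        axis = _estimate_body_axis(chords)
    else:
        axis = np.asarray(body_axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError("body_axis must be a non-zero vector")
        axis = axis / norm

    cross = axis[0] * chords[:, 1] - axis[1] * chords[:, 0]
    dot = chords @ axis
    deflection = np.degrees(np.arctan2(cross, dot))

    # curvature: sum over interior joints of |angle(v_i, v_{i+1})|
    seg_x = np.diff(trace.x, axis=1)
    seg_y = np.diff(trace.y, axis=1)
    v1x, v1y = seg_x[:, :-1], seg_y[:, :-1]
    v2x, v2y = seg_x[:, 1:], seg_y[:, 1:]
    crossj = v1x * v2y - v1y * v2x
    dotj = v1x * v2x + v1y * v2y
    ang = np.abs(np.degrees(np.arctan2(crossj, dotj)))
    degenerate = (v1x**2 + v1y**2 == 0) | (v2x**2 + v2y**2 == 0)
    if degenerate.any():
        logger.warning(
            "coincident consecutive tail points in %d joint(s); "
            "those joints contribute 0 to curvature", int(degenerate.sum()))
        ang = np.where(degenerate, 0.0, ang)
    curvature = ang.sum(axis=1)

    normal = np.array([-axis[1], axis[0]])
    tip_x = chords @ normal
    return KinematicSeries(frame_rate=trace.frame_rate, deflection=deflection,
                           curvature=curvature, tip_x=tip_x, body_axis=axis)


def segment_bouts(series: KinematicSeries, t: KinematicThresholds) -> list[tuple[int, int]]:
    """Active-movement intervals as half-open frame ranges ``[start, end)``.

    Maximal runs with |deflection| > ``min_active_deflection`` are merged
    when separated by quiescent gaps shorter than ``min_quiescence``.
    """
    active = np.abs(series.deflection) > t.min_active_deflection
    if not active.any():
        return []
    padded = np.diff(np.concatenate([[0], active.astype(int), [0]]))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    min_gap = int(round(t.min_quiescence * series.frame_rate))
    bouts: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        if bouts and s - bouts[-1][1] < min_gap:
            bouts[-1] = (bouts[-1][0], int(e))
        else:
            bouts.append((int(s), int(e)))
    return bouts


def _zero_crossings(d: np.ndarray) -> np.ndarray:
    """Indices treated as midline crossings of a signed series.

    A crossing is recorded at the first sample after a sign change and at
    exact zeros; a run of consecutive zeros (a resting stretch)
    contributes its two endpoints, so motion on either side of a rest gap
    is bounded where it actually starts and stops.

    Values within 1e-9 of zero (relative to the series amplitude) are
    snapped to zero first: at a crossing the signal nearly cancels and its
    floating-point sign would otherwise be arbitrary, making segmentation
    unstable under rigid rotations of the input coordinates.
    """
    eps = max(1e-12, 1e-9 * float(np.max(np.abs(d), initial=0.0)))
    d = np.where(np.abs(d) < eps, 0.0, d)
    sign = np.sign(d)
    crossings: list[int] = []
    zero_start: Optional[int] = None
    prev_nonzero = 0.0
    for i, s in enumerate(sign):
        if s == 0:
            if zero_start is None:
                zero_start = i
                crossings.append(i)
            continue
        if zero_start is not None:
            if i - 1 > zero_start:
                crossings.append(i - 1)
            zero_start = None
            prev_nonzero = s
            continue
        if prev_nonzero != 0 and s != prev_nonzero:
            crossings.append(i)
        prev_nonzero = s
    if zero_start is not None and len(sign) - 1 > zero_start:
        crossings.append(len(sign) - 1)
    return np.asarray(crossings, dtype=int)


def segment_halfbeats(series: KinematicSeries, bout: tuple[int, int],
                      t: Optional[KinematicThresholds] = None) -> list[HalfBeat]:
    """Half-beats delimited by consecutive deflection zero-crossings.

    Threshold-based bout bounds clip the first and last excursions part-way
    through, so the crossing search extends up to half of
    ``min_quiescence`` beyond each bout edge (never into a neighbouring
    bout, which by construction is at least ``min_quiescence`` away).
    A bout containing no crossing yields a single flagged half-beat
    spanning the whole bout.
    """
    t = t or KinematicThresholds()
    start, end = bout
    if end <= start:
        raise ValueError("empty bout")
    pad = int(t.min_quiescence * series.frame_rate) // 2
    lo = max(0, start - pad)
    hi = min(end + pad, series.deflection.size - 1)
    d = series.deflection[lo:hi + 1]
    crossings = _zero_crossings(d) + lo
    # keep the nearest crossing on each side of [start, end]
    inside = (crossings >= start) & (crossings <= end)
    before = crossings[crossings < start]
    after = crossings[crossings > end]
    keep = list(crossings[inside])
    d_abs = np.abs(series.deflection)
    # extend only across segments that carry actual excursion (a clipped
    # half-beat), never across pure rest
    if before.size and d_abs[int(before[-1]):start + 1].max() > 0:
        keep.insert(0, int(before[-1]))
    if after.size and d_abs[end:int(after[0]) + 1].max() > 0:
        keep.append(int(after[0]))
    crossings = np.asarray(keep, dtype=int)

    fr = series.frame_rate
    if crossings.size < 2:
        logger.warning("bout %s has no internal zero crossing; "
                       "flagging a single half-beat", bout)
        bounds = [start, hi]
        incomplete = True
    else:
        bounds = list(crossings)
        incomplete = False

    out: list[HalfBeat] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b <= a:
            continue
        period = (b - a) / fr
        seg_tip = series.tip_x[a:b + 1]
        traj = float(np.sum(np.abs(np.diff(seg_tip))))
        net = float(abs(seg_tip[-1] - seg_tip[0]))
        out.append(HalfBeat(
            start_frame=int(a), end_frame=int(b),
            period=period, frequency=1.0 / (2.0 * period),
            peak_deflection=float(np.max(np.abs(series.deflection[a:b + 1]))),
            peak_curvature=float(np.max(series.curvature[a:b + 1])),
            trajectory=traj, net_trajectory=net,
            velocity=traj / period, incomplete=incomplete,
        ))
    return out


def classify_halfbeat(hb: HalfBeat, t: KinematicThresholds) -> HalfBeat:
    """Attach response (swim/escape) and speed (slow/fast) class labels.

    Boundary values (exactly at the split) go to the lower class.
    """
    response = "swim" if hb.peak_deflection <= t.deflection_split else "escape"
    speed = "slow" if hb.frequency <= t.frequency_split else "fast"
    return replace(hb, response_class=response, speed_class=speed)


def bout_metrics(halfbeats: Sequence[HalfBeat], bout: tuple[int, int],
                 frame_rate: float) -> BoutMetrics:
    """Per-speed-class bout summary.

    Continuous metrics of an empty class are reported as missing (None),
    not zero; period variance uses the n-1 denominator and needs at least
    two half-beats.
    """
    start, end = bout
    duration = (end - start) / frame_rate
    per_class = {}
    for cls in ("slow", "fast"):
        hbs = [h for h in halfbeats if h.speed_class == cls]
        if not hbs:
            per_class[cls] = ClassMetrics(0, duration, None, None, None,
                                          None, None, None)
            continue
        trajs = np.array([h.trajectory for h in hbs])
        periods = np.array([h.period for h in hbs])
        per_class[cls] = ClassMetrics(
            n_halfbeats=len(hbs),
            bout_duration=duration,
            cumulative_trajectory=float(trajs.sum()),
            mean_trajectory=float(trajs.mean()),
            mean_velocity=float(np.mean([h.velocity for h in hbs])),
            max_deflection=float(max(h.peak_deflection for h in hbs)),
            max_curvature=float(max(h.peak_curvature for h in hbs)),
            period_variance=float(np.var(periods, ddof=1)) if len(hbs) >= 2 else None,
        )
    return BoutMetrics(start_frame=start, end_frame=end,
                       bout_duration=duration, per_class=per_class)


def score_trace(trace: TailTrace,
                t: Optional[KinematicThresholds] = None
                ) -> tuple[list[BoutMetrics], list[list[HalfBeat]]]:
    """Full pipeline: smooth, derive series, segment, classify, summarise."""
    t = t or KinematicThresholds()
    smoothed = smooth_trace(trace, t)
    series = compute_series(smoothed, body_axis=t.body_axis)
    bouts = segment_bouts(series, t)
    all_metrics: list[BoutMetrics] = []
    all_halfbeats: list[list[HalfBeat]] = []
    for bout in bouts:
        hbs = [classify_halfbeat(h, t) for h in segment_halfbeats(series, bout, t)]
        all_halfbeats.append(hbs)
        all_metrics.append(bout_metrics(hbs, bout, series.frame_rate))
    return all_metrics, all_halfbeats


def halfbeats_to_frame(halfbeats: Sequence[HalfBeat], bout_index: int = 0) -> pd.DataFrame:
    rows = []
    for i, h in enumerate(halfbeats):
        rows.append({
            "bout": bout_index, "halfbeat": i,
            "start_frame": h.start_frame, "end_frame": h.end_frame,
            "period_s": h.period, "frequency_hz": h.frequency,
            "peak_deflection_deg": h.peak_deflection,
            "peak_curvature_deg": h.peak_curvature,
            "trajectory": h.trajectory, "net_trajectory": h.net_trajectory,
            "velocity": h.velocity,
            "response_class": h.response_class, "speed_class": h.speed_class,
        })
    return pd.DataFrame(rows)


def bouts_to_frame(metrics: Sequence[BoutMetrics]) -> pd.DataFrame:
    rows = []
    for i, m in enumerate(metrics):
        for cls, c in m.per_class.items():
            rows.append({
                "bout": i, "speed_class": cls,
                "start_frame": m.start_frame, "end_frame": m.end_frame,
                "bout_duration_s": c.bout_duration,
                "n_halfbeats": c.n_halfbeats,
                "cumulative_trajectory": c.cumulative_trajectory,
                "mean_trajectory": c.mean_trajectory,
                "mean_velocity": c.mean_velocity,
                "max_deflection_deg": c.max_deflection,
                "max_curvature_deg": c.max_curvature,
                "period_variance_s2": c.period_variance,
            })
    return pd.DataFrame(rows)
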