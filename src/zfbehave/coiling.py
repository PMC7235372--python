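"""Embryonic coiling detection from per-ROI motion-energy signals.

Motion energy is the summed absolute pixel difference between consecutive
frames within an embryo's ROI.  Events are supra-threshold runs above a
robust (median/MAD) baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CoilSignal",
    "CoilEvent",
    "CoilSummary",
    "frame_difference",
    "detect_coils",
    "coil_summary",
]

MAD_TO_SD = 1.4826  # consistent scale factor for Gaussian noise


@dataclass
class CoilSignal:
    """Per-frame motion energy of one embryo ROI."""

    frame_rate: float
    motion_energy: np.ndarray
    embryo_id: str = "embryo"

    def __post_init__(self) -> None:
        self.motion_energy = np.asarray(self.motion_energy, dtype=float)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if np.any(self.motion_energy < 0):
            raise ValueError("motion_energy must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.motion_energy.size

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass
class CoilEvent:
    onset_frame: int
    offset_frame: int          # exclusive
    duration: float            # ms
    intensity: float           # area above baseline, energy * frames
    intercoil_gap: Optional[float] = None  # ms since previous event offset

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.intensity <= 0:
            raise ValueError("intensity must be positive")


@dataclass
class CoilSummary:
    frequency: float                 # events / recording seconds
    mean_duration: Optional[float]   # ms
    mean_intensity: Optional[float]
    mean_intercoil: Optional[float]  # ms


def frame_difference(stack: np.ndarray,
                     rois: Sequence[tuple[str, int, int, int, int]],
                     frame_rate: float = 50.0) -> list[CoilSignal]:
    """Per-ROI motion energy from a grayscale image stack.

    ``stack`` is (frames, height, width); each ROI is
    (embryo_id, x, y, w, h), 0-based with half-open extents.  Frame 0 has
    motion energy 0 by definition.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("stack must be (frames, h, w) with at least 2 frames")
    nf, H, W = stack.shape
    diffs = np.abs(np.diff(stack.astype(np.int64), axis=0))
    out = []
    for embryo_id, x, y, w, h in rois:
        if x < 0 or y < 0 or x + w > W or y + h > H or w <= 0 or h <= 0:
            raise ValueError(f"ROI {embryo_id!r} ({x},{y},{w},{h}) outside "
                             f"image of size {W}x{H}")
        energy = diffs[:, y:y + h, x:x + w].sum(axis=(1, 2)).astype(float)
        out.append(CoilSignal(frame_rate=frame_rate,
                              motion_energy=np.concatenate([[0.0], energy]),
                              embryo_id=str(embryo_id)))
    return out


def detect_coils(signal: CoilSignal, k_sd: float = 3.0,
                 merge_gap: float = 0.040,
                 min_duration: float = 0.040) -> list[CoilEvent]:
    """Threshold detection of coil events against a robust baseline.

    baseline = median, noise = MAD scaled to SD, threshold =
    baseline + k_sd * noise.  Supra-threshold runs separated by less than
    ``merge_gap`` seconds are merged into one event; merged runs shorter
    than ``min_duration`` are discarded as isolated noise excursions.
    """
    if signal.duration < 1.0:
        raise ValueError("need at least 1 s of signal")
    me = signal.motion_energy
    baseline = float(np.median(me))
    noise = float(np.median(np.abs(me - baseline))) * MAD_TO_SD
    thr = baseline + k_sd * noise

    above = me > thr
    if above.all():
        logger.warning("signal %s is entirely above threshold; single event",
                       signal.embryo_id)
    if not above.any():
        return []
    padded = np.diff(np.concatenate([[0], above.astype(int), [0]]))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)

    gap_frames = merge_gap * signal.frame_rate
    runs: list[list[int]] = []
    for s, e in zip(starts, ends):
        if runs and s - runs[-1][1] < gap_frames:
            runs[-1][1] = int(e)
        else:
            runs.append([int(s), int(e)])

    fr = signal.frame_rate
    min_frames = min_duration * fr
    events: list[CoilEvent] = []
    prev_end: Optional[int] = None
    for s, e in runs:
        if e - s < min_frames:
            continue
        intensity = float(np.sum(me[s:e] - baseline))
        if intensity <= 0:
            continue
        gap_ms = None if prev_end is None else (s - prev_end) / fr * 1e3
        events.append(CoilEvent(onset_frame=s, offset_frame=e,
                                duration=(e - s) / fr * 1e3,
                                intensity=intensity, intercoil_gap=gap_ms))
        prev_end = e
    return events


def coil_summary(events: Sequence[CoilEvent], recording_s: float = 300.0) -> CoilSummary:
    """Frequency / duration / intensity summary over a recording."""
    if recording_s <= 0:
        raise ValueError("recording_s must be positive")
    if not events:
        return CoilSummary(frequency=0.0, mean_duration=None,
                           mean_intensity=None, mean_intercoil=None)
    gaps = [e.intercoil_gap for e in events if e.intercoil_gap is not None]
    return CoilSummary(
        frequency=len(events) / recording_s,
        mean_duration=float(np.mean([e.duration for e in events])),
        mean_intensity=float(np.mean([e.intensity for e in events])),
        mean_intercoil=float(np.mean(gaps)) if gaps else None,
    )


def events_to_frame(events: Sequence[CoilEvent], embryo_id: str = "embryo") -> pd.DataFrame:
    return pd.DataFrame([{
        "embryo_id": embryo_id,
        "onset_frame": e.onset_frame,
        "offset_frame": e.offset_frame,
        "duration_ms": e.duration,
        "intensity": e.intensity,
        "intercoil_gap_ms": e.intercoil_gap,
    } for e in events])
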