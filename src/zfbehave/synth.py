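"""Synthetic-data generators with recorded ground truth.

Every downstream stage (tail kinematics, track metrics, coiling, ddCt) can
be exercised without recordings: these generators produce inputs with the
statistical structure the pipelines assume and return the exact quantities
a parameter-recovery test needs.  All generators are deterministic given
their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .coiling import CoilSignal
from .tail_kinematics import TailTrace
from .track_metrics import CentroidTrack

__all__ = [
    "TailSimParams",
    "TrackSimParams",
    "CoilSimParams",
    "CtPlateDesign",
    "gen_tail_trace",
    "gen_centroid_track",
    "gen_coil_signal",
    "gen_ct_plate",
]


# ---------------------------------------------------------------------------
# tail traces
# ---------------------------------------------------------------------------

@dataclass
class TailSimParams:
    """Parameters of the simulated high-speed tail recording.

    ``bouts`` is a list of (onset_s, length_s, beat_frequency_hz,
    peak_deflection_deg) tuples; bouts must not overlap.
    """

    duration: float
    frame_rate: float = 1000.0
    n_points: int = 20
    bouts: Sequence[tuple[float, float, float, float]] = ()
    wave_speed: float = 20.0  # body lengths / s of the traveling wave
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.n_points < 3:
            raise ValueError("n_points must be at least 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        prev_end = -math.inf
        for onset, length, freq, peak in sorted(self.bouts):
            if length <= 0 or freq <= 0 or peak <= 0:
                raise ValueError("bout length, frequency and deflection "
                                 "must be positive")
            if onset < prev_end:
                raise ValueError(
                    f"overlapping bouts: bout at {onset:g} s starts before "
                    f"the previous one ends ({prev_end:g} s)")
            if onset + length > self.duration:
                raise ValueError("bout extends beyond the recording")
            prev_end = onset + length


def gen_tail_trace(params: TailSimParams) -> tuple[TailTrace, pd.DataFrame]:
    """Simulate a tracked tail trace plus per-bout ground truth.

    The resting tail lies along +y with the base at the origin and unit
    length.  During a bout a traveling sinusoidal lateral wave displaces
    each point in x with an amplitude envelope growing linearly toward the
    tip, tuned so the base->tip chord deflection peaks at the requested
    angle.  Ground truth per bout: exact frequency, peak deflection and
    half-beat count ``round(2 * f * length)``.
    """
    rng = np.random.default_rng(params.seed)
    n_frames = int(round(params.duration * params.frame_rate))
    t = np.arange(n_frames) / params.frame_rate
    s = np.linspace(0.0, 1.0, params.n_points)  # 0 = base, 1 = tip

    x = np.zeros((n_frames, params.n_points))
    y = np.tile(s, (n_frames, 1))

    gt_rows = []
    for onset, length, freq, peak in sorted(params.bouts):
        a_tip = math.tan(math.radians(peak))  # unit tail length
        mask = (t >= onset) & (t < onset + length)
        tt = t[mask] - onset
        if params.wave_speed > 0:
            phase_lag = 2.0 * math.pi * freq * (s - 1.0) / params.wave_speed
        else:
            phase_lag = np.zeros_like(s)
        phase = 2.0 * math.pi * freq * tt[:, None] + phase_lag[None, :]
        x[mask] = a_tip * s[None, :] * np.sin(phase)
        gt_rows.append({
            "onset_s": onset, "length_s": length,
            "beat_frequency_hz": freq, "peak_deflection_deg": peak,
            "halfbeat_count": int(round(2.0 * freq * length)),
            "start_frame": int(round(onset * params.frame_rate)),
            "end_frame": int(round((onset + length) * params.frame_rate)),
        })

    if params.noise_sd > 0:
        x += rng.normal(0.0, params.noise_sd, x.shape)
        y += rng.normal(0.0, params.noise_sd, y.shape)

    trace = TailTrace(frame_rate=params.frame_rate, x=x, y=y)
    return trace, pd.DataFrame(gt_rows)


# ---------------------------------------------------------------------------
# centroid tracks
# ---------------------------------------------------------------------------

@dataclass
class TrackSimParams:
    """Parameters of the simulated centroid track.

    Spontaneous bouts arrive as a Poisson process; each tap triggers an
    escape with a constant-acceleration phase of ``accel_duration`` that
    then cruises at the attained velocity until the end of the escape
    window.
    """

    duration: float
    frame_rate: float = 25.0
    bout_rate: float = 0.0          # events / s
    bout_speed: float = 10.0        # mm/s cruise speed of spontaneous bouts
    accel_duration: float = 0.2     # s
    cruise_duration: float = 0.3    # s cruise phase of spontaneous bouts
    tap_times: Sequence[float] = ()
    escape_peak_accel: float = 500.0  # mm/s^2
    escape_window: float = 0.28     # s
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duration", "bout_rate", "bout_speed", "accel_duration",
                     "cruise_duration", "escape_peak_accel"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        taps = list(self.tap_times)
        if taps != sorted(taps) or len(set(taps)) != len(taps):
            raise ValueError("tap_times must be strictly increasing")
        for tt in taps:
            if tt < 0 or tt + self.escape_window > self.duration:
                raise ValueError(
                    f"tap at {tt:g} s has no full escape window inside the "
                    f"{self.duration:g} s recording")


def _event_displacement(tau: np.ndarray, accel: float, t_accel: float,
                        t_total: float) -> np.ndarray:
    """Distance along the heading at time-since-onset ``tau``.

    Constant acceleration for ``t_accel``, constant velocity until
    ``t_total``, then stationary.
    """
    v = accel * t_accel
    d_accel = 0.5 * accel * t_accel**2
    out = np.zeros_like(tau)
    m1 = (tau >= 0) & (tau < t_accel)
    out[m1] = 0.5 * accel * tau[m1] ** 2
    m2 = (tau >= t_accel) & (tau < t_total)
    out[m2] = d_accel + v * (tau[m2] - t_accel)
    out[tau >= t_total] = d_accel + v * (t_total - t_accel)
    return out


def gen_centroid_track(params: TrackSimParams
                       ) -> tuple[CentroidTrack, dict]:
    """Simulate a centroid track with bout/glide and escape structure.

    Returns the track and a ground-truth dict with ``movements`` (a
    DataFrame of onsets/durations/distances) and ``escapes`` (per tap:
    true peak acceleration and time accelerating).
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.frame_rate))
    t = np.arange(n) / params.frame_rate
    x = np.zeros(n)
    y = np.zeros(n)

    bout_total = params.accel_duration + params.cruise_duration
    events: list[tuple[float, float, float, float]] = []  # onset, accel, t_acc, total

    # escapes at taps (frame-aligned onsets keep ground truth exact)
    for tt in params.tap_times:
        onset = round(tt * params.frame_rate) / params.frame_rate
        t_acc = min(params.accel_duration, params.escape_window)
        events.append((onset, params.escape_peak_accel, t_acc,
                       params.escape_window))

    # spontaneous bouts: Poisson onsets thinned to avoid any overlap
    if params.bout_rate > 0 and params.bout_speed > 0:
        accel = (params.bout_speed / params.accel_duration
                 if params.accel_duration > 0 else 0.0)
        n_cand = rng.poisson(params.bout_rate * params.duration)
        candidates = np.sort(rng.uniform(0.0, params.duration - bout_total,
                                         size=n_cand))
        guard = 0.2  # s of enforced quiescence around every event
        for onset in candidates:
            onset = round(onset * params.frame_rate) / params.frame_rate
            span = (onset - guard, onset + bout_total + guard)
            if any(not (span[1] <= s or span[0] >= s + tot)
                   for s, _, _, tot in events):
                continue
            if params.accel_duration > 0:
                events.append((onset, accel, params.accel_duration, bout_total))
            else:
                # instantaneous start: pure cruise
                events.append((onset, 0.0, 0.0, bout_total))

    events.sort()
    movement_rows = []
    escape_truth = []
    tap_set = {round(tt * params.frame_rate) / params.frame_rate
               for tt in params.tap_times}
    for onset, accel, t_acc, total in events:
        heading = rng.uniform(0.0, 2.0 * math.pi)
        tau = t - onset
        d = _event_displacement(tau, accel, t_acc, total)
        x += d * math.cos(heading)
        y += d * math.sin(heading)
        v = accel * t_acc
        distance = 0.5 * accel * t_acc**2 + v * (total - t_acc)
        is_escape = onset in tap_set
        movement_rows.append({
            "onset_s": onset,
            "onset_frame": int(round(onset * params.frame_rate)),
            "duration_s": total,
            "distance_mm": distance,
            "is_escape": is_escape,
        })
        if is_escape:
            escape_truth.append({
                "tap_time_s": onset,
                "peak_acceleration": accel,
                "time_accelerating_s": t_acc,
                "displacement_mm": distance,
            })

    track = CentroidTrack(frame_rate=params.frame_rate, x=x, y=y)
    truth = {
        "movements": pd.DataFrame(movement_rows),
        "escapes": pd.DataFrame(escape_truth),
    }
    return track, truth


# ---------------------------------------------------------------------------
# coiling signals
# ---------------------------------------------------------------------------

@dataclass
class CoilSimParams:
    """Parameters of simulated per-embryo motion-energy signals."""

    duration: float
    frame_rate: float = 50.0
    n_embryos: int = 1
    coil_rate: float = 0.05           # Hz
    coil_duration_mean: float = 0.4   # s
    intensity_scale: float = 50.0     # peak motion-energy amplitude
    baseline_noise_sd: float = 1.0
    baseline_level: float = 10.0      # constant offset keeping energy >= 0
    peak_times: Optional[Sequence[float]] = None  # deterministic override
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_embryos < 1:
            raise ValueError("n_embryos must be at least 1")
        if self.coil_rate < 0:
            raise ValueError("coil_rate must be non-negative")
        for name in ("duration", "frame_rate", "coil_duration_mean",
                     "intensity_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.baseline_noise_sd < 0 or self.baseline_level < 0:
            raise ValueError("baseline parameters must be non-negative")


def gen_coil_signal(params: CoilSimParams
                    ) -> tuple[list[CoilSignal], pd.DataFrame]:
    """Simulate motion-energy signals: noisy baseline plus Gaussian bumps.

    Bump centres arrive as a Poisson process thinned to keep peaks well
    separated; an event nominally spans centre +/- 2 sigma with
    sigma = coil_duration_mean / 4.  Ground truth per event: embryo, onset,
    duration, and area above baseline (in energy x frames).
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.frame_rate))
    t = np.arange(n) / params.frame_rate
    sigma = params.coil_duration_mean / 4.0

    signals = []
    gt_rows = []
    for e in range(params.n_embryos):
        base = np.full(n, params.baseline_level)
        if params.baseline_noise_sd > 0:
            base = base + rng.normal(0.0, params.baseline_noise_sd, n)
        if params.peak_times is not None:
            centers = np.asarray(params.peak_times, dtype=float)
        elif params.coil_rate > 0:
            n_cand = rng.poisson(params.coil_rate * params.duration)
            cand = np.sort(rng.uniform(2 * sigma, params.duration - 2 * sigma,
                                       size=n_cand))
            centers = []
            for c in cand:
                if centers and c - centers[-1] < 4 * sigma:
                    continue  # thinning: keep peaks disjoint
                centers.append(c)
            centers = np.asarray(centers)
        else:
            centers = np.empty(0)

        # where the bump crosses a k=3 robust threshold, for onset-recovery
        # checks (the generator knows its own noise level)
        if params.baseline_noise_sd > 0:
            ratio = params.intensity_scale / (3.0 * params.baseline_noise_sd)
            thr_half = (sigma * math.sqrt(2.0 * math.log(ratio))
                        if ratio > 1 else 0.0)
        else:
            thr_half = 2 * sigma
        sig = base
        for c in centers:
            sig = sig + params.intensity_scale * np.exp(
                -0.5 * ((t - c) / sigma) ** 2)
            gt_rows.append({
                "embryo_id": f"embryo{e}",
                "center_s": c,
                "onset_s": c - 2 * sigma,
                "onset_frame": int(round((c - 2 * sigma) * params.frame_rate)),
                "duration_s": 4 * sigma,
                "threshold_onset_frame": int(math.ceil(
                    (c - thr_half) * params.frame_rate)),
                "threshold_duration_s": 2 * thr_half,
                "area": params.intensity_scale * sigma
                        * math.sqrt(2 * math.pi) * params.frame_rate,
            })
        signals.append(CoilSignal(frame_rate=params.frame_rate,
                                  motion_energy=np.clip(sig, 0.0, None),
                                  embryo_id=f"embryo{e}"))
    columns = ["embryo_id", "center_s", "onset_s", "onset_frame",
               "duration_s", "threshold_onset_frame", "threshold_duration_s",
               "area"]
    return signals, pd.DataFrame(gt_rows, columns=columns)


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------

@dataclass
class CtPlateDesign:
    """Design of a simulated qPCR plate.

    ``samples`` maps sample_id -> group; ``true_log2_ratio`` maps
    (group, gene) -> true log2 expression ratio relative to the calibrator
    group (which must be 0 for the calibrator samples' group).
    """

    target_genes: Sequence[str]
    samples: dict
    calibrator_samples: Sequence[str]
    true_log2_ratio: dict = field(default_factory=dict)
    housekeeping: Sequence[str] = ("rpl13", "elfa")
    base_ct: float = 25.0
    housekeeping_ct: float = 20.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if len(self.housekeeping) < 1:
            raise ValueError("at least one housekeeping gene is required")
        if not set(self.calibrator_samples) <= set(self.samples):
            raise ValueError("calibrator samples must be on the plate")
        if not self.calibrator_samples:
            raise ValueError("at least one calibrator sample is required")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def gen_ct_plate(seed: int, design: CtPlateDesign):
    """Simulate a Ct table around the designed true expression ratios.

    A target gene's Ct is lowered by one cycle for every doubling of true
    expression; housekeeping genes sit at a common level.  Returns the
    CtTable and a ground-truth DataFrame of true log2 ratios / fold
    changes per (group, gene).
    """
    from .assays import CtTable  # local import avoids a cycle at import time

    rng = np.random.default_rng(seed)
    rows = []
    for sample_id, group in design.samples.items():
        for gene in design.housekeeping:
            ct = design.housekeeping_ct + (
                rng.normal(0.0, design.noise_sd) if design.noise_sd else 0.0)
            rows.append({"sample_id": sample_id, "group": group,
                         "gene": gene, "ct": ct})
        for gene in design.target_genes:
            ratio = design.true_log2_ratio.get((group, gene), 0.0)
            ct = design.base_ct - ratio + (
                rng.normal(0.0, design.noise_sd) if design.noise_sd else 0.0)
            rows.append({"sample_id": sample_id, "group": group,
                         "gene": gene, "ct": ct})
    table = CtTable(data=pd.DataFrame(rows),
                    calibrator_samples=list(design.calibrator_samples),
                    housekeeping=tuple(design.housekeeping))
    truth = pd.DataFrame([
        {"group": g, "gene": gene,
         "true_log2_ratio": design.true_log2_ratio.get((g, gene), 0.0),
         "true_fold_change": 2.0 ** design.true_log2_ratio.get((g, gene), 0.0)}
        for g in sorted(set(design.samples.values()))
        for gene in design.target_genes
    ])
    return table, truth
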