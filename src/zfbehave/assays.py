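"""Small quantitative assays: swim-tunnel Umax, ddCt expression, blot densitometry."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TunnelTrial",
    "CtTable",
    "BlotLane",
    "SubjectExcluded",
    "umax",
    "umax_table",
    "ddct",
    "band_quant",
    "HOUSEKEEPING_GENES",
]

HOUSEKEEPING_GENES = ("rpl13", "elfa")


class SubjectExcluded(ValueError):
    """Raised for trials that never produced a scorable measurement."""


# ---------------------------------------------------------------------------
# swim tunnel
# ---------------------------------------------------------------------------

@dataclass
class TunnelTrial:
    """One incremental-flow swim-tunnel run.

    ``failure_step`` is the 1-based index of the 1-min step during which
    the fish failed; 0 means it never initiated swimming.
    """

    failure_step: int
    body_length: float              # cm
    acclimation_speed: float = 4.5  # cm/s
    step_increment: float = 4.5     # cm/s
    step_length: float = 60.0       # s
    subject_id: str = "fish"

    def __post_init__(self) -> None:
        if self.step_increment <= 0:
            raise ValueError("step_increment must be positive")
        if self.body_length <= 0:
            raise ValueError("body_length must be positive")
        if self.failure_step < 0:
            raise ValueError("failure_step must be >= 0")


def umax(trial: TunnelTrial) -> tuple[float, float]:
    """Maximum sustained speed: the last completed step before failure.

    Returns (cm/s, body lengths/s).  Failure during step 1 credits the
    acclimation speed (the published rule only covers later steps);
    a fish that never started (failure_step 0) is excluded.
    """
    if trial.failure_step == 0:
        raise SubjectExcluded(
            f"{trial.subject_id}: never initiated swimming; excluded")
    if trial.failure_step == 1:
        u = trial.acclimation_speed
    else:
        u = trial.step_increment * (trial.failure_step - 1)
    return u, u / trial.body_length


def umax_table(trials: Sequence[TunnelTrial]) -> pd.DataFrame:
    """Score a batch of trials, skipping excluded subjects with a warning."""
    rows = []
    for tr in trials:
        try:
            u_cm, u_bl = umax(tr)
        except SubjectExcluded as exc:
            logger.warning("%s", exc)
            continue
        rows.append({"subject_id": tr.subject_id,
                     "failure_step": tr.failure_step,
                     "body_length_cm": tr.body_length,
                     "umax_cm_s": u_cm, "umax_bl_s": u_bl})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# relative expression (ddCt)
# ---------------------------------------------------------------------------

@dataclass
class CtTable:
    """Tidy qPCR Ct measurements with housekeeping genes and calibrators.

    ``data`` columns: sample_id, group, gene, ct.
    """

    data: pd.DataFrame
    calibrator_samples: Sequence[str]
    housekeeping: Sequence[str] = HOUSEKEEPING_GENES

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "gene", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        if not list(self.calibrator_samples):
            raise ValueError("at least one calibrator sample is required")

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def ddct(table: CtTable) -> pd.DataFrame:
    """Relative quantity by the delta-delta-Ct method.

    dCt = Ct_target - mean(housekeeping Cts); ddCt subtracts the mean dCt
    of the calibrator samples per gene; RQ = 2**(-ddCt).  Samples missing
    a housekeeping measurement are dropped with a warning.  Housekeeping
    Cts are combined by their arithmetic mean (geometric mean expression).
    """
    df = table.data
    hk = df[df["gene"].isin(table.housekeeping)]
    hk_counts = hk.groupby("sample_id")["gene"].nunique()
    complete = set(hk_counts[hk_counts == len(table.housekeeping)].index)
    dropped = set(df["sample_id"]) - complete
    if dropped:
        logger.warning("samples missing a housekeeping gene, dropped: %s",
                       sorted(dropped))
    df = df[df["sample_id"].isin(complete)]
    hk_mean = (df[df["gene"].isin(table.housekeeping)]
               .groupby("sample_id")["ct"].mean())

    targets = df[~df["gene"].isin(table.housekeeping)].copy()
    targets["dct"] = targets["ct"] - targets["sample_id"].map(hk_mean)

    cal = targets[targets["sample_id"].isin(table.calibrator_samples)]
    if cal.empty:
        raise ValueError("no calibrator samples present after filtering")
    cal_dct = cal.groupby("gene")["dct"].mean()
    targets["ddct"] = targets["dct"] - targets["gene"].map(cal_dct)
    targets["rq"] = 2.0 ** (-targets["ddct"])
    return targets[["sample_id", "group", "gene", "ct", "dct", "ddct", "rq"]]


# ---------------------------------------------------------------------------
# blot densitometry
# ---------------------------------------------------------------------------

@dataclass
class BlotLane:
    """ROI mean intensities (8-bit) for target and loading-control bands."""

    target_band: float
    target_background: float
    control_band: float
    control_background: float
    roi_area: int = 1
    lane_id: str = "lane"

    def __post_init__(self) -> None:
        for name in ("target_band", "target_background",
                     "control_band", "control_background"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name} must lie in [0, 255] (8-bit units)")
        if self.roi_area <= 0:
            raise ValueError("roi_area must be positive")


def _relative_expression(lane: BlotLane) -> float:
    net_target = lane.target_band - lane.target_background
    net_control = lane.control_band - lane.control_background
    if net_control <= 0:
        raise ValueError(
            f"{lane.lane_id}: loading-control net intensity <= 0; lane invalid")
    return net_target / net_control


def band_quant(mutant: BlotLane, control: BlotLane) -> tuple[float, float, float]:
    """Background-subtracted target/loading-control ratio per lane.

    Returns (relative_mutant, relative_control, percent_reduction) where
    percent_reduction = 100 * (1 - relative_mutant / relative_control).
    """
    rel_mut = _relative_expression(mutant)
    rel_ctl = _relative_expression(control)
    if rel_ctl == 0:
        raise ValueError("control lane has zero relative expression")
    return rel_mut, rel_ctl, 100.0 * (1.0 - rel_mut / rel_ctl)
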