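"""Hierarchical run configuration with validated keys.

One YAML file carries every tunable of the pipelines; command-line flags
override file values, which override the documented defaults (the numeric
defaults are the protocol constants: 15-frame/3-point smoothing, 35 deg /
60 Hz splits, 280 ms escape window, 40 ms and 10 min bins, 4.5 cm/s
tunnel steps of 60 s, and 1000/50/25 fps frame rates).
"""

from __future__ import annotations

import copy
import logging
from typing import Any, Optional

import yaml

logger = logging.getLogger(__name__)

__all__ = ["DEFAULTS", "load_config", "merge_config", "RunConfig"]

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "tail": {
        "frame_rate": 1000.0,
        "deflection_split": 35.0,
        "frequency_split": 60.0,
        "smooth_frames": 15,
        "smooth_points": 3,
        "min_active_deflection": 3.0,
        "min_quiescence": 0.05,
    },
    "track": {
        "frame_rate": 25.0,
        "start_thr": 2.0,
        "stop_thr": 1.6,
        "bin_s": 600.0,
        "escape_window_ms": 280.0,
        "escape_bin_ms": 40.0,
    },
    "coil": {
        "frame_rate": 50.0,
        "k_sd": 3.0,
        "merge_gap_ms": 40.0,
        "recording_s": 300.0,
    },
    "umax": {
        "acclimation_speed": 4.5,
        "step_increment": 4.5,
        "step_length": 60.0,
    },
    "qpcr": {
        "housekeeping": ["rpl13", "elfa"],
    },
    "stats": {
        "alpha": 0.05,
    },
}


class RunConfig(dict):
    """Validated nested configuration (a thin dict wrapper)."""

    def section(self, name: str) -> dict:
        return self[name]


def _check_keys(user: dict, reference: dict, path: str = "") -> None:
    for key, value in user.items():
        if key not in reference:
            raise KeyError(f"unknown config key {path + key!r}")
        if isinstance(reference[key], dict):
            if not isinstance(value, dict):
                raise TypeError(f"config key {path + key!r} must be a mapping")
            _check_keys(value, reference[key], path + key + ".")


def merge_config(base: dict, override: Optional[dict]) -> RunConfig:
    """Deep-merge ``override`` into ``base`` after key validation."""
    merged = copy.deepcopy(base)
    if override:
        _check_keys(override, base)
        stack = [(merged, override)]
        while stack:
            dst, src = stack.pop()
            for k, v in src.items():
                if isinstance(v, dict):
                    stack.append((dst[k], v))
                else:
                    dst[k] = v
    return RunConfig(merged)


def load_config(path: Optional[str] = None) -> RunConfig:
    """Load YAML config merged over the defaults; log the effective values."""
    override = None
    if path is not None:
        with open(path) as fh:
            override = yaml.safe_load(fh) or {}
    cfg = merge_config(DEFAULTS, override)
    logger.info("effective configuration: %s", dict(cfg))
    return cfg
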