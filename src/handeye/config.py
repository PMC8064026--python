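"""Pipeline configuration: every numeric constant of the analysis in one
place, with YAML round-tripping.

Defaults are the analysis conventions: 10 Hz kinematic / 30 Hz gaze
dual-pass Butterworth cutoffs (2nd order per pass), the 90 Hz common
grid, 50 mm/s x 3-frame velocity criteria, the 1 N grasp threshold, the
5 x median / 5-frame saccade rule, the 1 degree / 100 ms I-DT rule, a
0.5 s maximum cross-correlation lag, the 18-valid-trial inclusion rule
and the 5th/15th MABC-2 percentile group cut-offs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

from .exceptions import ConfigurationError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # sample rates (Hz)
    gaze_rate: float = 90.0
    kin_rate: float = 120.0
    force_rate: float = 500.0
    # filtering
    kin_cutoff_hz: float = 10.0
    gaze_cutoff_hz: float = 30.0
    filter_order: int = 2  # per pass; the dual pass doubles the effective order
    max_interp_gap_s: float = 0.1
    # kinematic event detection
    speed_threshold_mm_s: float = 50.0
    speed_run_frames: int = 3
    grip_threshold_n: float = 1.0
    # gaze event detection
    saccade_multiplier: float = 5.0
    saccade_run_frames: int = 5
    dispersion_threshold_deg: float = 1.0
    min_fixation_s: float = 0.1
    # coupling
    max_lag_s: float = 0.5
    min_overlap_frames: int = 10
    min_overlap_fraction: float = 0.5
    # screening
    min_valid_trials: int = 18
    dcd_percentile_max: float = 5.0
    control_percentile_min: float = 15.0
    # inference
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            "gaze_rate", "kin_rate", "force_rate", "kin_cutoff_hz",
            "gaze_cutoff_hz", "filter_order", "speed_threshold_mm_s",
            "speed_run_frames", "grip_threshold_n", "saccade_multiplier",
            "saccade_run_frames", "dispersion_threshold_deg", "min_fixation_s",
            "max_lag_s", "min_overlap_frames",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not (0 < self.alpha < 1):
            raise ConfigurationError("alpha must be in (0, 1)")

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
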