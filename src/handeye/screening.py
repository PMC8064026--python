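"""Data-quality screening, inclusion rules and group assignment.

Trials carry a qualitative quality code 0-4 assigned by video review
(consumed here as data): 0 = procedure not followed, 1 = tracking too
poor to use, 2 = usable but with quality issues, 3 = very minor issues,
4 = clean. Codes 0-2 are removed; participants keep their data only if
at least 18 valid trials (50% of the 37-lift protocol) remain.

Groups follow MABC-2 percentile bands: at or below the 5th percentile is
DCD, above the 15th is Control, and the band in between is Intermediate
(retained for correlational analyses, dropped from group tests).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .exceptions import ConfigurationError

__all__ = [
    "GROUP_DCD",
    "GROUP_CONTROL",
    "GROUP_INTERMEDIATE",
    "TrialQuality",
    "ParticipantRecord",
    "filter_valid_trials",
    "participant_inclusion",
    "assign_group",
]

VALID_QUALITY_CODES = frozenset({3, 4})
MIN_VALID_TRIALS = 18
DCD_PERCENTILE_MAX = 5.0
CONTROL_PERCENTILE_MIN = 15.0

GROUP_DCD = "DCD"
GROUP_CONTROL = "Control"
GROUP_INTERMEDIATE = "Intermediate"


@dataclass(frozen=True)
class TrialQuality:
    """Per-trial qualitative quality code (0-4) with optional notes."""

    code: int
    notes: str = ""

    def __post_init__(self) -> None:
        if self.code not in (0, 1, 2, 3, 4):
            raise ConfigurationError(f"quality code must be 0-4, got {self.code}")


@dataclass
class ParticipantRecord:
    """Traits and group label for one participant."""

    id: str
    mabc2_standard_score: float
    mabc2_percentile: float
    dcdq_score: float
    aq_score: float
    adhd_score: float
    group: str = ""
    n_valid_trials: int = 0
    included: bool = True

    def __post_init__(self) -> None:
        if not self.group:
            self.group = assign_group(self.mabc2_percentile)


def filter_valid_trials(
    trials: Sequence, codes: Iterable[int | TrialQuality]
) -> list:
    """Keep only trials whose quality code is 3 or 4.

    ``trials`` and ``codes`` are parallel; a missing code is an error.
    """
    trials = list(trials)
    codes = list(codes)
    if len(codes) != len(trials):
        raise ConfigurationError(
            f"{len(trials)} trials but {len(codes)} quality codes"
        )
    out = []
    for trial, code in zip(trials, codes):
        if code is None:
            raise ConfigurationError("trial is missing a quality code")
        value = code.code if isinstance(code, TrialQuality) else int(code)
        TrialQuality(value)  # validates range
        if value in VALID_QUALITY_CODES:
            out.append(trial)
    return out


def participant_inclusion(
    valid_trial_count: int, min_valid: int = MIN_VALID_TRIALS
) -> bool:
    """Include a participant iff at least ``min_valid`` valid trials remain."""
    if valid_trial_count < 0:
        raise ConfigurationError("valid trial count cannot be negative")
    return valid_trial_count >= min_valid


def assign_group(mabc2_percentile: float) -> str:
    """Group label from the MABC-2 percentile.

    At or below the 5th percentile -> DCD; strictly above the 15th ->
    Control; the half-open band (5, 15] -> Intermediate.
    """
    p = float(mabc2_percentile)
    if not (0.0 <= p <= 100.0):
        raise ConfigurationError(f"percentile must be in [0, 100], got {p}")
    if p <= DCD_PERCENTILE_MAX:
        return GROUP_DCD
    if p > CONTROL_PERCENTILE_MIN:
        return GROUP_CONTROL
    return GROUP_INTERMEDIATE
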