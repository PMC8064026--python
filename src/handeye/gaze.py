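"""Saccade and fixation detection and gaze-anchoring metrics.

Saccades are detected from the magnitude of gaze acceleration: the
threshold is five times the median absolute acceleration of the analysed
segment (self-scaling, so detection is invariant to rescaling of the
position signal), and a saccade is a maximal run of at least five
consecutive valid frames above threshold that is not immediately
preceded or followed by missing data.

Fixations use dispersion-threshold identification (I-DT): a window is
grown from the 100 ms minimum duration; if its dispersion — the sum of
the x and y ranges — is within 1 degree it is extended greedily until
the next sample would break the threshold, and emitted with its centroid;
otherwise the window slides by one frame. Windows never span invalid
samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import AllInvalidError, SeriesError
from .series import UniformSeries

__all__ = [
    "GazeEvent",
    "GazeEventSummary",
    "detect_saccades",
    "detect_fixations",
    "event_rates",
    "final_fixation_onset",
]

SACCADE_MEDIAN_MULTIPLIER = 5.0
SACCADE_RUN_LENGTH = 5
DISPERSION_THRESHOLD_DEG = 1.0
MIN_FIXATION_S = 0.1
# Absolute floor on the acceleration threshold. Far below any saccadic
# acceleration (which is O(10^3) deg/s^2) yet far above filter-ringing
# residue, it keeps degenerate noise-free segments from turning
# numerical dust into runs. Constraint: 5 x median of an all-quiet
# segment is otherwise numerically zero.
ACCEL_FLOOR_DEG_S2 = 1.0


@dataclass(frozen=True)
class GazeEvent:
    """A saccade or fixation with onset/offset times (s).

    ``centroid`` is the mean (x, y) position in degrees, fixations only.
    """

    kind: str  # "saccade" | "fixation"
    onset: float
    offset: float
    centroid: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("saccade", "fixation"):
            raise SeriesError(f"unknown gaze event kind {self.kind!r}")
        if self.offset <= self.onset:
            raise SeriesError("gaze event offset must follow onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class GazeEventSummary:
    """Per-phase event rates plus the gaze-anchoring metric."""

    phase: str  # "reach" | "lift"
    saccade_rate: float  # events/s, onset-based counting
    fixation_rate: float  # events/s
    final_fixation_onset_rel: float | None = None  # s relative to reach onset


def detect_saccades(
    gaze_accel: UniformSeries,
    validity: np.ndarray | None = None,
    multiplier: float = SACCADE_MEDIAN_MULTIPLIER,
    run_length: int = SACCADE_RUN_LENGTH,
) -> list[GazeEvent]:
    """Acceleration-threshold saccade detection on one analysed segment.

    ``gaze_accel`` holds the scalar acceleration magnitude (deg/s^2) of
    the segment; the threshold is ``multiplier`` times the median of the
    valid samples. Runs adjacent to an invalid frame are rejected
    (blinks and tracker dropouts produce spurious transients).
    """
    accel = np.abs(gaze_accel.values)
    if accel.ndim != 1:
        raise SeriesError("saccade detection expects a scalar acceleration series")
    if validity is None:
        validity = gaze_accel.validity
    valid = (
        np.ones(accel.size, dtype=bool)
        if validity is None
        else np.asarray(validity, dtype=bool)
    )
    if not valid.any():
        raise AllInvalidError("all samples in the segment are invalid")
    threshold = max(
        multiplier * float(np.median(accel[valid])), ACCEL_FLOOR_DEG_S2
    )
    mask = (accel > threshold) & valid
    edges = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False]))))
    t = gaze_accel.times
    events: list[GazeEvent] = []
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start < run_length:
            continue
        if start > 0 and not valid[start - 1]:
            continue
        if stop < accel.size and not valid[stop]:
            continue
        events.append(GazeEvent("saccade", float(t[start]), float(t[stop - 1])))
    return events


def _dispersion(x: np.ndarray, y: np.ndarray) -> float:
    return float((x.max() - x.min()) + (y.max() - y.min()))


def detect_fixations(
    gaze_xy: UniformSeries,
    validity: np.ndarray | None = None,
    dispersion_threshold: float = DISPERSION_THRESHOLD_DEG,
    min_duration: float = MIN_FIXATION_S,
) -> list[GazeEvent]:
    """I-DT fixation detection (dispersion = sum of coordinate ranges).

    The minimum window covers ``min_duration`` seconds of span; windows
    are grown greedily and may not span invalid samples. Consecutive
    fixations are separated by at least one frame by construction.
    """
    if gaze_xy.values.ndim != 2 or gaze_xy.width != 2:
        raise SeriesError("fixation detection expects a 2-D (x, y) gaze series")
    x = gaze_xy.values[:, 0]
    y = gaze_xy.values[:, 1]
    n = gaze_xy.n
    if validity is None:
        validity = gaze_xy.validity
    valid = (
        np.ones(n, dtype=bool) if validity is None else np.asarray(validity, dtype=bool)
    )
    # min window: enough frames that offset - onset >= min_duration
    w = int(np.ceil(min_duration * gaze_xy.rate)) + 1
    if n < w:
        return []
    t = gaze_xy.times
    events: list[GazeEvent] = []
    i = 0
    while i + w <= n:
        j = i + w  # window is [i, j)
        if not valid[i:j].all():
            i += 1
            continue
        if _dispersion(x[i:j], y[i:j]) > dispersion_threshold:
            i += 1
            continue
        # greedy extension one sample at a time
        while (
            j < n
            and valid[j]
            and _dispersion(x[i : j + 1], y[i : j + 1]) <= dispersion_threshold
        ):
            j += 1
        events.append(
            GazeEvent(
                "fixation",
                float(t[i]),
                float(t[j - 1]),
                centroid=(float(x[i:j].mean()), float(y[i:j].mean())),
            )
        )
        i = j + 1  # next fixation can start no earlier than one frame later
    return events


def event_rates(
    events: list[GazeEvent], phase_window: tuple[float, float], phase: str = "lift"
) -> GazeEventSummary:
    """Onset-based event rates (events/s) within a phase window.

    An event belongs to the phase that contains its onset.
    """
    start, end = phase_window
    if end <= start:
        raise SeriesError("phase window must have positive duration")
    duration = end - start
    n_sacc = sum(1 for e in events if e.kind == "saccade" and start <= e.onset < end)
    n_fix = sum(1 for e in events if e.kind == "fixation" and start <= e.onset < end)
    return GazeEventSummary(
        phase=phase,
        saccade_rate=n_sacc / duration,
        fixation_rate=n_fix / duration,
    )


def final_fixation_onset(events: list[GazeEvent], seg) -> float | None:
    """Onset of the last fixation beginning before grasp, re reach onset.

    Returns seconds relative to reach onset (negative when the final
    pre-contact fixation began before the reach itself), or ``None``
    when no fixation started before object contact.
    """
    pre = [e for e in events if e.kind == "fixation" and e.onset < seg.grasp_onset]
    if not pre:
        return None
    return float(max(e.onset for e in pre) - seg.reach_onset)
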