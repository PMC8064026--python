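"""Reach/grasp/lift segmentation and reach kinematic metrics.

A lift trial is segmented with three events:

* **grasp onset** — first grip-force sample strictly exceeding 1 N;
* **reach onset** — first frame of the earliest run of >= 3 consecutive
  frames with hand speed strictly above 50 mm/s, before grasp onset;
* **lift offset** — first frame of the first run of >= 3 consecutive
  frames with object speed strictly below 50 mm/s, after the object has
  first exceeded 50 mm/s following grasp onset.

Thresholds are strict inequalities; ties at exactly the threshold do not
count, which keeps detection deterministic on synthetic data. Event
times are expressed on the common 90 Hz grid after resampling; the grasp
time found on the 500 Hz force stream is rounded to the nearest 90 Hz
frame when synchronising streams (see :mod:`handeye.coupling`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import LiftDetectionError, NoGraspError, NoReachError, SeriesError
from .series import UniformSeries

__all__ = [
    "EventSegmentation",
    "ReachMetrics",
    "detect_grasp_onset",
    "detect_reach_onset",
    "detect_lift_offset",
    "reach_metrics",
    "run_starts",
]

GRIP_THRESHOLD_N = 1.0
SPEED_THRESHOLD_MM_S = 50.0
RUN_LENGTH = 3


@dataclass(frozen=True)
class EventSegmentation:
    """Reach onset / grasp onset / lift offset times for one trial."""

    reach_onset: float
    grasp_onset: float
    lift_offset: float
    trial_onset: float = 0.0

    def __post_init__(self) -> None:
        if not (
            self.trial_onset <= self.reach_onset
            < self.grasp_onset
            < self.lift_offset
        ):
            raise SeriesError(
                "event ordering violated: require trial_onset <= reach_onset "
                f"< grasp_onset < lift_offset, got {self}"
            )


@dataclass(frozen=True)
class ReachMetrics:
    """Duration, peak speed, and relative time-to-peak of the reach."""

    movement_duration: float  # s, reach onset -> grasp onset
    max_hand_velocity: float  # mm/s
    time_to_peak_velocity: float  # % of reach movement time


def run_starts(mask: np.ndarray, run_length: int) -> np.ndarray:
    """Start indices of maximal True runs of at least ``run_length``."""
    mask = np.asarray(mask, dtype=bool)
    edges = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False]))))
    starts, stops = edges[::2], edges[1::2]
    return starts[(stops - starts) >= run_length]


def detect_grasp_onset(
    grip_force: UniformSeries, threshold: float = GRIP_THRESHOLD_N
) -> float:
    """Time of the first grip-force sample strictly exceeding ``threshold`` N."""
    above = np.flatnonzero(grip_force.values > threshold)
    if above.size == 0:
        raise NoGraspError(f"grip force never exceeded {threshold} N")
    return float(grip_force.times[above[0]])


def detect_reach_onset(
    hand_speed: UniformSeries,
    grasp_onset: float,
    threshold: float = SPEED_THRESHOLD_MM_S,
    run_length: int = RUN_LENGTH,
) -> float:
    """First frame of the earliest sustained supra-threshold hand-speed run.

    The search is restricted to frames strictly before ``grasp_onset``
    (put-down movements at trial end can therefore never qualify).
    """
    t = hand_speed.times
    window = t < grasp_onset
    if not window.any():
        raise NoReachError("no hand-speed samples before grasp onset")
    mask = (hand_speed.values > threshold) & window
    starts = run_starts(mask, run_length)
    if starts.size == 0:
        raise NoReachError(
            f"hand speed never exceeded {threshold} mm/s for "
            f"{run_length} consecutive frames before grasp onset"
        )
    return float(t[starts[0]])


def detect_lift_offset(
    object_speed: UniformSeries,
    grasp_onset: float,
    threshold: float = SPEED_THRESHOLD_MM_S,
    run_length: int = RUN_LENGTH,
) -> float:
    """First frame of the first sustained sub-threshold run after the lift.

    The object must first exceed ``threshold`` after ``grasp_onset``
    (i.e. actually move); the offset is the first frame of the first run
    of ``run_length`` consecutive frames strictly below threshold after
    that point. A single sub-threshold frame mid-lift does not end it.
    """
    t = object_speed.times
    v = object_speed.values
    after_grasp = t >= grasp_onset
    moving = np.flatnonzero((v > threshold) & after_grasp)
    if moving.size == 0:
        raise LiftDetectionError(
            f"object speed never exceeded {threshold} mm/s after grasp onset"
        )
    first_move = moving[0]
    below = v < threshold
    below[: first_move + 1] = False
    starts = run_starts(below, run_length)
    if starts.size == 0:
        raise LiftDetectionError("object never re-stabilised after the lift")
    return float(t[starts[0]])


def reach_metrics(hand_speed: UniformSeries, seg: EventSegmentation) -> ReachMetrics:
    """Reach metrics over ``[reach_onset, grasp_onset]``.

    Duration is grasp minus reach onset; the peak is the maximum hand
    speed in the window; time-to-peak is the peak's latency expressed as
    a percentage of the reach movement time.
    """
    t = hand_speed.times
    window = (t >= seg.reach_onset) & (t <= seg.grasp_onset)
    if window.sum() < 2:
        raise SeriesError("reach window is degenerate (fewer than two frames)")
    duration = seg.grasp_onset - seg.reach_onset
    v = hand_speed.values[window]
    tw = t[window]
    i_peak = int(np.argmax(v))
    return ReachMetrics(
        movement_duration=float(duration),
        max_hand_velocity=float(v[i_peak]),
        time_to_peak_velocity=float(100.0 * (tw[i_peak] - seg.reach_onset) / duration),
    )
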