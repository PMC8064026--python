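"""End-to-end orchestration: preprocess -> events -> coupling -> screening
-> group statistics, for in-memory cohorts and on-disk trial directories.

Every per-trial failure (no grasp, no reach, segment too short, gaze gap
through the lift segment, ...) is caught and logged; the trial is
excluded by the screening rules rather than aborting the run.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import gaze as gz
from . import io as hio
from . import preprocess as pp
from .config import PipelineConfig
from .coupling import CouplingResult, HandEyeCoupling, synchronize
from .exceptions import HandEyeError
from .kinematics import (
    EventSegmentation,
    ReachMetrics,
    detect_grasp_onset,
    detect_lift_offset,
    detect_reach_onset,
    reach_metrics,
)
from .screening import GROUP_CONTROL, GROUP_DCD, filter_valid_trials, participant_inclusion
from .series import FilterSpec, UniformSeries
from .simulate import Cohort, ParticipantData, TrialRecording
from .stats import GroupStudy, GroupStudyResults

__all__ = [
    "TrialResult",
    "process_trial",
    "summarize_participant",
    "run_cohort",
    "run_pipeline",
    "OUTCOME_COLUMNS",
]

logger = logging.getLogger("handeye.pipeline")

OUTCOME_COLUMNS = [
    "median_peak_r",
    "median_lag_s",
    "saccade_rate_reach",
    "saccade_rate_lift",
    "fixation_rate_reach",
    "fixation_rate_lift",
    "median_final_fixation_onset_s",
    "mean_movement_duration_s",
    "mean_max_hand_velocity",
    "mean_time_to_peak_pct",
]


@dataclass
class TrialResult:
    """Everything the pipeline measured on one trial."""

    participant: str
    trial: int
    segmentation: EventSegmentation
    reach: ReachMetrics
    coupling: CouplingResult | None = None
    saccades: list = dataclasses.field(default_factory=list)
    fixations: list = dataclasses.field(default_factory=list)
    reach_summary: gz.GazeEventSummary | None = None
    lift_summary: gz.GazeEventSummary | None = None
    final_fixation_onset_s: float | None = None


def _kinematic_speed(series: UniformSeries, config: PipelineConfig) -> UniformSeries:
    """10 Hz-filter a 3-D position stream, resample to the 90 Hz gaze
    grid, and return the resultant (Euclidean) speed."""
    filtered = pp.butterworth_zero_phase(
        series, FilterSpec(config.kin_cutoff_hz, config.filter_order)
    )
    resampled = pp.resample_uniform(filtered, config.gaze_rate)
    return pp.resultant_magnitude(pp.finite_difference(resampled))


def _prepare_gaze(
    rec: TrialRecording, config: PipelineConfig
) -> tuple[UniformSeries, UniformSeries, np.ndarray]:
    """Interpolate short gaps, filter valid segments at 30 Hz.

    Returns the filtered 2-D gaze series (for derivatives and coupling),
    the gap-interpolated unfiltered series (for dispersion-based
    fixation detection, which must not see the zero-phase filter's step
    ringing), and the original validity flags (interpolated frames stay
    invalid for the saccade adjacency rule).
    """
    interpolated = pp.interpolate_gaps(rec.gaze, config.max_interp_gap_s)
    spec = FilterSpec(config.gaze_cutoff_hz, config.filter_order)
    values = interpolated.values.copy()
    for i0, i1 in pp.valid_segments(interpolated, min_len=3 * config.filter_order + 1):
        seg = interpolated.crop_index(i0, i1)
        values[i0:i1] = pp.butterworth_zero_phase(seg, spec).values
    validity = (
        rec.gaze.validity
        if rec.gaze.validity is not None
        else np.ones(rec.gaze.n, dtype=bool)
    )
    filtered = UniformSeries(rec.gaze.rate, values, rec.gaze.t0, validity)
    return filtered, interpolated, validity


def _gaze_events_for_phase(
    filtered: UniformSeries,
    unfiltered: UniformSeries,
    validity: np.ndarray,
    window: tuple[float, float],
    phase: str,
    config: PipelineConfig,
) -> tuple[list, list, gz.GazeEventSummary]:
    """Detect saccades and fixations within one phase window.

    The saccade threshold (5 x median absolute acceleration) is computed
    on the analysed segment itself, per the detection convention.
    Dispersion-based fixation detection runs on the unfiltered
    (gap-interpolated) positions.
    """
    i0 = filtered.index_at(window[0])
    i1 = filtered.index_at(window[1]) + 1
    seg = filtered.crop_index(i0, i1)
    seg_valid = validity[i0:i1]
    finite = np.isfinite(seg.values).all(axis=1)
    # acceleration magnitude: second forward differences of the filtered signal
    accel = pp.resultant_magnitude(pp.finite_difference(pp.finite_difference(seg)))
    accel_valid = seg_valid[:-2] & seg_valid[1:-1] & seg_valid[2:]
    accel_finite = finite[:-2] & finite[1:-1] & finite[2:]
    saccades = gz.detect_saccades(
        accel,
        accel_valid & accel_finite,
        multiplier=config.saccade_multiplier,
        run_length=config.saccade_run_frames,
    )
    raw_seg = unfiltered.crop_index(i0, i1)
    fixations = gz.detect_fixations(
        raw_seg,
        np.isfinite(raw_seg.values).all(axis=1),
        # I-DT may span short interpolated gaps, not unfilled ones
        dispersion_threshold=config.dispersion_threshold_deg,
        min_duration=config.min_fixation_s,
    )
    summary = gz.event_rates(saccades + fixations, window, phase)
    return saccades, fixations, summary


def process_trial(
    rec: TrialRecording,
    config: PipelineConfig | None = None,
    gaze_events: bool = True,
) -> TrialResult:
    """Run the full per-trial analysis.

    ``gaze_events=False`` skips saccade/fixation detection (the coupling
    path does not need it), which matters when simulating thousands of
    cohorts for calibration.
    """
    config = config or PipelineConfig()
    grasp = detect_grasp_onset(rec.force, config.grip_threshold_n)
    wrist_90 = pp.resample_uniform(
        pp.butterworth_zero_phase(
            rec.wrist, FilterSpec(config.kin_cutoff_hz, config.filter_order)
        ),
        config.gaze_rate,
    )
    hand_speed = pp.resultant_magnitude(pp.finite_difference(wrist_90))
    object_speed = _kinematic_speed(rec.obj, config)
    # events live on the 90 Hz grid: round the force-derived grasp time
    grasp = round(grasp * config.gaze_rate) / config.gaze_rate
    reach_onset = detect_reach_onset(
        hand_speed, grasp, config.speed_threshold_mm_s, config.speed_run_frames
    )
    lift_offset = detect_lift_offset(
        object_speed, grasp, config.speed_threshold_mm_s, config.speed_run_frames
    )
    seg = EventSegmentation(
        reach_onset=reach_onset, grasp_onset=grasp, lift_offset=lift_offset
    )
    metrics = reach_metrics(hand_speed, seg)
    result = TrialResult(
        participant=rec.participant,
        trial=rec.trial,
        segmentation=seg,
        reach=metrics,
    )

    # hand vertical: filtered wrist z on the gaze grid
    hand_vertical = wrist_90.column(2)
    gaze_filtered, gaze_raw, validity = _prepare_gaze(rec, config)
    eye_vertical = gaze_filtered.column(1)
    try:
        pair = synchronize(hand_vertical, eye_vertical, seg, config.min_overlap_frames)
        if not np.isfinite(pair.eye_vertical.values).all():
            raise HandEyeError("gaze gap crosses the grasp-to-lift segment")
        result.coupling = HandEyeCoupling(
            pair,
            max_lag=config.max_lag_s,
            min_overlap=config.min_overlap_frames,
            min_overlap_frac=config.min_overlap_fraction,
        ).fit()
    except HandEyeError as exc:
        # invalid for coupling only; segmentation and gaze events still count
        logger.debug("%s trial %d: no coupling (%s)", rec.participant, rec.trial, exc)
        result.coupling = None

    if gaze_events:
        reach_win = (rec.gaze.t0, grasp)
        lift_win = (grasp, lift_offset)
        saccades_r, fixations_r, result.reach_summary = _gaze_events_for_phase(
            gaze_filtered, gaze_raw, validity, reach_win, "reach", config
        )
        saccades_l, fixations_l, result.lift_summary = _gaze_events_for_phase(
            gaze_filtered, gaze_raw, validity, lift_win, "lift", config
        )
        result.saccades = saccades_r + saccades_l
        result.fixations = fixations_r + fixations_l
        result.final_fixation_onset_s = gz.final_fixation_onset(
            fixations_r + fixations_l, seg
        )
    return result


def _mean_or_nan(values: list) -> float:
    return float(np.mean(values)) if values else float("nan")


def _median_or_nan(values: list) -> float:
    return float(np.median(values)) if values else float("nan")


def summarize_participant(
    p: ParticipantData,
    config: PipelineConfig | None = None,
    gaze_events: bool = True,
) -> tuple[dict, list[TrialResult]]:
    """Screen, process and aggregate one participant.

    Aggregation follows the per-metric convention: medians for peak R,
    lag and final-fixation onset; means for event rates and reach
    metrics.
    """
    config = config or PipelineConfig()
    valid_trials = filter_valid_trials(p.trials, p.quality_codes)
    included = participant_inclusion(len(valid_trials), config.min_valid_trials)
    results: list[TrialResult] = []
    for rec in valid_trials:
        try:
            results.append(process_trial(rec, config, gaze_events=gaze_events))
        except HandEyeError as exc:
            logger.debug("%s trial %d failed: %s", p.id, rec.trial, exc)
    row = {
        "participant": p.id,
        "group": p.group,
        **p.traits,
        "n_valid_trials": len(valid_trials),
        "n_analysed_trials": len(results),
        "included": included and len(results) > 0,
        "median_peak_r": _median_or_nan([r.coupling.peak_r for r in results if r.coupling]),
        "median_lag_s": _median_or_nan([r.coupling.lag_s for r in results if r.coupling]),
        "mean_movement_duration_s": _mean_or_nan([r.reach.movement_duration for r in results]),
        "mean_max_hand_velocity": _mean_or_nan([r.reach.max_hand_velocity for r in results]),
        "mean_time_to_peak_pct": _mean_or_nan([r.reach.time_to_peak_velocity for r in results]),
    }
    if gaze_events:
        row.update(
            saccade_rate_reach=_mean_or_nan(
                [r.reach_summary.saccade_rate for r in results if r.reach_summary]
            ),
            saccade_rate_lift=_mean_or_nan(
                [r.lift_summary.saccade_rate for r in results if r.lift_summary]
            ),
            fixation_rate_reach=_mean_or_nan(
                [r.reach_summary.fixation_rate for r in results if r.reach_summary]
            ),
            fixation_rate_lift=_mean_or_nan(
                [r.lift_summary.fixation_rate for r in results if r.lift_summary]
            ),
            median_final_fixation_onset_s=_median_or_nan(
                [
                    r.final_fixation_onset_s
                    for r in results
                    if r.final_fixation_onset_s is not None
                ]
            ),
        )
    return row, results


def run_cohort(
    cohort: Cohort | list[ParticipantData],
    config: PipelineConfig | None = None,
    gaze_events: bool = True,
) -> pd.DataFrame:
    """Process an in-memory cohort into a per-participant outcome table."""
    participants = cohort.participants if isinstance(cohort, Cohort) else cohort
    rows = [
        summarize_participant(p, config, gaze_events=gaze_events)[0]
        for p in participants
    ]
    return pd.DataFrame(rows)


def fit_group_study(
    participant_table: pd.DataFrame,
    outcomes: list[str] | None = None,
    traits: list[str] = ("mabc2_standard_score", "dcdq_score"),
) -> GroupStudyResults:
    """Group inference on the included DCD/Control participants."""
    df = participant_table[participant_table["included"]].copy()
    if outcomes is None:
        outcomes = [c for c in OUTCOME_COLUMNS if c in df.columns]
    traits = [t for t in traits if t in df.columns]
    return GroupStudy(df, outcomes=outcomes, traits=traits).fit()


def run_pipeline(
    config: PipelineConfig, in_dir: Path | str, out_dir: Path | str
) -> dict:
    """File-based end-to-end run: read a cohort directory, process it,
    and write events, coupling, participant and stats tables.

    Returns a run log dictionary (also written as ``run_log.json``).
    """
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    participants, rejections = hio.read_cohort(
        in_dir, config.gaze_rate, config.kin_rate, config.force_rate
    )
    rows, event_rows, gaze_rows, coupling_rows = [], [], [], []
    for p in participants:
        row, results = summarize_participant(p, config)
        rows.append(row)
        for r in results:
            for e in r.saccades + r.fixations:
                gaze_rows.append(
                    {
                        "participant": r.participant,
                        "trial": r.trial,
                        "kind": e.kind,
                        "onset_s": e.onset,
                        "offset_s": e.offset,
                        "centroid_x_deg": e.centroid[0] if e.centroid else None,
                        "centroid_y_deg": e.centroid[1] if e.centroid else None,
                    }
                )
            event_rows.append(
                {
                    "participant": r.participant,
                    "trial": r.trial,
                    "reach_onset_s": r.segmentation.reach_onset,
                    "grasp_onset_s": r.segmentation.grasp_onset,
                    "lift_offset_s": r.segmentation.lift_offset,
                    "movement_duration_s": r.reach.movement_duration,
                    "max_hand_velocity_mm_s": r.reach.max_hand_velocity,
                    "time_to_peak_pct": r.reach.time_to_peak_velocity,
                }
            )
            if r.coupling is not None:
                coupling_rows.append(
                    {
                        "participant": r.participant,
                        "trial": r.trial,
                        "peak_r": r.coupling.peak_r,
                        "lag_s": r.coupling.lag_s,
                        "n_overlap": r.coupling.n_overlap,
                    }
                )
    table = pd.DataFrame(rows)
    pd.DataFrame(event_rows).to_csv(out / "events.csv", index=False)
    pd.DataFrame(gaze_rows).to_csv(out / "gaze_events.csv", index=False)
    pd.DataFrame(coupling_rows).to_csv(out / "coupling.csv", index=False)
    table.to_csv(out / "participants.csv", index=False)
    study = fit_group_study(table)
    study.comparisons_frame().to_csv(out / "stats.csv", index=False)
    if len(study.correlations):
        study.correlations.to_csv(out / "correlations.csv", index=False)
    log = {
        "n_participants": len(participants),
        "n_included": int(table["included"].sum()),
        "n_dcd": int((table["group"] == GROUP_DCD).sum()),
        "n_control": int((table["group"] == GROUP_CONTROL).sum()),
        "rejections": rejections,
        "config": dataclasses.asdict(config),
    }
    with open(out / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2)
    logger.info(
        "pipeline complete: %d participants, %d included",
        log["n_participants"], log["n_included"],
    )
    return log
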