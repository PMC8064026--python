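"""On-disk layout: delimited text, one directory per participant.

Layout
------
::

    cohort_dir/
      traits.csv           participant, group, traits (one row each)
      trials.csv           participant, trial, quality_code
      ground_truth.json    optional sidecar: per-trial generator truth
      P000/
        trial_000_gaze.csv    time_s, x_deg, y_deg, valid
        trial_000_wrist.csv   time_s, x_mm, y_mm, z_mm
        trial_000_object.csv  time_s, x_mm, y_mm, z_mm
        trial_000_force.csv   time_s, force_n
      ...

All files are comma-separated UTF-8 with one header row, '.' decimal,
time in seconds from trial start. The vertical axis is the third
positional column, gravity-aligned, positive up. Readers validate
monotone time and the declared sample rate to within 1%.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SeriesError
from .series import UniformSeries
from .simulate import Cohort, GroundTruth, ParticipantData, TrialRecording

__all__ = [
    "write_cohort",
    "read_cohort",
    "read_trial",
    "write_trial",
    "RATE_TOLERANCE",
]

logger = logging.getLogger("handeye.io")

RATE_TOLERANCE = 0.01  # declared vs observed sample rate, relative

_STREAMS = {
    "gaze": ("time_s", "x_deg", "y_deg", "valid"),
    "wrist": ("time_s", "x_mm", "y_mm", "z_mm"),
    "object": ("time_s", "x_mm", "y_mm", "z_mm"),
    "force": ("time_s", "force_n"),
}


def _write_stream(path: Path, series: UniformSeries, columns: tuple[str, ...]) -> None:
    t = series.times
    vals = series.values if series.values.ndim == 2 else series.values[:, None]
    data = {"time_s": t}
    value_cols = [c for c in columns if c not in ("time_s", "valid")]
    for j, name in enumerate(value_cols):
        data[name] = vals[:, j]
    if "valid" in columns:
        data["valid"] = (
            np.ones(series.n, dtype=int)
            if series.validity is None
            else series.validity.astype(int)
        )
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6f")


def write_trial(participant_dir: Path, rec: TrialRecording) -> None:
    participant_dir.mkdir(parents=True, exist_ok=True)
    stem = f"trial_{rec.trial:03d}"
    _write_stream(participant_dir / f"{stem}_gaze.csv", rec.gaze, _STREAMS["gaze"])
    _write_stream(participant_dir / f"{stem}_wrist.csv", rec.wrist, _STREAMS["wrist"])
    _write_stream(participant_dir / f"{stem}_object.csv", rec.obj, _STREAMS["object"])
    _write_stream(participant_dir / f"{stem}_force.csv", rec.force, _STREAMS["force"])


def write_cohort(out_dir: Path | str, cohort: Cohort) -> None:
    """Write a cohort as per-participant trial directories plus tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.traits_table.to_csv(out / "traits.csv", index=False)
    trial_rows = []
    truth_sidecar: dict[str, list[dict]] = {}
    for p in cohort.participants:
        pdir = out / p.id
        for rec in p.trials:
            write_trial(pdir, rec)
        for j, code in enumerate(p.quality_codes):
            trial_rows.append(
                {"participant": p.id, "trial": j, "quality_code": code}
            )
        truth_sidecar[p.id] = [
            {
                k: v
                for k, v in dataclasses.asdict(t).items()
            }
            for t in p.truths
        ]
    pd.DataFrame(trial_rows).to_csv(out / "trials.csv", index=False)
    with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth_sidecar, fh)
    logger.info(
        "wrote cohort: %d participants to %s", len(cohort.participants), out
    )


def _read_stream(
    path: Path, expected_rate: float, columns: tuple[str, ...]
) -> UniformSeries:
    if not path.exists():
        raise SeriesError(f"missing stream file {path.name}")
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SeriesError(f"{path.name}: missing columns {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise SeriesError(f"{path.name}: fewer than two samples")
    dt = np.diff(t)
    if (dt <= 0).any():
        raise SeriesError(f"{path.name}: time not strictly increasing")
    rate = 1.0 / float(np.median(dt))
    if abs(rate - expected_rate) > RATE_TOLERANCE * expected_rate:
        raise SeriesError(
            f"{path.name}: observed rate {rate:.2f} Hz differs from declared "
            f"{expected_rate:.2f} Hz by more than {RATE_TOLERANCE:.0%}"
        )
    value_cols = [c for c in columns if c not in ("time_s", "valid")]
    vals = df[value_cols].to_numpy(dtype=float)
    if vals.shape[1] == 1:
        vals = vals[:, 0]
    validity = (
        df["valid"].to_numpy(dtype=float) > 0.5 if "valid" in columns else None
    )
    return UniformSeries(expected_rate, vals, float(t[0]), validity)


def read_trial(
    participant_dir: Path,
    trial: int,
    gaze_rate: float = 90.0,
    kin_rate: float = 120.0,
    force_rate: float = 500.0,
) -> TrialRecording:
    """Read one trial's four streams, validating layout, time and rate."""
    stem = f"trial_{trial:03d}"
    return TrialRecording(
        gaze=_read_stream(participant_dir / f"{stem}_gaze.csv", gaze_rate, _STREAMS["gaze"]),
        wrist=_read_stream(participant_dir / f"{stem}_wrist.csv", kin_rate, _STREAMS["wrist"]),
        obj=_read_stream(participant_dir / f"{stem}_object.csv", kin_rate, _STREAMS["object"]),
        force=_read_stream(participant_dir / f"{stem}_force.csv", force_rate, _STREAMS["force"]),
        participant=participant_dir.name,
        trial=trial,
    )


def read_cohort(
    in_dir: Path | str,
    gaze_rate: float = 90.0,
    kin_rate: float = 120.0,
    force_rate: float = 500.0,
) -> tuple[list[ParticipantData], list[dict]]:
    """Read a cohort directory; rejects bad trials with a logged reason.

    Returns the participants (with any unreadable trials dropped) and a
    list of rejection records ``{"participant", "trial", "reason"}``.
    """
    root = Path(in_dir)
    traits = pd.read_csv(root / "traits.csv")
    trials_tab = pd.read_csv(root / "trials.csv")
    truths: dict[str, list[dict]] = {}
    truth_path = root / "ground_truth.json"
    if truth_path.exists():
        with open(truth_path, encoding="utf-8") as fh:
            truths = json.load(fh)
    participants: list[ParticipantData] = []
    rejections: list[dict] = []
    for _, row in traits.iterrows():
        pid = row["participant"]
        pdir = root / pid
        sub = trials_tab[trials_tab["participant"] == pid].sort_values("trial")
        trials, codes, ptruths = [], [], []
        for _, trow in sub.iterrows():
            j = int(trow["trial"])
            try:
                rec = read_trial(pdir, j, gaze_rate, kin_rate, force_rate)
            except SeriesError as exc:
                logger.warning("rejecting %s trial %d: %s", pid, j, exc)
                rejections.append(
                    {"participant": pid, "trial": j, "reason": str(exc)}
                )
                continue
            rec.quality_code = int(trow["quality_code"])
            trials.append(rec)
            codes.append(int(trow["quality_code"]))
            if pid in truths and j < len(truths[pid]):
                ptruths.append(truths[pid][j])
        participants.append(
            ParticipantData(
                id=pid,
                group=row.get("group", ""),
                traits={
                    k: row[k]
                    for k in row.index
                    if k not in ("participant", "group")
                },
                trials=trials,
                truths=[_truth_from_dict(d) for d in ptruths],
                quality_codes=codes,
            )
        )
    return participants, rejections


def _truth_from_dict(d: dict) -> GroundTruth:
    d = dict(d)
    d["saccade_windows"] = [tuple(w) for w in d["saccade_windows"]]
    d["fixation_windows"] = [tuple(w) for w in d["fixation_windows"]]
    return GroundTruth(**d)
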