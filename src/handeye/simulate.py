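"""Synthetic object-lifting trials and cohorts with known ground truth.

A generated trial emulates the behaviour the analysis assumes:

* the wrist accelerates along a minimum-jerk reach whose 50 mm/s
  crossing lands exactly at the configured reach onset, and grip force
  steps above 1 N at grasp onset;
* the object (and with it the wrist) rises by ``lift_height`` along a
  minimum-jerk profile whose falling 50 mm/s crossing lands exactly at
  the configured lift offset;
* gaze is anchored on the object during the reach, then pursues the
  object's in-flight trajectory: the vertical eye channel is the hand's
  vertical profile (rescaled to degrees) advanced by ``lag_true`` plus
  white Gaussian noise of ``coupling_noise_sd``;
* saccadic gaze shifts are superimposed on the horizontal channel as
  single-frame steps with a 30% dynamic overshoot corrected on the next
  frame (a saccade with a glissade, completing within ~20 ms at 90 Hz),
  a shape whose filtered acceleration magnitude stays above half its
  peak for five-plus consecutive frames so the threshold detector's run
  rule holds; fixations are the dwell windows between shifts during the
  static (pre-lift and hold) phases;
* missing-gaze gaps are geometric-length runs of invalid frames.

The total gaze-shift count follows ``saccade_rate_true`` over the whole
trial; ``fixation_rate_true`` sets the shift rate inside the static
phases (which fixes the fixation rate there), and the remaining shifts
are placed in the pursuit window as catch-up saccades.

Cohorts draw per-participant traits, lags, and event rates from
group-structured distributions, assign per-trial quality codes, and
derive one independent seed per trial from the cohort seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import ConfigurationError
from .screening import GROUP_CONTROL, GROUP_DCD, GROUP_INTERMEDIATE, assign_group
from .series import UniformSeries

__all__ = [
    "TrialGenConfig",
    "CohortGenConfig",
    "GroupEffects",
    "GroundTruth",
    "TrialRecording",
    "Cohort",
    "ParticipantData",
    "generate_trial",
    "generate_cohort",
]

SPEED_THRESHOLD = 50.0  # mm/s, the segmentation threshold the profiles target
# frames the filtered step transient effectively occupies (for spacing and
# ground-truth window bookkeeping; the raw step itself is one frame)
_SACCADE_STEP_FRAMES = 5


@dataclass(frozen=True)
class TrialGenConfig:
    """Ground-truth parameters of one synthetic lift trial."""

    trial_duration: float = 3.5  # s
    reach_onset_true: float = 0.5  # s
    grasp_onset_true: float = 1.2  # s
    lift_offset_true: float = 2.2  # s
    lag_true: float = 0.05  # s, positive = eye leads hand
    coupling_noise_sd: float = 0.1  # deg, additive on the eye vertical channel
    saccade_rate_true: float = 2.2  # events/s over the whole trial
    fixation_rate_true: float = 2.0  # events/s within static phases
    gaze_gap_prob: float = 0.01  # per-frame probability a gap starts
    peak_reach_speed: float = 600.0  # mm/s
    lift_height: float = 150.0  # mm
    grip_force_plateau: float = 6.0  # N
    gaze_sample_rate: float = 90.0  # Hz
    kin_sample_rate: float = 120.0  # Hz
    force_sample_rate: float = 500.0  # Hz
    seed: int = 0
    # secondary, rarely-touched knobs
    mm_to_deg: float = 0.1  # deg of gaze per mm of vertical hand motion
    saccade_amplitude_range: tuple[float, float] = (7.0, 9.0)  # deg
    kin_noise_sd: float = 0.15  # mm, rigid-body marker noise
    force_noise_sd: float = 0.01  # N
    force_rise_tau: float = 0.02  # s, grip-force rise time constant

    def validate(self) -> None:
        if not (
            0.0
            <= self.reach_onset_true
            < self.grasp_onset_true
            < self.lift_offset_true
            <= self.trial_duration
        ):
            raise ConfigurationError(
                "event ordering must satisfy reach < grasp < lift offset "
                f"<= duration, got {self}"
            )
        for name in ("saccade_rate_true", "fixation_rate_true"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.coupling_noise_sd < 0:
            raise ConfigurationError("coupling_noise_sd must be non-negative")
        if not (0.0 <= self.gaze_gap_prob < 1.0):
            raise ConfigurationError("gaze_gap_prob must be in [0, 1)")
        if self.peak_reach_speed < 100.0:
            raise ConfigurationError("peak_reach_speed must be at least 100 mm/s")
        for name in ("gaze_sample_rate", "kin_sample_rate", "force_sample_rate"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Per-trial ground truth for every downstream estimand."""

    reach_onset_true: float
    grasp_onset_true: float
    lift_offset_true: float
    lag_true: float
    coupling_noise_sd: float
    saccade_rate_true: float
    fixation_rate_true: float
    saccade_windows: list[tuple[float, float]]
    fixation_windows: list[tuple[float, float]]
    lift_motion_end: float  # time the vertical rise truly completes

    @property
    def n_saccades(self) -> int:
        return len(self.saccade_windows)

    @property
    def n_fixations(self) -> int:
        return len(self.fixation_windows)


@dataclass
class TrialRecording:
    """Raw streams and metadata for one lift trial."""

    gaze: UniformSeries  # (n, 2) deg, 90 Hz, with validity flags
    wrist: UniformSeries  # (n, 3) mm, 120 Hz
    obj: UniformSeries  # (n, 3) mm, 120 Hz
    force: UniformSeries  # (n,) N, 500 Hz
    participant: str = "P000"
    trial: int = 0
    quality_code: int | None = None


def _minimum_jerk(u: np.ndarray) -> np.ndarray:
    """Normalised minimum-jerk position profile on [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    return u**3 * (10.0 - 15.0 * u + 6.0 * u * u)


@lru_cache(maxsize=128)
def _lift_profile_fraction(span_s: float, height_mm: float) -> float:
    """Fraction u* of the lift profile at which speed falls to 50 mm/s.

    The minimum-jerk speed is ``v(u) = 30 (H/D) u^2 (1-u)^2``; placing
    the configured lift offset at the falling threshold crossing requires
    ``u*^3 (1-u*)^2 = 50 * span / (30 H)`` with ``span = offset - grasp``
    and ``D = span / u*``.
    """
    q = SPEED_THRESHOLD * span_s / (30.0 * height_mm)
    peak = 0.6**3 * 0.4**2  # max of u^3 (1-u)^2, attained at u = 0.6
    if q >= peak:
        raise ConfigurationError(
            f"lift of {height_mm} mm over {span_s} s is too slow to cross "
            f"{SPEED_THRESHOLD} mm/s; increase lift_height or shorten the lift"
        )
    return brentq(lambda u: u**3 * (1.0 - u) ** 2 - q, 0.6, 1.0 - 1e-12)


def _reach_profile(config: TrialGenConfig) -> tuple[float, float, float]:
    """(start time, duration, amplitude) of the minimum-jerk reach.

    The profile is placed so its rising 50 mm/s crossing lands exactly at
    ``reach_onset_true`` given the configured peak speed.
    """
    vp = config.peak_reach_speed
    w = np.sqrt(SPEED_THRESHOLD * 1.875 / (30.0 * vp))
    u0 = (1.0 - np.sqrt(1.0 - 4.0 * w)) / 2.0  # rising crossing fraction
    duration = (config.grasp_onset_true - config.reach_onset_true) / (1.0 - u0)
    start = config.grasp_onset_true - duration
    if start < 0:
        raise ConfigurationError(
            "reach profile would start before the trial; move reach_onset_true "
            "later or increase peak_reach_speed"
        )
    amplitude = vp * duration / 1.875
    return start, duration, amplitude


def _landing_time(config: TrialGenConfig, mv0: float, span: float) -> float | None:
    """Eye-time of the deterministic pursuit-landing catch-up saccade.

    As the minimum-jerk pursuit decelerates there is a velocity band
    (around 1 degree per minimum-fixation window) where a dispersion
    window is marginally at threshold; a catch-up saccade placed 8
    frames after the last window that still breaks threshold leaves no
    room for a minimal window inside the ambiguous band, so the hold
    fixation starts unambiguously at the landing step.
    """
    h_deg = config.mm_to_deg * config.lift_height
    u9 = _flicker_fraction(h_deg, span)
    if u9 is None:
        return None
    return mv0 + u9 * span + 8.0 / config.gaze_sample_rate


@lru_cache(maxsize=128)
def _flicker_fraction(h_deg: float, span: float) -> float | None:
    """Profile fraction of the last dispersion window that breaks 1 deg."""
    win = 0.1  # dispersion-window span (s) of the minimum fixation duration

    def window_disp(u: float) -> float:
        return (
            _minimum_jerk(np.array([min(u + win / span, 1.0)]))
            - _minimum_jerk(np.array([u]))
        )[0] * h_deg

    if window_disp(0.6) <= 1.0:  # pursuit too slow to ever break threshold
        return None
    return brentq(lambda u: window_disp(u) - 1.0, 0.6, 1.0 - 1e-9)


def _place_spaced(
    rng: np.random.Generator, lo: float, hi: float, k: int, sep: float
) -> list[float]:
    """Place up to k points uniformly in [lo, hi] with minimum separation.

    Uses the spacings construction (uniforms on the slack interval plus
    mandatory gaps), which realises exactly min(k, capacity) points.
    """
    if hi <= lo or k <= 0:
        return []
    cap = int(np.floor((hi - lo) / sep)) + 1
    k = min(k, cap)
    slack = (hi - lo) - (k - 1) * sep
    u = np.sort(rng.uniform(0.0, slack, size=k))
    return [float(lo + u[j] + j * sep) for j in range(k)]


def _shift_times(
    rng: np.random.Generator, config: TrialGenConfig, mv0: float, mv1: float
) -> tuple[list[float], list[float], float | None]:
    """Gaze-shift start times: static phases, pursuit window, landing.

    The total count (including the deterministic pursuit-landing
    saccade) is drawn as Poisson(saccade_rate_true x trial_duration);
    static phases are filled at fixation_rate_true density first, the
    pursuit window takes the remainder, and any overflow returns to
    spare static capacity. Shift starts keep a minimum separation of
    0.28 s, which keeps both the inter-shift dwells above the 100 ms
    fixation minimum and the filtered step transients distinct.
    """
    sacc_dur = (_SACCADE_STEP_FRAMES + 1) / config.gaze_sample_rate
    span = mv1 - mv0
    t_land = _landing_time(config, mv0, span) if span > 0.4 else None
    min_sep = 0.28
    lead_margin = 0.15  # dwell room before the first shift of an interval
    tail_margin = sacc_dur + 0.15  # dwell room between last shift and the end
    hold_start = (t_land + sacc_dur) if t_land is not None else mv1
    intervals = [(0.0, mv0), (hold_start, config.trial_duration)]
    usable = [(lo + lead_margin, hi - tail_margin) for lo, hi in intervals]
    if span > 0.4:
        p_lo = mv0 + 0.30 * span
        p_hi = mv0 + 0.62 * span
        if t_land is not None:
            p_hi = min(p_hi, t_land - 0.25)
    else:
        p_lo = p_hi = 0.0

    def capacity(lo: float, hi: float, sep: float) -> int:
        return int(np.floor((hi - lo) / sep)) + 1 if hi > lo else 0

    caps = [capacity(lo, hi, min_sep) for lo, hi in usable]
    cap_p = capacity(p_lo, p_hi, 0.25)
    n_total = int(rng.poisson(config.saccade_rate_true * config.trial_duration))
    budget = max(n_total - (1 if t_land is not None else 0), 0)
    # desired static counts at fixation_rate density, clipped to capacity
    # and budget; the pursuit window takes the remainder; any overflow
    # returns to spare static capacity
    ks = [
        min(int(rng.poisson(config.fixation_rate_true * (hi - lo))), cap)
        for (lo, hi), cap in zip(intervals, caps)
    ]
    while sum(ks) > budget:
        ks[int(np.argmax(ks))] -= 1
    k_p = min(budget - sum(ks), cap_p)
    rem = budget - sum(ks) - k_p
    while rem > 0:
        spare = [cap - k for cap, k in zip(caps, ks)]
        if max(spare) <= 0:
            break
        ks[int(np.argmax(spare))] += 1
        rem -= 1
    static: list[float] = []
    for (lo, hi), k in zip(usable, ks):
        static.extend(_place_spaced(rng, lo, hi, k, min_sep))
    static.sort()
    pursuit = _place_spaced(rng, p_lo, p_hi, k_p, 0.25)
    if t_land is not None:
        pursuit.append(t_land)
    return static, pursuit, t_land


def generate_trial(
    config: TrialGenConfig, rng: np.random.Generator | None = None
) -> tuple[TrialRecording, GroundTruth]:
    """Generate one synthetic lift trial plus its ground truth.

    Identical configs (and seeds) produce bit-identical streams.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    T = config.trial_duration
    g = config.grasp_onset_true
    L = config.lift_offset_true
    H = config.lift_height

    # --- lift profile: place the falling 50 mm/s crossing at L
    u_star = _lift_profile_fraction(L - g, H)
    d_lift = (L - g) / u_star
    lift_motion_end = g + d_lift
    if lift_motion_end > T - 0.05:
        raise ConfigurationError(
            "lift motion would overrun the trial; shorten the lift span or "
            "extend trial_duration"
        )

    # --- kinematic streams (120 Hz)
    n_kin = int(round(T * config.kin_sample_rate)) + 1
    t_kin = np.arange(n_kin) / config.kin_sample_rate
    reach_start, reach_dur, reach_amp = _reach_profile(config)
    rise_kin = H * _minimum_jerk((t_kin - g) / d_lift)
    wrist = np.empty((n_kin, 3))
    wrist[:, 0] = -300.0 + reach_amp * _minimum_jerk((t_kin - reach_start) / reach_dur)
    wrist[:, 1] = -150.0
    wrist[:, 2] = 50.0 + rise_kin
    obj = np.empty((n_kin, 3))
    obj[:, 0] = 0.0
    obj[:, 1] = 0.0
    obj[:, 2] = 37.5 + rise_kin
    wrist += rng.normal(0.0, config.kin_noise_sd, size=wrist.shape)
    obj += rng.normal(0.0, config.kin_noise_sd, size=obj.shape)

    # --- grip force (500 Hz): step-like exponential rise to plateau at grasp
    n_force = int(round(T * config.force_sample_rate)) + 1
    t_force = np.arange(n_force) / config.force_sample_rate
    force = np.where(
        t_force < g,
        0.0,
        config.grip_force_plateau * (1.0 - np.exp(-(t_force - g) / config.force_rise_tau)),
    )
    force = np.maximum(force + rng.normal(0.0, config.force_noise_sd, n_force), 0.0)

    # --- gaze (90 Hz)
    rate = config.gaze_sample_rate
    n_gaze = int(round(T * rate)) + 1
    t_gaze = np.arange(n_gaze) / rate
    # vertical: hand vertical advanced by lag_true, rescaled to degrees
    eye_y = -5.0 + config.mm_to_deg * H * _minimum_jerk(
        (t_gaze + config.lag_true - g) / d_lift
    )
    if config.coupling_noise_sd > 0:
        eye_y = eye_y + rng.normal(0.0, config.coupling_noise_sd, n_gaze)

    # horizontal: dwell positions with discrete saccadic steps
    mv0 = max(g - config.lag_true, 0.0)
    mv1 = min(lift_motion_end - config.lag_true, T)
    static_shifts, pursuit_shifts, t_land = _shift_times(rng, config, mv0, mv1)
    all_shifts = sorted(static_shifts + pursuit_shifts)
    velocity = np.zeros(n_gaze)  # per-frame displacement of the horizontal channel
    saccade_windows: list[tuple[float, float]] = []
    position = 0.0
    lo_amp, hi_amp = config.saccade_amplitude_range
    for t_shift in all_shifts:
        k0 = int(round(t_shift * rate))
        if k0 + _SACCADE_STEP_FRAMES + 5 >= n_gaze:
            continue
        amp = rng.uniform(lo_amp, hi_amp) * rng.choice([-1.0, 1.0])
        if abs(position + amp) > 10.0:  # keep gaze within the calibrated workspace
            amp = -amp
        position += amp
        # a step with 30% overshoot corrected on the next frame: the
        # filtered acceleration transient stays high for 5-6 frames
        # (see module docstring)
        velocity[k0] += 1.3 * amp
        velocity[k0 + 1] -= 0.3 * amp
        # the zero-phase 30 Hz filter spreads the transient a few frames
        # each way; record a correspondingly generous truth window
        saccade_windows.append(
            (max(k0 - 8, 0) / rate, min(k0 + 10, n_gaze - 1) / rate)
        )
    eye_x = np.concatenate(([0.0], np.cumsum(velocity[:-1])))

    # fixation ground truth: inter-shift dwell windows of the static phases
    # (the hold dwell starts at the pursuit-landing saccade, not at the
    # nominal end of the vertical rise)
    fixation_windows: list[tuple[float, float]] = []
    sacc_end = (_SACCADE_STEP_FRAMES + 1) / rate
    hold_start = (t_land + sacc_end) if t_land is not None else mv1
    for lo, hi in ((0.0, mv0), (hold_start, T)):
        bounds = [lo] + [
            t for t in static_shifts if lo <= t <= hi
        ] + [hi]
        for i in range(len(bounds) - 1):
            a = bounds[i] + (sacc_end if i > 0 else 0.0)
            b = bounds[i + 1]
            if b - a >= 0.13:  # minimum fixation plus a detection margin
                fixation_windows.append((a, b))

    # missing-gaze gaps: geometric-length runs (mean 2 frames)
    validity = np.ones(n_gaze, dtype=bool)
    if config.gaze_gap_prob > 0:
        starts = np.flatnonzero(rng.random(n_gaze) < config.gaze_gap_prob)
        for s in starts:
            length = int(rng.geometric(0.5))
            validity[s : s + length] = False
        eye_x = eye_x.copy()
        eye_y = eye_y.copy()
        eye_x[~validity] = np.nan
        eye_y[~validity] = np.nan

    recording = TrialRecording(
        gaze=UniformSeries(rate, np.column_stack([eye_x, eye_y]), 0.0, validity),
        wrist=UniformSeries(config.kin_sample_rate, wrist),
        obj=UniformSeries(config.kin_sample_rate, obj),
        force=UniformSeries(config.force_sample_rate, force),
    )
    truth = GroundTruth(
        reach_onset_true=config.reach_onset_true,
        grasp_onset_true=g,
        lift_offset_true=L,
        lag_true=config.lag_true,
        coupling_noise_sd=config.coupling_noise_sd,
        saccade_rate_true=config.saccade_rate_true,
        fixation_rate_true=config.fixation_rate_true,
        saccade_windows=saccade_windows,
        fixation_windows=fixation_windows,
        lift_motion_end=lift_motion_end,
    )
    return recording, truth


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class GroupEffects:
    """Additive group offsets on the trial ground-truth parameters."""

    lag_s: float = 0.0
    coupling_noise_sd: float = 0.0
    fixation_rate: float = 0.0


_TABLE_TRAITS = {
    # group -> (mabc2 standard score, dcdq, aq, adhd) as (mean, sd)
    GROUP_DCD: {
        "mabc2_standard_score": (3.4, 1.5),
        "dcdq_score": (33.3, 13.9),
        "aq_score": (70.3, 27.2),
        "adhd_score": (24.5, 12.1),
    },
    GROUP_CONTROL: {
        "mabc2_standard_score": (10.3, 2.4),
        "dcdq_score": (58.8, 12.5),
        "aq_score": (52.8, 16.4),
        "adhd_score": (13.7, 9.0),
    },
    GROUP_INTERMEDIATE: {
        "mabc2_standard_score": (6.3, 0.9),
        "dcdq_score": (46.0, 13.0),
        "aq_score": (61.0, 22.0),
        "adhd_score": (19.0, 10.0),
    },
}

_PERCENTILE_BANDS = {
    GROUP_DCD: (0.5, 5.0),
    GROUP_INTERMEDIATE: (5.001, 15.0),
    GROUP_CONTROL: (16.0, 95.0),
}


@dataclass(frozen=True)
class CohortGenConfig:
    """Design of a synthetic cohort."""

    n_per_group: tuple[int, int] = (19, 39)  # (DCD, Control)
    n_intermediate: int = 12
    n_trials_per_participant: int = 37
    group_effects: dict = field(
        default_factory=lambda: {
            GROUP_DCD: GroupEffects(lag_s=0.03, fixation_rate=-0.3),
            GROUP_CONTROL: GroupEffects(),
            GROUP_INTERMEDIATE: GroupEffects(lag_s=0.015, fixation_rate=-0.15),
        }
    )
    trait_means_sds: dict = field(default_factory=lambda: _TABLE_TRAITS)
    quality_code_probs: tuple[float, ...] = (0.05, 0.05, 0.15, 0.35, 0.40)
    participant_lag_sd: float = 0.05  # s, between-participant lag spread
    trial_lag_sd: float = 0.01  # s, within-participant trial-to-trial jitter
    participant_rate_sd: float = 0.3  # events/s jitter on saccade/fixation rates
    base_trial: TrialGenConfig = field(default_factory=TrialGenConfig)
    seed: int = 0

    def validate(self) -> None:
        if any(n <= 0 for n in self.n_per_group):
            raise ConfigurationError("group counts must be positive")
        if self.n_intermediate < 0:
            raise ConfigurationError("n_intermediate cannot be negative")
        if self.n_trials_per_participant <= 0:
            raise ConfigurationError("n_trials_per_participant must be positive")
        probs = np.asarray(self.quality_code_probs, dtype=float)
        if probs.size != 5 or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                "quality_code_probs must be 5 non-negative values summing to 1"
            )


@dataclass
class ParticipantData:
    """One simulated participant: traits, trials and their ground truth."""

    id: str
    group: str
    traits: dict
    trials: list[TrialRecording]
    truths: list[GroundTruth]
    quality_codes: list[int]


@dataclass
class Cohort:
    """A simulated cohort plus its trait table."""

    participants: list[ParticipantData]
    traits_table: pd.DataFrame
    config: CohortGenConfig


def generate_cohort(config: CohortGenConfig) -> Cohort:
    """Generate a full cohort with group-structured traits and trials.

    Every participant and trial receives an independently derived seed
    from the cohort seed, so any subset regenerates reproducibly.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    groups = (
        [GROUP_DCD] * config.n_per_group[0]
        + [GROUP_CONTROL] * config.n_per_group[1]
        + [GROUP_INTERMEDIATE] * config.n_intermediate
    )
    participant_seeds = root.spawn(len(groups))
    participants: list[ParticipantData] = []
    rows = []
    codes = np.arange(5)
    probs = np.asarray(config.quality_code_probs, dtype=float)
    base = config.base_trial
    for idx, (group, pseed) in enumerate(zip(groups, participant_seeds)):
        rng = np.random.default_rng(pseed)
        effects: GroupEffects = config.group_effects.get(group, GroupEffects())
        traits = {
            name: float(rng.normal(mean, sd))
            for name, (mean, sd) in config.trait_means_sds[group].items()
        }
        lo, hi = _PERCENTILE_BANDS[group]
        traits["mabc2_percentile"] = float(rng.uniform(lo, hi))
        assert assign_group(traits["mabc2_percentile"]) == group
        lag_p = float(
            rng.normal(base.lag_true + effects.lag_s, config.participant_lag_sd)
        )
        sacc_rate_p = max(
            float(rng.normal(base.saccade_rate_true, config.participant_rate_sd)), 0.5
        )
        fix_rate_p = max(
            float(
                rng.normal(
                    base.fixation_rate_true + effects.fixation_rate,
                    config.participant_rate_sd,
                )
            ),
            0.5,
        )
        noise_p = max(base.coupling_noise_sd + effects.coupling_noise_sd, 0.0)
        quality = rng.choice(codes, size=config.n_trials_per_participant, p=probs)
        pid = f"P{idx:03d}"
        trials, truths = [], []
        for j in range(config.n_trials_per_participant):
            trial_rng = np.random.default_rng(pseed.spawn(1)[0])
            lag_t = float(trial_rng.normal(lag_p, config.trial_lag_sd))
            trial_cfg = replace(
                base,
                lag_true=lag_t,
                coupling_noise_sd=noise_p,
                saccade_rate_true=sacc_rate_p,
                fixation_rate_true=fix_rate_p,
            )
            rec, truth = generate_trial(trial_cfg, rng=trial_rng)
            rec.participant = pid
            rec.trial = j
            rec.quality_code = int(quality[j])
            trials.append(rec)
            truths.append(truth)
        participants.append(
            ParticipantData(
                id=pid,
                group=group,
                traits=traits,
                trials=trials,
                truths=truths,
                quality_codes=[int(c) for c in quality],
            )
        )
        rows.append(
            {
                "participant": pid,
                "group": group,
                "lag_true_participant": lag_p,
                **traits,
            }
        )
    return Cohort(
        participants=participants,
        traits_table=pd.DataFrame(rows),
        config=config,
    )
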