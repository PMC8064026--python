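"""Cross-correlational hand-eye coupling.

The vertical (gravity-aligned) wrist position and the vertical gaze
coordinate are synchronised by matching the grasp-onset frame, cropped
to the grasp-to-lift-offset segment, and cross-correlated over integer
frame shifts. At each candidate lag the Pearson correlation is computed
over the overlapping portion only, with each overlap independently
standardised, so the peak value stays in [-1, 1] and is interpretable as
how well the two signals match once offset in time. Positive lags mean
the eye leads the hand.

:class:`HandEyeCoupling` is the model object (built from an
:class:`AlignedPair` or two raw arrays); its :meth:`~HandEyeCoupling.fit`
returns a :class:`CouplingResult` carrying the peak correlation, the
signed lag, the full correlogram, a ``summary()`` table and a
correlogram plot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import TrialInvalidError, UndefinedCorrelationError
from .kinematics import EventSegmentation
from .series import UniformSeries

__all__ = [
    "AlignedPair",
    "CouplingResult",
    "HandEyeCoupling",
    "synchronize",
    "cross_correlate",
    "participant_coupling_summary",
]

DEFAULT_MAX_LAG_S = 0.5
MIN_OVERLAP_FRAMES = 10
MIN_OVERLAP_FRACTION = 0.5


@dataclass(frozen=True)
class AlignedPair:
    """Grasp-synchronised, segment-cropped hand and eye vertical signals."""

    hand_vertical: UniformSeries  # mm, 90 Hz
    eye_vertical: UniformSeries  # degrees, 90 Hz
    segment: tuple[float, float]  # (grasp_onset, lift_offset), s

    def __post_init__(self) -> None:
        if len(self.hand_vertical) != len(self.eye_vertical):
            raise TrialInvalidError("aligned signals must have equal length")

    @property
    def n(self) -> int:
        return len(self.hand_vertical)

    @property
    def rate(self) -> float:
        return self.hand_vertical.rate


def synchronize(
    hand_vertical: UniformSeries,
    eye_vertical: UniformSeries,
    seg: EventSegmentation,
    min_overlap: int = MIN_OVERLAP_FRAMES,
) -> AlignedPair:
    """Crop both 90 Hz series to [grasp onset, lift offset], index-aligned.

    The grasp time (found on the 500 Hz force stream) is rounded to the
    nearest frame of each series' grid, so the frame nearest the >1 N
    onset is index 0 of both cropped series.
    """
    if hand_vertical.rate != eye_vertical.rate:
        raise TrialInvalidError("hand and eye series must share a sample rate")
    i0_h = hand_vertical.index_at(seg.grasp_onset)
    i1_h = hand_vertical.index_at(seg.lift_offset) + 1
    i0_e = eye_vertical.index_at(seg.grasp_onset)
    n = min(i1_h - i0_h, len(eye_vertical) - i0_e)
    if n < min_overlap:
        raise TrialInvalidError(
            f"grasp-to-lift segment of {n} frames is below the "
            f"{min_overlap}-frame minimum"
        )
    return AlignedPair(
        hand_vertical=hand_vertical.crop_index(i0_h, i0_h + n),
        eye_vertical=eye_vertical.crop_index(i0_e, i0_e + n),
        segment=(seg.grasp_onset, seg.lift_offset),
    )


@dataclass
class CouplingResult:
    """Results of fitting :class:`HandEyeCoupling` to one trial.

    Attributes
    ----------
    peak_r : float
        Maximum signed Pearson correlation over candidate lags.
    lag_s : float
        Lag (s) at which the peak occurred; positive = eye leads hand.
    n_overlap : int
        Frames in the overlap used at the peak lag.
    lags_s, correlogram : ndarray
        The full cross-correlogram (NaN where an overlap was degenerate).
    """

    peak_r: float
    lag_s: float
    n_overlap: int
    lags_s: np.ndarray = field(repr=False)
    correlogram: np.ndarray = field(repr=False)
    rate: float = 90.0

    @property
    def lag_frames(self) -> int:
        return int(round(self.lag_s * self.rate))

    def summary(self) -> str:
        lines = [
            "Hand-eye coupling (cross-correlogram peak)",
            "==========================================",
            f"peak R           {self.peak_r: .4f}",
            f"lag              {self.lag_s: .4f} s "
            f"({self.lag_frames:+d} frames at {self.rate:g} Hz)",
            f"overlap at peak  {self.n_overlap:d} frames",
            f"lags searched    [{self.lags_s.min():.3f}, {self.lags_s.max():.3f}] s",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the cross-correlogram, marking the peak."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.lags_s, self.correlogram, lw=1.2)
        ax.axvline(self.lag_s, color="crimson", ls="--", lw=1)
        ax.scatter([self.lag_s], [self.peak_r], color="crimson", zorder=3)
        ax.set_xlabel("lag (s), positive = eye leads hand")
        ax.set_ylabel("Pearson r")
        ax.set_title(f"peak R = {self.peak_r:.3f} at lag = {self.lag_s:.3f} s")
        return ax


class HandEyeCoupling:
    """Per-trial hand-eye coupling model.

    Parameters
    ----------
    pair : AlignedPair
        Grasp-synchronised vertical hand and eye signals.
    max_lag : float
        Largest |lag| searched, seconds. The search is additionally
        constrained so every overlap keeps at least
        ``max(min_overlap, min_overlap_frac * n)`` frames: the
        grasp-to-lift segment is short and unconstrained lags on tiny
        overlaps produce spurious peaks.
    """

    def __init__(
        self,
        pair: AlignedPair,
        max_lag: float = DEFAULT_MAX_LAG_S,
        min_overlap: int = MIN_OVERLAP_FRAMES,
        min_overlap_frac: float = MIN_OVERLAP_FRACTION,
    ) -> None:
        self.pair = pair
        self.max_lag = float(max_lag)
        self.min_overlap = int(min_overlap)
        self.min_overlap_frac = float(min_overlap_frac)

    @classmethod
    def from_arrays(
        cls, hand: np.ndarray, eye: np.ndarray, rate: float = 90.0, **kwargs
    ) -> "HandEyeCoupling":
        """Build directly from two aligned vertical traces."""
        hand = np.asarray(hand, dtype=float)
        eye = np.asarray(eye, dtype=float)
        pair = AlignedPair(
            UniformSeries(rate, hand), UniformSeries(rate, eye), (0.0, (len(hand) - 1) / rate)
        )
        return cls(pair, **kwargs)

    def _lag_range(self) -> int:
        n = self.pair.n
        rate = self.pair.rate
        floor = max(self.min_overlap, int(np.ceil(self.min_overlap_frac * n)))
        k_max = min(int(round(self.max_lag * rate)), n - floor)
        if k_max < 0:
            raise TrialInvalidError(
                f"segment of {n} frames cannot satisfy the minimum overlap"
            )
        return k_max

    def fit(self) -> CouplingResult:
        """Cross-correlate over integer frame shifts and locate the peak.

        For lag k (frames, positive = eye leads): the first ``n - k``
        eye samples are paired with the last ``n - k`` hand samples.
        Ties in peak r are broken toward the smallest |lag|, then the
        positive lag.
        """
        x = self.pair.eye_vertical.values  # eye
        y = self.pair.hand_vertical.values  # hand
        n = self.pair.n
        rate = self.pair.rate
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise UndefinedCorrelationError(
                "constant signal: correlation undefined on every overlap"
            )
        k_max = self._lag_range()
        ks = np.arange(-k_max, k_max + 1)
        m = n - np.abs(ks)  # overlap lengths

        # prefix sums for per-overlap means and variances
        cx = np.concatenate(([0.0], np.cumsum(x)))
        cx2 = np.concatenate(([0.0], np.cumsum(x * x)))
        cy = np.concatenate(([0.0], np.cumsum(y)))
        cy2 = np.concatenate(([0.0], np.cumsum(y * y)))
        # cross terms: full correlation; sum_i x[i] * y[i+k] = c[n-1-k]
        c_full = np.correlate(x, y, mode="full")
        cross = c_full[n - 1 - ks]

        pos = ks >= 0
        kp = np.abs(ks)
        # eye window: [0, m) for k>=0, [|k|, n) for k<0
        sx = np.where(pos, cx[m] - cx[0], cx[n] - cx[kp])
        sx2 = np.where(pos, cx2[m] - cx2[0], cx2[n] - cx2[kp])
        # hand window: [k, n) for k>=0, [0, m) for k<0
        sy = np.where(pos, cy[n] - cy[kp], cy[m] - cy[0])
        sy2 = np.where(pos, cy2[n] - cy2[kp], cy2[m] - cy2[0])

        var_x = sx2 - sx * sx / m
        var_y = sy2 - sy * sy / m
        cov = cross - sx * sy / m
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = np.sqrt(var_x * var_y)
            r = np.where(denom > 0, cov / denom, np.nan)
        r = np.clip(r, -1.0, 1.0)

        if not np.isfinite(r).any():
            raise UndefinedCorrelationError(
                "every overlap had a constant signal; correlation undefined"
            )
        r_max = np.nanmax(r)
        cand = np.flatnonzero(np.isfinite(r) & (r >= r_max - 1e-12))
        # tie-break: smallest |lag|, then positive
        order = np.lexsort((-ks[cand], np.abs(ks[cand])))
        best = cand[order[0]]
        return CouplingResult(
            peak_r=float(r[best]),
            lag_s=float(ks[best] / rate),
            n_overlap=int(m[best]),
            lags_s=ks / rate,
            correlogram=r,
            rate=rate,
        )


def cross_correlate(
    pair: AlignedPair, max_lag: float = DEFAULT_MAX_LAG_S, **kwargs
) -> CouplingResult:
    """Functional wrapper: fit :class:`HandEyeCoupling` on ``pair``."""
    return HandEyeCoupling(pair, max_lag=max_lag, **kwargs).fit()


def participant_coupling_summary(
    results: Sequence[CouplingResult],
) -> tuple[float, float]:
    """Component-wise median (peak R, lag) across a participant's trials.

    Even trial counts use the midpoint of the two central values.
    Raises on zero valid trials: the participant is excluded upstream.
    """
    if len(results) == 0:
        raise TrialInvalidError("participant has no valid coupling trials")
    peak = float(np.median([r.peak_r for r in results]))
    lag = float(np.median([r.lag_s for r in results]))
    return peak, lag
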