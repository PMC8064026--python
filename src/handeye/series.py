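"""Uniformly sampled time series: the carrier for all pipeline signals.

Gaze (2-D, degrees, 90 Hz), wrist/object rigid-body position (3-D, mm,
120 Hz) and grip force (1-D, N, 500 Hz) are all held in the same
:class:`UniformSeries` container: a start time, a sample rate, a value
array (1-D for scalars, 2-D ``(n, width)`` for vectors) and an optional
per-sample validity flag used by the gaze branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import SeriesError

__all__ = ["UniformSeries", "FilterSpec"]


@dataclass
class UniformSeries:
    """A uniformly sampled signal.

    Parameters
    ----------
    rate : float
        Sample rate in Hz; must be positive.
    values : ndarray
        Shape ``(n,)`` or ``(n, width)``; ``n >= 1``.
    t0 : float
        Time of the first sample, seconds.
    validity : ndarray of bool, optional
        Per-sample validity. ``False`` marks missing (or interpolated)
        samples; used only by the gaze branch.
    """

    rate: float
    values: np.ndarray
    t0: float = 0.0
    validity: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise SeriesError(f"sample rate must be positive, got {self.rate}")
        if self.values.shape[0] == 0:
            raise SeriesError("series must hold at least one sample")
        if self.values.ndim > 2:
            raise SeriesError("values must be 1-D or 2-D")
        if self.validity is not None:
            self.validity = np.asarray(self.validity, dtype=bool)
            if self.validity.shape[0] != self.values.shape[0]:
                raise SeriesError("validity length must match values")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return 1 if self.values.ndim == 1 else self.values.shape[1]

    @property
    def duration(self) -> float:
        """Span from first to last sample, seconds."""
        return (self.n - 1) / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate

    def index_at(self, t: float) -> int:
        """Index of the sample nearest to time ``t`` (clipped to range)."""
        i = int(round((t - self.t0) * self.rate))
        return min(max(i, 0), self.n - 1)

    def column(self, j: int) -> "UniformSeries":
        """Extract one component of a vector series as a scalar series."""
        if self.values.ndim != 2:
            raise SeriesError("column() requires a vector series")
        return replace(self, values=self.values[:, j])

    def crop_index(self, i0: int, i1: int) -> "UniformSeries":
        """Slice samples ``[i0, i1)``, keeping the time origin consistent."""
        if not (0 <= i0 < i1 <= self.n):
            raise SeriesError(f"invalid crop [{i0}, {i1}) for n={self.n}")
        return UniformSeries(
            rate=self.rate,
            values=self.values[i0:i1],
            t0=self.t0 + i0 / self.rate,
            validity=None if self.validity is None else self.validity[i0:i1],
        )


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth design, applied forward then backward.

    ``cutoff`` is the per-pass design cutoff in Hz (the dual pass squares
    the magnitude response); ``order`` is the per-pass filter order.
    """

    cutoff: float
    order: int = 2

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise SeriesError(f"cutoff must be positive, got {self.cutoff}")
        if self.order < 1:
            raise SeriesError(f"order must be >= 1, got {self.order}")
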