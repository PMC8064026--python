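"""Filtering, resampling and differentiation shared by both signal branches.

The kinematic branch smooths rigid-body positions with a dual-pass
(zero-phase) low-pass Butterworth at 10 Hz and resamples them to the
90 Hz gaze grid; the gaze branch filters at 30 Hz. Velocity and
acceleration are forward differences scaled by the sample rate.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .exceptions import SeriesError
from .series import FilterSpec, UniformSeries

__all__ = [
    "butterworth_zero_phase",
    "resample_uniform",
    "finite_difference",
    "resultant_magnitude",
    "interpolate_gaps",
    "valid_segments",
]

# Reflective padding of 3 x filter order per pass suppresses endpoint
# transients on short trials without demanding long series.
_PAD_FACTOR = 3


@lru_cache(maxsize=64)
def _butter_design(order: int, cutoff: float, rate: float):
    b, a = sps.butter(order, cutoff, btype="low", fs=rate)
    return b, a, sps.lfilter_zi(b, a)


def _dual_pass(b, a, zi, x: np.ndarray, padlen: int) -> np.ndarray:
    """Forward-backward filtering with reflective (even) end padding.

    Equivalent to ``scipy.signal.filtfilt(..., padtype="even")`` but
    reuses the cached steady-state initial conditions.
    """
    one_d = x.ndim == 1
    if one_d:
        x = x[:, None]
    ext = np.concatenate((x[padlen:0:-1], x, x[-2 : -padlen - 2 : -1]), axis=0)
    zi_c = zi[:, None]
    y, _ = sps.lfilter(b, a, ext, axis=0, zi=zi_c * ext[0])
    y = y[::-1]
    y, _ = sps.lfilter(b, a, y, axis=0, zi=zi_c * y[0])
    out = y[::-1][padlen:-padlen]
    return out[:, 0] if one_d else out


def butterworth_zero_phase(series: UniformSeries, spec: FilterSpec) -> UniformSeries:
    """Dual-pass zero-phase low-pass Butterworth filter.

    The filter is designed at ``spec.cutoff`` (per pass) and applied
    forward then backward, so the effective magnitude response is the
    square of the single-pass response and the phase shift is zero.

    Raises
    ------
    SeriesError
        If the cutoff is at/above Nyquist or the series is shorter than
        the padding the dual pass requires.
    """
    nyquist = series.rate / 2.0
    if spec.cutoff >= nyquist:
        raise SeriesError(
            f"cutoff {spec.cutoff} Hz must be below Nyquist {nyquist} Hz"
        )
    padlen = _PAD_FACTOR * spec.order
    if series.n <= padlen:
        raise SeriesError(
            f"series of {series.n} samples too short for filtering "
            f"(needs > {padlen})"
        )
    b, a, zi = _butter_design(spec.order, spec.cutoff, series.rate)
    filtered = _dual_pass(b, a, zi, series.values, padlen)
    return UniformSeries(series.rate, filtered, series.t0, series.validity)


def resample_uniform(series: UniformSeries, target_rate: float) -> UniformSeries:
    """Resample to ``target_rate`` by linear interpolation.

    The output spans the same time interval (its last sample falls within
    one output frame of the input's last sample). Validity, if present,
    propagates conservatively: an output sample is valid only when both
    bracketing input samples are valid.
    """
    if target_rate <= 0:
        raise SeriesError(f"target rate must be positive, got {target_rate}")
    if series.n < 2:
        raise SeriesError("resampling requires at least two samples")
    n_out = int(np.floor(series.duration * target_rate)) + 1
    t_new = series.t0 + np.arange(n_out) / target_rate
    t_old = series.times
    if series.values.ndim == 1:
        out = np.interp(t_new, t_old, series.values)
    else:
        out = np.column_stack(
            [np.interp(t_new, t_old, series.values[:, j]) for j in range(series.width)]
        )
    validity = None
    if series.validity is not None:
        # valid iff both neighbours of the interpolation interval are valid
        idx = np.clip(np.searchsorted(t_old, t_new, side="right") - 1, 0, series.n - 2)
        validity = series.validity[idx] & series.validity[idx + 1]
    return UniformSeries(target_rate, out, series.t0, validity)


def finite_difference(series: UniformSeries) -> UniformSeries:
    """Forward differences scaled by the sample rate.

    ``out[i] = (x[i+1] - x[i]) * rate``; the output is one sample shorter
    and time-stamped at interval midpoints so that derivative series stay
    alignable with their parents. Applying twice yields acceleration.
    """
    if series.n < 2:
        raise SeriesError("finite difference requires at least two samples")
    dv = np.diff(series.values, axis=0) * series.rate
    return UniformSeries(series.rate, dv, series.t0 + 0.5 / series.rate)


def resultant_magnitude(series: UniformSeries) -> UniformSeries:
    """Per-sample Euclidean norm of a vector series (e.g. 3-D position)."""
    if series.values.ndim != 2:
        raise SeriesError("resultant requires a vector series")
    mag = np.linalg.norm(series.values, axis=1)
    return UniformSeries(series.rate, mag, series.t0, series.validity)


def interpolate_gaps(series: UniformSeries, max_gap_s: float = 0.1) -> UniformSeries:
    """Linearly interpolate short invalid gaps in place of missing samples.

    Gaps of at most ``max_gap_s`` are filled by linear interpolation from
    the nearest valid neighbours; the filled samples stay flagged invalid
    so that downstream rules ("not preceded or followed by missing data")
    still see them. Longer gaps are left as-is (NaN) and split the series
    for filtering via :func:`valid_segments`.
    """
    if series.validity is None:
        return series
    valid = series.validity.copy()
    values = series.values.copy()
    max_len = int(round(max_gap_s * series.rate))
    n = series.n
    invalid = ~valid
    if not invalid.any():
        return series
    # enumerate maximal invalid runs
    edges = np.flatnonzero(np.diff(np.concatenate(([False], invalid, [False]))))
    t = series.times
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start > max_len or start == 0 or stop == n:
            continue  # too long, or no valid neighbour on one side
        ti = t[start:stop]
        tp = [t[start - 1], t[stop]]
        if values.ndim == 1:
            values[start:stop] = np.interp(ti, tp, [values[start - 1], values[stop]])
        else:
            for j in range(values.shape[1]):
                values[start:stop, j] = np.interp(
                    ti, tp, [values[start - 1, j], values[stop, j]]
                )
    return UniformSeries(series.rate, values, series.t0, series.validity)


def valid_segments(series: UniformSeries, min_len: int = 1) -> list[tuple[int, int]]:
    """Maximal index ranges ``[i0, i1)`` of finite samples of length >= min_len.

    After :func:`interpolate_gaps`, short gaps are finite (interpolated)
    and long gaps remain NaN, so segments split exactly at long gaps.
    """
    vals = series.values
    finite = np.isfinite(vals) if vals.ndim == 1 else np.isfinite(vals).all(axis=1)
    edges = np.flatnonzero(np.diff(np.concatenate(([False], finite, [False]))))
    return [
        (int(a), int(b)) for a, b in zip(edges[::2], edges[1::2]) if b - a >= min_len
    ]
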