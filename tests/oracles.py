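"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plainly as possible (explicit Python
loops, no vectorisation, no shared code with the package) so that
agreement with the package's implementations is informative.
"""

from __future__ import annotations

import numpy as np


def brute_first_exceed(values, threshold):
    """Index of first sample strictly exceeding threshold, else None."""
    for i, v in enumerate(values):
        if v > threshold:
            return i
    return None


def brute_run_scan(mask, run_length):
    """Start indices of maximal True runs of at least run_length."""
    starts = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i >= run_length:
                starts.append(i)
            i = j
        else:
            i += 1
    return starts


def brute_reach_onset_index(speed, grasp_index, threshold=50.0, run_length=3):
    mask = [v > threshold and i < grasp_index for i, v in enumerate(speed)]
    runs = brute_run_scan(mask, run_length)
    return runs[0] if runs else None


def brute_lift_offset_index(speed, grasp_index, threshold=50.0, run_length=3):
    first_move = None
    for i in range(len(speed)):
        if i >= grasp_index and speed[i] > threshold:
            first_move = i
            break
    if first_move is None:
        return None
    mask = [i > first_move and speed[i] < threshold for i in range(len(speed))]
    runs = brute_run_scan(mask, run_length)
    return runs[0] if runs else None


def brute_saccades(accel, valid, multiplier=5.0, run_length=5, floor=1.0):
    """Threshold-scan saccade detection; returns (start, stop) index pairs
    with stop exclusive."""
    accel = [abs(a) for a in accel]
    vals = sorted(a for a, v in zip(accel, valid) if v)
    if not vals:
        raise ValueError("no valid samples")
    m = len(vals)
    median = vals[m // 2] if m % 2 else 0.5 * (vals[m // 2 - 1] + vals[m // 2])
    threshold = max(multiplier * median, floor)
    events = []
    i = 0
    n = len(accel)
    while i < n:
        if accel[i] > threshold and valid[i]:
            j = i
            while j < n and accel[j] > threshold and valid[j]:
                j += 1
            ok = j - i >= run_length
            if i > 0 and not valid[i - 1]:
                ok = False
            if j < n and not valid[j]:
                ok = False
            if ok:
                events.append((i, j))
            i = j
        else:
            i += 1
    return events


def brute_fixations(
    x, y, valid, dispersion_threshold=1.0, min_frames=None, rate=90.0,
    min_duration=0.1,
):
    """Literal I-DT: grow a window from the minimum duration; returns
    (start, stop) index pairs with stop exclusive."""
    n = len(x)
    if min_frames is None:
        min_frames = int(np.ceil(min_duration * rate)) + 1
    events = []
    i = 0

    def disp(a, b):
        xs = x[a:b]
        ys = y[a:b]
        return (max(xs) - min(xs)) + (max(ys) - min(ys))

    while i + min_frames <= n:
        j = i + min_frames
        if not all(valid[i:j]):
            i += 1
            continue
        if disp(i, j) > dispersion_threshold:
            i += 1
            continue
        while j < n and valid[j] and disp(i, j + 1) <= dispersion_threshold:
            j += 1
        events.append((i, j))
        i = j + 1
    return events


def brute_cross_correlogram(eye, hand, k_max):
    """Pearson r at every integer lag via np.corrcoef on the overlap."""
    n = len(eye)
    out = {}
    for k in range(-k_max, k_max + 1):
        if k >= 0:
            a, b = eye[: n - k], hand[k:]
        else:
            a, b = eye[-k:], hand[: n + k]
        if np.std(a) == 0 or np.std(b) == 0:
            out[k] = np.nan
        else:
            out[k] = float(np.corrcoef(a, b)[0, 1])
    return out


def brute_jzs_bf(t, n1, n2, scale=np.sqrt(2) / 2, n_grid=400_000):
    """Dense-trapezoid quadrature of the JZS integrand over log g.

    The prior concentrates mass near g -> 0, so the grid is geometric.
    """
    nu = n1 + n2 - 2
    n_eff = n1 * n2 / (n1 + n2)
    log_g = np.linspace(np.log(1e-9), np.log(1e9), n_grid)
    g = np.exp(log_g)
    shrink = 1.0 + n_eff * g
    like = shrink**-0.5 * (1.0 + t * t / (shrink * nu)) ** (-(nu + 1) / 2.0)
    prior = scale / np.sqrt(2 * np.pi) * g**-1.5 * np.exp(-(scale**2) / (2 * g))
    # d g = g d(log g)
    numerator = np.trapezoid(like * prior * g, log_g)
    denominator = (1.0 + t * t / nu) ** (-(nu + 1) / 2.0)
    return numerator / denominator


def brute_mannwhitney_exact_p(a, b):
    """Exact two-sided p by enumeration over all label assignments."""
    from itertools import combinations

    pooled = list(a) + list(b)
    n1 = len(a)

    def u_stat(idx):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        u = sum(1 for x in ga for y in gb if x > y) + 0.5 * sum(
            1 for x in ga for y in gb if x == y
        )
        return u

    observed = u_stat(range(n1))
    n1n2 = n1 * len(b)
    dev = abs(observed - n1n2 / 2.0)
    count = total = 0
    for idx in combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_stat(idx) - n1n2 / 2.0) >= dev - 1e-12:
            count += 1
    return count / total
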