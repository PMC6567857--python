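"""Shared trough/onset detection primitives for SEP, CSD-sink and MUA metrics.

One rule everywhere: a deflection qualifies when its extremum exceeds the
baseline level by ``criterion_k`` baseline SDs; its onset is the last
baseline-level crossing found walking backward from the extremum, with
linear sub-sample interpolation of the exact crossing time.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks


def window_mask(t: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    return (t >= window[0]) & (t < window[1])


def first_trough(x: np.ndarray, t: np.ndarray, baseline_window: tuple[float, float],
                 search_window: tuple[float, float], criterion_k: float):
    """First local minimum in the search window deeper than baseline − k·SD.

    Returns ``(trough_idx, baseline_mean, baseline_sd)`` or ``None``.
    """
    bmask = window_mask(t, baseline_window)
    if not bmask.any():
        raise ValueError("baseline window not covered by the trace")
    mu = float(x[bmask].mean())
    sd = float(x[bmask].std())
    idx, _ = find_peaks(-(x - mu), height=criterion_k * sd)
    smask = window_mask(t, search_window)
    idx = idx[smask[idx]]
    if idx.size == 0:
        return None
    return int(idx[0]), mu, sd


def backtrack_onset(x: np.ndarray, t: np.ndarray, trough_idx: int, level: float):
    """Last crossing of ``level`` before the trough (negative deflection).

    Walks backward from the trough until the trace is at/above the baseline
    level, then interpolates the crossing time.  Returns ``None`` when the
    trace never reaches the level before the trough.
    """
    j = trough_idx
    while j >= 0 and x[j] < level:
        j -= 1
    if j < 0:
        return None
    if x[j] == level or j == trough_idx:
        return float(t[j])
    # crossing between samples j (>= level) and j+1 (< level)
    frac = (x[j] - level) / (x[j] - x[j + 1])
    return float(t[j] + frac * (t[j + 1] - t[j]))


def front_baseline_onset(x: np.ndarray, t: np.ndarray, trough_idx: int, mu: float):
    """Onset as the intersection of the deflection front with the baseline.

    The front line is anchored at the (sub-sample) 20% and 80% depth
    crossings, found walking back from the trough, and extrapolated up to
    the baseline level.  Because both anchors sit on the steep part of the
    front this is far less sensitive to baseline noise than the raw
    last-crossing rule, and it is exact for a linear front.  Returns
    ``None`` when the anchors are degenerate.
    """
    depth = mu - x[trough_idx]
    if depth <= 0:
        return None
    t20 = backtrack_onset(x, t, trough_idx, mu - 0.2 * depth)
    t80 = backtrack_onset(x, t, trough_idx, mu - 0.8 * depth)
    if t20 is None or t80 is None or not t80 > t20:
        return None
    return t20 - (t80 - t20) / 3.0
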