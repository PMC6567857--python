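"""Multi-unit activity: adaptive-threshold spike detection, sliding-window
spike density, and early-response MUA metrics.

Spikes are negative deflections of the 300–5000 Hz band exceeding
``k`` standard deviations (k = 5 by default), with the SD measured over the
most silent 1 s segment of each channel's filtered trace, one spike per
suprathreshold excursion at its negative extremum, and a 1 ms dead time.
Spike density is a peristimulus estimate on a 1 ms sliding window advanced
in 0.2 ms steps, pooled over trials and the selected layer channels and
normalized per trial.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from ._detect import backtrack_onset, front_baseline_onset, window_mask
from .errors import ParameterError
from .io import StimulusTrain, WidebandRecording

__all__ = ["SpikeTimes", "MUADensity", "MUAMetrics", "quietest_segment",
           "detect_spikes", "spike_density", "mua_metrics", "oscillation_frequency"]


@dataclass
class SpikeTimes:
    """Per-channel sorted spike times in absolute recording time (ms)."""

    times_ms: tuple[np.ndarray, ...]
    thresholds_uV: tuple[float, ...]
    noise_sd_uV: tuple[float, ...]

    @property
    def n_channels(self) -> int:
        return len(self.times_ms)

    def count(self) -> int:
        return int(sum(t.size for t in self.times_ms))


@dataclass
class MUADensity:
    """Peristimulus spike density (spikes/ms) pooled over trials and channels."""

    time_ms: np.ndarray
    density: np.ndarray
    n_trials: int
    channels_used: tuple[int, ...]
    bin_ms: float
    step_ms: float


@dataclass
class MUAMetrics:
    onset_ms: float
    first_peak_density: float
    first_peak_delay_ms: float
    rising_slope: float           # spikes/ms²
    max_peak_density: float
    max_peak_delay_ms: float
    baseline_density: float


def quietest_segment(trace: np.ndarray, fs_hz: float, span_ms: float = 1000.0,
                     step_ms: float = 100.0) -> tuple[float, float]:
    """Locate the most silent ``span_ms`` of a trace.

    Windows start on a ``step_ms`` grid; returns ``(start_ms, sd)`` of the
    minimum-SD window.  A constant trace returns sd = 0 (threshold
    undefined; callers must treat it as a flag).
    """
    x = np.asarray(trace, dtype=float)
    span = int(round(span_ms * fs_hz / 1000.0))
    if x.size < span:
        raise ParameterError(f"trace shorter than {span_ms} ms")
    step = max(int(round(step_ms * fs_hz / 1000.0)), 1)
    starts = np.arange(0, x.size - span + 1, step)
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))
    s1 = c1[starts + span] - c1[starts]
    s2 = c2[starts + span] - c2[starts]
    var = np.maximum(s2 / span - (s1 / span) ** 2, 0.0)
    i = int(np.argmin(var))
    return float(starts[i] / fs_hz * 1000.0), float(np.sqrt(var[i]))


def _detect_channel(x: np.ndarray, fs_hz: float, k: float, dead_time_ms: float,
                    span_ms: float, step_ms: float) -> tuple[np.ndarray, float, float]:
    _start, sd = quietest_segment(x, fs_hz, span_ms, step_ms)
    if sd == 0.0:
        return np.empty(0), 0.0, 0.0
    thr = -k * sd
    below = x < thr
    if not below.any():
        return np.empty(0), thr, sd
    edges = np.diff(below.astype(np.int8))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0] + 1
    if below[0]:
        starts = np.concatenate(([0], starts))
    if below[-1]:
        ends = np.concatenate((ends, [x.size]))
    dead = dead_time_ms * fs_hz / 1000.0
    peaks = []
    last = -np.inf
    for s, e in zip(starts, ends):
        p = s + int(np.argmin(x[s:e]))
        if p - last >= dead:
            peaks.append(p)
            last = p
    idx = np.asarray(peaks, dtype=float)
    return idx / fs_hz * 1000.0, thr, sd


def detect_spikes(spike_band: WidebandRecording, threshold_k: float = 5.0,
                  dead_time_ms: float = 1.0, quietest_span_ms: float = 1000.0,
                  quietest_step_ms: float = 100.0) -> SpikeTimes:
    """Threshold-detect MUA spikes on every channel of a band-passed recording.

    The threshold is per channel: −``threshold_k`` × the SD of that
    channel's most silent ``quietest_span_ms`` segment.  Each suprathreshold
    excursion contributes one spike at its negative extremum; spikes closer
    than ``dead_time_ms`` to the previous one are suppressed.
    """
    if spike_band.duration_ms < quietest_span_ms:
        raise ParameterError("recording must be at least as long as the quiet span")
    times, thrs, sds = [], [], []
    for c in range(spike_band.geometry.n_channels):
        t_ms, thr, sd = _detect_channel(
            np.asarray(spike_band.data[:, c], dtype=float), spike_band.fs_hz,
            threshold_k, dead_time_ms, quietest_span_ms, quietest_step_ms)
        times.append(t_ms + spike_band.t0_ms)
        thrs.append(thr)
        sds.append(sd)
    return SpikeTimes(tuple(times), tuple(thrs), tuple(sds))


def spike_density(spikes: SpikeTimes, stim: StimulusTrain, channels: Sequence[int],
                  window_ms: tuple[float, float], bin_ms: float = 1.0,
                  step_ms: float = 0.2) -> MUADensity:
    """Sliding-window peristimulus spike density.

    ``density(t) = count in [t − bin/2, t + bin/2) / (bin × n_trials)``,
    pooled across trials and the given channels, on a grid spanning the
    window in ``step_ms`` steps.
    """
    channels = list(channels)
    if not channels:
        raise ParameterError("channel set must be non-empty")
    if len(stim) == 0:
        raise ParameterError("stimulus train is empty")
    pooled = []
    for c in channels:
        times = spikes.times_ms[c]
        for onset in stim.onsets:
            rel = times[(times >= onset + window_ms[0]) & (times < onset + window_ms[1])] - onset
            pooled.append(rel)
    rel = np.sort(np.concatenate(pooled)) if pooled else np.empty(0)
    grid = np.arange(window_ms[0], window_ms[1] + step_ms / 2.0, step_ms)
    lo = np.searchsorted(rel, grid - bin_ms / 2.0, side="left")
    hi = np.searchsorted(rel, grid + bin_ms / 2.0, side="left")
    density = (hi - lo) / (bin_ms * len(stim))
    return MUADensity(grid, density, len(stim), tuple(channels), bin_ms, step_ms)


def mua_metrics(d: MUADensity, baseline_window_ms: tuple[float, float] = (-200.0, 0.0),
                search_window_ms: tuple[float, float] = (3.0, 50.0),
                criterion_k: float = 3.0,
                peak_fraction: float = 0.2) -> MUAMetrics | None:
    """Early-response MUA descriptors, mirroring the SEP detection rules.

    The first peak is the first density maximum inside the search window
    that exceeds both baseline mean + ``criterion_k`` × baseline SD and
    ``peak_fraction`` of the window's maximum density (with Poisson-
    discrete baselines a chance coincidence of a few spontaneous spikes
    can clear the SD criterion alone); the onset is the intersection of
    the rising front with the baseline mean; the slope is the steepest
    rise between onset and first peak.  Returns ``None`` (no-response
    flag) when no peak meets the criteria.
    """
    t, y = d.time_ms, d.density
    bmask = window_mask(t, baseline_window_ms)
    if not bmask.any():
        raise ParameterError("baseline window not covered by the density grid")
    mu = float(y[bmask].mean())
    sd = float(y[bmask].std())
    # sub-peaks closer than the sliding-window width are not resolvable
    min_sep = max(int(np.ceil(d.bin_ms / d.step_ms)), 1)
    smask = window_mask(t, search_window_ms)
    floor = max(mu + criterion_k * sd, peak_fraction * float(y[smask].max(initial=0.0)))
    idx, _ = find_peaks(y, height=floor, distance=min_sep)
    idx = idx[smask[idx]]
    if idx.size == 0:
        return None
    p1 = int(idx[0])
    # onset: intersection of the rising front with the baseline level
    # (the raw last-crossing walk is dragged early by spontaneous counts)
    onset = front_baseline_onset(-y, t, p1, -mu)
    if onset is None:
        onset = backtrack_onset(-y, t, p1, -mu)
    if onset is None:
        onset = float(t[smask][0])
    deriv = np.gradient(y) / d.step_ms
    front = (t >= onset) & (t <= t[p1])
    slope = float(np.max(deriv[front])) if front.any() else 0.0
    sidx = np.nonzero(smask)[0]
    pmax = int(sidx[np.argmax(y[sidx])])
    return MUAMetrics(
        onset_ms=float(onset),
        first_peak_density=float(y[p1]),
        first_peak_delay_ms=float(t[p1]),
        rising_slope=slope,
        max_peak_density=float(y[pmax]),
        max_peak_delay_ms=float(t[pmax]),
        baseline_density=mu,
    )


def oscillation_frequency(d: MUADensity, early_window_ms: tuple[float, float],
                          prominence_frac: float = 0.25) -> float | None:
    """Frequency of the early high-frequency burst.

    Peaks inside the window with prominence at least ``prominence_frac`` of
    the tallest early peak are located, refined to sub-grid precision by
    parabolic interpolation, and the frequency is 1000 / mean inter-peak
    interval.  Returns ``None`` (undefined flag) with fewer than two peaks.
    """
    t, y = d.time_ms, d.density
    mask = window_mask(t, early_window_ms)
    if not mask.any():
        return None
    seg = y[mask]
    tseg = t[mask]
    if seg.max() <= 0:
        return None
    min_sep = max(int(np.ceil(d.bin_ms / d.step_ms)), 1)
    idx, _ = find_peaks(seg, prominence=prominence_frac * seg.max(), distance=min_sep)
    if idx.size < 2:
        return None
    # refine each peak time by a local background-subtracted centroid
    # (much less jittery than the raw grid maximum for count-noise data);
    # the window is kept narrower than the inter-peak spacing so that
    # neighboring burst peaks do not pull the centroid
    refined = []
    half_w = max(int(round(1.0 / d.step_ms)), 1)
    for p in idx:
        lo = max(p - half_w, 0)
        hi = min(p + half_w, seg.size - 1)
        w = seg[lo:hi + 1] - seg[lo:hi + 1].min()
        if w.sum() <= 0:
            refined.append(float(tseg[p]))
            continue
        refined.append(float(np.sum(tseg[lo:hi + 1] * w) / np.sum(w)))
    ipi = np.diff(refined)
    return float(1000.0 / np.mean(ipi))
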