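"""Sensory-evoked potential (SEP) parameterization.

The SEP is the first negative LFP trough of the averaged evoked response.
Four descriptors are extracted: onset latency (baseline crossing of the
front), peak latency, peak amplitude (trough depth below baseline, reported
as a positive magnitude) and maximal front slope (steepest descent between
onset and trough).  Amplitudes at fixed latencies are read out with linear
interpolation after baseline subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._detect import backtrack_onset, first_trough, front_baseline_onset, window_mask
from .conditioning import EvokedAverage
from .errors import ParameterError

__all__ = ["SEPMetrics", "detect_sep", "amplitude_at", "first_derivative"]


@dataclass
class SEPMetrics:
    onset_ms: float
    peak_latency_ms: float
    peak_amplitude_uV: float
    max_slope_uV_per_ms: float
    baseline_uV: float
    amplitude_at: dict[float, float] = field(default_factory=dict)


def first_derivative(trace: np.ndarray, fs_hz: float) -> np.ndarray:
    """dV/dt in μV/ms: central differences interior, one-sided at the edges."""
    x = np.asarray(trace, dtype=float)
    if x.size < 3:
        raise ParameterError("need at least 3 samples for a derivative")
    return np.gradient(x) * fs_hz / 1000.0


def detect_sep(avg: EvokedAverage, channel: int,
               search_window_ms: tuple[float, float] = (3.0, 50.0),
               baseline_window_ms: tuple[float, float] = (-100.0, 0.0),
               criterion_k: float = 4.0) -> SEPMetrics | None:
    """Detect and parameterize the first SEP trough on one channel.

    Returns ``None`` (no-response flag) when no trough in the search window
    is deeper than ``criterion_k`` baseline SDs below the baseline mean.
    """
    t = avg.time_ms
    x = np.asarray(avg.channel(channel), dtype=float)
    hit = first_trough(x, t, baseline_window_ms, search_window_ms, criterion_k)
    if hit is None:
        return None
    trough, mu, _sd = hit
    onset = front_baseline_onset(x, t, trough, mu)
    if onset is None:
        onset = backtrack_onset(x, t, trough, mu)
    if onset is None:
        onset = float(t[window_mask(t, search_window_ms)][0])
    deriv = first_derivative(x, avg.fs_hz)
    front = (t >= onset) & (t <= t[trough])
    max_slope = float(np.max(-deriv[front])) if front.any() else 0.0
    return SEPMetrics(
        onset_ms=float(onset),
        peak_latency_ms=float(t[trough]),
        peak_amplitude_uV=float(mu - x[trough]),
        max_slope_uV_per_ms=max_slope,
        baseline_uV=mu,
    )


def amplitude_at(avg: EvokedAverage, channel: int, t_ms: float,
                 baseline_window_ms: tuple[float, float] = (-100.0, 0.0)) -> float:
    """Baseline-subtracted LFP value at ``t_ms`` (signed, linear interpolation)."""
    t = avg.time_ms
    if not (t[0] <= t_ms <= t[-1]):
        raise ParameterError(f"t = {t_ms} ms outside the averaged window")
    x = np.asarray(avg.channel(channel), dtype=float)
    bmask = window_mask(t, baseline_window_ms)
    mu = float(x[bmask].mean()) if bmask.any() else 0.0
    return float(np.interp(t_ms, t, x) - mu)
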