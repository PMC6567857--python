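"""Pharmacological decomposition of the evoked response.

The drug-resistant component is the averaged drug-condition response; the
drug-sensitive component is the pointwise difference control − drug (both
baseline-subtracted first), so resistant + sensitive reconstructs the
control trace to machine precision.  Each component is characterized by
its relative contribution at chosen latencies, 20–80% rise time, time to
peak, an exponential decay constant fitted after the last peak, and the
latency of an optional second (biphasic-decay) peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from ._detect import window_mask
from .conditioning import EvokedAverage
from .errors import AlignmentError, ParameterError

__all__ = ["DecompositionResult", "ExpFit", "decompose", "contribution_at",
           "rise_time_2080", "fit_exponential_decay", "find_second_peak",
           "decay_fit_window"]


@dataclass
class DecompositionResult:
    """Resistant (drug) and sensitive (control − drug) traces, μV."""

    time_ms: np.ndarray
    control: np.ndarray
    resistant: np.ndarray
    sensitive: np.ndarray
    channel: int
    contributions: dict[float, tuple[float, float]] = field(default_factory=dict)
    kinetics: dict[str, dict[str, float]] = field(default_factory=dict)


@dataclass
class ExpFit:
    amplitude_uV: float
    tau_ms: float
    fit_window_ms: tuple[float, float]
    residual_rms: float


def decompose(control_avg: EvokedAverage, drug_avg: EvokedAverage, channel: int,
              baseline_window_ms: tuple[float, float] = (-100.0, 0.0)) -> DecompositionResult:
    """Split the control response into drug-resistant and drug-sensitive parts.

    Both averages must share the exact same time grid; each trace is
    baseline-subtracted (mean over ``baseline_window_ms``) before the
    subtraction, so ``resistant + sensitive == control`` pointwise.
    """
    tc, td = control_avg.time_ms, drug_avg.time_ms
    if tc.shape != td.shape or not np.array_equal(tc, td):
        raise AlignmentError("control and drug averages are on different time grids")
    bmask = window_mask(tc, baseline_window_ms)
    if not bmask.any():
        raise AlignmentError("baseline window not covered by the averaged traces")
    c = np.asarray(control_avg.channel(channel), dtype=float)
    r = np.asarray(drug_avg.channel(channel), dtype=float)
    c = c - c[bmask].mean()
    r = r - r[bmask].mean()
    return DecompositionResult(tc.copy(), c, r, c - r, channel)


def contribution_at(dec: DecompositionResult, t_ms: float) -> tuple[float, float] | None:
    """Percent contributions (resistant, sensitive) at a latency.

    Linear interpolation between grid samples; ``None`` (undefined flag)
    when the control value at ``t_ms`` is zero.  Where defined the two
    percentages sum to exactly 100.
    """
    c = float(np.interp(t_ms, dec.time_ms, dec.control))
    if c == 0.0:
        return None
    r = float(np.interp(t_ms, dec.time_ms, dec.resistant))
    res = 100.0 * r / c
    return res, 100.0 - res


def rise_time_2080(trace: np.ndarray, time_ms: np.ndarray, onset_ms: float,
                   peak_ms: float) -> float | None:
    """20–80% rise time of a deflection's front, sub-sample interpolated.

    Works on the magnitude of the (baseline-subtracted) trace between onset
    and peak; returns ``None`` when either crossing is absent.
    """
    mask = (time_ms >= onset_ms) & (time_ms <= peak_ms)
    if mask.sum() < 2:
        return None
    t = time_ms[mask]
    y = np.abs(np.asarray(trace, dtype=float)[mask])
    peak_mag = np.abs(float(np.interp(peak_ms, time_ms, trace)))
    if peak_mag <= 0:
        return None

    def first_crossing(level: float) -> float | None:
        above = y >= level
        if not above.any():
            return None
        j = int(np.argmax(above))
        if j == 0:
            return float(t[0])
        frac = (level - y[j - 1]) / (y[j] - y[j - 1])
        return float(t[j - 1] + frac * (t[j] - t[j - 1]))

    t20 = first_crossing(0.2 * peak_mag)
    t80 = first_crossing(0.8 * peak_mag)
    if t20 is None or t80 is None:
        return None
    return t80 - t20


def decay_fit_window(trace: np.ndarray, time_ms: np.ndarray, last_peak_ms: float,
                     floor_frac: float = 0.05) -> tuple[float, float]:
    """Fit window from the last peak to where the magnitude first falls below
    ``floor_frac`` of the peak magnitude (or the end of the trace)."""
    y = np.abs(np.asarray(trace, dtype=float))
    peak_mag = np.abs(float(np.interp(last_peak_ms, time_ms, trace)))
    after = time_ms > last_peak_ms
    below = after & (y < floor_frac * peak_mag)
    end = float(time_ms[below][0]) if below.any() else float(time_ms[-1])
    return float(last_peak_ms), end


def fit_exponential_decay(trace: np.ndarray, time_ms: np.ndarray,
                          fit_window_ms: tuple[float, float]) -> ExpFit | None:
    """Least-squares fit of ``A · exp(−(t − t₀)/τ)`` to the magnitude trace.

    Initialized log-linearly, refined by nonlinear least squares.  Returns
    ``None`` (fit-failure flag) for non-decaying windows (τ ≤ 0, divergent
    fits) or fewer than 10 samples.
    """
    mask = (time_ms >= fit_window_ms[0]) & (time_ms <= fit_window_ms[1])
    if mask.sum() < 10:
        raise ParameterError("decay fit needs at least 10 samples in the window")
    t = time_ms[mask] - fit_window_ms[0]
    y = np.abs(np.asarray(trace, dtype=float)[mask])
    pos = y > 0
    if pos.sum() < 10:
        return None
    slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
    if slope >= 0:
        return None
    a0, tau0 = float(np.exp(intercept)), float(-1.0 / slope)
    try:
        popt, _ = curve_fit(lambda tt, a, tau: a * np.exp(-tt / tau), t, y,
                            p0=(a0, tau0), maxfev=10000)
    except RuntimeError:
        return None
    a, tau = float(popt[0]), float(popt[1])
    if tau <= 0 or not np.isfinite(tau):
        return None
    resid = y - a * np.exp(-t / tau)
    return ExpFit(a, tau, (float(fit_window_ms[0]), float(fit_window_ms[1])),
                  float(np.sqrt(np.mean(resid**2))))


def find_second_peak(sensitive_trace: np.ndarray, time_ms: np.ndarray,
                     after_ms: float = 30.0,
                     prominence_frac: float = 0.10) -> float | None:
    """Latency of the first late peak of the component magnitude after
    ``after_ms`` with prominence ≥ ``prominence_frac`` of the main peak;
    ``None`` for a monophasic decay."""
    y = np.abs(np.asarray(sensitive_trace, dtype=float))
    main = float(y[(time_ms >= 0)].max(initial=0.0))
    if main <= 0:
        return None
    idx, _ = find_peaks(y, prominence=prominence_frac * main)
    idx = idx[time_ms[idx] >= after_ms]
    if idx.size == 0:
        return None
    return float(time_ms[idx[0]])
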