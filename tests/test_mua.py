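"""MUA analysis: quietest-segment search, threshold detection, density
estimation, metrics on constructed waveforms, and detector properties."""

import numpy as np
import pytest

from lamep.errors import ParameterError
from lamep.io import ProbeGeometry, StimulusTrain, WidebandRecording
from lamep.mua import (MUADensity, SpikeTimes, detect_spikes, mua_metrics,
                       oscillation_frequency, quietest_segment, spike_density)

FS = 32000.0
GEOM3 = ProbeGeometry.uniform(3, 100.0, 100.0)


def _rec(x):
    data = np.zeros((x.size, 3), dtype=float)
    data[:, 0] = x
    return WidebandRecording(data, FS, GEOM3)


def _spike_wave(amp):
    n = int(0.5e-3 * FS)
    return amp * np.concatenate([-np.sin(np.pi * np.arange(n) / n),
                                 0.35 * np.sin(np.pi * np.arange(n) / n)])


class TestQuietestSegment:
    def test_quiet_gap_found_inside_loud_background(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 10.0, size=int(FS * 5))
        lo = int(FS * 2.2)
        x[lo:lo + int(FS)] = rng.normal(0, 1.0, size=int(FS))
        start_ms, sd = quietest_segment(x, FS)
        assert abs(start_ms - 2200.0) <= 150.0
        assert sd == pytest.approx(1.0, rel=0.05)

    def test_homogeneous_noise_sd_close_to_global(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 3.0, size=int(FS * 4))
        _start, sd = quietest_segment(x, FS)
        assert sd == pytest.approx(x.std(), rel=0.05)

    def test_all_zero_trace_flags_sd_zero(self):
        _start, sd = quietest_segment(np.zeros(int(FS * 2)), FS)
        assert sd == 0.0

    def test_short_trace_is_error(self):
        with pytest.raises(ParameterError):
            quietest_segment(np.zeros(100), FS)


class TestDetectSpikes:
    def test_zero_trace_detects_nothing(self):
        spikes = detect_spikes(_rec(np.zeros(int(FS * 2))))
        assert spikes.count() == 0

    def test_injected_spikes_recovered(self):
        rng = np.random.default_rng(2)
        sd = 10.0
        x = rng.normal(0, sd, size=int(FS * 10))
        band_sd = sd * np.sqrt(4700.0 / 16000.0)
        wave = _spike_wave(8.0 * band_sd)
        true_ms = 300.0 + 480.0 * np.arange(20)
        for t0 in true_ms:
            i = int(t0 * FS / 1000.0)
            x[i:i + wave.size] += wave
        from lamep.conditioning import bandpass_spike
        spikes = detect_spikes(bandpass_spike(_rec(x)))
        det = spikes.times_ms[0]
        hits = sum(np.any(np.abs(det - (t + 0.25)) <= 0.5) for t in true_ms)
        assert hits >= 19
        assert det.size - hits <= 1  # ≤1 false positive per this 10 s stretch

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 5.0, size=int(FS * 3))
        counts = [detect_spikes(_rec(x), threshold_k=k).count()
                  for k in (3.0, 4.0, 5.0)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_translation_equivariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 5.0, size=int(FS * 3))
        wave = _spike_wave(60.0)
        for t0 in (500.0, 1200.0, 2100.0):
            i = int(t0 * FS / 1000.0)
            x[i:i + wave.size] += wave
        shift = int(0.25 * FS)  # 250 ms
        y = np.concatenate([x[shift:], x[:shift]])  # advance by 250 ms
        a = detect_spikes(_rec(x)).times_ms[0]
        b = detect_spikes(_rec(y)).times_ms[0]
        a = a[(a > 300.0) & (a < 2500.0)]
        b = b[(b > 50.0) & (b < 2250.0)]
        assert np.allclose(np.sort(a) - 250.0, np.sort(b), atol=0.1)

    def test_short_recording_is_error(self):
        with pytest.raises(ParameterError):
            detect_spikes(_rec(np.zeros(int(FS * 0.5))))


def _spikes(per_channel):
    return SpikeTimes(tuple(np.asarray(c, dtype=float) for c in per_channel),
                      (0.0,) * len(per_channel), (1.0,) * len(per_channel))


class TestSpikeDensity:
    def test_single_spike_kernel(self):
        spikes = _spikes([[1010.0], [], []])
        stim = StimulusTrain((1000.0,))
        d = spike_density(spikes, stim, [0, 1, 2], (-50.0, 50.0))
        near = np.abs(d.time_ms - 10.0) < 0.45
        far = np.abs(d.time_ms - 10.0) > 0.55
        assert np.allclose(d.density[near], 1.0)
        assert np.allclose(d.density[far], 0.0)

    def test_no_spikes_identically_zero(self):
        d = spike_density(_spikes([[], [], []]), StimulusTrain((1000.0,)),
                          [0, 1, 2], (-50.0, 50.0))
        assert np.all(d.density == 0.0)

    def test_poisson_rate_recovered(self):
        rng = np.random.default_rng(5)
        rate = 0.05  # spikes/ms
        onsets = 1000.0 + 400.0 * np.arange(500)
        times = []
        for onset in onsets:
            n = rng.poisson(rate * 100.0)
            times.extend(onset + rng.uniform(0.0, 100.0, size=n))
        d = spike_density(_spikes([np.sort(times)]), StimulusTrain(tuple(onsets)),
                          [0], (0.0, 100.0))
        mid = (d.time_ms > 5) & (d.time_ms < 95)
        sem = np.sqrt(rate / (1.0 * 500))
        assert d.density[mid].mean() == pytest.approx(rate, abs=3 * sem)

    def test_density_conservation(self):
        rng = np.random.default_rng(6)
        onsets = 1000.0 + 500.0 * np.arange(40)
        times = np.sort(rng.uniform(900.0, 21000.0, size=400))
        stim = StimulusTrain(tuple(onsets))
        d = spike_density(_spikes([times]), stim, [0], (-50.0, 100.0))
        count = sum(((times >= o - 50.0) & (times < o + 100.0)).sum() for o in onsets)
        integral = d.step_ms * d.density.sum()
        edge = sum(((np.abs(times - (o - 50.0)) < d.bin_ms)
                    | (np.abs(times - (o + 100.0)) < d.bin_ms)).sum()
                   for o in onsets)
        assert abs(integral - count / len(onsets)) <= (edge + 1) / len(onsets)

    def test_empty_channel_set_is_error(self):
        with pytest.raises(ParameterError):
            spike_density(_spikes([[]]), StimulusTrain((1000.0,)), [], (-50.0, 50.0))


def _density(t, y, n_trials=100):
    return MUADensity(np.asarray(t, dtype=float), np.asarray(y, dtype=float),
                      n_trials, (0,), 1.0, 0.2)


class TestMuaMetrics:
    def test_triangular_bump_peak_on_grid(self):
        t = np.arange(-200.1, 50.0, 0.2)  # grid hits 9.3 exactly
        y = np.maximum(0.0, 0.4 * (1.0 - np.abs(t - 9.3) / 2.0))
        m = mua_metrics(_density(t, y))
        assert m.first_peak_delay_ms == pytest.approx(9.3, abs=1e-9)
        assert m.first_peak_density == pytest.approx(0.4)
        assert m.onset_ms == pytest.approx(9.3 - 2.0, abs=0.21)
        assert m.onset_ms <= m.first_peak_delay_ms <= m.max_peak_delay_ms

    def test_flat_density_flags_no_response(self):
        t = np.arange(-200.0, 50.0, 0.2)
        assert mua_metrics(_density(t, np.zeros_like(t))) is None


class TestOscillationFrequency:
    def test_planted_peaks_every_2p5_ms(self):
        t = np.arange(-200.0, 50.0, 0.2)
        y = np.zeros_like(t)
        for c in (8.0, 10.5, 13.0):
            y += 0.4 * np.exp(-0.5 * ((t - c) / 0.5) ** 2)
        f = oscillation_frequency(_density(t, y), (5.0, 20.0))
        assert f == pytest.approx(400.0, abs=2.0)

    def test_single_peak_is_undefined(self):
        t = np.arange(-200.0, 50.0, 0.2)
        y = 0.4 * np.exp(-0.5 * ((t - 9.0) / 0.5) ** 2)
        assert oscillation_frequency(_density(t, y), (5.0, 20.0)) is None
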