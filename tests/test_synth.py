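"""Generator correctness: kernel kinetics, the CSD forward model, spike-train
statistics, pairing semantics and determinism."""

import numpy as np
import pytest

from lamep.errors import ParameterError, ValidationError
from lamep.io import ProbeGeometry, default_geometry
from lamep.synth import (ComponentKinetics, MUAProfile, SimulationConfig,
                         component_waveform, generate_spike_train, lfp_from_csd,
                         simulate_pair)

FAST = ComponentKinetics(7.5, 2.0, 11.1, 100.0)


class TestComponentWaveform:
    def test_zero_before_onset_and_negative_going(self):
        t = np.arange(0.0, 200.0, 0.01)
        w = component_waveform(FAST, t)
        assert np.all(w[t < 7.5] == 0.0)
        assert np.all(w <= 0.0)

    def test_amplitude_normalization(self):
        t = np.arange(0.0, 200.0, 0.01)
        w = component_waveform(FAST, t)
        assert w.min() == pytest.approx(-100.0, abs=0.01)

    def test_decay_tau_definition(self):
        # value at (peak time + tau) is peak/e: the post-peak decay is an
        # exact exponential with the configured constant
        k = ComponentKinetics(5.0, 2.0, 11.1, 100.0)
        t = np.arange(0.0, 300.0, 0.01)
        w = component_waveform(k, t)
        ip = int(np.argmin(w))
        itau = ip + int(round(11.1 / 0.01))
        assert w[itau] / w[ip] == pytest.approx(np.exp(-1), rel=1e-3)

    def test_rise_time_20_80_closed_form(self):
        t = np.arange(0.0, 100.0, 0.001)
        w = -component_waveform(FAST, t)  # magnitude
        t20 = t[np.argmax(w >= 20.0)]
        t80 = t[np.argmax(w >= 80.0)]
        assert t80 - t20 == pytest.approx(2.0, abs=0.005)

    def test_fast_component_returns_to_baseline(self):
        # fast kinetics decay toward baseline: ~10% of peak 30 ms after
        # onset and below 5% within 40 ms (exact exponential, tau 11.1 ms)
        t = np.arange(0.0, 200.0, 0.01)
        w = -component_waveform(FAST, t) / 100.0
        assert w[np.searchsorted(t, 7.5 + 30.0)] < 0.12
        assert w[np.searchsorted(t, 7.5 + 40.0)] < 0.05

    def test_second_lobe_delay(self):
        k = ComponentKinetics(8.0, 3.9, 88.3, 100.0, 28.5, 0.22)
        t = np.arange(0.0, 400.0, 0.01)
        w = -component_waveform(k, t)
        first = t[np.argmax(w)]
        late = (t > first + 15.0)
        seg = w[late]
        loc = np.nonzero((seg[1:-1] > seg[:-2]) & (seg[1:-1] >= seg[2:]))[0] + 1
        # the decaying main lobe shifts the summed local maximum slightly
        # ahead of the nominal lobe peak (~0.7 ms at the default kinetics)
        assert t[late][loc[0]] == pytest.approx(first + 28.5, abs=1.0)

    def test_unresolvable_grid_is_error(self):
        with pytest.raises(ParameterError):
            component_waveform(FAST, np.arange(0.0, 100.0, 5.0))

    def test_second_lobe_fields_must_pair(self):
        with pytest.raises(ValidationError):
            ComponentKinetics(7.5, 2.0, 11.1, 100.0, second_peak_delay_ms=30.0)


class TestLfpFromCsd:
    def test_zero_csd_gives_zero_lfp(self):
        geom = default_geometry()
        lfp = lfp_from_csd(np.zeros((14, 5)), geom)
        assert np.all(lfp == 0.0)

    def test_impulse_sink_gives_tent_profile(self):
        # independent oracle: dense solve of the tridiagonal system
        geom = ProbeGeometry.uniform(8, 100.0, 100.0)
        c = np.zeros((6, 1))
        c[2, 0] = -5.0
        h = 0.1
        m = (np.diag(np.full(6, 2.0)) - np.diag(np.ones(5), 1)
             - np.diag(np.ones(5), -1)) / h**2
        expected = np.linalg.solve(m, c)
        lfp = lfp_from_csd(c, geom)
        assert np.allclose(lfp[1:-1], expected, atol=1e-12)
        # tent: piecewise-linear in depth on both sides of the sink
        inner = lfp[:, 0]
        assert np.allclose(np.diff(inner[:4]), np.diff(inner[:4])[0], atol=1e-9)
        assert np.allclose(np.diff(inner[3:]), np.diff(inner[3:])[0], atol=1e-9)

    def test_roundtrip_with_second_difference_operator(self):
        geom = default_geometry()
        rng = np.random.default_rng(5)
        c = rng.normal(size=(14, 20))
        lfp = lfp_from_csd(c, geom)
        h = geom.spacing_um / 1000.0
        back = -(lfp[:-2] - 2 * lfp[1:-1] + lfp[2:]) / h**2
        assert np.max(np.abs(back - c)) < 1e-9 * max(np.abs(c).max(), 1.0)

    def test_too_few_channels_is_geometry_error(self):
        from lamep.errors import GeometryError
        geom = ProbeGeometry.uniform(3, 100.0, 100.0)
        with pytest.raises(GeometryError):
            lfp_from_csd(np.zeros((3, 4)), geom)  # wrong interior row count


class TestGenerateSpikeTrain:
    grid = np.arange(0.0, 100.0, 0.1)

    def test_zero_profile_zero_spikes(self):
        trains = generate_spike_train(np.zeros_like(self.grid), self.grid, 10, 0)
        assert all(t.size == 0 for t in trains)

    def test_poisson_total_count(self):
        rate = np.full_like(self.grid, 0.01)  # spikes/ms over 100 ms
        trains = generate_spike_train(rate, self.grid, 1000, 7)
        total = sum(t.size for t in trains)
        assert abs(total - 1000) < 3 * np.sqrt(1000)

    def test_fixed_seed_reproducible(self):
        rate = np.full_like(self.grid, 0.05)
        a = generate_spike_train(rate, self.grid, 5, 11)
        b = generate_spike_train(rate, self.grid, 5, 11)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            generate_spike_train(np.full_like(self.grid, -1.0), self.grid, 1, 0)


def _tiny_cfg(**kw):
    base = dict(seed=3, n_trials=3, isi_range_ms=(1600.0, 1800.0))
    base.update(kw)
    return SimulationConfig(**base)


class TestSimulatePair:
    def test_null_drug_effect_is_bit_identical(self):
        ctrl, drug, _stim, _t = simulate_pair(_tiny_cfg(drug_suppression=0.0))
        assert np.array_equal(ctrl.data, drug.data)

    def test_fixed_seed_is_bit_identical(self):
        a = simulate_pair(_tiny_cfg())
        b = simulate_pair(_tiny_cfg())
        assert np.array_equal(a[0].data, b[0].data)
        assert np.array_equal(a[1].data, b[1].data)
        assert a[2].onsets_ms == b[2].onsets_ms
        for c in range(16):
            assert np.array_equal(a[3].spike_times["drug"][c],
                                  b[3].spike_times["drug"][c])

    def test_full_block_noiseless_drug_is_fast_component_alone(self):
        cfg = _tiny_cfg(drug_suppression=1.0, noise_sd_uV=0.0, lfp_noise_sd_uV=0.0)
        _ctrl, drug, stim, truth = simulate_pair(cfg)
        fs = cfg.fs_hz
        i0 = int(np.ceil(stim.onsets[0] * fs / 1000.0))
        seg = drug.data[i0:i0 + int(0.2 * fs), truth.lfp_channel]
        t_rel = np.arange(seg.size) / fs * 1000.0
        expected = component_waveform(cfg.fast_kinetics, t_rel)
        assert np.max(np.abs(seg - expected)) < 1e-2 * cfg.fast_kinetics.peak_amp_uV

    def test_calibration_fidelity_of_control_peak(self):
        # noiseless control trace at the analysis channel must hit the
        # analytic fast+slow mixture minimum within one 1 ms grid step
        cfg = _tiny_cfg()
        _c, _d, _s, truth = simulate_pair(cfg)
        tdense = np.arange(0.0, 300.0, 0.01)
        mix = (component_waveform(cfg.fast_kinetics, tdense)
               + component_waveform(cfg.slow_kinetics, tdense))
        trace = truth.noiseless_lfp["control"][truth.lfp_channel]
        assert trace.min() == pytest.approx(mix.min(), abs=abs(mix.min()) * 5e-3)
        t_at_min = truth.truth_time_ms[np.argmin(trace)]
        assert abs(t_at_min - tdense[np.argmin(mix)]) <= 1.0

    def test_true_csd_consistent_with_noiseless_lfp(self):
        cfg = _tiny_cfg()
        _c, _d, _s, truth = simulate_pair(cfg)
        h = cfg.geometry.spacing_um / 1000.0
        for cond in ("control", "drug"):
            v = truth.noiseless_lfp[cond]
            back = -(v[:-2] - 2 * v[1:-1] + v[2:]) / h**2
            assert np.max(np.abs(back - truth.true_csd[cond])) < 1e-9 * np.abs(
                truth.true_csd[cond]).max()

    def test_invalid_suppression_rejected(self):
        with pytest.raises(ValidationError):
            _tiny_cfg(drug_suppression=1.5)
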