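"""Epoch statistics: rate arithmetic, the decrement, the matched-samples
signed-rank test against an exhaustive enumeration oracle and scipy, and the
sampled-neuron estimate."""

import itertools
import warnings

import numpy as np
import pytest
from scipy.stats import rankdata, wilcoxon

from lamep.epochs import (EpochDefinition, decrement, epoch_rates,
                          estimate_sampled_neurons, paired_epoch_tests,
                          signed_rank_test)
from lamep.errors import ParameterError, ValidationError
from lamep.io import StimulusTrain
from lamep.mua import SpikeTimes

EPOCHS = EpochDefinition.from_edges()


def _spikes(per_channel):
    return SpikeTimes(tuple(np.asarray(c, dtype=float) for c in per_channel),
                      (0.0,) * len(per_channel), (1.0,) * len(per_channel))


def enumeration_p(diffs):
    """Oracle: exhaustive two-sided signed-rank p over all 2^n sign patterns."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array([sum(r for r, s in zip(ranks, signs) if s)
                   for signs in itertools.product([False, True], repeat=n)])
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestEpochRates:
    def test_planted_spikes_give_exact_corrected_rate(self):
        onsets = tuple(5000.0 + 3000.0 * k for k in range(100))
        ch0 = np.sort([o + 15.0 for o in onsets])  # 1 spike/trial in 10-20 ms
        spikes = _spikes([ch0, []])
        st = epoch_rates(spikes, StimulusTrain(onsets), [0, 1], EPOCHS)
        rates = dict(zip(st.epochs.names, st.rates_hz))
        assert rates["10-20"] == pytest.approx(50.0)  # 1/(2 ch × 0.010 s)
        for name in ("5-8", "8-10", "20-50", "50-100"):
            assert rates[name] == pytest.approx(0.0, abs=1e-9)

    def test_zero_spikes_give_zero_rates(self):
        onsets = tuple(5000.0 + 3000.0 * k for k in range(10))
        st = epoch_rates(_spikes([[], []]), StimulusTrain(onsets), [0, 1], EPOCHS)
        assert np.allclose(st.rates_hz, 0.0)
        assert st.spont_rate_hz == 0.0

    def test_homogeneous_poisson_corrects_to_zero(self):
        rng = np.random.default_rng(0)
        onsets = tuple(5000.0 + 3000.0 * k for k in range(60))
        duration = onsets[-1] + 2000.0
        means = []
        for _ in range(50):
            times = np.sort(rng.uniform(0.0, duration,
                                        size=rng.poisson(8.0 * duration / 1000.0)))
            st = epoch_rates(_spikes([times]), StimulusTrain(onsets), [0], EPOCHS)
            means.append(st.rates_hz)
        grand = np.asarray(means).mean(axis=0)
        # 8 Hz homogeneous rate: corrected epoch rates are zero in expectation
        sem = np.sqrt(8000.0 / (60 * 3.0)) / np.sqrt(50)  # worst epoch (3 ms)
        assert np.all(np.abs(grand) < 4 * sem)

    def test_epoch_validation(self):
        with pytest.raises(ValidationError):
            EpochDefinition(((10.0, 5.0),))
        with pytest.raises(ValidationError):
            EpochDefinition(((5.0, 10.0), (8.0, 20.0)))


class TestDecrement:
    @pytest.mark.parametrize("c,d,expected", [
        (10.0, 10.0, 0.0),
        (10.0, 0.0, 1.0),
        (10.0, -0.2, 1.02),
    ])
    def test_arithmetic(self, c, d, expected):
        assert decrement(c, d) == pytest.approx(expected)

    def test_rescale_invariance(self):
        assert decrement(10.0, 4.0) == pytest.approx(decrement(250.0, 100.0))

    def test_zero_control_undefined(self):
        assert decrement(0.0, 5.0) is None


class TestSignedRank:
    def test_identical_samples_give_p_one(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = signed_rank_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0
        assert res.n_effective == 0

    def test_most_extreme_pattern_exact_p(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = signed_rank_test(x, np.zeros(6))
        assert res.p_value == 2.0 / 64.0

    def test_symmetry_under_swap(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(size=7)
            y = rng.normal(size=7)
            assert signed_rank_test(x, y).p_value == signed_rank_test(y, x).p_value

    def test_matches_enumeration_oracle_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = rng.integers(3, 9)
            x = rng.integers(-4, 5, size=n).astype(float)  # ties and zeros
            y = np.zeros(n)
            if np.all(x == 0):
                continue
            assert signed_rank_test(x, y).p_value == enumeration_p(x)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            ours = signed_rank_test(x, y)
            ref = wilcoxon(x, y, zero_method="wilcox", alternative="two-sided",
                           method="exact")
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_large_sample_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0.3, 1.0, size=40)
        y = rng.normal(0.0, 1.0, size=40)
        ours = signed_rank_test(x, y)
        ref = wilcoxon(x, y, zero_method="wilcox", alternative="two-sided",
                       method="approx", correction=False)
        assert ours.method == "normal"
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)


class TestSampledNeurons:
    @pytest.mark.parametrize("spikes,p,expected", [
        (10.0, 0.2, 50.0), (24.0, 0.2, 120.0), (0.0, 0.2, 0.0)])
    def test_arithmetic(self, spikes, p, expected):
        assert estimate_sampled_neurons(spikes, p) == pytest.approx(expected)

    def test_invalid_probability(self):
        with pytest.raises(ParameterError):
            estimate_sampled_neurons(10.0, 0.0)


class TestPairedEpochTests:
    def test_table_structure_and_null(self):
        onsets = tuple(5000.0 + 3000.0 * k for k in range(20))
        stim = StimulusTrain(onsets)
        rng = np.random.default_rng(5)
        ctrl, drug = [], []
        for _ in range(6):
            times = np.sort(rng.uniform(0.0, onsets[-1] + 2000.0, size=400))
            st = epoch_rates(_spikes([times]), stim, [0], EPOCHS)
            ctrl.append(st)
            times = np.sort(rng.uniform(0.0, onsets[-1] + 2000.0, size=400))
            drug.append(epoch_rates(_spikes([times]), stim, [0], EPOCHS))
        df = paired_epoch_tests(ctrl, drug)
        assert list(df["epoch"]) == list(EPOCHS.names)
        assert ((df["p_value"] >= 0) & (df["p_value"] <= 1)).all()
        assert (df["n_animals"] == 6).all()
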