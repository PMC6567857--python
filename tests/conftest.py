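"""Shared fixtures: one small paired simulation for unit tests and a
session-scoped set of ten calibrated-default paired runs for the recovery and
drug-effect tests (each run plays the role of one animal)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from lamep.io import AnalysisConfig
from lamep.pipeline import analyze_condition, characterize_sensitive
from lamep.decomposition import decompose
from lamep.sep import detect_sep
from lamep.synth import SimulationConfig, simulate_pair

# scaled-down protocol: the stimulation protocol uses 5-10 s intervals; the
# test runs shorten the interval so a 100-trial session stays ~3 min of
# 16-channel 32 kHz data (the analysis windows all fit inside 1.7 s)
SCALED_ISI = (1700.0, 2200.0)
N_ANIMALS = 10


@dataclass
class PairedRun:
    truth: object
    stim: object
    control: object            # ConditionResult
    drug: object               # ConditionResult
    sep_truth_channel: object  # SEPMetrics at the generator's analysis channel
    sensitive_kinetics: dict


def _run_animal(seed: int, analysis_cfg: AnalysisConfig) -> PairedRun:
    cfg = SimulationConfig(seed=seed, n_trials=100, isi_range_ms=SCALED_ISI)
    rec_c, rec_d, stim, truth = simulate_pair(cfg)
    res_c = analyze_condition(rec_c, stim, analysis_cfg)
    res_d = analyze_condition(rec_d, stim, analysis_cfg, layers=res_c.layers)
    sep_t = detect_sep(res_c.average, truth.lfp_channel)
    dec = decompose(res_c.average, res_d.average, truth.lfp_channel)
    kin = characterize_sensitive(dec, analysis_cfg)
    return PairedRun(truth, stim, res_c, res_d, sep_t, kin)


@pytest.fixture(scope="session")
def analysis_config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def cohort_runs(analysis_config):
    """Ten simulated animals at calibrated defaults, fully analyzed."""
    return [_run_animal(seed, analysis_config) for seed in range(N_ANIMALS)]


@pytest.fixture(scope="session")
def small_pair():
    """One fast paired simulation for structural/pipeline tests."""
    cfg = SimulationConfig(seed=123, n_trials=15, isi_range_ms=SCALED_ISI)
    return cfg, simulate_pair(cfg)
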