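"""End-to-end orchestration: conditioning → layers → SEP/CSD/MUA → epochs →
decomposition → tables, as one logged, reproducible run.

``run_pipeline`` consumes a control recording (and optionally a paired drug
recording), applies every analysis stage with parameters from one
:class:`~lamep.io.AnalysisConfig`, writes the result tables as TSV into an
output directory and returns a manifest (config snapshot, input digests,
per-stage outputs, timestamps) that makes the run reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .conditioning import align_trials, average_evoked, bandpass_spike, downsample_lfp
from .csd import assign_layers, compute_csd, sink_onset
from .decomposition import (decay_fit_window, decompose, contribution_at,
                            find_second_peak, fit_exponential_decay, rise_time_2080)
from .epochs import EpochDefinition, decrement, epoch_rates
from .errors import LamepError, StageError
from .io import (AnalysisConfig, StimulusTrain, WidebandRecording, read_recording,
                 read_stimulus_train, write_table)
from .mua import detect_spikes, mua_metrics, oscillation_frequency, spike_density
from .sep import amplitude_at, detect_sep

log = logging.getLogger(__name__)

__all__ = ["RunManifest", "ConditionResult", "analyze_condition", "run_pipeline",
           "make_report"]


@dataclass
class RunManifest:
    config: dict
    inputs: dict[str, str]          # label -> sha256 (or "in-memory")
    version: str
    seed: int
    outputs: dict[str, str]
    timestamps: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         default=str) + "\n")


@dataclass
class ConditionResult:
    """All per-condition products of the analysis chain."""

    average: object
    csd: object
    layers: object
    spikes: object
    sep: object
    density: object
    mua: object
    osc_freq_hz: float | None
    epoch_stats_l23: object
    epoch_stats_l4: object


def _digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def analyze_condition(rec: WidebandRecording, stim: StimulusTrain,
                      cfg: AnalysisConfig, layers=None) -> ConditionResult:
    """Run the full single-condition chain.

    When ``layers`` is given (e.g. from the control condition) it is reused
    so both conditions are read out from identical channels.
    """
    lfp = downsample_lfp(rec, cfg.lfp_rate_hz)
    stack = align_trials(lfp, stim, cfg.align_window_ms)
    avg = average_evoked(stack)
    csd = compute_csd(avg, cfg.csd_baseline_window_ms)

    band = bandpass_spike(rec, *cfg.spike_band_hz)
    spikes = detect_spikes(band, cfg.threshold_k, cfg.dead_time_ms,
                           cfg.quietest_span_ms, cfg.quietest_step_ms)

    if layers is None:
        mua_onsets = {}
        for c in range(rec.geometry.n_channels):
            d = spike_density(spikes, stim, [c],
                              (cfg.mua_baseline_window_ms[0], cfg.mua_search_window_ms[1]),
                              cfg.density_bin_ms, cfg.density_step_ms)
            m = mua_metrics(d, cfg.mua_baseline_window_ms, cfg.mua_search_window_ms,
                            cfg.mua_criterion_k)
            if m is not None:
                mua_onsets[c] = m.onset_ms
        layers = assign_layers(csd, mua_onsets, cfg.expected_l4_depth_um,
                               cfg.sep_search_window_ms, cfg.sep_criterion_k)

    sep = detect_sep(avg, layers.l23_mid_channel, cfg.sep_search_window_ms,
                     cfg.sep_baseline_window_ms, cfg.sep_criterion_k)
    if sep is not None:
        for t_at in cfg.sep_amplitude_at_ms:
            sep.amplitude_at[t_at] = amplitude_at(avg, layers.l23_mid_channel, t_at,
                                                  cfg.sep_baseline_window_ms)

    dens = spike_density(spikes, stim, layers.l23_channels,
                         (cfg.mua_baseline_window_ms[0], 100.0),
                         cfg.density_bin_ms, cfg.density_step_ms)
    mm = mua_metrics(dens, cfg.mua_baseline_window_ms, cfg.mua_search_window_ms,
                     cfg.mua_criterion_k)
    osc = None
    if mm is not None:
        osc = oscillation_frequency(
            dens, (mm.onset_ms, mm.onset_ms + cfg.osc_window_span_ms),
            cfg.osc_prominence_frac)

    epochs = EpochDefinition.from_edges(cfg.epoch_edges_ms)
    st23 = epoch_rates(spikes, stim, layers.l23_channels, epochs, cfg.spont_window_ms)
    st4 = epoch_rates(spikes, stim, layers.l4_channels, epochs, cfg.spont_window_ms)
    return ConditionResult(avg, csd, layers, spikes, sep, dens, mm, osc, st23, st4)


def _sep_row(cond: str, res: ConditionResult) -> dict:
    row = {"condition": cond}
    if res.sep is None:
        row["no_response"] = True
        return row
    s = res.sep
    row.update(onset_ms=s.onset_ms, peak_latency_ms=s.peak_latency_ms,
               peak_amplitude_uV=s.peak_amplitude_uV,
               max_slope_uV_per_ms=s.max_slope_uV_per_ms)
    for t_at, v in s.amplitude_at.items():
        row[f"amplitude_at_{t_at:g}ms_uV"] = v
    return row


def characterize_sensitive(dec, cfg: AnalysisConfig) -> dict[str, float]:
    """Kinetic summary of the drug-sensitive component trace."""
    t, y = dec.time_ms, dec.sensitive
    out: dict[str, float] = {}
    mag = -y
    if mag.max(initial=0.0) <= 0:
        return out
    i_pk = int(np.argmax(mag))
    out["time_to_peak_ms"] = float(t[i_pk])
    # onset: last zero crossing before the peak
    j = i_pk
    while j > 0 and mag[j] > 0:
        j -= 1
    onset = float(t[j])
    out["onset_ms"] = onset
    rt = rise_time_2080(y, t, onset, float(t[i_pk]))
    if rt is not None:
        out["rise_2080_ms"] = rt
    second = find_second_peak(y, t, cfg.second_peak_after_ms,
                              cfg.second_peak_prominence_frac)
    if second is not None:
        out["second_peak_ms"] = second
    last_peak = second if second is not None else float(t[i_pk])
    fit = fit_exponential_decay(y, t, decay_fit_window(y, t, last_peak,
                                                       cfg.decay_fit_floor_frac))
    if fit is not None:
        out["decay_tau_ms"] = fit.tau_ms
        out["decay_fit_rms_uV"] = fit.residual_rms
    return out


def run_pipeline(cfg: AnalysisConfig, control_inputs, drug_inputs, out_dir) -> RunManifest:
    """Run the full pipeline and write all result tables.

    ``control_inputs``/``drug_inputs`` are either ``(recording, stim)``
    object pairs or ``(data_path, meta_path, stim_path)`` path triples;
    ``drug_inputs`` may be ``None`` for a control-only run (the
    decomposition and drug-effect tables are then skipped).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, str] = {}
    stamps: dict[str, float] = {"start": time.time()}

    def load(label, spec):
        if spec is None:
            return None, None
        if len(spec) == 2 and isinstance(spec[0], WidebandRecording):
            inputs[label] = "in-memory"
            return spec
        data, meta, stim_path = spec
        inputs[f"{label}:data"] = _digest(data)
        inputs[f"{label}:stim"] = _digest(stim_path)
        return read_recording(data, meta), read_stimulus_train(stim_path)

    rec_c, stim_c = load("control", control_inputs)
    rec_d, stim_d = load("drug", drug_inputs)

    outputs: dict[str, str] = {}

    def stage(name, fn):
        log.info("stage %s", name)
        t0 = time.time()
        try:
            result = fn()
        except LamepError as exc:
            raise StageError(name, exc) from exc
        stamps[name] = time.time() - t0
        return result

    res_c = stage("analyze_control", lambda: analyze_condition(rec_c, stim_c, cfg))
    res_d = None
    if rec_d is not None:
        res_d = stage("analyze_drug",
                      lambda: analyze_condition(rec_d, stim_d, cfg, layers=res_c.layers))

    conditions = [("control", res_c)] + ([("drug", res_d)] if res_d else [])

    # sep.tsv
    write_table(pd.DataFrame([_sep_row(c, r) for c, r in conditions]), out / "sep.tsv")
    outputs["sep"] = "sep.tsv"

    # csd.tsv (long: condition, depth, time, csd) and sink onsets
    rows = []
    for cond, r in conditions:
        for i, depth in enumerate(r.csd.depths_um):
            o = sink_onset(r.csd.data[i], r.csd.time_ms, cfg.csd_baseline_window_ms,
                           cfg.sep_search_window_ms, cfg.sep_criterion_k)
            rows.append({"condition": cond, "depth_um": depth,
                         "sink_onset_ms": np.nan if o is None else o,
                         "peak_sink": float(r.csd.data[i].min())})
    write_table(pd.DataFrame(rows), out / "csd.tsv")
    outputs["csd"] = "csd.tsv"

    # layers.tsv
    lay = res_c.layers
    rows = [{"channel": c, "depth_um": lay.depths_um[c],
             "layer": "L4" if c in lay.l4_channels else "L2/3",
             "is_l23_mid": c == lay.l23_mid_channel}
            for c in sorted(lay.depths_um)]
    write_table(pd.DataFrame(rows), out / "layers.tsv")
    outputs["layers"] = "layers.tsv"

    # mua.tsv
    rows = []
    for cond, r in conditions:
        row = {"condition": cond}
        if r.mua is not None:
            m = r.mua
            row.update(onset_ms=m.onset_ms, first_peak_density=m.first_peak_density,
                       first_peak_delay_ms=m.first_peak_delay_ms,
                       rising_slope=m.rising_slope,
                       max_peak_density=m.max_peak_density,
                       max_peak_delay_ms=m.max_peak_delay_ms,
                       oscillation_freq_hz=np.nan if r.osc_freq_hz is None else r.osc_freq_hz)
        else:
            row["no_response"] = True
        rows.append(row)
    write_table(pd.DataFrame(rows), out / "mua.tsv")
    outputs["mua"] = "mua.tsv"

    # epochs.tsv
    frames = []
    for cond, r in conditions:
        for layer, st in (("L2/3", r.epoch_stats_l23), ("L4", r.epoch_stats_l4)):
            f = st.as_frame()
            f.insert(0, "layer", layer)
            f.insert(0, "condition", cond)
            frames.append(f)
    write_table(pd.concat(frames, ignore_index=True), out / "epochs.tsv")
    outputs["epochs"] = "epochs.tsv"

    # stats.tsv (single-animal drug decrements; cohort p-values are computed
    # across animals with epochs.paired_epoch_tests)
    if res_d is not None:
        rows = []
        for layer, sc, sd_ in (("L2/3", res_c.epoch_stats_l23, res_d.epoch_stats_l23),
                               ("L4", res_c.epoch_stats_l4, res_d.epoch_stats_l4)):
            for k, name in enumerate(sc.epochs.names):
                dec = decrement(float(sc.rates_hz[k]), float(sd_.rates_hz[k]))
                rows.append({"layer": layer, "epoch": name,
                             "control_rate_hz": sc.rates_hz[k],
                             "drug_rate_hz": sd_.rates_hz[k],
                             "decrement": np.nan if dec is None else dec})
        write_table(pd.DataFrame(rows), out / "stats.tsv")
        outputs["stats"] = "stats.tsv"

    # decomp.tsv
    if res_d is not None:
        dec = stage("decompose", lambda: decompose(
            res_c.average, res_d.average, res_c.layers.l23_mid_channel,
            cfg.sep_baseline_window_ms))
        for t_at in cfg.contrib_latencies_ms:
            contrib = contribution_at(dec, t_at)
            if contrib is not None:
                dec.contributions[t_at] = contrib
        dec.kinetics["sensitive"] = characterize_sensitive(dec, cfg)
        df = pd.DataFrame({"time_ms": dec.time_ms, "control_uV": dec.control,
                           "resistant_uV": dec.resistant, "sensitive_uV": dec.sensitive})
        write_table(df, out / "decomp.tsv")
        outputs["decomp"] = "decomp.tsv"
        rows = [{"quantity": f"contribution_resistant_at_{t:g}ms_pct", "value": v[0]}
                for t, v in dec.contributions.items()]
        rows += [{"quantity": f"sensitive_{k}", "value": v}
                 for k, v in dec.kinetics["sensitive"].items()]
        write_table(pd.DataFrame(rows), out / "decomp_summary.tsv")
        outputs["decomp_summary"] = "decomp_summary.tsv"

    stamps["end"] = time.time()
    manifest = RunManifest(config=dataclasses.asdict(cfg), inputs=inputs,
                           version=__version__, seed=cfg.seed, outputs=outputs,
                           timestamps=stamps)
    manifest.to_json(out / "manifest.json")
    return manifest


def make_report(out_dir) -> str:
    """Human-readable markdown summary of a pipeline run directory."""
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise LamepError(f"no manifest.json under {out}")
    manifest = json.loads(manifest_path.read_text())
    missing = [name for name, rel in manifest["outputs"].items()
               if not (out / rel).exists()]
    if missing:
        raise LamepError(f"missing result tables: {', '.join(missing)}")
    lines = [f"# lamep run report", "",
             f"version {manifest['version']}, seed {manifest['seed']}", ""]
    for name, rel in manifest["outputs"].items():
        if name in ("decomp",):
            continue  # trace table, too long to inline
        df = pd.read_csv(out / rel, sep="\t")
        lines += [f"## {name}", "", df.to_string(index=False), ""]
    return "\n".join(lines)
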