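"""Decompose the control response into drug-resistant and drug-sensitive
components and characterize their kinetics.

The resistant component is the drug-condition average; the sensitive
component is control - drug, pointwise.  Their contributions shift from
almost fully resistant at response onset to almost fully sensitive late in
the response.
"""

from lamep import (AnalysisConfig, SimulationConfig, align_trials, average_evoked,
                   contribution_at, decompose, downsample_lfp, simulate_pair)
from lamep.pipeline import characterize_sensitive

cfg = SimulationConfig(seed=31, n_trials=60, isi_range_ms=(1700.0, 2200.0))
control, drug, stim, truth = simulate_pair(cfg)
acfg = AnalysisConfig()


def avg(rec):
    return average_evoked(align_trials(downsample_lfp(rec, acfg.lfp_rate_hz),
                                       stim, acfg.align_window_ms))


dec = decompose(avg(control), avg(drug), truth.lfp_channel,
                acfg.sep_baseline_window_ms)
print("relative contributions (resistant % / sensitive %):")
for t_at in acfg.contrib_latencies_ms:
    c = contribution_at(dec, t_at)
    if c is not None:
        print(f"  {t_at:5.1f} ms: {c[0]:5.1f} / {c[1]:5.1f}")

kin = characterize_sensitive(dec, acfg)
print("sensitive-component kinetics:")
for k, v in kin.items():
    print(f"  {k:20s} {v:8.2f}")
# Configured truth: rise 3.9 ms, first peak ~17.5 ms, biphasic decay with a
# second peak near 46 ms, decay tau 88.3 ms.  The contribution pattern
# (resistant-dominated early, sensitive-dominated late) is emergent.
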