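# lamep — laminar evoked-potential analysis

`lamep` is a Python toolkit for analyzing sensory-evoked responses
recorded with linear multi-site ("laminar") silicon probes in cortex —
the kind of experiment where a whisker is deflected while a 16-site,
100 μm-spaced probe spans the cortical depth of one barrel column.  It
implements the full analysis chain used in pharmacological dissection
studies of the evoked response, together with a calibrated synthetic
recording generator, so that every estimator in the chain can be
validated by recovering known ground truth.

**Who it is for:** electrophysiologists quantifying evoked LFP/MUA
responses across cortical layers, and anyone needing a tested, scriptable
reference implementation of these classic estimators.

## What it computes

Given a wideband recording, a stimulus-onset train and a paired
drug-condition recording:

- **Conditioning** — block-mean downsampling to the LFP rate (1 kHz),
  zero-phase 300–5000 Hz band-passing, stimulus-aligned trial averaging.
- **SEP parameterization** — the sensory-evoked potential is the first
  negative trough of the averaged LFP; reported are onset latency
  (intersection of the front with the baseline), peak latency, peak
  amplitude, maximal front slope and fixed-latency amplitude readouts.
- **CSD** — the current-source density as the negated second spatial
  difference, `CSD_i = −(V_{i−1} − 2V_i + V_{i+1})/h²`, sinks negative,
  after 1 s-baseline subtraction; layer assignment from the earliest
  sinks near the expected granular depth (600 μm).
- **MUA** — spike detection at −5 SD of each channel's quietest second,
  peristimulus spike density (1 ms window, 0.2 ms steps), onset/peak/slope
  metrics and the early high-frequency burst rate (~400 Hz).
- **Epoch statistics** — baseline-corrected firing rates in the
  Armstrong-James epochs (5–8, 8–10, 10–20, 20–50, 50–100 ms), the drug
  decrement `(control − drug)/control`, and a two-sided Wilcoxon
  signed-rank test for matched samples with an exact tie-aware null
  (exhaustively verified) for small cohorts.
- **Decomposition** — the drug-resistant component (drug average) and the
  drug-sensitive component (control − drug), with per-latency relative
  contributions, 20–80% rise times, an exponential decay fit and
  second-peak detection.

The synthetic generator (`lamep.synth`) produces paired control/drug
recordings with exact ground truth: a fast drug-resistant LFP component
(onset 7.5 ms, rise 2.0 ms, decay τ 11.1 ms, 469 μV), a slow drug-sensitive
component (rise 3.9 ms, τ 88.3 ms, biphasic decay peaking again near
46 ms) calibrated so the summed control SEP peaks at 621 μV, Gaussian
current sinks at 600 μm (granular) and 360 μm (supragranular), burst +
late-tail Poisson spiking, and reproducible noise.  See
[docs/methods.md](docs/methods.md) for the model and every numerical
choice.

## Worked example

Simulate one session and read the SEP and the layer map off it
(`examples/02_sep_and_csd.py`):

```text
averaged 40 trials; CSD map 14 channels x 1500 samples
layers: L4 channels [5, 6] ([560.0, 660.0] um), L2/3 [1, 2, 3], analysis site ch 2
SEP at L2/3 site: onset 7.70 ms, peak 15.0 ms, amplitude 439 uV, max slope 111 uV/ms, LFP(50 ms) -212 uV
  sink at   560 um: onset  7.54 ms
  sink at   660 um: onset  7.37 ms
```

The probe channels at 560/660 μm carry the earliest sink, identifying the
granular layer; the SEP onset recovered at the L2/3 analysis site (7.7 ms)
matches the generator's configured 7.5 ms front.  The pharmacological
decomposition (`examples/04_decomposition.py`) shows the hand-off between
components across the response:

```text
relative contributions (resistant % / sensitive %):
   10.5 ms:  84.4 /  15.6
   14.3 ms:  61.3 /  38.7
   46.0 ms:   7.1 /  92.9
sensitive-component kinetics:
  rise_2080_ms             3.97
  second_peak_ms          45.00
  decay_tau_ms            88.32
```

— the early response is carried almost entirely by the drug-resistant
component while the late response is almost entirely drug-sensitive, and
the sensitive component's fitted decay constant (88.3 ms) and second peak
(~45 ms) recover the generator's configured kinetics.  The epoch table
(`examples/05_epoch_statistics.py`) shows the same dissociation in the
spiking: early epochs unchanged, 20–50 and 50–100 ms epochs suppressed by
~99%.

Each script in `examples/` is a self-contained narrative: generation and
saving (`01`), SEP/CSD (`02`), MUA density and the ~400 Hz burst (`03`),
decomposition (`04`), epoch statistics and the sampled-neuron estimate
(`05`).  A thin CLI wraps the same chain for shell use:

```bash
lamep simulate --seed 7 --n-trials 20 --isi 1700 2200 --out-dir scratch/run
lamep run --control scratch/run/control --drug scratch/run/drug \
      --stim scratch/run/pair.stim.txt --out-dir scratch/run/out
lamep report --run-dir scratch/run/out
```

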