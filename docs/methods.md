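# Methods

`lamep` analyzes stimulus-evoked activity recorded with a linear multi-site
("laminar") probe in sensory cortex, and ships a synthetic-recording
generator calibrated so that every analysis stage can be validated by
recovering known ground truth.  This note describes the models, the
estimators, the numerical choices, and what the synthetic tests do and do
not demonstrate.

## The data model

A recording is a samples × channels matrix of extracellular potential (μV)
at a single sampling rate (32 kHz by default), taken from a 16-site probe
with 100 μm spacing inserted perpendicular to the cortical surface; channel
depths are μm below the pia, increasing with channel index.  Stimuli are
brief whisker deflections delivered as 200 ms pulses at 5–10 s intervals;
all analysis is keyed to the train of stimulus-onset times (ms).

## Analysis chain

**Conditioning.**  The local field potential (LFP) is obtained by
block-mean decimation to 1 kHz: each output sample is the mean of one
32-sample block, time-stamped at the block center.  A boxcar decimator was
chosen over a polyphase FIR because its impulse response is non-negative:
a linear-phase anti-aliasing FIR leaks ~1% sidelobes several milliseconds
*ahead* of a fast evoked front, which systematically biases
baseline-intersection onset latencies early by 2–3 ms, while the boxcar
cannot pre-ring.  The cost is weaker stopband rejection away from the
output-rate harmonics; for evoked averages over ≥tens of trials the
aliased broadband noise is negligible.  The spike band is extracted with a
zero-phase Butterworth band-pass (300–5000 Hz, second-order sections run
forward and backward), so spike peak times are not displaced.

**Trial alignment.**  Windows are half-open `[pre, post)` in ms relative
to each stimulus onset; the sample at time 0 is the first sample at or
after the onset; trials whose window leaves the recording are dropped and
counted.  The evoked average is the pointwise mean across trials.

**SEP parameterization.**  The sensory-evoked potential (SEP) is the first
negative trough of the averaged LFP in a 3–50 ms search window whose depth
exceeds 4 baseline SDs (baseline window −100–0 ms; the factor and windows
are configuration parameters).  Peak amplitude is the trough depth below
the baseline mean, reported as a positive magnitude.  Onset is the
intersection of the SEP front with the baseline level, computed by
anchoring a line at the front's 20% and 80% depth crossings (sub-sample
interpolated) and extrapolating to the baseline.  This front-line rule was
chosen over the naive "walk back from the trough to the last
baseline-level crossing" because the naive walk continues through any
stretch where baseline noise sits below the baseline-window mean; its
expected overshoot, measured in samples, is independent of the noise
amplitude, giving an irreducible 1–3 ms early bias at a 1 kHz LFP rate.
The front-line rule is exact for linear fronts and its anchors sit on the
steep part of the front where noise contributes ~0.05 ms of jitter.  The
maximal slope is the largest descent rate (central differences) between
onset and trough.  Fixed-latency amplitudes (e.g. the 50 ms readout) are
linearly interpolated after baseline subtraction.

**CSD.**  The current-source density is the negated second spatial
difference of the baseline-subtracted averaged LFP,
`CSD_i = −(V_{i−1} − 2 V_i + V_{i+1})/h²` with h in mm, computed at
interior channels only (no boundary padding) after subtracting the
per-channel mean of the 1 s pre-stimulus average.  Sinks (inward current)
are negative.  No conductivity scaling is applied; maps are relative.
Spatial up-interpolation is display-only and honors the node values.

**Layer assignment.**  The granular layer (L4) is identified as the
adjacent interior channel pair with the earliest sink onsets nearest the
expected depth of 600 μm (ties quantized at 0.5 ms and broken toward the
expected depth, then by MUA onset).  Only channels whose peak sink reaches
at least 20% of the map's largest sink are candidates: with a 4-SD
criterion alone, an occasional noise trough on a superficial channel can
pose as the "earliest sink".  The supragranular group (L2/3) is every
channel more than 100 μm below the pia and more than 100 μm above the
shallowest L4 site (2–3 channels at 100 μm pitch); its middle channel is
the LFP/CSD analysis site.

**MUA.**  Spikes are negative deflections of the spike band exceeding 5
SDs, with the SD measured per channel over the most silent 1 s segment
(searched on a 100 ms grid — ~10× cheaper than per-sample with a
negligible SD difference for stationary noise).  Each suprathreshold
excursion yields one spike at its negative extremum; a 1 ms dead time
prevents double-counting one waveform.  Spike density is a peristimulus
estimate with a 1 ms window sliding in 0.2 ms steps, pooled over trials
and the selected layer channels and normalized per trial (spikes/ms).
MUA metrics mirror the SEP rules: the first peak is the first density
maximum above baseline mean + 3 SD *and* above 20% of the window maximum
(a Poisson-discrete baseline makes the SD criterion alone as small as ~3
coincident spontaneous spikes); peaks closer than the 1 ms window width
are merged (unresolvable); onset uses the same front-line baseline
intersection; the burst oscillation frequency is 1000 / the mean interval
between early density peaks, each refined by a local
background-subtracted centroid (±1 ms), which is much less jittery than a
grid argmax on count noise.

**Epochs and statistics.**  The response is staged in the Armstrong-James
post-stimulus epochs (5–8, 8–10, 10–20, 20–50, 50–100 ms).  The epoch rate
is the pooled spike count / (trials × channels × duration), minus the same
statistic over a 1 s pre-stimulus window (a single shared spontaneous
window; the convention mirrors the CSD baseline).  The drug effect is the
decrement `(control − drug)/control`, computed on group means and per
animal; it exceeds 1 when drug-condition activity falls below the
spontaneous baseline.  Differences between matched conditions are tested
with a two-sided Wilcoxon signed-rank test: zero differences dropped,
average ranks for ties, an exact tie-aware null (dynamic programming over
doubled rank sums) for up to 25 effective pairs, and a tie-corrected
normal approximation beyond.  The exact path is implemented in-package
because scipy's exact mode refuses ties; tests verify bit-exact agreement
with exhaustive 2^n enumeration and with scipy on tie-free data.  The
sampled-neuron estimate divides spikes-per-response by an assumed
per-response firing probability (0.2 by default).

**Decomposition.**  With a paired drug condition, the drug-resistant
component is the drug-condition average and the drug-sensitive component
is control − drug, both baseline-subtracted on identical grids, so
resistant + sensitive reconstructs the control trace to machine precision.
Contributions at chosen latencies are 100·resistant/control (undefined
where control is zero; the pair always sums to 100 where defined).
Kinetics: 20–80% rise time by sub-sample interpolation on the front;
decay constant by nonlinear least squares of `A·exp(−t/τ)` (log-linear
initialization) on the magnitude from the last peak down to 5% of it; a
second (biphasic-decay) peak is the first late magnitude maximum after
30 ms with prominence ≥10% of the main peak.

## The synthetic generator

**Evoked components.**  Each pharmacological component is a negative
deflection with a raised-cosine front glued to an exact exponential decay:

    k(s) = (1 − cos(π s/T))/2,   0 ≤ s < T,   T = rise_2080 · π/(acos(−0.6) − acos(0.6))
    k(s) = exp(−(s − T)/τ),      s ≥ T

so the 20–80% rise time and the decay constant are honored exactly in
closed form (a difference of two exponentials cannot decay exactly
exponentially near its peak; with the fast kinetics the discrepancy is
~10%).  The maximal front slope is `amp·π/(2T)`.  An optional second lobe
is a delayed, scaled copy of the same kernel.  Defaults: a fast
(drug-resistant) component with onset 7.5 ms, rise 2.0 ms, τ 11.1 ms and
469 μV at the analysis channel (front slope ≈151 μV/ms); a slow
(drug-sensitive) component with onset 8.0 ms, rise 3.9 ms, τ 88.3 ms,
second lobe peaking near 46 ms at 22% of the main lobe, and 298.7 μV —
the amplitude solved (once, by bisection) so the summed control response
peaks at 621 μV.  With these defaults the drug-only trace peaks at
12.4 ms/469 μV, the control at ~15 ms/621 μV, and the resistant component
contributes ~87% at 10.5 ms, ~64% at the control peak and ~7% at 46 ms —
the early/late dissociation pattern, emergent rather than configured.

**Spatial model.**  Each component has a Gaussian sink profile over the
interior channels (fast centered at 600 μm — granular; slow at 360 μm —
supragranular; σ = 100 μm).  The LFP is the solution of the negated
second-difference system with zero boundary potentials, so the package's
CSD operator recovers the configured sink maps exactly (round trip
< 1e−9).  Amplitudes are referenced to the channel nearest 360 μm.

**Spiking.**  Layer channel groups (3 supragranular, 2 granular) receive
an inhomogeneous Poisson drive: an early burst of Gaussian bumps
(σ = 0.5 ms) spaced at 1/398 Hz with first/maximal sliding-window
densities 0.32/0.56 spikes/ms (supragranular; the granular burst starts
earlier), plus a late tail proportional to the slow component's magnitude
(0.10 spikes/ms at its peak), plus 2 Hz spontaneous activity per channel
(1 Hz outside the layer groups).  Two calibration corrections make the
configured numbers what the *detector* reports: bump amplitudes are
divided by the analytic boxcar attenuation of the 1 ms sliding window
(≈0.856 for σ = 0.5 ms), and rates are boosted by the first-order
non-paralyzable dead-time loss `λ/(1 − ∫_{t−τ}^{t} λ)`.  Spike waveforms
are biphasic (negative-then-positive) 1 ms kernels whose peak is
`spike_snr` × the white-noise SD inside the 300–5000 Hz band.

**Noise.**  Wideband Gaussian white noise (10 μV SD) sets the spike
detection floor; a band-limited 1/f-power component (1–450 Hz) adds
correlated LFP background.  Its default of 6 μV per trial leaves ~0.6 μV
of residual on a 100-trial average, chosen so single-animal latency
jitter stays below ~1 ms — the level implied by the reported group
latency SEs (an onset SE of 0.3 ms over ten animals is impossible if
per-animal measurement jitter were several ms).  The synthetic front's
cosine take-off is gentler than real SEP fronts, which is why the
background must be modest for comparable latency precision.

**Pairing.**  The drug condition differs from the control only by the
slow LFP component scaled by `1 − drug_suppression` and by the late spike
tail thinned by the same factor (shared uniform draws), with noise and
burst draws shared between conditions — so `drug_suppression = 0` yields
bit-identical recordings and early-epoch paired differences are exactly
null.  Setting `independent_noise=True` redraws noise and spikes
independently per condition, which is the right regime for checking the
size of the paired test under the null (with shared draws the null
rejection rate is trivially zero).  The full output is bit-reproducible
for a fixed seed.

## Problem sizes

The generator's protocol default keeps the 5–10 s inter-stimulus
intervals.  The test suite and the acceptance script pass
`isi_range_ms=(1700, 2200)` and 100 trials per condition, so one session
is ~3.3 minutes of 16-channel 32 kHz data (~400 MB as float32) instead of
~12 minutes; all analysis windows (1 s baselines, 400 ms post-stimulus)
fit inside the shortened interval, so no estimator is affected.  Recovery
checks use ten simulated animals; detection checks use twenty 60 s
single-column recordings; the signed-rank null calibration uses
spike-level simulation (40 seeds × 10 animals), where wideband synthesis
would add cost but no information about the statistic.

## What passing tests show — and what they do not

Parameter recovery demonstrates that the estimators are unbiased at the
calibrated scales and noise levels, that the CSD forward/inverse pair is
consistent, and that the paired statistics have the advertised size and
power under the generator's assumptions.  The generator does not emulate:
electrode drift or movement artifacts; non-Poisson spike statistics
(bursting, refractory interactions beyond the dead-time model);
multi-whisker receptive-field structure; trial-to-trial adaptation of the
evoked response; conductivity inhomogeneities (CSD maps are relative); or
overlapping spike waveforms across units.  Real recordings may therefore
need artifact screening before this chain is applied, and absolute CSD
magnitudes should not be compared across preparations.

## Degenerate inputs and tie-breaks

Constant spike-band traces flag an undefined threshold (SD = 0) and yield
no spikes; flat averaged traces flag "no response" (`None`) rather than
fabricating metrics; a control rate of zero makes the decrement undefined;
all-zero paired differences return p = 1 with a warning.  Layer-assignment
ties are broken toward the expected L4 depth and then by MUA onset;
equal-magnitude density sub-peaks within one window width are merged.
Exponential fits reject non-decaying windows (τ ≤ 0) instead of returning
a spurious constant.
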