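# Methods

This note documents the models, conventions and numerical choices behind
`laminarpac`, and what the synthetic-data generator does and does not
emulate.

## Signal conventions

All voltages are microvolts; channel 0 is the most superficial probe site
(stratum oriens side) and indices increase toward stratum
lacunosum-moleculare. Instantaneous phase is the angle of the analytic
(Hilbert) signal of a zero-phase band-passed trace: 0° at a local field
peak, ±180° at the trough. The "maximal downward deflection" of the
stratum-radiatum (SR) oscillation — the phase at which sharp-wave-like input
is strongest — is therefore ±180° under this convention, and both the
generator and every analyzer share it, which makes phase-recovery tests
exact rather than convention-dependent.

Morlet components use 10-cycle wavelets (MNE's zero-mean family). MNE's
wavelets are energy-normalised, not passband-normalised, so each frequency's
output is divided by the wavelet's response to a unit tone at its own centre
frequency; after this calibration the envelope of a pure tone equals its
amplitude, which is what the amplitude-extraction contract promises.

## Welch power and the PDD map

Recordings are cut into 1 s epochs advancing by 0.4 s (60% overlap) with a
Hann taper. A 1 s epoch natively yields a 1 Hz grid, which is incompatible
with the 0.5 Hz bin spacing the power stack requires; each epoch is
therefore zero-padded to a 2 s FFT, preserving both the stated epoch length
and the stated grid. Power is reported as a density (µV²/Hz) on 1–300 Hz.

The PDD is `100·(mean_injured/mean_sham − 1)` per (channel, frequency) cell,
with means taken over epochs and then animals. The significance mask comes
from a per-cell one-way comparison over pooled epochs (`mode="epochs"`,
the default). Treating epochs as replicates is pseudo-replication — epochs
from one animal share that animal's realisation, and 60% overlap correlates
neighbouring epochs, so the mask is anti-conservative; a per-animal Welch-t
alternative (`mode="animals"`) is provided for conservative inference.
Cells with zero sham power have an undefined ratio and are excluded from
the mask.

The aligned window places 6 channels above the pyramidal-layer (SP) channel
and 18 below (toward SR), total 25; the split is configurable. Ties in the
multiunit-band argmax resolve to the most superficial channel. When a
recording cannot support the 600–900 Hz multiunit band (LFP-rate data), the
generator supplies a per-channel multiunit power proxy that alignment uses
directly.

## CSD

The standard second-spatial-difference estimator with extracellular
conductivity treated as a unit scalar (relative units): the analyses here
use CSD qualitatively, to localise sinks. Edge channels are dropped by
default; optional boundary replication (Vaknin padding) keeps them. The
spline inverse-CSD family is out of scope.

## KL modulation index

`MI = (H0 − H)/H0` with `H0 = log N` over `N = 18` phase bins of 20°. This
is the Kullback–Leibler distance of the phase-binned, normalised amplitude
distribution from uniform, scaled to [0, 1]: 0 for phase-independent
amplitude, 1 for single-bin concentration, invariant to global amplitude
scaling and to whole-bin phase rotation. Natural logarithms are used; the
base cancels in the ratio. Empty phase bins (possible on short inputs)
contribute zero mean amplitude and trigger a warning. The first and last
0.5 s of each phase/envelope series are trimmed against filter transients.

The comodulogram takes amplitudes from 10-cycle Morlet components of the SP
channel (1–300 Hz) and phases from ±1 Hz band-passes of the SR channel
(1–20 Hz) followed by the Hilbert transform. Group comparisons are per-cell
Student t tests, uncorrected at p < 0.05 by design (a multiplicity
correction can be applied downstream to the returned p-value matrix).

## Unit classification

CA1: the SP band is five channels (±2 around the SP channel, 100 µm at
50 µm spacing); units one channel outside it are border units. Non-border
units outside SP are interneurons by definition, regardless of firing rate.
SP/border units are split on three features: firing rate (fixed division at
3.5 Hz), waveform width at 25% of spike height measured on the ×5 upsampled
mean waveform (height relative to a baseline 1 ms before the peak; the
extremum is found on the absolute deviation so spike polarity does not
matter), and burstiness as the first moment of the 0–50 ms autocorrelogram
in 2 ms bins (a uniform short-lag histogram gives 25 ms; bursty trains fall
well below). The width and burstiness thresholds are data-driven — the
valley between the two feature clusters found by a deterministic 1-D
two-means split — because only the 3.5 Hz rate division is a fixed
constant; with fewer than two in-band units the thresholds are undefined
and those units stay unclassified. Border pyramidal cells are then moved
into SP, and border interneurons follow when an isolated pyramidal cell has
its maximum amplitude on the same channel.

MS: the waveform power spectrum is integrated over 25 equal-width (600 Hz)
bins spanning 1–16 kHz — linear spacing is a documented choice; the bin
grid is not otherwise constrained — and the bin4/bin2 ratio separates
"inflected" (putative cholinergic) from non-inflected (putative
GABAergic/glutamatergic) waveforms, with the inflected group accepted as
cholinergic only below 4 Hz. The ratio threshold is again a two-means
split. Waveforms are zero-padded to a 4096-point FFT so the 600 Hz bins are
well resolved at 32 kHz sampling.

## Entrainment

Spike phases are linearly interpolated on the unwrapped analytic phase of
the reference channel — the aligned channel nearest 425 µm below SP (at
50 µm spacing that offset is an exact half-spacing tie, resolved toward
SP). Entrainment per unit is the mean resultant vector; significance is the
Rayleigh test (small-sample-corrected approximation) at α = 0.05. Group
circular means are compared with the Watson–Williams test (with the
1 + 3/(8κ̂) correction; a warning is issued when the pooled resultant is
below 0.45) and distributions with the two-sample Kuiper test (asymptotic
series with Stephens' effective-sample-size correction). Fast-oscillation
entrainment bins each spike's Morlet phase at 1–400 Hz into 18 bins and
applies the same MI core to the spike-count distribution; this is computed
per unit (and averaged at the group level), the reading consistent with
per-unit profile comparisons. At least 100 spikes are required.

## Spike-triggered averages and PSTHs

The STA averages ±500 ms multichannel snippets of the unfiltered LFP around
each spike whose window lies fully inside the recording; the peak-to-peak
statistic is taken on the deepest SR channel of the aligned window. The
PSTH spans ±50 ms around each trigger in 2 ms bins and is normalised by the
unit's total spike count in the recording (so the histogram sums to the
in-window fraction of the unit's spikes). Triggers are local minima of the
band-passed trace gated by an envelope floor: a trough is accepted when its
envelope exceeds twice the median envelope while also being at least 20% of
the peak envelope, or when it is within 60% of the peak envelope. The
composite rule keeps steady oscillations (whose envelope never exceeds
twice its own median) fully triggered while rejecting noise troughs in
near-silent stretches; a zero signal yields no triggers. The centered
window follows the observation that the inhibition of MS firing begins just
after the trough.

## Synthetic cohorts

The generator produces, per animal, a 32-channel laminar recording and
spike-sorted units with full ground truth:

* **SR sharp-wave-like rhythm** — a narrowband Gaussian quasi-oscillation
  (spectral bump centred at 12 Hz, σ = 0.75 Hz, i.e. energy mostly within
  10–15 Hz) with 200 µV RMS at its depth peak ~450 µm below SP, a Gaussian
  depth envelope (σ = 4 channels), and sign inversion above the SP band
  (the 180° phase reversal). Carriers are synthesised in the frequency
  domain with a deterministic magnitude spectrum and random phases, so
  every animal has an identical long-run spectrum and expectation-identical
  groups are truly null at the bin level; a pure-tone mode exists for
  closed-form tests.
* **Anesthesia theta** — a 2–5 Hz carrier of the same construction,
  100 µV RMS, envelope growing toward the deep end, with a linear laminar
  phase shift (180° across the probe) applied by rotating the analytic
  signal.
* **High-frequency bursts** — Gaussian-envelope events (σ = 12 ms, ~8 per
  second, carrier N(225, 10) Hz) confined to SP (depth σ = 1.2 channels).
  Per-burst amplitude is `1 − d + d·(1 + cos(φ − 180°))/2` with d the
  coupling depth and φ the SR phase at burst time, times a lognormal
  (σ = 0.25) intrinsic variability — maximal at the SR trough, as for
  sharp-wave-coupled ripples.
* **Background** — 1/f pink noise (20 µV RMS per channel, deterministic
  magnitude spectrum) and a 600–900 Hz multiunit-band bump at SP used by
  alignment (its power profile also ships as the alignment proxy for
  LFP-rate data).
* **CA1 units** — pyramidal cells: von Mises phase-modulated Poisson trains
  (thinning) around the SR phase, target rate 1.25 Hz (lognormal across
  units, SD 0.91), preferred phase N(193.8°, 24.9°), per-unit resultant
  N(0.24, 0.09) converted to κ by inverting A(κ) = I₁/I₀; each event
  continues into a burst with probability 0.35 per extra spike at ~4 ms
  intra-burst intervals (the event rate is scaled by (1 − p) so the drawn
  rate is the realised total rate); spikes inside a high-frequency burst
  are pulled toward the burst carrier peak. Interneurons: tonic trains at
  5.12 Hz (SD 7.50), phase target R = 0.27 at 181.8°, distributed over
  SO/SP/SR. Waveforms are difference-of-Gaussians templates (wide σ=0.22 ms
  vs narrow σ=0.08 ms main lobes) decaying across channels with a 50 µm
  space constant. An absolute 1 ms refractory period is enforced.
* **MS units** — Poisson trains whose intensity is multiplied by
  (1 − depth) in a window 14–34 ms after each SR trough (depth 0.7 sham,
  0.15 injured, lognormal across units); GABA/Glu rates 5.30 Hz (SD 6.42)
  sham vs 8.46 Hz (SD 9.76) injured, cholinergic ~2.8 Hz both groups.
  Cholinergic templates add a delayed positive lobe (the repolarisation
  "inflection") that raises the spectral bin4/bin2 ratio.
* **Injury preset** — amplitude factors √(1−0.467) on the SR rhythm and
  √(1−0.744) on the bursts (the printed peak power losses), coupling depth
  0.25 vs 0.9, mildly broadened burst carrier (SD 25 Hz), reduced
  entrainment (R 0.19 at 208.7°), MS disinhibition as above.

Across-unit dispersions are modelled as lognormal spreads matched to the
reported mean ± SD (the across-unit distribution is not otherwise
constrained); rate draws are truncated to configurable bounds, and a
dedicated "well-separated" preset pulls the rate clusters away from the
fixed 3.5 Hz / 4 Hz divisions for exact label-recovery checks — with the
paper-matched spreads the clusters genuinely straddle those cuts, so 100%
recovery is only meaningful for separable clusters.

What the generator does **not** emulate: biophysical waveform diversity and
electrode drift, non-stationary anesthesia depth, spike-sorting errors and
overlapping spikes, gamma-band coupling, correlated noise across channels,
and any behavioural covariates. Passing recovery tests therefore shows the
analysis chain is correct and calibrated on data with the assumed
statistical structure, not that it is robust to every failure mode of real
recordings.

## Problem sizes and determinism

Tests and the acceptance script use scaled-down cohorts — typically 1–3
animals per group, 30–240 s at 1 kHz, and tens of units — chosen so the
full suite runs in well under an hour on one core while every recovered
quantity keeps comfortable statistical margins; the generator's scientific
defaults (5 animals, 15 min at 2 kHz, 32 channels) remain the preset values.
All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence` spawning (one child stream per animal), so
cohorts, pipeline summaries and the acceptance report are bit-reproducible
for a given seed.

## Known limitations

* The epoch-pooled significance mask inherits the pseudo-replication of its
  design; use `mode="animals"` for conservative claims.
* The per-cell PAC and MI(f) group tests are uncorrected for multiplicity
  by design.
* Fast-oscillation MI profiles of a strong narrowband rhythm form a plateau
  across neighbouring frequencies (a 10-cycle wavelet stays phase-coherent
  with the rhythm), so peak location should be read at band resolution, not
  bin resolution.
* The Watson–Williams test assumes concentrated samples; at the low
  resultants typical of MS units its p-values should be treated with
  caution (the Kuiper test does not share the assumption).
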