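# Methods

`cnpipe` re-implements, as a tested library plus analysis drivers, the
complete desk-side workflow of an in-vivo extracellular recording experiment
in which brief sound pulses and optogenetic light stimulation are delivered
to the cochlear nucleus: sound-level calibration, analog trigger encoding
and timestamp decoding, threshold spike detection, PSTH-based classification
of responding units against a Poisson surrogate null, per-unit firing
metrics, and auditory brainstem response (ABR) extraction.  Because no
recordings are deposited, a synthetic-session generator with complete ground
truth defines the conditions under which every stage is validated.

## Sound calibration

A speaker is calibrated by playing 2 s band-limited noise pulses at a ladder
of amplification factors and reducing each recorded microphone trace to a
sound pressure level.  The level is computed from the power spectral density
(Hann window, non-overlapping segments; one segment spanning the whole trace
by default) so that out-of-band noise does not contaminate the estimate:

    RMS   = sqrt( Σ_i PSD_i · BinSize )                 [V]
    dBSPL = 20 · log10( (RMS / MicSens) / p_ref )

with `MicSens = 0.00423643 V/Pa` (1/4" free-field measurement microphone)
and `p_ref = 20 µPa`, the standard SPL reference.  Two printed-formula
corrections are deliberate: the summed `PSD_i · BinSize` is mean-square
voltage, so the square root is required for the expression to be an RMS (the
formula is sometimes printed without it); and the reference pressure is
2×10⁻⁵ Pa, not 2×10⁻⁶ (a common misprint — with 2×10⁻⁶ every level would be
overstated by 20 dB, and a 0.2 Pa tone would not come out at its textbook
80 dBSPL).  The logarithm is base 10, the dB convention.

The calibration table maps 300 logarithmically spaced factors to measured
dBSPL (≈0.2–0.5 dB per step over a 60 dB range, hence ~0.5 dB lookup
precision).  The speaker is injected as a plain callable `factor → recorded
trace`, so the table builder is testable without hardware; silent outputs
are flagged invalid rather than dropped.  Lookup returns the factor whose
measured level is nearest the target, resolving exact ties to the larger
factor (louder-side rounding) and refusing targets outside the measured
range.

## Trigger encoding and timestamp decoding

Stimulus times are marked on the second sound-card channel as analog square
waves of *twice* the stimulus duration, the positive half coincident with
the stimulus.  A diode before the acquisition input clips the negative half,
so the recorded pulse has exactly the stimulus duration; the negative half
exists only to keep the AC-coupled card from producing capacitive droop.
For combined stimulation the sound and light square waves are summed on the
one channel: the plateau above the laser trigger level (3.3 V) drives the
laser and marks the light pulse, and the amplitude steps inside it mark the
embedded sound pulse.  This replaces digital timestamp inputs, a noticeable
fraction of which arrive >150 µs late.

Decoding inverts the scheme from the rectified channel alone: rising/falling
crossings of the event threshold (default: half the smallest square
amplitude) delimit pulses, crossings closer than 0.5 ms are merged (noise
debounce), a plateau above 3.3 V marks light, amplitude steps larger than
the event threshold inside a light plateau split out the coincident sound
event, and supra-second light pulses are labelled continuous.  The first
sample at-or-above threshold is the onset.  Pulses shorter than two samples
are discarded and counted.  On noiseless synthetic sessions the round trip
is exact to the sample, including the 4 ms light-before-sound lead of
combined stimulation.

Two encoding details depart from the strict double-length convention.
Continuous-light blocks (20 s on / 10 s off) cannot carry a 40 s square, so
their negative half is clipped at the next block's onset; pulsed modalities
keep the strict no-overlap error.  And when the record's sample rate equals
exactly twice the sound band's upper edge (30 kHz for 5–15 kHz), the
synthetic noise burst's upper edge is clipped to 0.45·fs — the anti-aliased
representation such a recording would contain; triggers are unaffected.

Default protocols: sound — 3 ms, 80 dBSPL, 5–15 kHz Gaussian noise pulses at
10 Hz, five blocks of 200; light pulses — 10 ms at 10 Hz, one block of 200
when presented alone, and paired 4 ms before every sound pulse in combined
stimulation; continuous green light — five 20 s blocks with 10 s intervals.
The inter-block interval of pulsed protocols is set to the same 10 s, which
keeps continuous-light blocks exactly coextensive with stimulation blocks.

## Spike detection

Wide-band traces are band-passed 300–7500 Hz with a 4th-order Butterworth
applied forward and backward (zero phase, so detected peak times are not
biased; the effective magnitude order doubles).  The noise SD is estimated
robustly as `median(|x|)/0.6745`, which is insensitive to the spikes
themselves.  Events are local minima below −`threshold_sd`·SD (default 4.5,
usual range 2–4.5) with a 1 ms refractory separation, the deeper trough
winning; 2 ms snippets are cut around each peak (zero-padded at the trace
edges).  Clustering into single units is out of scope — the synthetic
fixtures carry one unit per channel, and real multi-unit traces should go to
a dedicated sorter.

## PSTH and the Poisson-surrogate response test

PSTHs count spikes in 2 ms bins over a 100 ms window centered on each
stimulus onset (25 baseline bins before, 25 response bins from t = 0,
half-open `[left, right)` so the t = 0 bin is response-side), summed over
trials.  The test statistic is the baseline-corrected spike count: mean
response-bin count minus mean baseline-bin count.

Significance comes from a simulated null: N surrogate histograms (default
N = the condition's trial count; 1000–2000 typical) with every bin an
independent Poisson draw at λ = the observed mean baseline-bin count, each
reduced to its own corrected count, and

    p = (g + 1) / (N + 1),   g = #{ surrogates with corrected count > observed }

with strict inequality (ties do not count against the unit).  A unit
responds to a condition when p < 0.05.  Categories: sound-only, light-only,
sound+light-only, or sound-and-light (both pulsed conditions significant);
ambiguous combinations resolve to the pulsed modality's label with the full
p-vector retained.  Surrogates are seeded per (unit, condition) by a
counter-based scheme, so results are reproducible and order-independent.

Two properties of this test are worth knowing.  First, it is one-sided for
rate *increases*: suppressed units produce negative corrected counts and
p ≈ 1, and surface instead through the modulation-direction metric.  Second,
it is mildly anti-conservative at low rates: λ is estimated from the same 25
baseline bins that enter the observed statistic, so a downward baseline
fluctuation simultaneously inflates the statistic and tightens the surrogate
null.  An exact Monte-Carlo oracle of the procedure puts the size at ≈0.079
for λ = 1 per bin, ≈0.06 around λ = 4–20, and ≈0.05 by λ = 60; across a
log-uniform 0.5–30 Hz population at 1000 trials, the empirical
false-positive fraction is ≈0.06 rather than the nominal 0.05.  A related
small-sample pathology: a unit whose baseline bins are all empty gets λ̂ = 0,
so any single post-stimulus spike reaches the p floor 1/(N+1).  The test
suite checks the implementation *against the oracle* (agreement isolates
coding errors from the method's intrinsic size) and the acceptance suite
reports the raw false-positive fraction as measured.

## Unit metrics

- Firing rate: spikes per second over the entire recording, stimulation
  epochs included.  Units split at 9 Hz (strictly greater = fast-spiking);
  the empirical rate distribution is bimodal with a gap around this value,
  so the tie direction is immaterial in practice.
- Modulation direction between conditions (e.g. sound vs concomitant
  sound+light): sign of the rate change, tolerance 0 Hz by default.
- Response latency: center of the first response bin exceeding baseline
  mean + 3 SD whose *following* bin also exceeds the baseline mean (one-bin
  persistence guard).  The criterion multiplier defaults to 3 rather than 2:
  at a realistic 1.5 Hz baseline over 1000 trials (λ = 3 per bin) an
  isolated Poisson bin crosses an estimated 2 SD threshold in ~8% of bins,
  so a first-crossing rule at 2 SD false-triggers on roughly a quarter of
  units, while at 3 SD the recovery of injected 10–40 ms onsets is 99/100
  within one bin.  The multiplier remains an explicit parameter because the
  estimator itself is a modelling choice, not a published definition.
  Gaussian response jitter also places genuine response spikes in the bin
  before the one containing the mean onset, so recovery is judged at
  adjacent-bin resolution.
- Group comparison: Welch's two-sample, two-tailed t-test, Bonferroni
  multiplied by the number of comparisons and capped at 1; fully degenerate
  equal groups return 1.

## ABR extraction

The high-frequency event-related LFP from the same intracerebral electrode
is band-passed 500–1500 Hz (4th-order Butterworth, zero-phase — causal
filtering would bias wave latencies, which are an output), sliced −3 to
+12 ms around each sound onset (450 samples at 30 kHz), and averaged;
epochs falling outside the recording are skipped and counted.  Peaks are
samples exceeding the epoch mean + 1 SD that are greater than the previous
sample and at least the next (a plateau's first sample wins); endpoints are
excluded, the mean/SD window is the whole epoch, and the first five peaks
feed group summaries.  The criterion is scale-covariant, so detected
latencies are invariant to gain — and, as a corollary, a pure-noise average
still yields qualifying local maxima; what separates evoked waves from noise
peaks is amplitude against the per-sweep noise, not the count.

## Synthetic sessions

The generator emulates the study's conditions with full ground truth.
Schedules are the default protocols above; unit archetypes, with defaults
drawn from the firing statistics such experiments report:

| archetype            | baseline | response                                   |
|----------------------|----------|--------------------------------------------|
| sound_responder      | 1.5 Hz   | +1 locked spike, P=0.8, 2 ms after sound   |
| light_responder      | 1.5 Hz   | same, after light pulses                    |
| delayed_responder    | 1.5 Hz   | same, 19 ms after sound (polysynaptic regime) |
| suppressed_responder | 20 Hz    | baseline thinned 80% for 30 ms after sound |
| nonresponder_low     | 1.5 Hz   | none (must stay <9 Hz)                     |
| nonresponder_high    | 26.8 Hz  | none (must stay >9 Hz)                     |
| tonic_modulated      | 16.4 Hz  | rate ×2 during continuous light            |

Baseline spiking is homogeneous Poisson; response spikes are additive at
onset + response_onset + N(0, 0.5 ms); suppression is thinning.  Raw traces
add a biphasic template (80 µs trough, slower positive rebound, trough
amplitude in multiples of the noise SD — default SNR 8) to Gaussian noise at
each spike time, overlaps summing linearly.  The ABR-bearing LFP adds, after
*every* sound pulse, five Gaussian bumps (σ = 0.2 ms, latencies 1.5–5.5 ms,
amplitudes 1.0/0.8/0.9/0.6/0.5) on per-sweep Gaussian noise of SD 1.0 —
noise comparable to the largest wave, so single sweeps are noise-dominated
and only averaging reveals the waves, as in real ABRs.  Each component
(schedule encoding, every unit, raw noise, LFP noise) draws from its own RNG
stream derived from the master seed, so adding a unit perturbs nothing else
and identical seeds give byte-identical session files.

What the generator does *not* emulate — and hence what green tests do not
establish about real data: spike waveform variability and overlap between
units on one channel, electrode drift, non-Poisson history dependence
(bursting, refractoriness in the baseline), stimulus-level dependence of
responses, and correlated (non-Gaussian, non-stationary) noise.

## File formats

Analog records are flat interleaved little-endian int16 with a JSON sidecar
(sample rate, channel names, volts per bit) — the flat-binary convention of
common open acquisition systems; spike times, schedules, PSTHs, unit tables
and ABR traces/peaks are plain CSV; the session truth ledger is JSON.

## Problem sizes

Default validation scales were chosen to give tight statistical checks at
desk scale: 500 null units for classifier size, 100 units each for power and
latency recovery, 1000-trial sessions (five blocks of 200), 200-sweep ABRs,
10 s spike-detection fixtures.  The full test suite runs in well under a
minute; the acceptance script in a few seconds.

## Known limitations

- The surrogate test's mild anti-conservativity at low rates and its λ̂ = 0
  small-sample pathology (both quantified above) are properties of the
  published procedure reproduced here, not adjustable defects.
- Suppression is invisible to the significance test (one-sided); only the
  modulation metric reports it.
- Spike detection is single-channel and threshold-based; overlapping units
  are not separated.
- The latency estimator is a pragmatic definition of a quantity the source
  workflow reports without defining; conclusions that hinge on absolute
  latency should sweep `criterion_sd`.
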