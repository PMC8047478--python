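# Methods

This note documents the models, procedures and numerical choices behind
`illuseeg`, and what the synthetic-data validation does and does not show.

## Stimulus construction

**Speech-shaped noise.** The masker's magnitude spectrum is the mean
magnitude spectrum of the speech snippets, zero-padded to the longest
snippet length. Segments of that length are synthesised with fresh
uniform-random phases (real inverse FFT enforces Hermitian symmetry), then
tiled and cropped to the requested duration. Averaging magnitude spectra —
rather than, say, concatenating snippets and transforming once — matches
the ensemble long-term speech spectrum, which is the property that makes
the masker effective. Phase randomisation leaves the magnitude spectrum
invariant, so re-synthesising noise from its own output reproduces the
spectrum (a tested idempotence property).

**ISI schedule.** Sessions default to three 600-s blocks of twelve 50-s
sub-blocks with 5 stimuli each (180 total). The four within-sub-block gaps
are drawn once from [3, 19] s, sorted ascending (short ISIs first, long
last — the expectation manipulation), and accepted only if the wrap-around
gap into the next sub-block also falls in [3, 19] s; the frozen pattern
then tiles all 36 sub-blocks, so every consecutive onset difference in the
session respects the ISI bounds and the onset pattern is identical across
sub-blocks.

**Adaptive staircase.** The 1-up/2-down rule (one miss raises the level,
two consecutive detections lower it; the two-down counter resets after any
level change) asymptotically tracks the 70.7 % point of the psychometric
function. Steps start at 1 dB, halve to 0.5 dB after the 4th reversal; the
run stops after the 9th reversal and returns the mean level of the last 5
reversal levels. Two finite-procedure properties matter:

* *Reversal parity.* Reversal levels alternate between track valleys
  (miss after a descent) and peaks (detection pair after an ascent).
  Averaging an odd number (5) of them makes the estimate sensitive to
  which kind comes first. A start level clearly above threshold forces
  every run to descend first, giving three valleys in the last five and a
  ~2-percentage-point low bias in the tracked probability (68.5 % measured
  over 4000 simulated runs). Starting at the prior threshold estimate
  (`start_level` defaults to the observer's expected threshold region)
  randomises the first-reversal direction and restores 70.7–71.4 %
  tracking. The asymptotic rule is exact: with 25 reversals and an even
  (20-reversal) average the simulated tracking is 70.71 %.
* *Guard.* A 200-trial cap aborts non-terminating runs with the trial
  trace in the error message.

**Hearing-level bracketing.** Descend in 2-dB steps until "not hearing",
drop 10 dB, ascend in 2-dB steps until "hearing again", three repeats; the
individual hearing level is the mean of all six report levels (both report
types pooled, the literal reading of the procedure).

**Session assembly.** Main sessions place snippets at the schedule onsets
with levels uniform in threshold ± 1.5 dB; button-press control sessions
place 60 clearly audible snippets (threshold + 5–6 dB) every 10 ± 1 s.
Levels are dB re a unit-RMS snippet in the units of the noise bed.

## Behavioral classification

All times stay continuous (seconds); sample quantisation happens only at
epoching. A response is linked to the most recent stimulus with onset in
[r − 1.8, r − 0.3] s; the first qualifying response wins per stimulus, so
the hit mapping is injective. Stimuli with no response inside 3.6 s are
misses; responses with no stimulus in the preceding 3.6 s are FAs;
everything between is deliberately discarded as margin. CR anchors are
packed greedily into stretches free of events within the epoch half-width
plus a 1-s guard. Interval boundaries are closed; the simulated observer
truncates RTs strictly inside (0.301, 1.799) s because an RT exactly on
the window boundary is ambiguous at floating-point precision — with that
convention the classifier reproduces the generator's own labels exactly
on every seeded session (a tested round-trip).

The RT histogram uses 42-ms bins, a Gaussian-weighted moving average of
420 ms (10 bins, MATLAB-style α = 2.5 ⇒ σ = (N−1)/5), and is rescaled so
the trapezoidal integral over bin centers is exactly one.

## Preprocessing

Filters are Hamming-windowed sinc FIRs with even order (type I linear
phase): 0.3 Hz highpass (transition 0.6 Hz, order 1100) and 45/30 Hz
lowpasses (orders 84/88) at the 200 Hz working rate. The highpass is
realised as the spectral inversion of the complementary lowpass, making
the DC null exact (a directly designed highpass of this spec leaves
~5·10⁻³ DC gain). "One-pass zero-phase" means a single forward
convolution compensated by the group delay of order/2 samples; an impulse
maps onto the taps centered at the impulse sample, and linearity holds to
1e−9.

Downsampling (1000 → 200 Hz) applies an anti-alias lowpass at 0.8× the
target Nyquist before integer decimation, preserving the time base.
Epochs include both window endpoints (a [−4.6, 1.9] s window at 200 Hz is
1301 samples) with the anchor at t = 0; anchors too close to the record
edges are dropped and reported. Peak-to-peak rejection is strict
("higher than"): a trial at exactly the 300 µV threshold survives. The
liberal 400 µV pre-cleaning screen excludes a configurable frontal set
(default Fp1/Fp2/Fpz/AF7/AF8/AF3/AF4/AFz) so blink trials survive into the
artifact-decomposition stage; that stage itself (ICA) is exposed only as
an optional hook defaulting to identity.

## ERP analysis

Component peaks are raw extrema (no interpolation), ties broken to the
earliest sample, inside fixed windows: stimulus-aligned LP 400–1300 ms and
EN 100–600 ms; response-aligned LP −250–250 ms and EN −900 to −100 ms, all
at Pz. Baselines: −200–0 ms pre-stimulus (an alternative −1.3 to −1.1 s
window used in some displays ships as `stimulus_early`), −3.1 to −2.9 s
pre-response. Topographies are per-channel time averages over an interval;
spatial correlation is Pearson's r over channels.

## Time-frequency analysis

The wavelet bank spans 1–45 Hz with cycles n(f) = 3 + 7(f−1)/44. With
envelope std σ_t = n/(2πf), FDHM = 2√(2 ln 2)·σ_t = n√(2 ln 2)/(πf) falls
from 1.1243 s at 1 Hz to 83.3 ms at 45 Hz, and the spectral FWHM
2√(2 ln 2)·f/n rises from 0.785 to 10.597 Hz; their product is the
constant 4 ln 2/π. Wavelets are truncated at ±4σ_t and normalised to unit
total energy (Σ|w|² = 1) so power is comparable across frequencies. Power
is evaluated on a 10-ms time grid with wavelets constructed directly on a
0.2-Hz frequency grid (no post-hoc interpolation). Samples within half a
wavelet length of an epoch edge are flagged invalid and excluded from
every downstream statistic.

The ERSP averages |W|² over trials (squared magnitude; plain magnitude is
available by flag — the wording "absolute values averaged" vs the power
units used everywhere downstream is a genuine ambiguity, resolved in
favour of power). Relative baseline: (P − P̄_base)/P̄_base with the
per-frequency baseline ending one FDHM before the activation start, so
wavelet smearing cannot leak activation power into the baseline; a
frequency whose margin consumes the whole baseline raises an error naming
it. Band traces average frequency bins in SCP 1–4, alpha 8–12, beta
15–25 Hz.

## Cluster statistics

The permutation unit is a per-subject swap of the two conditions,
equivalent to a random sign flip of that subject's difference map — for
activation-vs-baseline input, maps are activation samples minus the
subject's time-averaged baseline. The cluster-forming threshold is the
2.5th/97.5th percentile of t(N−1) (sample quantiles of the map itself
would select 5 % of samples even under the null). Clusters connect
supra-threshold samples over adjacent time bins, adjacent frequency bins,
and neighbouring channels (3D distance ≤ 0.55 on the unit head, ≈ 32° arc,
giving ~6 neighbours on the 64-channel 10-10 layout and a connected
graph); positive and negative clusters are kept separate and singletons
are allowed. Every observed cluster is tested against the same null
distribution of the maximum absolute cluster sum;
p = (1 + #{null ≥ obs})/(1 + B) keeps p > 0. For N subjects with
2^N ≤ B the full enumeration of sign assignments replaces sampling, and
the Monte-Carlo p then equals the exhaustive p exactly. Zero-variance
samples map to ±∞ (clamped) by convention, documented in `dependent_t`.
Trial-count equalisation subsamples the larger side uniformly without
replacement, seeded, preserving trial order.

## Synthetic data

Background EEG is 1/f noise (PSD ∝ f^−1 by default, σ = 20 µV per
channel) with 50 % of the variance contributed by a component shared
across channels (spatially correlated noise makes the cluster test's null
behaviour realistic). All trials of a condition are generated in one
batched FFT.

Planted effects:

* **EN/LP** — Gaussian deflections amplitude·exp(−(t−latency)²/2w²) times
  a cosine-falloff topography centered on Pz/CPz (C3/C4 for motor
  effects). Defaults follow the magnitudes reported for this paradigm:
  response-aligned hits LP +7.5 µV at −25 ms, EN −2.7 µV at −250 ms; FAs
  LP +4.2 µV at −15 ms, EN −2.9 µV at −415 ms; stimulus-aligned hits LP
  +2.5 µV at 800 ms, EN −2.1 µV at 345 ms.
* **SCP / alpha-ERD / beta-ERD** — the band-limited part of the noise is
  multiplied by √(1 + a·env(t)) under a Gaussian envelope, so band power
  changes by the relative amount a at the envelope peak (+0.5 for the SCP
  enhancement; −0.4 / −0.3 for alpha/beta ERD). The modulated band is
  widened by the Morlet spectral FWHM at its edges: analysis wavelets
  integrate over that width, and a sharp-edged modulation would read out
  ~50 % diluted.

Condition recipe: hits carry EN + LP + SCP + both ERDs; FAs the same with
LP and SCP scaled by 0.6 (illusory percepts are weaker); misses and CRs
are noise only; button presses carry only the motor ERDs. Trial counts
default to the study's mean clean counts (108 hits, 67 FAs, 57 misses, 60
button presses; CRs — undefined in a continuous design — default to 60).
Between-subject variability is a Normal(1, 0.15) amplitude scale.
Everything is a deterministic function of one seed.

What the generator does **not** emulate: ocular/cardiac artifacts (ICA is
out of scope), non-stationary noise, RT-dependent component latency
jitter within a condition, volume-conduction-realistic topographies, or
any coupling between the behavioral observer and the EEG effects beyond
the condition labels. Passing recovery tests therefore validate the
analysis chain's arithmetic and inferential behaviour, not its robustness
to real-world artifacts.

## Validation protocol and measured behaviour

* **Wavelet widths** are checked against the closed forms exactly
  (1124/83 ms, 0.78/10.60 Hz).
* **Staircase tracking**: 1000 seeded runs against a logistic observer
  (midpoint 0 dB, slope 1/dB) give a mean tracked probability of
  70.7–71.4 % depending on the seed batch (see the reversal-parity
  discussion above).
* **Type-I error**: on 200 null datasets (16 subjects, spatially
  correlated 1/f epochs, 2 channels × 40 bins, 500 permutations) the
  family-wise significant-cluster rate at α = 0.05 measured 0.04.
* **Oracle equivalence**: cluster finding matches a flood-fill oracle
  exactly; Monte-Carlo p equals exhaustive p at N = 4; the event
  classifier matches an O(n·m) rule scan on 1000 random sessions.
* **Component recovery** uses the chain as it would run on real data:
  per-subject averages are passed through the 0.3–30 Hz ERP filters, the
  grand average over 16 subjects (100 trials each) is peak-picked, and
  the result is compared with the *noiseless planted waveform passed
  through the same filters* — the highpass attenuates the slow Gaussian
  deflections by ~20 %, so the raw planted amplitude is the wrong
  reference. Amplitudes at the reference latency recover well within
  ±3 SEM. Raw-extremum latencies are the fragile quantity: without the
  highpass, sub-0.3 Hz drift moves extrema by 30–110 ms; with it,
  single-replicate errors have SD ≈ 20 ms (LP) and ≈ 40 ms (EN — its
  2.2 µV filtered trough is flat within ±70 ms at grand-average SNR), so
  the acceptance check evaluates the mean over four replicate simulated
  experiments, which lands within ±25 ms for both components. Single-run
  EN latency should not be over-interpreted at this SNR — in synthetic or
  real data.
* **Power**: the hit-vs-FA late-positivity contrast (a +3.3 µV Pz
  difference at the default trial counts) yields a significant positive
  cluster in ≥ 90 % of 50 simulated 16-subject datasets.

Problem sizes in the test-suite simulations (channel subsets of 2–32, the
trial/subject counts above, 200–500 permutations) were chosen so each
check measures what it claims with comfortable Monte-Carlo margins.
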