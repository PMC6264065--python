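# Methods

## Stimulus model

A trial is a pure tone at one of {1000, 2000, 4000} Hz whose virtual
source sweeps 0° → +90° → −90° → 0° at constant angular speed, one
cycle per 3 s (120°/s), hence two cycles per 6-s trial. Spatial
movement is conveyed by interaural intensity alone (no interaural time
differences or HRTFs): the panning law fixes three anchors — both ears
at `target − 10 dB` at 0°, ipsilateral ear at `target` and
contralateral ear silent at ±90° — and interpolates linearly in the dB
domain between them.

Interpolating "toward silence" in dB is ill-defined (silence is
−∞ dB), so the contralateral ear fades linearly in dB from
`target − 10` at 0° to a configurable silence floor (default
`target − 60 dB`) at ±90°, below which the channel is muted. The law
is exactly mirror-symmetric: negating the azimuth swaps the two ears.

The sweep is discretised the way the intensities are delivered: each
90° quarter is divided into six equal sub-segments (five interior
breakpoints), the per-ear level is evaluated at each sub-segment's
temporal midpoint and held constant within it, and consecutive steps
are joined by 10-ms linear crossfades so the envelope is click-free
while remaining audibly stepwise. Trials start and end with 20-ms
raised-cosine ramps. Midpoint sampling keeps the discretised envelope
mirror-symmetric; its measured repetition period is 3 s to within one
sub-segment (0.125 s), and the FFT peak of the envelope falls exactly
on 1/3 Hz.

Digital level calibration maps dBA to amplitude as
`a(L) = ref_amp · 10^((L − ref_dBA)/20)` with defaults
`ref_dBA = 70`, `ref_amp = 0.5` full scale. Only relative levels are
meaningful; absolute SPL calibration requires hardware and is out of
scope. Levels that would map above full scale raise an error naming
the offending dBA value.

## Protocol

A session is a 5-s introduction plus 16 consecutive 6-s trials:
trial 1 silent (negative control), trials 2–6 at 1000 Hz, 7–11 at
2000 Hz, 12–16 at 4000 Hz, each block a uniform random permutation of
{30, 40, 50, 60, 70} dBA. Inter-trial intervals are drawn uniformly
from [2, 5] s (the continuous choice; a discrete set would also be
defensible). An experiment is eight sessions; session *i* uses seed
`master_seed + i`, making the whole schedule reproducible from one
integer.

## EOG processing

1. **Bipolar derivation** — left minus right periocular electrode,
   isolating horizontal gaze; common-mode components cancel here.
2. **Down-sampling 2048 → 512 Hz** — default is a zero-phase FIR
   anti-alias polyphase decimator with linear end-extension; the
   classical order-8 Chebyshev-I IIR decimator is available
   (`method="cheby"`). The FIR default was chosen because the
   Chebyshev design's passband ripple, squared by zero-phase
   application, attenuates a 0.33 Hz component by up to 1.1%, while
   the FIR path is amplitude-exact to ~1e-6.
3. **Epoching** — 6-s epochs cut at trigger onsets, no pre-stimulus
   baseline (none is needed; the filter removes offsets).
4. **DC removal** — per-epoch mean subtraction.
5. **Band-pass** — Butterworth design of order 4 with cut-offs 0.2 and
   0.4 Hz, applied forward-backward (`sosfiltfilt`), i.e. zero phase
   and squared (effectively 8th-order) magnitude.

**Edge handling is the consequential numerical choice here.** The
passband period (3 s) is half the epoch length, so an unpadded or
short-padded filtfilt is transient-dominated: with reflection padding
of one epoch length, a unit 1/3 Hz sinusoid comes back with peak 0.81
instead of ~1.0. Epochs are stimulus-locked and contain an integer
number of sweep cycles, so periodic extension is near-exact for the
component of interest: the default tiles the epoch four times on each
side (`pad_factor=4`, `pad_mode="wrap"`) before filtering and crops
the centre. Under this default a 6-s unit 1/3 Hz sinusoid is returned
with peak 1.00 ± 0.01 and a 50 Hz tone is suppressed below 0.01.
Reflection padding remains available via `pad_mode` for free-running
(non-stimulus-locked) signals.

One artifact of periodic extension worth knowing about: a slow ramp
(e.g. baseline drift) across the epoch becomes a sawtooth with period
6 s, whose harmonics at 1/6 and 1/3 Hz lie in the passband. In
practice this sets the noise floor of the amplitude feature (inaudible
trials land near 0.05 of the reference rather than at zero), which is
also what real recordings show — inaudible trials are never exactly
flat.

## Feature and statistics

The trial feature is `max |x(t)|` of the filtered epoch ("EOG
amplitude"). Within each session every amplitude is divided by that of
the session's reference trial (2000 Hz at 70 dBA, audible to any
normal-hearing listener), removing the large inter-individual and
inter-session variation of the corneo-retinal potential. Trials are
labelled against the listener's pure-tone thresholds: above → audible,
below → inaudible, exactly at threshold → discarded; the silent
trial 1 is a no-sound control outside the comparison. Session means
per condition give eight paired values.

The paired comparison uses an **exact two-sided Wilcoxon signed-rank
test**: zero differences dropped, tied |differences| mid-ranked, and
the null distribution of W⁺ computed exactly over all 2ⁿ sign
assignments conditioned on the observed rank multiset, via a
shift-convolution over doubled ranks (doubling makes mid-ranks
integral). A literal 2ⁿ enumeration ships alongside as an independent
oracle and the test suite checks the two agree on random instances,
including ties. For eight uniformly positive pairs the two-sided p is
2/256 = 0.0078125, the smallest value attainable at n = 8. A
Lilliefors normality check (classical fixed-parameter KS by flag)
documents why the nonparametric test is used; Bonferroni correction
(`min(1, p·m)`, m = participants) handles multiplicity across
participants.

Sessions in which one condition is empty (possible for extreme
audiograms) are excluded from the pairing with a warning.

## Synthetic listener

The generator's defaults are the study conditions the tests assume:
8 sessions × 16 trials of 6 s at 2048 Hz, flat true thresholds of
40 dBA (earplug-elevated normal hearing, mid-grid so that exactly one
intensity per frequency is discarded), oculomotor gain 40 µV, sensor
noise 10 µV per electrode. When the sensation level
SL = intensity − threshold is positive the horizontal component
contains `gain · logistic(slope·SL) · sin(2π t/3 + φ)` with φ jittered
per trial (SD 0.3 rad); at or below threshold there is no reflex —
the "out of phase when inaudible" observation is modelled as the
absence of any phase-locked component rather than an oscillation with
random phase. The logistic slope default is 0.1 dB⁻¹ so the reflex
still grows perceptibly over the tested 0–30 dB SL range (a steeper,
saturating choice would make all audible trials equal); with it, the
rank correlation between sensation level and measured normalized
amplitude across a default experiment is ≈ 0.9. Baseline drift
defaults to 10 µV at 0.05 Hz with random phase — enough to exercise
the filter's stopband and set a realistic inaudible-trial floor
without drowning the dose-response (see the sawtooth note above).
Common-mode 0.1 Hz activity (30 µV) and per-electrode DC offsets
(SD 100 µV) are added to both channels to exercise the bipolar
derivation and DC removal; they carry no horizontal-gaze information.

Continuous session recordings include the 5-s introduction and random
inter-trial gaps, and the trigger events match the schedule exactly;
regeneration from the same master seed is byte-identical
(per-session RNG streams spawned from one `SeedSequence`).

What the simulator deliberately does **not** model: blinks and
saccade artifacts, 1/f electrode noise, eye-openings corrupting the
reference trial, per-frequency differences in reflex gain, and any
acoustic coupling (earplugs and booth noise are collapsed into the
elevated thresholds). Passing tests therefore show that the pipeline
recovers the contrast its model assumes — not that the contrast is
present in any particular human recording.

### Staircase

The simulated modified Hughson-Westlake procedure starts at 60 dBA
within [0, 100] dBA, descends 10 dB after each response and ascends
5 dB after each miss; the threshold is the lowest level with responses
on ≥ 2 of up to 3 ascending arrivals. Responses are deterministic
(heard iff level ≥ true threshold) unless a psychometric slope is
supplied, in which case response probability is logistic around the
true threshold. Deterministic listeners with on-grid thresholds are
recovered exactly; off-grid thresholds return the next 5-dB step
above, which is the procedure's quantisation, not an error.

## Problem sizes and determinism

A full simulated experiment (8 sessions, ≈ 153 s of 2-channel
2048 Hz signal each) takes about a second to generate and process.
The null-calibration check runs 100 such experiments with zero
oculomotor gain and verifies the Wilcoxon rejection rate at α = 0.05
stays at the nominal level (≤ 10/100). Every stochastic step runs off
an explicit seed: schedules via `master_seed + session`, recordings
via spawned `SeedSequence` streams, so all reported numbers are
reproducible bit-for-bit.

## Known limitations

- The amplitude feature uses only magnitude; the phase locking between
  sweep and gaze, clearly informative, is not exploited.
- No per-ear assessment: intensity panning stimulates both ears.
- No artifact rejection; a blink inside an epoch would inflate its
  amplitude, and a corrupted reference trial would rescale a whole
  session.
- The dose-response law and drift model are pragmatic choices, not
  fitted oculomotor physiology.
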