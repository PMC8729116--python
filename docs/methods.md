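# Methods

## Overview

`borborygmi` implements a complete bowel-sound (BS) analysis pipeline for
abdominal audio: preprocessing, Mel-spectrogram featurization of 60 ms
slices, a compact convolutional BS/non-BS classifier, conversion of the
per-window prediction series into time-stamped events, four acoustic
features per recording, and a paired nonparametric comparison of fasted
vs fed states. Because clinical BS corpora are essentially never shared,
the package also contains a first-class synthetic recording generator
that defines the conditions under which everything is validated.

## Signal model and preprocessing

Recordings are mono, 16-bit PCM at 11025 Hz (the nearest standard rate
to the ~11 kHz used by clinical acquisition hardware; any other input
rate is resampled on load with polyphase band-limited interpolation).
All time intervals are half-open `[start, end)` in float seconds.

Preprocessing is a second-order Butterworth high-pass at 80 Hz, applied
forward-backward (`sosfiltfilt`). Zero-phase filtering was chosen so
that event time stamps are never shifted by group delay; the price is
that the effective response is the squared single-pass magnitude — the
attenuation at 80 Hz is 6 dB rather than the single-pass 3 dB. The
closed form used in tests is |H(f)| = 1/sqrt(1 + (fc/f)^4) per pass.

## Featurization (128 x 3 Mel slices)

Each 60 ms slice is framed at 50 ms with a 5 ms shift — exactly three
frames — windowed with Hann, transformed with a 1024-point FFT (next
power of two above the 551-sample frame), and projected onto 128
triangular Mel filters spanning 0 Hz to Nyquist. Per slice, power is
converted to dB with an 80 dB floor below the slice maximum and min-max
normalized into [0, 1]; an exactly constant slice maps to all zeros.
Per-slice normalization makes the classifier amplitude-invariant: it
must discriminate on spectral *shape*, which is the physiologically
meaningful cue (BS spectrograms are spiky, noise spectrograms flat).

Labelled datasets are sliced from recordings plus label tracks: BS
intervals of at least 60 ms yield consecutive non-overlapping slices
(remainder dropped; overlap would create near-duplicate training
samples), shorter intervals yield one slice centred on the interval
midpoint using surrounding context. Noise intervals are sliced the same
way. Class balancing randomly down-samples the majority class (seeded).

## Classifier

Three 3x3 "same" convolution stages (32/64/64 filters) each followed by
ReLU and 2x1 max pooling along the Mel axis only — the 3-frame time axis
is too narrow to pool and survives all stages (128 -> 64 -> 32 -> 16
Mel rows). Dropout 0.2 precedes the flatten; a 64-unit dense hidden
layer and a 2-way softmax finish the network (~253k parameters).
Training uses Adadelta (rho 0.95, eps 1e-6, step size 1.0 — the
original parameter-free formulation) on cross-entropy for 30 epochs at
batch size 128, recording train/validation accuracy per epoch. One
integer seed drives weight initialization, shuffling and dropout masks;
training is bit-deterministic on a given platform.

The network engine is a small numpy implementation (im2col convolutions
in float32 via BLAS matmul) built for this input geometry; gradients are
verified against finite differences in the test suite. The decision
threshold is 0.5 and exposed in the configuration.

## Event segmentation

The trained classifier sweeps a recording with a moving window (50 ms
hop by default, window = the 60 ms training geometry). Runs of at least
3 adjacent BS-predicted windows become candidates; the candidate start
is the first window start of the run and the end is the start of the
first following non-BS window (at the track end: last window start plus
one hop). Candidates separated by at most 100 ms merge into one event —
inclusively at exactly 100 ms — keeping the original runs as
inter-burst spans. With the default hop the >=3-window rule implies a
~150 ms minimum detectable span, which cannot resolve 20-40 ms single
bursts; `hop_s` and `min_run` are therefore parameters, and fine
segmentation uses e.g. a 5-25 ms hop with `min_run` 2.

## Acoustic features

Per recording: total BS duration per minute (s/min), and the medians
over events of

* spectral centroid (SC): amplitude-weighted mean frequency of the
  event's mean magnitude spectrum (50 ms Hann frames, 5 ms shift;
  events shorter than a frame use one zero-padded frame);
* half-maximum spectral bandwidth (SBW): extent from the lowest to the
  highest grid frequency with amplitude at least half the maximum (the
  total-extent convention, not the contiguous band around the peak);
* mean-crossing ratio (MCR): sign changes of the demeaned waveform
  divided by the number of samples; exact zeros adopt the previous
  nonzero sign.

The median aggregation is robust to the occasional long continuous
event. Features are computed on high-pass-filtered audio — the same
preprocessing the detector sees — so centroids exclude sub-80 Hz
energy. Note that within-event background noise contributes broadband
amplitude to the spectrum, so realized SC values sit above the nominal
event centre frequencies; this mirrors real recordings, where the
spectrum under an event is never the event alone. A recording with no
events reports zero duration and missing spectral features, and such
subjects drop out of the paired tests pairwise.

## Statistics

For each channel (RLQ, LUQ) and each of the four features, the fasted
and fed per-subject aggregates are compared with a two-sided Wilcoxon
signed-rank test: zero differences dropped, exact null distribution for
n <= 25 (falling back to the normal approximation when tied ranks make
the exact distribution unsound), normal approximation with continuity
correction otherwise. Exactly 8 p-values are Bonferroni-adjusted with
m = 8 and annotated at adjusted p < 0.05 and p < 0.01. Summary tables
report median (IQR, linear-interpolation quantiles) per feature x
channel x state.

Pairing one value per subject x channel x state is the default because
the design is within-subject; pooling all events with a rank-sum test is
available behind a flag. (Box-plot figure legends in this literature
sometimes advertise a p < 0.001 tier; the machine-readable output uses
the 0.05/0.01 tiers throughout.)

## Synthetic recording generator

Four subtypes with distinct morphology, all durations confined to
[0.02, 1.6] s:

* **SB** — one band-limited pulse of 20-40 ms with fast attack and
  exponential decay;
* **MB** — 2-8 such bursts separated by 10-100 ms silent gaps, with
  burst-to-burst amplitude variation (0.4-1.0 relative);
* **CRS** — 0.2-1.6 s of band-limited noise under a slowly varying
  random envelope, floored so the sound stays continuous;
* **HS** — a stack of 1-12 harmonics on a 200-800 Hz fundamental with
  1/k-ish rolloff, optionally frequency-swept, every component capped
  below 4 kHz.

Band-limited noise is synthesized in the frequency domain with a
Gaussian band magnitude whose full width at half maximum equals the
configured bandwidth, so the realized half-max spectral bandwidth
tracks the configuration and the realized centroid tracks the centre
frequency (no filter-skirt leakage, and the mean-crossing ratio stays
decoupled from the bandwidth parameter — necessary for a fed condition
that narrows bandwidth while leaving MCR untouched). Default centre
frequencies are 300-550 Hz (200-800 Hz fundamentals for HS), bandwidths
150-350 Hz, peak amplitudes 0.05-0.30 of full scale.

The background is pink (1/f-shaped) noise at −45 dBFS RMS, giving event
peak SNRs of roughly 19-35 dB. Event arrivals are a homogeneous Poisson
process (default 40 events/min fasted — yielding ~9 s of BS per minute,
a plausible fasted level); events are placed uniformly over the
positions still free, longest first, with a 100 ms guard gap between
any two events, which also enforces the single-burst isolation rule.
Everything is deterministic given a seed.

Fasted/fed shifts are expressed per condition: an event-rate factor
(1.6 by default, which scales BS duration per minute), a bandwidth
scale (0.85), and an optional additive centroid shift (0 by default).
Cohorts pair recordings within subject: each subject carries a
log-normal event-rate multiplier (sd 0.12) and a centre-frequency
jitter (sd 5%) shared across that subject's four recordings; the LUQ
channel runs at 0.8x the RLQ rate, mimicking site-dependent activity.

**What the simulator does not emulate:** physiological arrival
patterns (bursting, meal dynamics), room acoustics and sensor transfer
functions, non-stationary interference (speech, rustling), inter-event
correlation, or realistic subtype-specific spectra beyond the simple
morphologies above. Passing tests therefore demonstrate that the
pipeline recovers the structure this generator encodes at realistic
SNRs — not clinical performance on human recordings.

## Reference scales and their rationale

Validation uses deliberately scaled-down volumes (the real protocol
recorded hours per subject):

* classifier corpus: 22 min of simulated audio, subtype mix
  0.40/0.30/0.18/0.12 (ordering SB > MB > CRS > HS kept, rarer
  subtypes over-represented so the classifier sees enough of each;
  natural-mix cohorts are used everywhere else) -> ~9,200 balanced
  samples, split 70/30;
* held-out subtype corpus: 800 s with an SB-heavy mix so every subtype
  exceeds 200 tagged samples (single bursts contribute one slice each);
* paired cohorts: 20 subjects x 2 channels x 90 s per state; 50
  effect replicates and 25 null replicates for power and family-wise
  error estimates. The label-shuffled control trains 5 epochs — enough
  for the network to settle at its label-free behaviour.

## Numerical choices and degenerate inputs

* Mel/dB floor 80 dB below the slice maximum; constant slices map to
  zeros rather than NaN.
* Metrics with empty denominators (no positives/negatives) are reported
  as missing, never as 0.
* Merging uses an inclusive 100 ms boundary; a run touching the track
  end closes at last window start + hop.
* Frame/window counts use an epsilon before `floor` to protect exact
  ratios (e.g. 10 ms / 5 ms) from binary rounding.
* The event spectrum of a silent span is all zeros; SC/SBW are then
  missing.
* Wilcoxon with all-zero differences reports p = 1 with a degeneracy
  flag; fewer than 5 complete pairs is an error.

## Known limitations

* Multi-burst (MB) slice labels are intrinsically noisy: with 10-100 ms
  gaps between 20-40 ms bursts, about 11% of the 60 ms slices cut from
  an MB event contain no burst energy at all, which bounds attainable
  MB slice-level accuracy near 0.89 under this generator; the trained
  model reaches ~0.76 (single bursts, harmonic and continuous sounds
  reach 0.99-1.00). Event-level detection is unaffected because runs
  and merging bridge the gaps.
* The classifier is validated on the simulator only; no claim is made
  about human recordings.
* Cross-platform bit reproducibility of training is not promised
  (BLAS-dependent); metric-level reproducibility is.
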