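# Methods

This note documents the models, conventions and numerical choices behind
`adhf_voice`, and what the synthetic stack does and does not establish
about real clinical recordings.

## Preprocessing

Recordings are resampled to a common 25,000 Hz analysis rate by
polyphase rational resampling; the native microphone (44,100 Hz) and
accelerometer (11,025 Hz) rates have exact rational ratios to 25,000 Hz,
so no drift accumulates.  Microphone signals are then high-pass filtered
at 70 Hz to remove low-frequency room noise.  The filter is a zero-phase
spectral multiplication with a raised-cosine (Hann) edge that is zero
below `cutoff − smoothing/2` = 20 Hz and unity above
`cutoff + smoothing/2` = 120 Hz.  Note that tones *inside* the
transition band are partially passed — a 50 Hz tone survives at ~21 % of
its amplitude — which is the intended shape of this filter family, not a
defect; true stopband content (≤ 20 Hz) is removed essentially
completely.  Accelerometer signals are resampled only (configurable),
and amplitude is never normalized: the spectral measures downstream
(CPP, HNR) are level-robust by construction.

## Frame-level measures

**F0 tracking.** Each 40 ms Hann-positioned frame (every 3.3 ms; exact
step 82 samples) yields the normalized cross-correlation over lags
corresponding to the 60–300 Hz default search range.  Local maxima above
0.3 become candidates (parabolically refined to sub-sample lag); a
Viterbi pass chooses the path maximizing summed correlation strength
minus transition costs — 0.35 per octave of F0 movement and 0.14 for
voiced↔unvoiced switches — with an unvoiced state of constant strength
0.45 (the voicing threshold).  Frames whose RMS sits more than 40 dB
below the utterance maximum are forced unvoiced.  The thresholds mimic
common pitch-tracker defaults and are exposed as arguments.

**CPP.** For each 40.96 ms Hann frame (every 10.24 ms; 1024/256
samples), the power cepstrum of the frame is searched between
quefrencies of 3.3 and 16.7 ms — equivalently F0 between ~303 and
~60 Hz — and CPP is the dB height of the peak above the least-squares
regression line fitted to the dB power cepstrum over that same range,
evaluated at the peak quefrency.  The regression-line noise floor is the
convention of the smoothed-CPP literature.  CPP is exactly invariant to
amplitude scaling (scaling only shifts the zero-quefrency bin).
All-zero frames are NaN and excluded from summaries.

**Creak.** Four bounded descriptors are computed on a 100 ms window
every 10 ms: the slope of the 10 ms sub-frame power contour (dB/frame,
clipped to ±50); peak normalized autocorrelation over 2–20 ms lags
(unbiased for rectangular truncation); mean correlation of adjacent 4 ms
pulse snippets; and a subharmonic/wide-spacing score combining the
fraction of inter-pulse intervals above 13 ms with their coefficient of
variation.  Pulse instants come from Hilbert-envelope peaks.  A logistic
combiner over the z-scored descriptors yields the per-frame creak
probability.  The combiner was fitted once, with the package's own L1
logistic optimizer (λ = 0.01), on labelled frames from the synthetic
generator (creaky vs modal/noise/silence, seed 7); its coefficients are
frozen in `framewise.CREAK_MODEL` so detection is deterministic, and
`train_creak_detector` reproduces the fit.  A multilayer network would
add nothing at this feature dimensionality, and a linear combiner keeps
the decision auditable.  The subharmonic score carries most of the
weight; the power-slope and pulse-similarity descriptors are retained in
the feature vector (they separate speech from silence/noise) but were
zeroed by the L1 penalty in the shipped fit.

**Perturbation.** Jitter(local) = mean |Tᵢ−Tᵢ₋₁| / mean Tᵢ × 100 over
consecutive cycle lengths, from parabolic-refined waveform peaks in the
vowel's center 500 ms; cycles outside 0.5–1.7× the autocorrelation
period estimate are discarded as peak-picking failures.  Shimmer is the
analogue on refined peak heights.  HNR converts the unbiased normalized
autocorrelation peak r to 10·log10(r/(1−r)); on synthetic vowels with
additive noise at a known SNR this lands within ~0.1 dB of the SNR.
The low–high spectral ratio uses a 4 kHz band edge (a common
spectral-tilt convention; the band edge is an argument).  Fewer than 10
detected cycles → all four measures are missing.

## Voicing, phrases and summaries

A frame is voiced if it has non-zero tracked F0, lies within a speech
phrase, or has creak probability above 0.8.  The in-phrase criterion
depends on phrases, which depend on voicing; the fixed point is resolved
in two passes: (1) voicing from F0/creak, (2) phrases built from those
frames, then all frames inside a phrase marked voiced with an `IN_PHRASE`
provenance flag.  The mask lives on the creak track's 10 ms grid with F0
frames mapped by nearest time.

A speech phrase is the speech between two successive inhalations: voiced
runs merge when the intervening gap is ≤ 500 ms and split otherwise.
The boundary case (exactly 500 ms) merges — the definitional phrases
"longer than 500 ms splits" and "less than 500 ms merges" leave it
unassigned, and the merge choice is the permissive one.  Phrase-duration
SD is the sample SD, defined as 0 for a single phrase.  Phrase percent
divides total phrase duration by the utterance duration after trimming
leading/trailing silence beyond 1 s, so dead air at the recorder does
not dilute the measure.

F0 and CPP summaries use only values between the 5th and 95th empirical
percentiles (linear-interpolation percentiles, inclusive bounds); the
vowel-task F0 SD is additionally restricted to frames within 50 Hz of
the median, which removes octave-type tracking errors while keeping
normal pitch fluctuation.  Maximum phonation time is the time between
the first and last voiced frames of the MPT recording.

## Cohort statistics and classification

Same-task repeats within a day are averaged per measure (a measure is
missing only if missing in every repeat).  Each participant's first
recorded day is labelled admission (+1) and the last discharge (−1);
single-day participants contribute one admission row and are excluded
from paired statistics.  Model input keeps only labelled rows, drops any
row with a missing feature, and z-normalizes columns over the retained
rows; the "MPT−" variant drops the maximum-phonation feature first
(keeping participants who never performed it), the "MPT+" variant keeps
it and loses those participants to the missing-data rule.
Z-normalization is computed over the full retained input by default —
matching the described procedure — which leaks a small amount of
held-out information into CV folds; `build_model_input(...,
normalize=False)` plus fold-internal scaling is available where
leakage-safety matters more than fidelity.

The classifier minimizes mean logistic loss plus λ·Σ|βⱼ| (intercept
unpenalized — required for the large-λ majority-class limit) by FISTA
with soft-thresholding: deterministic, stopping when the coefficient
change drops below 1e-8 or at 10,000 iterations.  At λ = 0 on separable
data the minimizer diverges, so the iteration cap is reached by design;
the model is returned with `converged=False` and a warning rather than
an error, because its decision boundary is still the correct one.  λ is
selected from 30 geometric points on [0.001, 1] by minimum mean
cross-validated loss (ties to the smaller λ), with fits warm-started
down the sweep within each fold.

Sign conventions are fixed globally: +1 = admission, discharge
probability = σ(−f(x)), a row is predicted discharge only if that
probability strictly exceeds 0.5 (a tie is admission).  Under this
convention e^βⱼ multiplies the *admission* odds per 1-SD feature
increase; the odds-ratio report includes both e^β and its reciprocal
(discharge odds) so either reading is explicit.  Metrics treat admission
as the positive class: TAR (sensitivity), TDR (specificity), APV, DPV,
accuracy, and a rank-statistic AUC with half-credit for ties.
Odds-ratio and trajectory reporting use a final model refitted on all
labelled rows at the CV-selected λ; the refit λ is not separately tuned.

Trajectories score *every* daily row (admission, intermediate,
discharge) with the final model, normalizing with the training-time
column statistics stored in the model — never re-estimated — so scores
do not depend on which days are scored.  Rows with missing features are
skipped.  The cohort summary counts, among participants with more than
one scored day, the fraction whose last-day discharge probability
exceeds their first-day value.

## Synthetic generators

**Voice.** An exponentially decaying glottal pulse train (τ = 0.5 ms)
drives a fixed three-formant /a/ resonator (700/1220/2600 Hz).  Cycle
lengths and amplitudes carry iid Gaussian perturbations; the jitter and
shimmer parameters are expressed on the local-measure scale (the iid SD
is divided by 2/√π so the expected local jitter/shimmer equals the
setting).  The source is rendered at 8× oversampling and decimated so
that sub-sample pulse timing is band-limited rather than aliased — with
an exponential pulse, fractional timing is otherwise indistinguishable
from amplitude modulation and appears as a spurious ~3–4 % shimmer floor
at F0s that do not divide the sample rate.  Creaky segments substitute
irregular 40–70 Hz pulses (15 % interval jitter, occasional secondary
pulses at 45 % of the cycle).  White noise is added at a specified SNR
relative to the voiced signal; pauses are digital silence when
noiseless.  Truth (per-frame F0, voicing, creak, phrase intervals, pulse
times) is emitted alongside.

**Cohort.** The feature-level generator draws, per participant, a random
number of hospital days (2–10, with a 3/52 chance of a single usable
day, matching the study's incidence), a per-feature baseline
(between-participant SD 1), and a latent severity declining linearly
from 1 at admission to 0 at discharge with day-level jitter (SD 0.12).
Feature = baseline + loading × severity + noise (within SD 1); the
loading for a target paired effect d* is −d*·√2·within_sd, which makes
the population paired Cohen's d of the admission→discharge change
exactly d*.  Defaults plant the microphone-channel effect sizes
(total phrase duration −0.50, MPT +0.49, vowel F0 mean +0.35, CPP
effects ±0.17–0.27), with ~46 % of participants performing the MPT task
and 3 % per-cell missingness.  An audio-level mode maps severity to
acoustic parameters (SNR, F0, phrase/pause stretching, phonation length)
and renders actual recordings for integration tests.

**What passing tests show — and don't.** The synthetic voices are
single-formant-set, stationary-F0 stimuli; real speech has coarticulated
formant movement, breath noise that is not white, room reverberation,
and creak that shades gradually into modal voice.  The cohort generator
plants linear severity loadings with Gaussian noise; real feature
distributions are skewed and correlated across tasks.  Passing tests
therefore establish that the *operations are implemented correctly*
(they recover known truth, match oracles, and behave monotonically), not
that the features would achieve any particular accuracy on clinical
recordings — the clinical effect sizes at this cohort scale give
cross-validated accuracies only modestly above chance, and the synthetic
cohort reproduces exactly that regime.

## Problem sizes and numerical notes

Tests and the acceptance script run on desk-scale problems chosen to
keep the sampling error of each check well inside its tolerance:
1.5–2.5 s vowels for tracker/perturbation recovery, 52-participant
cohorts (the study scale) for effect-size and null-classification
checks, 200 replicates for the paired-d recovery bound, and a
6-participant audio cohort for the end-to-end integration test.  Frame
steps are exact sample counts (82/250/256 at 25 kHz) for
bit-reproducibility; percentile and SD conventions are pinned
(linear-interpolation percentiles, sample SD with n−1); all generators
are seed-deterministic.  Known limitations: the F0 tracker reports the
cross-correlation lag without glottal-closure alignment, so absolute
pulse timing is not meaningful; the creak detector is trained only on
synthetic creak and will not transfer to real vocal fry without
retraining; and perturbation measures assume a voiced, approximately
stationary vowel center.
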