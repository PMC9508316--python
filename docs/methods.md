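# Methods

`steercouple` implements a hybrid EEG–EMG analysis of steering behaviour:
movement onsets are read off the steering-wheel angle, EEG independent
components and deltoid EMG are decomposed into time–frequency power
(ERSP), and a pre-movement mu-band EEG template is cross-correlated,
trial-by-trial, against EMG spectrograms to quantify corticomuscular
coupling, with permutation statistics and two explicit null
constructions. This note documents the models, the parameters that
matter, the numerical choices, and what the synthetic data generator does
and does not emulate.

## Behavioural model and onset detection

A steering excursion is modelled as a signed sigmoid ramp (truncated
logistic, exactly zero outside its support), a plateau, and a sigmoid
return. Two onset detectors are provided.

**Chord distance.** Within a per-trial wheel trace, the first contiguous
stretch of |angle| > 2° marks the excursion. The onset is the sample
between the trial start and the excursion peak that maximizes the
perpendicular distance to the chord joining those two points — the
classic elbow/knee construction. Time and |angle| are normalized to unit
range first so the maximizer is scale-invariant and symmetric under sign
flips; ties break to the earliest sample. Trials with more than one
well-separated suprathreshold segment are discarded as ambiguous (noise
flicker at the slow threshold crossing is first healed by merging
segments separated by < 0.2 s). On the synthetic ramp this lands within
one or two samples of the 2° crossing, about 30 ms after the true ramp
support start; detection error stays below 40 ms at 0.5° sensor noise.

**Quantize / binarize.** The continuous wheel signal is snapped to levels
spaced 0.125 of its min–max range (9 levels), binarized against the level
nearest zero, clustered in time (zero gaps < 1 s merged, one-runs
< 0.25 s dropped), and each 0→1 transition is an onset. Its fidelity
contract — quantized-vs-original correlation > 99% and rectified-AUC
discrepancy < 5% — is checked on every run and recomputed by
`scripts/acceptance.py`. The rectified (absolute-value) area is used so
left and right excursions cannot cancel in a mixed session. This route's
effective threshold is half a level (≈ 5.6° for a 90° excursion), so its
onsets trail the ramp start by up to ~0.15 s; the pipeline therefore uses
it for coarse event discovery and direction labelling (sign of the mean
angle in the 0.5 s after the transition) and refines every onset with the
chord method on a ±2 s window.

Non-steering pseudo-events are centers placed every 1 s inside maximal
binarized-zero runs such that the ±2 s epoch plus a guard stays inside
the run. The pipeline default guard of 1.7 s keeps these epochs clear of
the 1.5 s pre-onset desynchronization lead-in of the following trial.

## Epoching and cleaning

Epochs are half-open windows [t_min, t_max) so sample counts are exact
(`[-2.5, 2.5)` at 500 Hz → 2500 samples). Line noise at the first five
harmonics of 50 Hz is removed by sliding-window (1 s) regression on
sine/cosine pairs at the exact harmonic frequencies with a continuous
global phase — a spectrum-estimation approach that, unlike notch filters,
leaves broadband EMG power untouched (< 1 dB change ≥ 5 Hz away);
harmonics at or above Nyquist are dropped with a warning. EEG epochs are
common-average referenced. Artifact screening is fully automatic: per
trial and channel, the linear-trend slope and log band powers
(delta…gamma) are converted to robust z-scores (per-channel medians, one
median/MAD scale pooled over trials and channels — per-channel MADs from
a few dozen trials are too variable to keep the z tails honest) and a
trial is dropped when any channel exceeds z = 5 on either feature.

## ICA and scalp-map clustering

Epoched EEG is decomposed with FastICA (negentropy contrast) on the
concatenated trials; determinism comes from a fixed seed, ordering by
explained sensor variance, and a sign convention (largest-|weight|
element of each scalp map positive) that also makes squared-Euclidean
clustering immune to polarity flips. Components pass a three-criterion
brain-likeness screen, all thresholds configurable: (a) a spatially
smooth, near-unimodal map (neighbor-average correlation ≥ 0.6; at most
two positive-side local maxima above half the peak — the shallow
opposite-sign rim that common-average referencing adds around a focal map
is not counted as a mode); (b) a 1/f-like activation spectrum (log–log
PSD slope ≤ −0.5 with 7–14 Hz excluded from the fit so a mu/alpha peak is
allowed); (c) activation kurtosis ≤ 30.

Scalp maps are clustered across subjects by K-means under
d(x, c) = (x − c)(x − c)′, restarted from k-means++ seeds on a
canonically ordered copy of the data (input-order invariance), with empty
clusters re-seeded from the farthest point. The number of clusters is
chosen by a bootstrap stability index: pairs of 80% subsamples are
clustered independently and scored by the Pearson correlation of their
co-assignment matrices on the shared items; k* is the largest candidate
whose mean index exceeds 0.85, falling back to the argmax. The pipeline
caps candidate k so clusters keep at least three members on average —
subsampled co-assignment is not a meaningful stability measure for
near-singleton clusters.

## Time–frequency decomposition

ERSP uses complex Morlet wavelets (Gaussian envelope,
σ_t = n_cycles/(2πf), support ±4σ, amplitude-normalized so a unit
sinusoid reads unit power — any per-frequency scale cancels in the
baseline). Grids: EEG 2–40 Hz in 38 linear steps with 3–12 cycles; EMG
2–200 Hz in 198 linear steps with 3–60 cycles; the cycle ramp is linear
in frequency index. Output columns are spaced 10 ms — the only hop for
which a 0.5 s window is exactly 50 columns and a 3 s window exactly 300.
Edge-contaminated samples (within half a wavelet of an epoch edge) are
flagged per frequency.

Baseline normalization is single-trial and divisive: each trial's power
is divided by its own mean over the baseline window. For the
trial-averaged ERSP the normalized power is averaged **before** the
single dB conversion; taking the log per trial first would bias every
cell by E[log X] − log E[X] (≈ −2.5 dB for near-exponential power), so a
stationary process would not read 0 dB. Per-trial dB panels (needed for
the trial-by-trial coupling) convert each trial individually, as
single-trial dB requires. Onset-locked panels use a [−2, 2] s baseline;
cue-locked data would use [−0.5, −0.1] s.

## Coupling by 2-D cross-correlation

The EEG template ("mask") is the subject- and condition-specific dB ERSP
over the mu/beta band and the pre-movement window: frequency bins from
the bin nearest 8 Hz to the bin nearest 20 Hz inclusive (13 rows on the
EEG grid) by [−1.5, −1) s (50 columns). The EMG target is the
single-trial dB panel over [−1, 2) s (198 × 300). `xcorr2` is the
unnormalized full 2-D cross-correlation
out[i, j] = Σ mask[u, v] · panel[u+i−(M−1), v+j−(N−1)] (210 × 349 for the
preset shapes; integer inputs are summed exactly); the first 12 rows,
where the mask overhangs below the panel's frequency axis, are discarded
(198 × 349). A globally normalized variant (both inputs demeaned, output
divided by the product of their Frobenius norms) sits behind a flag, but
the published pairing is deliberately unnormalized. Per-trial matrices are
averaged within subject; because the operation is linear in the panel
this is computed as one cross-correlation of the trial-mean panel.
Masks pair with EMG panels of the same steering condition.

Two null ensembles probe specificity, each over seeded iterations with
per-iteration sub-streams: a **half-split** of non-steering trials (only
the first half of a random split is used, itself divided into
pseudo-left/right sets) and a **label shuffle** of the steering trials.
Note the ensembles are exchangeable marginally, not conditionally: with
distinct left/right masks an ensemble centers on
xcorr(mask_L − mask_R, all-trial mean panel), not on zero.

## Statistics

Condition contrasts are element-wise dependent-sample t-maps across
subjects. Multiple comparisons are controlled by sign-flip permutation
with a weighted cluster mass statistic: clusters are 4-connected regions
of |t| above the two-sided t-quantile at cluster_alpha = 0.05, scored by
Σ(|t| − t_thresh)^θ with θ = 1 by default (θ exposed; it weights height
against extent), and observed masses are referred to the permutation
distribution of the maximum mass with the (1 + count)/(1 + n_perm)
convention. An exhaustive mode enumerates all 2^n sign patterns (the
identity pattern then replaces the +1 correction). The identity flip must
count against itself: the vectorized null path accumulates ~1e−7 relative
error on near-degenerate t cells, so masses are compared with a 1e−6
relative tolerance — far below the O(1) mass changes a genuinely
different sign pattern causes. Family-wise error is calibrated (within
the binomial band around α = 0.05 over 200 null repetitions in the test
suite). Scalar coupling statistics are converted against a null ensemble
as Z = (obs − mean)/sd with normal-tail p-values, two-sided by default.
`earliness` is the difference between the earliest significant time
columns of two significance masks; cross-correlation columns map to time
as the panel time of the mask origin (column lag × 10 ms from the panel
start).

## Synthetic sessions

The generator emulates the statistical structure the analysis assumes,
with every effect parameterized and a ground-truth table per trial:

- **Wheel**: signed truncated-logistic excursions, defaults rise 0.5 s,
  plateau 1.2 s, return 0.5 s, peak 90°, additive 0.5° Gaussian sensor
  noise. The published task reports no amplitude or speed distributions,
  so these are one-time "quiet pace" choices, exposed in `SessionSpec`,
  not claims about the study. Ground-truth onset is the ramp support
  start; the ramp crosses 2° about 31 ms later.
- **EMG** (4 channels): baseline 20–200 Hz band-limited unit-variance
  noise; the deltoid contralateral to the steering direction carries a
  sustained smooth-gated burst from onset − 0.2 s lasting 1.5 s, scaled
  so the burst-window RMS exceeds baseline by `emg_snr` (default 12 dB);
  the ipsilateral deltoid is mildly suppressed (×0.7); forearm channels
  carry no direction effect.
- **EEG** (default 32 channels on an idealized sunflower layout):
  a fixed forward mixture of a mu source (left centro-parietal Gaussian
  topography) and an occipital distractor, plus per-channel 1/f noise at
  `eeg_snr` (default 10 dB) below the source RMS. Both rhythms are
  stochastic narrowband (10 ± 1 Hz) oscillations with independent
  log-normal waxing/waning envelopes — deterministic same-frequency
  sinusoids would be mutually correlated and rotation-degenerate, which
  no ICA can resolve; bursty narrowband rhythms are both realistic and
  separable. The mu envelope additionally drops by `erd_depth` (default
  0.5) from onset − 1.5 s to onset + 1 s on left-steering trials only.
- **Sessions** concatenate trials with 8–10 s quiet gaps (the invariant
  is ≥ 3 s; the larger default leaves room for non-steering epochs that
  clear the ERD lead-in) into continuous records, all randomness drawn
  from one seeded generator with deterministic per-trial sub-streams;
  identical specs give byte-identical sessions. Causal filter warm-ups
  are generated and discarded.

What the generator does **not** emulate: volume conduction beyond smooth
Gaussian topographies, muscle crosstalk, eye/cardiac artifacts, bad
channels, fatigue or learning dynamics, and any coupling between the EEG
phase and the EMG waveform — the EEG–EMG relation in synthetic data is
purely the co-occurrence of ERD and burst around the same onsets.
Passing tests therefore demonstrate that the pipeline recovers planted
effect structure through the full analysis chain at realistic SNR, not
that real recordings would behave this way.

## Problem sizes and defaults

The recovery suite runs a cohort of 8 synthetic subjects at the published
per-subject trial count (44 left + 44 right), with exhaustive sign-flip
enumeration (2⁸ patterns, so every corrected p is exact and
deterministic, floor 2/256 ≈ 0.008), 100 null iterations and 40
non-steering trials per subject — a cohort size chosen so the whole suite
stays desk-scale while permutation across subjects has real resolution
below α. The library defaults follow the published analysis (1000
permutations, 300 null iterations, α = 0.05).

## Known limitations

- The chord-distance onset assumes one dominant excursion per trial
  window; genuinely multi-phasic steering is discarded as ambiguous
  rather than segmented.
- Brain-component screening is a heuristic stand-in for dipole-fit-based
  selection; its thresholds are tuned to the synthetic topographies and
  will need adjustment for real montages.
- The EDF writer targets the plain 16-bit EDF profile (one-second
  records, per-channel physical scaling); EDF+ annotations are not
  written.
- `earliness` compares first-significant columns only; it does not model
  the mask-width convolution spread, which is part of why the coupling
  statistic leads the EMG-only one.
- With statistically identical synthetic subjects, cluster tests on
  pseudo-conditions (half-split / shuffle) can flag a method-inherent
  constant — single-trial dB panels of stationary signal average the
  mean-log/log-mean gap (≈ −2.5 dB), and the left/right mask sums differ
  systematically because the desynchronization precedes only left
  steering — as a "significant" consistent offset. Real cohorts bury this
  term under inter-subject variability; the synthetic cohort does not,
  so the pseudo-condition cluster check is expected to flag it. The Z
  statistic of the observed coupling against the null ensembles is the
  robust specificity measure here.
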