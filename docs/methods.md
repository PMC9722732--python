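# Methods

This note documents the models, estimators and conventions implemented in
`cmcdetect`, the parameters that matter, and what the synthetic validation
does and does not establish.

## Study design being modeled

One recording run is a block design of 8-s task trials and 4-s rest trials
(defaults: 20 + 20), separated by a 3-s inter-trial interval. A task trial
opens with a 4-s preparatory period; at the go cue the participant performs
or attempts finger extension (target muscle: extensor digitorum, ED) or
grasping (flexor digitorum superficialis, FD) and holds the contraction at
about 15% of the muscle's maximum voluntary contraction (MVC) until the
trial ends. Trial ordering is pseudo-random with two constraints: never more
than two consecutive trials of the same condition, and a run never opens
with two rest trials. EEG is sampled at 1 kHz (extended 10-20 montage; a
28-channel sensorimotor subset FC5…P6 is analyzed), bipolar surface EMG at
2 kHz from 16 upper-limb/shoulder muscles.

## Synthetic session generator

The generator (`cmcdetect.synth`) is the test bed for the whole pipeline; it
plants a known coupling and known onsets so that every downstream estimate
has a ground truth.

**EMG model.** Each muscle idles as unit-RMS band-limited (30–450 Hz) white
noise scaled to 2% MVC. In a task trial the target muscle's envelope ramps
(50-ms raised cosine) to `activation_level`·MVC at the true onset
t₀ = cue + 4 s + jitter (jitter ~ N(0, 50 ms), truncated at ±3 SD). The
coupling enters *multiplicatively* on the envelope:

    emg(t) = carrier(t) · env(t) · (1 + m·g(t)·sin(2π f₀ t + φ_trial)),

with modulation depth m (`coupling_strength`, default 0.5), coupling
frequency f₀ (default 20 Hz) and a gate g(t) rising at t₀. Rectification
demodulates the envelope modulation into the band where coherence is
measured; additive narrowband components on the raw EMG would instead be
destroyed by rectification. The ramp is raised-cosine because an
instantaneous step would inject a broadband transient that confounds
onset-latency validation.

**EEG model.** Each channel carries independent 1/f-amplitude noise (SD
8 µV) + white noise (SD 3 µV) + a 50 Hz line sinusoid (2 µV, random phase).
The designated coupled channel additionally receives α·g(t)·sin(2π f₀ t +
φ_trial) — the same sinusoid, same per-trial random phase — post-onset only,
with α = 10^(snr/20)·σ_background (`eeg_snr_db`, default −6 dB). The
per-trial phase makes across-trial coherence reflect within-trial phase
locking rather than a global phase. No volume conduction or forward
modeling is attempted.

Defaults were chosen once for testability: they produce a clearly separable
but not degenerate feature space (single-window coherence ≈ 0.6–0.9 at f₀
post-onset against a ≈ 0.14 bias floor). All generator randomness flows from
one seed through named substreams, so identical configurations are
bit-identical.

**What the generator does not emulate.** Volume-conducted EEG topographies
(channels are independent), non-stationary background rhythms, movement
artifacts and electrode drift, EMG cross-talk between muscles, inter-trial
variability of coupling strength, or the weaker and more variable coupling
of stroke patients. Passing tests therefore establish the *correctness of
the algorithms and the recoverability of planted structure*, not clinical
performance on real recordings.

**Trial sequencer.** Orderings are sampled uniformly over all sequences
satisfying both run constraints, by stepwise label choice weighted by the
(memoized) count of valid completions. Infeasible counts (e.g. 5 task / 1
rest — brute-force enumeration finds no valid arrangement) raise an explicit
error. Feasibility is equivalent to n_task ≤ 2(n_rest+1) and
n_rest ≤ 2·n_task + 1 (the asymmetry comes from the forbidden double-rest
opening).

**Artifact injection.** For screening tests, a configurable fraction of
trials receives 200 µV 10-Hz EEG bursts (chosen to survive the 3–60 Hz
band-pass and trip the 100 µV rule) on one or two channels, or EMG
corruption (×10 bursts or flatlines), with a truth list of corrupted
(trial, channel) pairs.

## Preprocessing

Filters are Butterworth (4th order band-pass/high-pass, 8th order
anti-alias low-pass at 400 Hz, 2nd-order IIR notch with Q = 30), all applied
forward–backward: zero-phase filtering is essential because group delay
would bias every onset-latency measurement. The nominal EMG "3–500 Hz
band-pass" cannot have its upper edge realized after decimation to 1 kHz
(500 Hz is the output Nyquist); the anti-alias low-pass takes the role of
the upper edge. Epochs are cut at the cue sample, half-open
[cue, cue + duration), 0-based indices, time 0 = cue onset — this
convention holds throughout the package.

**EEG screening.** A channel is artifactual in a trial if any sample exceeds
100 µV in magnitude (evaluated on the 28-channel analysis subset — channels
outside it play no role downstream). Two or more artifactual channels reject
the trial; exactly one is repaired by spherical-spline interpolation
(Perrin-style scalp splines, stiffness m = 4, 50 Legendre terms, 1e-5
regularization, electrode positions from the standard 10-20 montage).

**EMG screening.** The reference criterion compares per-trial EMG
characteristics to the condition median. The characteristic vector here is
{RMS, excess kurtosis, 95% spectral edge frequency, zero-crossing rate};
a trial is flagged when any component deviates from the per-condition median
by more than k = 4.5 scaled MADs (MAD × 1.4826). The vector is a documented,
configurable stand-in — the criterion's source does not pin down the feature
set. Flagged trials are auto-rejected in batch mode or returned as a review
list, replacing interactive visual confirmation. Fewer than three kept
trials per condition skips the screen (median unstable) with a warning.

**Compliance.** The target-muscle envelope threshold is median + 5·MAD of
the pooled kept rest-trial envelopes. A rest trial exceeding it continuously
for ≥ 500 ms is rejected (movement during rest); a task trial never
exceeding it during the movement period [4 s, end) is rejected (instruction
missed).

## EMG onset

Envelope: 30–300 Hz band-pass → Teager–Kaiser energy operator
ψ[n] = x[n]² − x[n−1]x[n+1] (endpoints copy neighbors) → rectify → 50 Hz
low-pass → clip at 0. Hodges–Bui parameters (none are fixed by convention):
baseline [0.5, 3.5] s post-cue (inside the preparatory period), test window
50 ms, h = 3 SD, search restricted to ≥ 3.5 s (0.5 s before the go cue) to
avoid cue-transient false alarms. A numerically flat baseline falls back to
σ = 1e-6·μ with a warning. On 100 default synthetic trials the detector
recovers planted onsets with ≈ 25 ms median absolute error and fires on 0/50
rest-like segments; raising h can only delay the detected onset (monotone by
construction).

## Coherence estimation

Magnitude-squared coherence over mean-detrended, Hann-tapered (periodic
window) segments; no small-sample bias correction. For L independent
segments E[C] ≈ 1/L — this bias floor (1/160 across-trial, 1/7
single-window) is the reference level for "no coupling" in tests, not zero.

* Across-trial: eight non-overlapping 1-s segments per 8-s task epoch,
  pooled over trials → 1 Hz resolution over 0–60 Hz. The characteristic
  frequency f₀ is the argmax over 13–30 Hz, ties broken to the lowest
  frequency.
* Single-window: seven 250-ms segments with 50% overlap inside each 1-s
  window → 4 Hz resolution. f₀ estimated on the 1 Hz grid generally falls
  between 4 Hz bins; the value is taken at the nearest bin and both
  frequencies are recorded. (At the default 20 Hz the grids coincide.)
* Rectification is |·| of the band-passed EMG; no demodulation variant.

One estimator property worth knowing: a strong *deterministic* narrowband
EEG component (the planted cortical sinusoid, or a real sustained rhythm) is
phase-coherent across the segments of a trial whenever the frequency has an
integer number of cycles per segment. At that bin the effective number of
independent averages is the number of *trials*, not segments, so the
zero-coupling floor rises from 1/160 to ≈ 1/20. Ablation confirms this:
removing the EEG sinusoid restores the 1/160 floor. Interpretation of small
coherence values near a strong cortical peak should use the trial-count
floor.

## Feature selection and offline evaluation

Candidate pairs = target muscle × sensorimotor channels of the hemisphere
contralateral to the moving hand (odd 10-20 indices for right-hand
movements, even for left; midline excluded) — 12 candidates. Fisher score
J = (μ_task − μ_rest)²/(s²_task + s²_rest) with n−1 variances; descending
rank, deterministic tie-break by candidate order, top two selected. J is
invariant under common affine transforms of both classes; zero variance with
distinct means scores +inf (perfect separation), with equal means 0.
Whole-interval features use the [5, 6] s window of task trials (holding
phase) and [2, 3] s of rest trials; selection is per movement × side with no
cross-session pooling.

Offline classification: linear-kernel SVM with C = 1 (no tuning), features
standardized by training-split mean/SD (coherence lives in [0, 1]; without
standardization the margin scale is arbitrary). "Ten-iteration
cross-validation" is implemented as ten random stratified 80/20 resamples
(Monte-Carlo CV) — the 80/20 description with half-task/half-rest training
splits matches resampling, not 10-fold partitioning. Class balancing
(subsample the majority class when |n_task − n_rest| ≥ 3) happens once,
before CV.

## Pseudo-online evaluation

Windows are 1 s long, advanced by shift ∈ {125, 250, 500} ms, and
timestamped by their END time — the moment the data would be available
online; all delays are measured against end times, which makes TP delays
nonnegative by construction. Window counts follow
floor((T − 1)/shift) + 1: 57 per 8-s trial at 125 ms.

**Detection (double threshold).** Threshold = 95th percentile
(linear-interpolation definition) of all rest-trial window CMC values of the
rank-1 pair, at the same shift as the task analysis. A CMC onset is the end
time of the first window of the earliest run of consecutive supra-threshold
windows spanning ≥ 500 ms. Each window contributes `shift` of new data, so
the run length required is k = ceil(500/shift) = 4, 2, 1 windows — one
self-consistent rule across shifts (the plausible alternative, counting only
(k−1)·shift of span, would demand 5/3/2 windows and makes a single 500-ms
step non-qualifying at the coarsest shift). Per task trial: TD if the CMC
onset is at or after the EMG onset, FD if before, ND if absent; rates are
normalized by task-trial count and the mean delay (MD) averages
CMC − EMG onset over TD trials only.

The detector has an intrinsic false-alarm floor: 7-segment coherence
estimates have heavy upper tails, heavily overlapping windows are
correlated, and an 8-s task trial exposes 2–4× more windows than the 4-s
rest trials from which the threshold is pooled. With zero coupling, 40–75%
of task trials (rising with shift) still produce a qualifying run. With the
default coupling the observed FD rates (≈ 13% at 125 ms, rising with shift)
sit exactly in this regime; FD is a property of the double-threshold rule,
not of the coupling.

**Classification (leave-one-out).** For each task trial, a linear SVM is
trained on the whole-interval features of all *other* kept trials — rest
trials included, since a binary margin cannot be fit on one class; the
held-out trial is predicted window by window. With accumulation factor M: a
window is post-onset when its end time exceeds the EMG onset, runs
straddling the onset are split at that boundary; the trial is FP if M
consecutive task predictions fall entirely pre-onset (pre-onset runs take
precedence — the online detector would already have fired), else TP at the
first post-onset M-run with T_M = the M-th window's end time, else FN. The
precedence rule makes TP/FP/FN exclusive, so hit + FPR + FNR = 1 per
condition. Both the onset scanner and this scoring are verified against
exhaustive brute-force enumeration of all binary prediction strings up to
length 12 for all shifts and M ∈ {1, 2, 3}.

## Problem sizes and determinism

The validation cohort is ten sessions of 20 + 20 trials (the nominal run
length), analyzed at all three shifts and M ∈ {1, 2, 3}; the onset-recovery
study uses 100 independent task trials. On these sizes the qualitative
optimization structure is reproduced: FPR non-increasing and delay
increasing in M, detection delay increasing in shift, f₀ recovered at the
planted 20 Hz, the planted pair Fisher-ranked first, and hit rate ≥ 0.9 at
shift 125 ms with M = 2. Every pipeline run is bit-reproducible from its
configuration: one master seed feeds named substreams (sequencer, EEG/EMG
noise, trial parameters, balancing, CV splits).

## Known limitations

* The synthetic EEG has no spatial structure, so spherical-spline repair is
  validated on smooth synthetic scalp fields rather than realistic
  topographies, and the anatomical pair restriction is exercised on labels,
  not physiology.
* The EMG statistical-screening feature set is a documented stand-in for an
  underspecified criterion.
* Coherence magnitudes, hit rates and delays on synthetic data characterize
  the algorithms under the generator's assumptions; they are qualitative
  analogues of, not predictions for, patient data.
* Real-data ingestion covers the HDF5 session container and BrainVision
  EEG reading; EDF and BrainVision export are not implemented.
* Inferential statistics on the metric tables (repeated-measures ANOVA,
  post-hoc tests) are left to standard statistics packages; the pipeline
  produces the per-session metric tables those tests consume.
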