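# Methods

## Problem and data model

Intraoperative cortico-cortical evoked potentials (CCEPs) probe effective
connectivity between cortical speech areas: a single electrical pulse is
delivered near Broca's area and the averaged response is recorded over the
posterior temporal cortex. The clinical question this package addresses is
whether the pre-resection CCEP waveform predicts deterioration of speech
function after tumour surgery.

One *test* is one averaged post-stimulus epoch: 8 or 16 ECoG channels,
300 ms at 25 kHz (7500 samples per channel, microvolts), stored as one EDF
file. A patient contributes 2–16 tests; a cohort manifest (CSV) carries
the patient identity, surgical phase (pre/post resection), a recording
quality flag set by expert review, and the pre/post speech-dysfunction
scores on a 0–45 clinical scale (0 = normal). The binary outcome is 1 iff
the post-surgery score exceeds the pre-surgery score; it is a property of
the patient, so every test of a patient shares the label. The analyzed
cohort is restricted to quality-passing, pre-resection tests; both filters
are configurable.

Because the original recordings are not public, all empirical results in
this repository are computed on synthetic cohorts (below) with known
generating parameters.

## Waveform reduction

Per channel: (1) **bin averaging** — the 7500-sample trace is reduced to
300 one-millisecond bin means (25 samples per bin); (2) **trailing moving
average** with a 20 ms window — the first 20 bins produce the smoothed
value at index 20, so smoothed indices run 20…300 ms and every latency
inherits a systematic lag of about half the window (≈10 ms; the
latency-recovery study below measures 10.0 ms). Latencies are reported
*uncorrected*, as read off the smoothed trace; (3) **artifact trim** — the
start index always advances 1 ms (discarding the first millisecond), then
up to 10 more times while the candidate start value deviates from the mean
of the remaining signal by more than 1.25 × half the remaining signal's
peak-to-peak range. The total shift is therefore 1–11 ms. The stated
comparison ("amplitude of the rest of the signal multiplied by 1.25")
admits several readings; this half-peak-to-peak deviation rule is locked
by unit tests against a step-through reference; (4) **channel selection**
— the channel with the largest post-trim oscillation amplitude
(max − min over the valid range) is kept; ties break to the lowest channel
index. 8-channel tests are padded to the canonical 16 channels with
*absent* markers that every channel-wise statistic skips — zero-filling
would bias the channel-amplitude minimum and mean. Trimming runs per
channel before selection.

## Features

Per test: the maximum / mean / minimum of per-channel amplitudes over
present channels; the mean of the selected trace (signed); up to two local
maxima and two local minima with latencies, subject to a 20 ms minimum
peak separation and a 5 μV minimum height measured from the valid-range
mean (the reference level for the height threshold is our choice; higher
peaks win distance conflicts, and survivors are reported in latency
order); and optionally the augmented Dickey–Fuller p-value of the trace
(computed via statsmodels, excluded from model inputs by default — CCEP
traces are non-stationary over 300 ms, so the feature carries little
signal).

Missing extrema are restituted two ways. **zeros**: values and latencies
become 0. **ratio_mean**: the first peak is restituted as
mean_train(peak1/amplitude) × the row's amplitude, the second as
mean_train(peak2/peak1) × the row's (possibly restituted) first peak;
troughs follow the same recursion on magnitudes with the sign of the
training-mean trough; latencies take the training-mean latency. The
ratio-mean recursion is this package's definition (the formula it derives
from is ambiguous in its source); an extremum never observed in training
falls back to zeros with a warning.

All model inputs are min–max scaled to [0, 1]. Restitution ratios and
scaling bounds are fit on the **training rows of each resampling
repetition** — fitting them before the split leaks test-set range
information; a `fit_on_all` flag reproduces the leakier ordering for
comparison. A constant training feature maps to 0 everywhere; held-out
values may fall outside [0, 1].

## Benchmark design

The grid crosses split scheme {by_test, by_patient} × restitution
{zeros, ratio_mean} × classifier {random forest, logistic regression, SVM
linear / RBF / polynomial} — 20 cells — each repeated 300 times
(6000 runs) on fresh stratified 80/20 resamples. Per repetition: split →
train-side restitution and scaling → 5-fold CV accuracy on the training
side → fit on the full training side → specificity, sensitivity,
precision, recall, accuracy, F1 and AUC on the held-out side. Cell values
are means over repetitions (standard deviations are kept alongside).

Design choices the underlying procedure leaves open:

* **Hyperparameters** are scikit-learn's documented defaults (logistic
  regression gets `max_iter=1000` for convergence at these sizes),
  recorded per run in the JSON-lines log.
* **AUC** uses continuous scores — class-1 probability where available,
  otherwise the decision margin (SVMs) — with the usual rank statistic
  (ties count half). Runs whose held-out truth is single-class have no
  AUC and are excluded from that average only. Precision and F1 are 0
  when nothing is predicted positive.
* **by_patient splitting** assigns whole patients greedily: one patient
  per class is forced into the test side whenever the class has two or
  more patients, then random patients join while that moves the test row
  count toward the 20% target. Exact row stratification is impossible
  under whole-patient assignment; this approximation keeps both classes
  on both sides whenever feasible.
* **CV folds inherit the grouping**: under by_patient the inner folds are
  patient-grouped (StratifiedGroupKFold) so the fold structure matches
  the outer split. `cv_folds = n_train` degrades to leave-one-out. A fold
  arrangement with a single-class training side is re-drawn (up to 100
  seeds) before erroring.
* **Seeding**: repetition *r* uses `base_seed + r` for the split and
  `base_seed + 10^6 + r` for model initialization. Parallelism is over
  grid cells with this per-repetition seeding, so results are identical
  at any `--jobs` setting.

## Synthetic cohorts

The generator emulates the structure the pipeline consumes, not cortical
biophysics. Patient-level morphology: a dominant positive wave of
30 ± 10 μV at 80 ± 15 ms, an early negative deflection (probability 0.8)
of 18 ± 6 μV near 35 ms, optional later positive (0.6) and negative (0.4)
waves — all Gaussian bumps of ≈9 ms width, since the pipeline consumes
only amplitudes and latencies. Per test, amplitudes and latencies are
jittered by `within_patient_sd` (default 0.3) × the between-patient sd,
giving the strong within-patient similarity that motivates grouped
splitting. Every channel carries 2 μV white noise and a 60 μV stimulus
artifact decaying with a 3 ms constant; one channel per patient adds the
evoked response. Cohort structure mirrors the study: 26 patients, 2–16
tests each, 8 or 16 channels per patient, and a quality flag passing ≈50%
of tests (the study kept 105 of 216 pre-resection tests after expert
screening). Post-resection files can be generated but are off by default
— they were never analyzed. EDF export uses a ±1000 μV physical range at
16 bits (≈0.03 μV quantization), typical of ECoG exports.

Outcomes are drawn per patient from a logistic model on the standardized
patient-level peak amplitude and latency; the intercept is solved
(Brent's method) so the expected prevalence of deterioration equals the
target (default 0.6, reflecting the deterioration-heavy imbalance the
binary regrouping was designed to reduce). Default effect: +2.0 on the
standardized amplitude, 0 on latency; the large-sample ceiling for that
effect (AUC of the true latent amplitude) is ≈0.86.

What the generator does **not** emulate: real N1/N2 waveshape detail,
correlated or non-stationary noise, channel cross-talk, electrode-contact
variation, and any post-resection signal change. Passing tests therefore
demonstrate that the pipeline recovers what it is designed to measure
under its own assumptions, not clinical performance.

## Validation studies and problem sizes

* **Latency recovery** — 200 single-peak epochs (40 μV, 2 μV noise, no
  artifact, no jitter), detected first-maximum latency within
  half-window + 1 = 11 ms of truth. Measured mean lag ≈ +10.0 ms, the
  trailing-window lag; recovery rate 100%.
* **Leakage demonstration** — one 26-patient cohort with near-identical
  repeats (`within_patient_sd` 0.1) and a weak effect (0.5); 100
  resamples per split mode with an RBF SVM; one-sided Welch test on F1.
  Record-level splitting inflates F1 by ≈0.3 — the qualitative
  by-test vs by-patient gap the grouped design exists to expose.
* **Null calibration** — labels drawn once per cohort make a single
  cohort carry an accidental patient-level label–feature correlation that
  resampling cannot average away (at 26 patients the per-cohort mean AUC
  ranges roughly 0.2–0.7, and small-sample grouped evaluation also shows
  a mild downward "anti-learning" tendency). The study therefore averages
  30 independent zero-effect cohorts × 10 grouped resamples (300 runs
  total) of 150 patients × 2–4 tests — the accident lives at patient
  level, so many patients and few repeats is the efficient shape. Mean
  AUC ≈ 0.51, within [0.45, 0.55].
* **Effect recovery** — same shape at effect 2.0 over 10 cohorts: mean
  grouped AUC ≈ 0.81–0.82 against the 0.86 ceiling; AUC increases
  monotonically over effects {0, 1, 2} (≈0.51 / 0.70 / 0.81).
* **Benchmark grid** — the full 20-cell grid on a default 26-patient
  cohort runs at 30 repetitions per cell in the test and acceptance
  scripts (600 runs, ≈2 minutes); the 300-repetition default is the
  production setting.

## Known limitations

Latencies are uncorrected for the ≈10 ms trailing-average lag (matching
the upstream convention); comparisons across window sizes must account
for it. The ratio-mean restitution can propagate a restituted first peak
into the second peak's restitution. By-patient splits only approximate
both the 20% row fraction and class stratification. At 26 patients,
single-cohort results carry substantial label-draw noise — the
multi-cohort studies above are the calibrated way to assess the pipeline,
and nothing here speaks to performance on real clinical recordings.
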