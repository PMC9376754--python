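# ccepml

Predicting postoperative speech deterioration from intraoperative
cortico-cortical evoked potentials (CCEPs), for clinical-neurophysiology
and biosignal-ML researchers.

During awake surgery near the speech cortex, a single electrical pulse at
Broca's area evokes a response over the posterior temporal cortex; the
averaged 300 ms ECoG epoch (8/16 channels, 25 kHz) is one *test*, stored
as one EDF file, with 2–16 tests per patient. The question: do features
of the pre-resection waveform predict whether the patient's speech score
(0–45 clinical scale) worsens after surgery (binary outcome
y = 1{post > pre}, shared by all tests of a patient)?

The package implements the full analysis chain:

1. **Ingest** — EDF epochs + a cohort manifest (identity, phase, quality
   flag, scores); restriction to screened pre-resection tests.
2. **Reduction** — per channel, 7500 samples → 300 one-ms bin means →
   trailing 20 ms moving average → artifact trim (start shifted 1 ms
   always, up to 10 ms more while the start value deviates from the rest
   by > 1.25 × the rest's half peak-to-peak range) → selection of the
   channel with the largest oscillation amplitude, A = max − min.
3. **Features** — max/mean/min of per-channel amplitudes, trace mean, up
   to 2 maxima and 2 minima (λᵢ, vᵢ) with ≥ 20 ms separation and ≥ 5 μV
   height; missing extrema restituted with zeros or training-mean ratios
   (e.g. v̂₂ = E_train[v₂/v₁]·v₁); min–max scaling fit on training rows.
4. **Benchmark** — {by-test, by-patient splits} × {zeros, ratio-mean} ×
   {RF, LR, SVM-linear/RBF/poly}, stratified 80/20 resampling, 5-fold CV
   on the training side, 300 repetitions per cell (20 cells, 6000 runs),
   reporting CV accuracy, specificity, sensitivity, precision, recall,
   accuracy, F1 and AUC averaged per cell. By-patient (grouped) splitting
   keeps every patient on one side — the comparison with record-level
   splitting quantifies identity-leakage inflation.
5. **Synthetic cohorts** — since the clinical recordings are unreleased,
   a generator produces EDF cohorts with known ground truth (evoked
   Gaussian deflections, stimulus artifact, noise, within-patient repeat
   similarity, logistic patient-level outcome model) for calibration and
   power studies. See `docs/methods.md`.

## Worked example

```python
from ccepml import CcepSpeechExperiment, ExperimentConfig, SyntheticCohortSpec
from ccepml.synthetic import generate_cohort

spec = SyntheticCohortSpec(seed=42)          # 26 patients, 2-16 tests each
manifest, truth = generate_cohort(spec, "demo_cohort")

config = ExperimentConfig(n_repetitions=30, base_seed=42)
experiment = CcepSpeechExperiment.from_cohort("demo_cohort/manifest.csv",
                                              config=config)
results = experiment.fit()
print(results.summary())
```

prints (abridged to two of the four input variants):

```
CCEP speech-outcome resampling benchmark
  tests: 138   patients: 26   repetitions/cell: 30   runs: 600

split: by_test   missing-value scheme: zeros
                       CV  Spec  Sens  Prec   Rec   Acc  F1-score   AUC
model
random_forest       0.924 0.879 0.922 0.953 0.922 0.910     0.935 0.956
logistic_regression 0.822 0.500 0.923 0.825 0.923 0.802     0.869 0.905
svm_linear          0.883 0.817 0.883 0.927 0.883 0.864     0.901 0.905
svm_rbf             0.906 0.854 0.913 0.943 0.913 0.896     0.926 0.953
svm_poly            0.913 0.950 0.900 0.980 0.900 0.914     0.937 0.964

split: by_patient   missing-value scheme: zeros
                       CV  Spec  Sens  Prec   Rec   Acc  F1-score   AUC
model
random_forest       0.765 0.289 0.902 0.745 0.902 0.714     0.804 0.715
logistic_regression 0.759 0.321 0.821 0.731 0.821 0.653     0.754 0.702
svm_linear          0.765 0.558 0.773 0.791 0.773 0.696     0.760 0.721
svm_rbf             0.759 0.255 0.876 0.733 0.876 0.678     0.780 0.695
svm_poly            0.748 0.320 0.875 0.753 0.875 0.705     0.796 0.734
```

Reading the numbers: the same classifiers score far higher under
record-level (`by_test`) splitting than under grouped (`by_patient`)
splitting — the by-test figures are inflated by patient-identity leakage
(repeat tests of one patient are nearly identical and share a label), so
only the by-patient block estimates generalization to new patients. The
grouped results show the characteristic high-sensitivity /
low-specificity profile: deteriorating patients are caught at the cost of
false alarms among stable ones. The simulated effect here links outcome
to evoked-peak amplitude; every number is on a synthetic cohort.

The same pipeline runs from the shell:

```bash
ccepml init --out cfg.yaml
ccepml synth    --config cfg.yaml --seed 42 --out cohort/
ccepml features --manifest cohort/manifest.csv --config cfg.yaml --out features.csv
ccepml evaluate --features features.csv --config cfg.yaml --out results/ --jobs 2
ccepml report   --results results/
```

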