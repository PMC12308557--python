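# preshock

Pre-shock ECG analysis for predicting defibrillation success in
out-of-hospital cardiac arrest (OHCA).

When a patient in ventricular fibrillation (VF) is about to receive a
defibrillation shock, the 9 seconds of ECG recorded just before the shock
carry information about whether the shock will restore organized
electrical activity (ROEA) or not (NoROEA). `preshock` implements the
full analysis chain for this prediction task, for researchers in
biomedical signal processing and resuscitation science:

1. **Preprocessing** — uniform resampling to 250 Hz and a zero-phase
   4th-order Butterworth bandpass (0.5–48 Hz) that removes baseline
   drift, mains interference and muscle artifact.
2. **Feature extraction** — R-peak detection (centered energy-envelope
   detector with an adaptive threshold) and six features per record:

   | feature | definition | units |
   |---|---|---|
   | heart rate | HR = 60 / mean(RR) | bpm |
   | QRS amplitude | mean per-beat max(QRS) − min(QRS) | mV |
   | QRS duration | mean per-beat \|t(max) − t(min)\| | ms |
   | total power | ∫ \|X(f)\|² df over the analysis band | mV² |
   | LF power | band power, low-frequency band | mV² |
   | HF power | band power, high-frequency band | mV² |

   Band powers integrate a Welch power spectral density normalized so the
   full-band integral equals the signal's mean square.
3. **Feature screening** — per-feature ROC-AUC (Mann–Whitney identity,
   ties counted half) and one-way ANOVA F; the top-k subset (default
   k = 3: QRS amplitude, total power, LF power in the clinical study
   design) feeds the classifier.
4. **Classification** — soft-margin SVM (RBF kernel), z-scored inputs,
   grid search over C ∈ {0.01…1000} and γ ∈ {0.01…100} with stratified
   inner cross-validation, and class-imbalance handling by
   inverse-frequency class weights and/or SMOTE (applied to training
   data only). Validation utilities: stratified 70/30 hold-out,
   leave-one-subject-out CV, ±10% hyperparameter sensitivity, feature
   ablation, and random-forest / logistic-regression baselines.

Because the clinical pre-shock dataset this design targets is not
publicly deposited, the package ships a first-class **synthetic
generator**: biphasic QRS-like templates (opposed Gaussian lobes) at
jittered RR intervals plus band-limited noise, with every injected
quantity returned as ground truth, and class-conditional Gaussian
feature summaries for cohort-level sampling. All validation is
parameter *recovery* against this ground truth.

## Worked example

```python
import preshock as ps

params = ps.WaveformParams(target_hr=110, qrs_amplitude=1.5,
                           qrs_extremum_gap=85.0, noise_power=0.001, seed=7)
record, truth = ps.synth_waveform(params)
clean = ps.preprocess(record)          # 250 Hz, 0.5-48 Hz zero-phase bandpass
fv = ps.extract_features(clean)
```

prints (see `examples/02_extract_features.py`):

```
detected 16 beats (injected 16)
      heart_rate =  110.783 bpm
   amplitude_qrs =    1.522 mV
    qrs_duration =   85.750 ms
    total_power2 =    0.077 mV^2
       lf_power2 =    0.031 mV^2
       hf_power2 =    0.044 mV^2
```

The detector found every injected beat, and the three injected
parameters — 110 bpm, 1.5 mV peak-to-trough, 85 ms extremum gap — are
recovered within one sample period and a few percent. The band powers
characterize the template train itself (they depend on rate and
morphology rather than on an injected target).

The other scripts in `examples/` walk through cohort synthesis, feature
screening, and the full training/validation battery. A thin CLI mirrors
the library (`preshock simulate | extract | select | train | loso |
ablate | compare | run-all`).

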