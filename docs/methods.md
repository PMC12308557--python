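# Methods

## Problem setting

A 9-second single-channel ECG (lead II convention) recorded immediately
before a defibrillation shock in out-of-hospital cardiac arrest is used
to predict the shock outcome: return of organized electrical activity
(ROEA, the "successful" class) versus no return (NoROEA). The clinical
development cohort this design is based on contained 251 usable records
(56 ROEA, 195 NoROEA; a further 9 of the original 260 were
indeterminable and excluded — the pipeline mirrors this by counting and
excluding records on which beat detection fails). That dataset is not
publicly deposited, so everything here is validated on synthetic
records with known ground truth; see "What the generator does and does
not emulate" below.

## Preprocessing

Records are polyphase-resampled to 250 Hz and filtered with a 4th-order
Butterworth bandpass, 0.5–48 Hz. "4th order" means the lowpass
prototype order of the bandpass design; the band edges are the −3 dB
points by construction, which the tests pin numerically. Filtering is
zero-phase (forward–backward, second-order sections) so that the times
of QRS extrema — inputs to the duration feature — are not shifted by
group delay; the effective magnitude response is the square of the
single-pass response. Edge transients are handled by ~1 s of reflective
padding, generous relative to the 0.5 Hz corner for a 9-s record. No
separate 50/60 Hz notch is used; mains frequencies lie above the 48 Hz
corner.

## R-peak detection

The literature on this prediction task computes RR- and QRS-derived
quantities without committing to a detector, so the package uses an
energy-envelope detector in the Pan–Tompkins tradition, simplified for
short bandpassed episodes: square the signal, smooth with a *centered*
150 ms moving average (no group delay), pick envelope peaks with a
200 ms refractory period. Thresholding is two-pass: a provisional pass
at 25% of the envelope maximum identifies candidate beats; the final
threshold is 40% of the *median* candidate height. The second pass is
what makes the detector robust on records whose template amplitude was
drawn small: isolated noise bumps sit far below the median beat height
even when they approach a fixed fraction of the maximum.

Because the envelope is centered, the fiducial lands near the center of
each biphasic deflection rather than on one extremum. The per-beat
analysis window is ±60 ms around the fiducial; with a typical 85 ms
(SD 8–12 ms) extremum gap the peak and trough sit at roughly ±43 ms, so
both stay inside the window up to ~3 SD gaps. A window centered on one
extremum would clip the other — this is why the fiducial convention
matters.

## Features

* **Heart rate**: 60 / mean(RR) over successive fiducials, bpm.
  Requires ≥ 2 beats; fewer raises an "insufficient beats" error that
  the cohort-level table builder converts into an exclusion count.
* **QRS amplitude**: per-beat window max − min, averaged over beats,
  mV. A whole-trace (single widest beat) convention is available via
  `per_beat=False`; per-beat averaging is the default because a literal
  whole-trace max − min is dominated by the single noisiest excursion.
  The same applies to **QRS duration**, the per-beat |t(max) − t(min)|
  mean in ms, which takes the absolute value so the convention is
  insensitive to which extremum comes first.
* **Band powers**: Welch periodogram (Hann window, 4-s segments, 50%
  overlap — a variance/resolution compromise for a 9-s record),
  normalized as power per unit time: the integral of the one-sided
  density over [0, fs/2] equals the signal's mean square, making values
  duration-independent and comparable across records. Band power is the
  trapezoidal integral of the density over the band, with interpolated
  band edges.

### Band configuration

Defaults: total 0.5–48 Hz, LF 0.5–4 Hz, HF 4–10 Hz. The textbook
heart-rate-variability bands (LF 0.04–0.15 Hz, HF 0.15–0.4 Hz) are
available through `BandConfig.hrv_literal()` but are numerically
degenerate in this pipeline: they lie below the 0.5 Hz high-pass corner
and below the ~0.11 Hz spectral resolution of a 9-s record. The
VF-oriented defaults follow the observation that the organized
low-frequency components of fibrillation waveforms concentrate around
0.5–4 Hz, with most VF energy between 1 and 10 Hz. Neither
configuration is claimed to be the one used on the clinical data — that
computation is not recoverable — so both are exposed and the default is
the physically meaningful one.

## Feature screening

Per-feature ROC-AUC is computed through the Mann–Whitney rank identity
with half credit for ties, reported in discriminative orientation
max(AUC, 1 − AUC) with a direction flag: a feature that is
systematically lower in the positive class is equally informative. The
one-way ANOVA F statistic (MSB/MSW, df (g−1, n−g)) accompanies it.
Ranking defaults to AUC with F as tiebreaker and then feature name
(deterministic ordering); k defaults to 3. Groups with fewer than two
members or zero pooled within-group variance raise a degenerate-groups
error rather than returning an infinite F.

## Classification

Soft-margin SVM in the standard dual formulation (box constraint
0 ≤ αᵢ ≤ C, Σαᵢyᵢ = 0), RBF kernel by default, delegated to
scikit-learn's SVC; the tests assert the KKT conditions on toy fits.
Class codes follow the convention 1 = NoROEA, 2 = ROEA. Inputs are
z-scored with statistics learned on training data only (population SD;
constant features map to zero with a warning flag).

* **Grid search**: C ∈ {0.01, 0.1, 1, 10, 100, 1000},
  γ ∈ {0.01, 0.1, 1, 10, 100}, scored by mean stratified inner-CV
  accuracy (5 folds, auto-reduced with a warning if a class is too
  small), ties broken toward smaller C then smaller γ. When SMOTE is
  enabled it is re-applied inside each inner training fold.
* **Imbalance**: default "both" — inverse-frequency class weights
  (`class_weight="balanced"`) and SMOTE to equal counts. Each is
  independently switchable to reproduce with/without-SMOTE contrasts.
  SMOTE is implemented in the package (x + λ(x_nn − x), λ ∈ [0,1),
  x_nn among the k = 5 nearest minority neighbors) and pinned by a
  brute-force k-NN segment test.
* **Splitting**: per-class round(ratio·n) to nearest integer, ties to
  even, which reproduces the 136/39 train and 59/17 test allocation of
  a 195/56 cohort at ratio 0.7.
* **Validation battery**: leave-one-subject-out CV re-fits scaler,
  SMOTE and grid search inside every fold (no leakage, asserted by
  tests); sensitivity refits at the 9 points of the ±10% (C, γ) grid
  and reports the max accuracy deviation; ablation enumerates the full
  set, each leave-one-out set and each pair (7 rows for 3 features —
  for three features each leave-one-out subset coincides with a pair;
  both labels are kept to mirror the conventional table layout);
  baseline comparison tunes random forest (trees {100, 300}, depth
  {none, 10}) and logistic regression (L2 strength decades) on the same
  split and scaled inputs.

A documented label-mapping ambiguity exists in the source literature
for this task (the prose attaches "Class 1" and the 99.0% precision
figure to different classes in different places); this package fixes
1 = NoROEA, 2 = ROEA throughout, and its metric computations are
label-map-agnostic identities.

## Synthetic generator

Each record is a train of biphasic QRS-like templates — two opposed
Gaussian lobes — at RR intervals 60/HR·(1 + 0.05·z), z ~ N(0,1) clipped
at ±3 (5% jitter separates intervals without creating detection
ambiguity). The lobe half-separation is solved numerically (bisection)
so the template's extremum gap equals the requested QRS duration
exactly, and the template is rescaled so peak-to-trough equals the
requested amplitude; lobe width is gap/4, keeping template energy
within roughly 2–25 Hz, inside the analysis passband, so filtering does
not bias amplitude recovery. Additive noise is Gaussian, band-limited
to 0.5–48 Hz, rescaled to an exact mean-square power. A sampling rate
below twice the highest generated frequency is rejected.

Cohort sampling draws per-record heart rate, amplitude and extremum gap
from class-conditional Gaussian summaries (successful class:
HR 110 ± 12 bpm, amplitude 1.5 ± 0.4 mV, duration 85 ± 8 ms, total
power 0.6 ± 0.12 mV², LF 0.25 ± 0.06 mV², HF 0.08 ± 0.02 mV²;
unsuccessful: 130 ± 18, 0.9 ± 0.3, 105 ± 12, 0.35 ± 0.09, 0.12 ± 0.04,
0.04 ± 0.01). `sample_feature_table` draws the six features directly
(bypassing waveforms) for classifier-level experiments. Physically
nonnegative draws are floored at 1% of the class mean. Default
waveform noise power is 0.001 mV² — the generator's low-noise regime,
an order of magnitude below the energy of even a 3-SD-small template,
so that detection failures reflect the detector rather than an
arbitrary noise choice. Seeding uses one master seed with per-record
substreams, so fixed seeds give bit-identical cohorts.

### What the generator does and does not emulate

It emulates: the record format (9 s, 250 Hz, mV), class-conditional
marginal distributions of the six features, beat-to-beat timing jitter,
and band-limited measurement noise. It does **not** emulate real VF
dynamics (no chaotic re-entry, no amplitude drift, no CPR artifact),
inter-feature covariance (the published summaries are marginal only, so
features are drawn independently), or post-shock waveforms. Two
consequences matter when interpreting results:

* Classification numbers on synthetic cohorts are *easier* than on
  clinical data — independent Gaussians with these means/SDs admit
  roughly 97% Bayes accuracy on the three selected features — so they
  serve as attainable bounds, not as reproductions of clinical
  performance.
* Feature *ranking* on synthetic cohorts follows the marginal effect
  sizes, under which HF power and QRS duration also separate the
  classes strongly; the clinical selection of amplitude/total/LF power
  presumably reflects real-data covariances the generator cannot know.
  The screening machinery is therefore validated on constructed
  oracles, not on reproducing the clinical trio.

## Numerical choices and degenerate inputs

* Welch detrending is off so Parseval consistency holds for
  deterministic signals (within 1% for sinusoids; ~5% for band-limited
  noise through the window's energy weighting, tested at 10%).
* All-zero records yield an empty beat train; < 2 beats raises
  `InsufficientBeatsError`, which cohort tooling converts to exclusion
  counts.
* Filter designs are validated for stability (poles strictly inside the
  unit circle) at construction.
* Reports are serialized deterministically (sorted keys, no
  timestamps); two runs with the same configuration hash are
  byte-identical.

## Problem sizes

The shipped experiments use 500 train / 2500 test records per class and
10 replicate seeds for the classification bound, and 200 waveforms for
the recovery experiment — sizes at which the standard error of each
reported mean is a few tenths of a percent of its value, while a full
run stays in the tens of seconds on a single CPU.

## Known limitations

* The detector is tuned for bandpassed, template-like VF surrogates; on
  real VF (no distinct QRS complexes) "R-peak" detection is itself a
  modeling convention inherited from the study design.
* LOSO with full inner grid search is O(n) SVM grid searches and is
  meant for cohort sizes in the hundreds.
* SMOTE assumes a Euclidean feature space; features are expected to be
  z-scored first (the pipeline does this).
* The CLI's `evaluate` verb operates on prediction files; model
  persistence is out of scope.
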