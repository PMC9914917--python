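# Methods

## Problem setting

Increased intracranial pressure (IICP) after traumatic brain injury is
conventionally detected with an invasive intracranial catheter. The pipeline
implemented here classifies IICP — defined as mean ICP ≥ 25 mmHg over a 2-s
window, with an inclusive threshold — from a single scalp EEG channel. The
design target is a stepped porcine injury model: a 5-min baseline followed
by four 6-min inflation steps holding ICP near 20, 30, 40 and 50 mmHg, with
EEG sampled at 250 Hz and band-passed to 0.5–47 Hz at acquisition.

## Synthetic cohort model

Real recordings of this kind are restricted, so the package generates them.
The generator is *not* a biophysical model of injured cortex; it is a
statistical surrogate that plants the qualitative signatures reported for
this preparation so that the downstream statistics have something real to
find, and nothing to find when the signal is switched off.

**ICP trace.** Piecewise protocol at 10 Hz: baseline mean 12.4 mmHg, then per
step a 30-s linear ramp to the target followed by a plateau, with additive
Gaussian jitter (SD 1.5 mmHg) throughout. The hemodynamic sampling rate is a
deliberate reduction from kHz-class acquisition hardware: downstream
synchronization needs only epoch means, which are unchanged by the coarser
grid.

**EEG.** `s(t) = A(b(t)) · (√(1−p)·Σ_k √(w_k(b(t)))·o_k(t) + √p·pink(t))`,
where `o_k` are unit-variance band-limited Gaussian oscillators for the five
conventional bands (delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30, gamma
30–47 Hz), `pink` is 1/f-amplitude noise band-limited to 0.5–47 Hz with
variance fraction `p = 0.3`, `b(t)` is the ICP bin (<20, 20–30, 30–40,
40–50, ≥50 mmHg) active at time `t`, `w` the per-bin band weights and `A`
the per-bin RMS amplitude in µV. Default weights move monotonically with the
bin — gamma 0.06→0.16 and beta 0.14→0.26 rising, theta 0.22→0.08 and delta
0.38→0.30 falling, alpha flat — and amplitudes rise 32.5→41.5 µV. These
defaults are directional calibration anchors taken from the reported
per-bin index means for this preparation, not fitted targets; in
particular the non-monotone (U-shaped) behaviour reported for the
delta-based ratios across bins is deliberately not reproduced, and the
absolute band SDs generated here are larger than the animal values. The
`SpectralProfile.flat()` constructor removes all ICP dependence and defines
the pipeline's null condition.

**Subjects.** Each of the 30 subjects draws a log-normal amplitude factor
(σ = 0.15) and Gaussian jitter on the band weights (SD 0.02, renormalized),
so between-subject variance is real and subject-level splits matter. MAP and
HR follow per-bin anchors (90.2→120.1 mmHg, 96.1→134.8 bpm) with noise and a
per-subject offset. All randomness flows from `numpy` `SeedSequence` spawns
of one master seed; identical configuration and seed reproduce the cohort
bit for bit.

**What the generator does not emulate.** Artifacts (movement, ECG/EMG
contamination), burst suppression, the recovery-phase EEG flattening seen
after severe injury, non-stationarity within a plateau, and any direct
biophysical ICP→EEG coupling. Passing tests therefore demonstrate that the
pipeline recovers a planted spectral effect of realistic size under
realistic between-subject variability — not that the classifier performance
transfers to real animals.

A note on protocol arithmetic: the full protocol yields 25 retained minutes
per subject (750 cohort-minutes); reported analyzed totals for the animal
experiment are slightly lower (~612 min), implying unstated per-animal
truncation that the generator does not imitate.

## Preprocessing

4th-order Butterworth band-pass 0.5–47 Hz applied zero-phase
(forward–backward) to the whole record before epoching, so no per-epoch edge
transients and no group delay. Epochs are 2.0 s with 1.5 s overlap (0.5-s
stride), half-open windows `[start, start+2)`, no partial trailing epoch.
Epoch hemodynamics are the mean of trace samples inside the window; an epoch
crossing a phase boundary takes its start-time phase. The first 60 s of each
injury step are excluded (any epoch intersecting the stabilization window is
dropped; baseline is kept in full), leaving 5 + 4×5 = 25 min, i.e. 2985
epochs, per subject.

## Feature definitions

Spectra use Welch's method: 1-s Hann segments, 50% overlap, constant
detrend (a periodogram alternative is selectable). Band powers integrate the
density over half-open intervals `[lo, hi)`; relative powers divide by the
0.5–47 Hz total, so the five shares sum to exactly 1.

The ratio indices are not standardized in the field's nomenclature; the
definitions chosen here, fixed behind one registry so alternates can be
swapped, are

- `THETAPR = Pθ/Ptot`, `GAMMAPR = Pγ/Ptot`
- `DTABR = log10((Pδ+Pθ)/(Pα+Pβ))`
- `DELTAR = log10(Pδ/(Pθ+Pα+Pβ+Pγ))`

with every band power floored at `1e-12·Ptot`. The log-ratio forms were
chosen because the reported values for this preparation show DELTAR negative
and DTABR positive with near-mirror magnitudes, which plain power ratios
cannot produce. `magnitude` is the epoch RMS in µV; `sd_<band>` is the
standard deviation after a zero-phase band-pass to that band; log energy
entropy is `Σ ln(s_i² + 1e-12)` (natural log). The candidate bank is rounded
out with per-band relative powers, five-band spectral entropy, line length,
zero-crossing rate and Hjorth mobility/complexity — 21 candidates, so the
selection stage has a genuine ranking problem. The ten indices the held-out
comparison is organized around are the bank's first ten registry entries.

## Feature selection

Min-max normalization is fitted on derivation subjects only (constant
columns map to 0; validation values extrapolate without clipping). Ranking
uses diagonal NCA for classification: weighted-L1 distance
`d_ij = Σ_r w_r²|x_ir−x_jr|`, kernel `exp(−d/σ)` with σ = 1 on normalized
features, objective = mean leave-one-out soft same-class probability minus
`λΣw_r²` with λ = 1/n by default. Optimization is plain gradient ascent with
a backtracking line search, which makes the objective provably non-decreasing
per iteration; the analytic gradient is verified against central finite
differences in the tests. Because the objective is O(n²), fitting uses a
label-stratified, subject-spread, seed-controlled subsample (default 2000
epochs). Features are then filtered by a pooled-variance two-sample t-test
at raw p < 0.05 — deliberately uncorrected for multiplicity, matching the
procedure being reproduced — and the 10 largest weights among survivors are
adopted (registry order breaks ties; shortfalls warn rather than fail).

## Classifiers

All four models consume the same frozen selected-feature schema:

- **LR** — unpenalized binomial logistic regression.
- **NB** — naive Bayes with per-feature, per-class Gaussian-KDE densities
  (normal-reference bandwidth), evaluated on a 512-point grid and
  interpolated, with a floor so out-of-range values cannot zero a posterior.
- **SVM** — RBF kernel with kernel scale 1.7 (γ = 1/1.7²) and box constraint
  C = 1; scores are a logistic squash of the margin with slope 3 (monotone,
  0.5 at the decision boundary, decisive beyond the support vectors), so
  ranking metrics are exact and no Platt refit is needed.
- **RF** — random-subspace ensemble: 30 unpruned trees, each on
  ⌈√d⌉ features drawn without replacement, all training rows.

Cross-validation partitions *subjects*, not epochs (fold sizes in subjects
differ by ≤ 1), because adjacent overlapping epochs are nearly duplicated
data and epoch-level folds would leak; an epoch-level mode exists for
comparison. The holdout split assigns the first 21 subjects in cohort order
to derivation and the last 9 to validation; a guard refuses to evaluate any
model on a subject that contributed to its fit, and normalization/selection
never see validation rows.

## Evaluation

Accuracy, sensitivity, specificity, precision, F1 and MCC come from the
0.5-threshold confusion matrix (zero-denominator ratios report 0 and flag
the report degenerate); AUC uses midrank tie handling (the Mann–Whitney
form) on the continuous scores. 95% CIs use a cluster bootstrap that
resamples whole subjects with replacement (percentile interval, 1000 draws
by default), chosen because within-subject epochs are strongly dependent and
epoch-level binomial intervals would be far too narrow.

## Problem sizes and numerical choices

Defaults run the full 30-subject protocol: 89,550 epochs (2985/subject),
~60% IICP-positive — the protocol geometry (baseline + one sub-threshold
step negative, three steps positive) fixes this prevalence. NCA fits on
2000 subsampled epochs; the RBF-SVM trains on a stratified subsample of
8000 derivation epochs (its cost is quadratic in n, and planted-signal
recovery is insensitive to the cap); LR/NB/RF train on all ~62k derivation
epochs. The full pipeline completes in roughly two minutes on one CPU.
ε-floors: 1e-12 for entropy and ratio logs. EDF output quantizes to 16-bit
over a symmetric physical range (quantization error ≤ 2·max|s|/65535 µV).

## Known limitations

- The generator's spectral shifts are step functions of the ICP bin; real
  EEG changes continuously and non-monotonically with ICP.
- Classifier scores are well-ranked but not calibrated across subjects with
  different amplitude random effects; threshold-based metrics (accuracy,
  sensitivity) are therefore pessimistic relative to AUC, and no
  recalibration is attempted.
- Single channel only; no artifact model or artifact rejection beyond the
  acquisition band-pass.
- `sd_theta` carries only a weak IICP contrast by construction: the falling
  theta share and the rising overall amplitude nearly cancel in the
  theta-band SD, echoing the non-monotone theta-band behaviour seen in this
  preparation. Its epoch-level significance can vary with the cohort seed.
- The t-test filter is applied per feature without multiplicity correction,
  by design; with ~90k dependent epochs nearly any feature reaches nominal
  significance, so the NCA ranking, not the t-test, does the real work.
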