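# Methods

This note documents the models, conventions and design choices behind
`eegcbf`: what each stage computes, which constants matter, what the
synthetic cohort does and does not emulate, and where the underlying
problem left genuine freedom.

## Problem setting

During CPR after ventricular fibrillation (VF), chest compressions restore
a fraction of pre-arrest carotid blood flow (CBF). Recovery of at least
30 % of baseline flow is the conventional threshold above which cortical
electrical activity returns; below it the frontal EEG flattens into burst
suppression or isoelectricity. The pipeline classifies each ~3-s pre-shock
compression pause — the only artifact-free EEG during CPR — into
low-recovery (group 0, rate < 30 %) or high-recovery (group 1, rate
≥ 30 %) using quantitative EEG parameters alone, and evaluates the
classifier leave-one-animal-out (LOAO) so that no animal contributes to
both training and test data.

## Signal conventions

* Sampling rate 250 Hz; analysis band 0.5–47 Hz.
* Band-limiting: 4th-order Butterworth applied forward–backward
  (zero-phase). Measured response: gain 1.00 at 10 Hz, −24 dB at 60 Hz;
  refiltering changes an in-band tone by < 0.1 %.
* Pause segmentation: three 2-s windows per pause at offsets 0, 0.5 and
  1.0 s (500 samples each, 375 shared between neighbours), reducing
  per-pause variance while keeping windows long enough for 0.5-Hz spectral
  resolution.
* Spectral estimator: unwindowed one-sided periodogram of the demeaned
  window. The scaling satisfies Parseval exactly
  (`sum(power) == var(x)`), which the tests assert. Band powers use the
  half-open convention `P[a, b) = sum over a <= f < b`, so
  delta/theta/alpha/beta/gamma partition 1–47 Hz without double counting
  and band powers are exactly additive.

## The 20 parameters

Time domain: Magnitude (max |x|, µV); Ratio05 (% of samples with
|x| < 5 µV, strict inequality at the boundary); BSR (% of window time in
suppression, where suppression = contiguous runs with |x| < 5 µV lasting
≥ 0.5 s — the run-length criterion is the standard burst-suppression
convention; the threshold matches the isoelectric limit; both are config).

Frequency domain: log10 band-power ratios DeltaR, DAR, DTABR, BetaR
(log10 is the BIS-family convention and matches the magnitude of published
group medians of ±0.7 or less); power fractions ExtraPR … GammaPR on the
0–1 scale; BG_Alpha+ on the 0–100 scale (its published medians of ~40–55
are only consistent with a percentage); BcSEF = SEF95 · (1 − BSR/100)
with SEF95 the lowest frequency accumulating 95 % of 1–47 Hz power — a
fully suppressed window therefore has BcSEF = 0 whatever its spectrum.

Bispectral: SynchFastSlow = log10 of the bispectral magnitude summed over
the full 0.5–47 Hz triangle over the sum over the 40–47 Hz sum-frequency
region, from third-order FFT products of the window.

Entropies (natural log): the per-sample energy distribution is
p_i = x_i² / Σ x_j². Shannon = −Σ p ln p; Rényi with α = 0.5 is
2·ln Σ √p; spectral entropy is the Shannon entropy of the normalized
1–47 Hz power distribution divided by ln(n_bins), giving a value in
[0, 1]. All logs are floored at 1e−12 so every feature is finite on every
input, including an all-zero window.

**Log-energy entropy convention.** The definition "Σ log p(x_i)²" is
genuinely underdetermined: applied to the normalized p it yields values
near −2n·ln n (about −6200 for 500 samples), while the published group
medians (−241 / +1122) are only consistent with the wavelet-toolbox
convention Σ ln(x_i²) over raw µV samples. Both are implemented behind
`FeatureConfig.entropy_convention`; the default is `raw_energy` for the
log-energy entropy (matching the published scale) and the probability
form for Shannon/Rényi. Neither is asserted against published numbers —
only the group ordering is.

## Labeling

Recovery rate = 100 · (mean CBF over the 10 s preceding the pause) /
(pre-arrest baseline CBF); the averaging window is not fixed by the
problem statement and is exposed in config. Group 1 iff rate ≥ 30 %
(threshold inclusive). Labels are invariant under joint rescaling of both
flows.

## Feature selection

Diagonal NCA: one nonnegative weight per feature, distance
d_w(i,j) = Σ_r w_r² |x_ir − x_jr| on z-scored features, maximizing the
expected leave-one-out soft-nearest-neighbour classification accuracy with
an l2 penalty (λ defaults to 1/n). Weights start at 1 (deterministic) and
are optimized with L-BFGS; the weights rank the features. This is the
feature-selection variant of NCA; a full linear-map NCA would not yield
per-feature weights. The exact rank order on any given dataset depends on
the regularization and optimizer, so only the selection *policy* is pinned
against the published table: significance (pooled-variance two-sample
t-test, p < 0.05) is a hard filter applied after ranking, and exactly the
top 10 significant features are kept. Replaying that policy on the
packaged published ranking/p-value table reproduces all 20 published
keep/drop decisions, including the two instructive edge cases (a rank-4
feature dropped for p = 0.864; a p < 0.001 feature dropped for rank 18).
Selection is computed once on the full cohort by default, as the original
analysis did; `--selection-in-fold` moves it inside each training fold to
avoid selection leakage.

## Class balancing

SMOTE with k = 5 minority neighbours, equalize-to-majority target, applied
inside each training fold only — never to held-out animals. Synthetic rows
are convex combinations x + u·(neighbor − x), u ~ U(0, 1), so they lie in
the minority convex hull; originals are preserved verbatim and synthetic
rows carry a provenance flag. On the canonical fold shape (117 majority /
71 minority) this yields 117 / 117.

## Classifiers

All models sit behind one train/score contract with train-set z-scoring
and continuous class-1 scores in [0, 1] (decision threshold 0.5):

| model | configuration |
|---|---|
| LR | unpenalized binomial logistic regression |
| SVM | polynomial kernel, degree 3, C = 1, coef0 = 1, gamma = 1/(d·var); Platt sigmoid calibration via unshuffled stratified 5-fold predictions |
| KNN | k = 9, Euclidean metric, weights 1/(d² + 1e−12) |
| RF | 30 decision trees, random-subspace: each tree sees ⌈√d⌉ features drawn without replacement, all samples |
| MLP | one hidden layer of 10 units, L-BFGS (deterministic full-batch quasi-Newton) training |

"10 hidden layers" in the original description is read as one hidden layer
of 10 units, the single-hidden-layer convention of the era's tooling, and
is configurable. The original's scaled-conjugate-gradient trainer has no
scikit-learn counterpart; L-BFGS is the closest deterministic full-batch
second-order method. An inner 5-fold CV mentioned alongside the LOAO loop
is treated as an optional diagnostic; all reported metrics come from the
outer LOAO evaluation, which is the only well-defined protocol when each
fold's test animal is nearly single-class.

## Evaluation

Because most animals contribute predominantly one class, per-fold
sensitivity/specificity are often undefined; per-fold predictions are
therefore pooled across all folds before computing the confusion matrix,
accuracy/sensitivity/specificity/precision/F1 and the ROC. Undefined
ratios are reported as NaN with a warning, never silently as 0. ROC
thresholds are the sorted unique scores plus ±∞; the trapezoidal AUC
equals the normalized Mann–Whitney U statistic, which the tests verify on
1,000 random instances.

## The synthetic cohort

The generator exists so every stage is testable without animal data. What
it emulates:

* the protocol state machine (pause count = defibrillation attempts,
  max 1 + 10; non-ROSC after the 10th ACLS attempt),
* the four EEG regimes and their amplitude envelopes (baseline > ±20 µV,
  isoelectric < ±5 µV strictly, compression artifact > ±50 µV with
  fundamental at the 102 min⁻¹ compression rate and harmonics),
* a class structure with Table-2-like imbalance (default marginal group-0
  fraction 119/225 ≈ 0.53) and per-animal class purity 0.9, so most
  animals contribute predominantly one class,
* group-wise feature distributions whose median differences carry the
  published sign for all 10 selected parameters, with group-1 Magnitude
  and both spectral-entropy medians inside the published IQR bands.

EEG model: exactly band-limited (0.5–47 Hz) colored noise with spectral
exponent β ramping from 1.15 (low recovery, delta-leaning) to 0.80 (high
recovery), an alpha-band (10 ± 4 Hz) power bump ramping 0.6 → 3.2, RMS
amplitude ramping 1.8 → 7.5 µV, a slow multiplicative amplitude modulation
(depth 0.5 → 0.15) that concentrates epoch energy at low recovery and
separates the entropy indices, and a two-state burst/suppression envelope
whose suppressed fraction follows a logistic ramp centered at 22 %
recovery (suppression level 0.9 µV RMS). All ramps are logistic in the
recovery rate; every constant lives in `GeneratorConfig`. A ±6 %-point
jitter between achieved flow and the EEG's effective recovery rate models
animal-level variability in the flow–EEG coupling and keeps the
classification problem non-trivial near the threshold.

CBF model: piecewise-constant per stage (compression blocks at
rate/100 × baseline, ~2 % additive noise), so labels recomputed from the
flow trace agree with the generator's assignment; low/high rate draws are
kept ≥ 0.5 %-points away from the 30 % criterion so measurement noise
cannot flip a label.

What it does **not** emulate: real VF EEG morphology (spindles, epileptiform
transients), electrode artifacts during pauses, ABP/ETCO2 physiology,
drug effects, or the inter-animal covariance structure of real recordings.
Consequently the synthetic group separation is cleaner than in animal
data: all five classifiers reach pooled LOAO AUCs around 0.95–0.99 on the
default cohort, above the published animal-data range (0.909–0.934).
Passing tests demonstrate the pipeline's correctness and the stated
qualitative behavior, not field performance.

Default problem sizes were chosen to keep a full run (8 animals, ~30 min
of simulated signal each, ~250 sub-epochs) around two seconds, so the
multi-seed suites (20 cohorts) finish in about a minute.

## Numerical choices and degenerate inputs

* Epsilon 1e−12 floors every log argument, the KNN distance weights and
  the bispectral denominator.
* An all-zero window yields BSR = Ratio05 = 100, zero spectra with warned
  zero power fractions, zero spectral entropy and SynchFastSlow = 0.
* NCA ties in the weight vector break by feature order (stable argsort);
  duplicated features converge to near-equal weights.
* Zero-variance features get p = 1 (warned); constant features are guarded
  in z-scoring (divisor 1).
* EDF export uses one 1-s record per second, 16-bit, symmetric physical
  range; the last record is zero-padded for non-integer-second traces.
  Round-trips agree within one quantization step and match `mne`'s reader.
* Determinism: one seed drives generator, SMOTE, and every stochastic
  estimator; identical (config, seed) reproduces byte-identical written
  artifacts, which a test asserts.

## Known limitations

* The bispectral SynchFastSlow uses the raw third-order product of one
  2-s window (no segment averaging), which is noisy; it is excluded by the
  t-test in practice, mirroring the published outcome.
* The published Rényi medians (6.93/9.83) exceed the 500-sample uniform
  bound (ln 500 ≈ 6.21) under any normalized-distribution reading, so the
  original estimator cannot be recovered exactly; only the group ordering
  is reproduced.
* Exact NCA rank order on synthetic cohorts varies with λ and data, and is
  deliberately not an acceptance surface; the published ranking is pinned
  through the packaged reference table instead.
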