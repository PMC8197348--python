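# eegcbf — EEG-based prediction of carotid blood flow recovery during CPR

During cardiopulmonary resuscitation (CPR) the quality of cerebral
perfusion decides whether a cardiac-arrest patient recovers brain function,
but no routine feedback signal reflects it. In a ventricular-fibrillation
(VF) swine model, frontal single-channel EEG recorded during the ~3-s
compression-free pauses before defibrillation attempts carries enough
information to classify whether carotid blood flow (CBF) has recovered to
at least 30 % of its pre-arrest baseline — the accepted threshold for
recovery of cortical activity.

`eegcbf` implements that entire analysis as a tested, reusable pipeline for
biomedical-signal researchers, exercised end to end on a bundled synthetic
VF/CPR cohort generator (no animal data are required or distributed):

1. **Synthetic cohorts** — a protocol-faithful simulator (1 min untreated
   VF, four 2-min basic-life-support compression blocks, up to ten
   advanced-life-support blocks, a ~3-s pre-shock pause per defibrillation
   attempt) producing 250 Hz EEG regimes (baseline > ±20 µV, isoelectric
   < ±5 µV, periodic compression artifact > ±50 µV, recovery-dependent
   mixed activity with burst suppression) and a consistent CBF trace.
2. **Quantitative EEG features** — each pause is band-limited to 0.5–47 Hz
   and cut into three 2-s sub-epochs (1.5-s overlap); 20 parameters are
   computed per sub-epoch: burst suppression ratio (BSR), maximal amplitude,
   bispectral SynchFastSlow, the band-power ratios
   `DeltaR = log10(P[8,20)/P[1,4))`, `DAR = log10(P[1,4)/P[8,13))`,
   `DTABR = log10(P[1,8)/P[8,30))`, `BetaR = log10(P[20,47)/P[11,20))`,
   six band-power fractions of total 1–47 Hz power, the BSR-compensated
   spectral edge frequency `BcSEF = SEF95·(1 − BSR/100)`, Shannon /
   log-energy / Rényi (α = 0.5) / spectral entropies, the isoelectric
   fraction Ratio05, and `BG_Alpha+ = 100·P[8,47)/P[1,47)`.
3. **Labeling** — recovery rate = 100 · (mean CBF over the 10 s preceding
   the pause) / (pre-arrest baseline CBF); group 1 iff rate ≥ 30 %.
4. **Feature selection** — diagonal neighborhood component analysis (NCA)
   ranks the 20 candidates; a pooled-variance Student's t-test (p < 0.05)
   acts as a hard filter; the top 10 surviving parameters are kept.
5. **Class balancing** — SMOTE equalizes the minority class inside each
   training fold (convex interpolation toward the k = 5 nearest minority
   neighbours).
6. **Models and evaluation** — logistic regression, degree-3 polynomial
   SVM (C = 1, Platt-calibrated), k-NN (k = 9, squared-inverse distance
   weights), a 30-tree random-subspace forest and a 10-unit MLP, evaluated
   leave-one-animal-out with predictions pooled across folds into one
   confusion matrix, accuracy / sensitivity / specificity / precision / F1
   and a trapezoidal ROC-AUC.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_extract_features.py --seed 1
python analysis/04_evaluate_models.py --seed 1
```

The extraction step prints, for the default 8-animal cohort at seed 1:

```
extracted 258 sub-epochs from 8 animals
class counts: group 0 (low CBF) = 183, group 1 (high CBF) = 75

group-wise medians of four headline parameters:
       Magnitude   BSR  BcSEF  SpectralEntropy
group
0          8.664  92.4   2.52            0.755
1         22.055   0.0  34.00            0.792
```

Low-recovery pauses are dominated by burst suppression (median BSR 92 %),
which drives BcSEF toward zero, while high-recovery pauses show larger,
spectrally richer activity — the separation the classifiers exploit. The
evaluation step then prints the pooled leave-one-animal-out performance:

```
model  accuracy  sensitivity  specificity  precision    f1   auc
   LR     0.977        0.947        0.989      0.973 0.959 0.996
  SVM     0.977        0.933        0.995      0.986 0.959 0.982
  KNN     0.973        0.960        0.978      0.947 0.954 0.975
   RF     0.969        0.947        0.978      0.947 0.947 0.979
  MLP     0.973        0.933        0.989      0.972 0.952 0.993
 mean     0.974        0.944        0.986      0.965 0.954 0.985
```

Every model separates the two CBF groups with AUC well above 0.9 on the
synthetic cohort (the generator's group separation is cleaner than real
animal data, so these numbers sit above the published animal results; see
`docs/methods.md`). The same pipeline is scriptable through a CLI:

```bash
eegcbf run --seed 1 --out runs/demo
eegcbf simulate --seed 1 --out runs/sessions   # manifests + CSV signals
```

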