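# Methods

`serumpeaks` re-implements a serum MALDI-TOF-MS biomarker discovery and
validation workflow as a tested pipeline: spectral preprocessing, peak
detection and cross-sample clustering, nonparametric marker ranking,
genetic-algorithm panel selection scored by SVM leave-one-out
cross-validation, blind-set evaluation, and a clinical validation layer
(ROC, logistic marker combination, survival analysis). A synthetic-cohort
generator with known ground truth stands in for the original sera, which are
not publicly available.

## Preprocessing

Order is fixed and logged per spectrum: mass-window restriction (default
900–10,500 Da, the acquisition window of linear positive mode) →
undecimated-wavelet denoising → baseline subtraction → total-ion-current
(TIC) normalization.

**Denoising.** Undecimated (stationary) discrete wavelet transform,
Daubechies-8, levels = min(6, ⌊log₂ n⌋ − 2), soft thresholding of all detail
levels at the universal threshold √(2 ln n)·σ̂ with σ̂ = MAD(finest
details)/0.6745. The transform is shift-invariant, so denoising does not
move peak apexes (tested: ≤ 1 grid point over 20 noisy fixtures). σ̂ is
retained as the spectrum's noise scale and re-scaled through normalization,
so downstream SNR thresholds stay meaningful. Thresholding is implemented
directly (sign(d)·max(|d|−T, 0)); the shrinkage form `1 − T/|d|` is
undefined at exactly-zero coefficients, which occur in noise-free regions.

**Baseline.** Smoothed morphological opening: rolling minimum over a 200-Da
window followed by a rolling maximum of the same width, then a 100-Da mean
filter. The opening recovers monotone baselines exactly (the erosion's lag
is undone by the dilation), which a plain smoothed rolling minimum does not
— on a decaying-exponential fixture the plain version leaves a ~3% residual
versus < 2% required. Edges are padded by odd reflection (linear trend
continuation) so the opening stays exact at the boundaries; the estimate is
clamped to [0, signal].

**Normalization.** Intensities are scaled so the TIC equals a target; the
default target is the cohort mean of the baseline-corrected TICs. The
scaling multiplies by one precomputed factor, so spectra differing by a
binary-representable gain normalize bit-identically. **The training cohort's
target is frozen and applied to any later (blind) cohort** — re-deriving the
target from test data would be a form of test-time re-standardization.

## Peak detection and clustering

Strict local maxima with height ≥ 5·σ̂ (S/N 5, the ClinProTools-style
default; S/N 3 admits wavelet-ringing sidelobes of strong peaks, ~10% of
the parent height at ~0.5% of m/z, which inflate the cluster count by ~40%).
Maxima closer than 0.3% of m/z (linear-mode mass accuracy) keep only the
taller; the centroid is the intensity-weighted mean of the three points
around the apex.

Pooled peaks are clustered along m/z by a running-centroid chain rule: a
peak farther than 0.3% from the running centroid starts a new cluster;
clusters in fewer than 10% of samples are dropped. The matrix cell is the
peak height (max when a sample has two peaks in a cluster, logged); a
missing peak contributes 0. The chain is processed in a canonical
(m/z, sample, height) order, so sample permutations cannot change the
result.

## Marker ranking

Two-sided Wilcoxon rank-sum test per cluster: exact distribution when
min(n₁, n₂) ≤ 8 without ties, normal approximation with tie and continuity
corrections otherwise. Per-marker AUC is U/(n₁n₂) with ties counted ½,
oriented ≥ 0.5; the direction records which group has the larger mean.
Selection uses raw p-values (a Benjamini–Hochberg column is emitted for
information only). The candidate shortlist keeps p < 10⁻⁵ and AUC > 0.78,
truncated to the 10 smallest p.

## Panel selection

Chromosomes are bit-vectors over the shortlist with at most 10 bits set.
Fitness is the Youden index J = sensitivity + specificity − 1 from
leave-one-out cross-validation of an RBF-kernel SVM (C = 1,
gamma = 1/(n_features·Var), balanced class weights). Within every fold the
n−1 retained samples are log1p-transformed and z-scored and the held-out
sample transformed with the fold's parameters; zero-variance features are
dropped per fold. Balanced class weights are used because J costs both error
types equally while the training cohort is unbalanced (89 CRC vs 63 HC); an
unweighted SVM leans toward the majority class and loses specificity.

Ties in J break toward fewer members, then lower summed candidate p, then
(to make the argmax unique — small-sample rank-sum p-values tie exactly)
lexicographically toward the strongest members. The population is
warm-started with p-ranked prefixes (the strongest k markers for each k),
a standard wrapper-selection warm start; uniform crossover (rate 0.8),
per-bit mutation (0.02), tournament-2 selection and 2-elite elitism drive
the search; the best panel ever evaluated is returned and the best-fitness
trajectory is non-decreasing by construction. Fitness values are memoized,
so cost scales with distinct subsets visited, not generations. Defaults are
population 50 × 100 generations; scaled runs (tests, the acceptance script)
use 20 × 15, which saturates the ~9-candidate search space that the default
synthetic cohort produces. For candidate sets of ≤ 8 markers, a higher
mutation rate (~0.1) is advisable: with short chromosomes the default 0.02
yields almost no exploration after convergence.

The final model refits the standardization and SVM on the full training
matrix. Blind evaluation matches panel members to test clusters by m/z
within the clustering tolerance, applies the stored transform unchanged, and
consults test labels only at scoring.

## Clinical validation layer

Empirical ROC over all distinct thresholds; AUC by the Mann–Whitney identity
(ties ½), 95% CI by Hanley–McNeil. The Youden cutoff is reported in score
space as a midpoint between adjacent distinct scores; among tied-J
candidates the one closest to the median score is reported (midpoint of the
two closest if equidistant). Markers that fall with disease (MST1) are
analysed with `positive_high=False`; the cutoff stays in original units.

Marker combination is an additive logistic regression on z-scored continuous
features and raw binary features; the combined score is the linear
predictor. Perfect separation (which the FOBT's 100% specificity makes
likely) falls back to a ridge-penalized fit rather than failing. CEA is
log-transformed before standardization (right-skewed). Group comparisons are
two-sided Student/Welch t or one-way ANOVA; identical constant groups return
p = 1 (no evidence) while zero within-group variance with unequal means is
an error.

Survival: expression is dichotomized at the Youden cutoff of the
outcome-ROC (orientation chosen so AUC ≥ 0.5); Kaplan–Meier curves and the
two-group log-rank test (hypergeometric tie variance, two-sided p from
χ²₁) come from `lifelines`.

## Synthetic cohorts

**Spectra.** 173 peak clusters on a 1-Da grid over 900–10,500 Da: ten
planted at the published marker masses — 1694, 1781, 1868 Da up-regulated in
CRC; 1947, 1951, 2073, 2084, 2886, 4478, 6856 Da down-regulated — at fold
change 2.5 (the conservative floor of the reported effect sizes), the rest
log-uniform with ≥ 0.7% relative separation (log-uniform placement mimics
the low-mass crowding of serum profiles and keeps the separation constraint
uniformly feasible). Per-sample heights are log-normal around the group mean
with mean-one multiplicative noise (σ_log = 0.6), chosen so single planted
markers show empirical AUC ≈ 0.80–0.92 — matching a study whose candidate
markers all exceeded AUC 0.78 yet needed a 7-marker panel for ~98–99%
cross-validated accuracy. Each spectrum adds Gaussian peaks of width
σ = 0.0008·m/z, an exponentially decaying baseline (amplitude 800, decay
2,000 Da), mildly heteroscedastic Gaussian noise (SD 8 at low mass decaying
by 30%), and a per-spectrum gain U(0.7, 1.3) that exercises TIC
normalization. The width constant follows from the reported markers
themselves: 1947 and 1951 Da were printed as distinct peaks, so the
instrument resolved 4 Da at ~1950 (FWHM < 4 Da, σ/mz < 0.0009). A strongly
mass-dependent noise SD is avoided because detection uses a single robust
noise scale per spectrum.

Two consequences of the 0.3% feature tolerance are inherent and documented:
1947/1951 merge into one (doubly differential) cluster, and 2073/2084
interact at detection, occasionally costing one of them the AUC > 0.78 gate.
Planted-marker recovery is therefore counted truth-side: a planted mass
counts as recovered when any panel member matches it within the tolerance.

**Clinical table.** MST1 from zero-truncated normals with the reported
group/stage means and SDs (healthy 959.65 ± 407.07 ng/ml; stage I
343.97 ± 277.76; stage IV 132.49 ± 138.36); stages II and III are
interpolated (250 and 230, SD 261.99) to keep the stage trend and the pooled
stage-I–III mean (≈ 266) consistent. CEA is log-normal with stage-increasing
medians (1.8 µg/l in HC to 9 in stage IV) tuned to the reported AUC ≈ 0.77;
FOBT is Bernoulli(0.641) in CRC and always negative in HC. These choices
preserve the reported ordering AUC(MST1) > AUC(CEA) with AUC(MST1) ≈ 0.93.

**Survival.** Expression log-normal; exponential event times with the
hazard multiplied by the hazard ratio (default 4) below the true cutoff;
censoring times uniform on (0, c) with c solved so the expected censored
fraction matches the requested rate.

## What passing tests do and do not show

The generator draws cluster masses once per cohort, uses independent
log-normal heights per cluster, and Gaussian peak shapes — it does not model
isotope envelopes, adducts, matrix clusters, mass-calibration drift between
acquisition days, or correlated biological covariation between proteins.
Passing the end-to-end recovery check therefore shows the pipeline's
machinery is sound under the stated effect sizes and noise, not that it
would achieve the same operating point on real sera; the published blind
sensitivity/specificity (94.7/92.3) cannot be reproduced without the
original spectra, and the synthetic analogue (blind sensitivity and
specificity ≥ 0.90 with ≥ 6 of 10 planted masses recovered and no noise
clusters, in ≥ 90% of 20 seeds) is the substitute.

## Problem sizes and determinism

Scaled runs used throughout tests and the acceptance script: 217 spectra of
9,601 points, LOOCV over 152 training samples, GA 20 × 15 with memoization;
one end-to-end cohort takes ~20–30 s on one CPU. A single global seed fans
out to stage seeds via `SeedSequence(global, spawn_key=(stage,))`; reruns of
the same config are bit-identical, and blind labels enter only at scoring.
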