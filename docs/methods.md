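# Methods

## Problem and pipeline

The package classifies voice records of sustained vowels as healthy control
(HC, class 0) or Parkinson's disease (PD, class 1) from 44 tabulated acoustic
parameters in six families (jitter, shimmer, harmonics-to-noise ratio,
nonlinear measures, MFCC, Delta-MFCC). The pipeline has three stages:

1. **Reduction** — per-family Pearson correlation analysis; families with
   strong internal correlation are compressed by PCA with an
   eigenvalue-retention rule; candidate features (PCA projections + raw
   nonlinear parameters) are screened by a two-sided Mann–Whitney–Wilcoxon
   (MWW) rank test at significance level α.
2. **Semi-supervised clustering** — density-based competitive seed selection
   followed by seeded K-means over all records (labeled and unlabeled).
3. **Classification** — each prototype centroid is labeled by an R-nearest-
   neighbor majority vote over the labeled subset; members inherit their
   prototype's label. KNN and RBF-SVM supply supervised baselines.

## Reduction stage

*PCA variant.* PCA is computed on the correlation matrix of each family
(z-scored parameters, training statistics frozen for projection). The
families mix units spanning orders of magnitude (absolute jitter in seconds
vs HNR in dB), so covariance-matrix PCA would be dominated by scale;
correlation-PCA is the defensible choice. Component signs are fixed so each
component's largest-magnitude loading is positive, making projections
reproducible across platforms.

*Retention rule.* h is the minimal component count whose eigenvalue share
reaches the threshold (default 0.90). h is derived from the data; callers
may pin a family's h via `pin_components` for strict compatibility with an
external analysis.

*MWW variant.* Exact enumeration is used when the smaller sample has ≤ 8
observations and the pooled data are tie-free; otherwise the tie-corrected
normal approximation with continuity correction. The exact branch is
verified against brute-force enumeration of all rank splits in the test
suite.

*Selection.* A candidate is retained when p < α (default 0.05). Inside
cross-validation the PCA models and the selection are fitted on the training
fold only and applied frozen to the held-out fold, avoiding selection
leakage; a `fit_features_on_all` flag restores whole-dataset fitting for
compatibility with protocols that fit the reduction once. If a training fold
selects nothing (routine on null data, where each of ~27 candidates has an α
chance), the fold falls back to the full candidate set with a warning rather
than aborting the run; the standalone `build_and_select` raises instead.

## Clustering stage

*Proximity range η and density threshold γ.* Defaults are resolved from the
data: η = 10th percentile of the pairwise-distance distribution, γ = 75th
percentile of the density distribution (clamped into the valid range
1 < γ ≤ N). Both accept absolute overrides. The percentile defaults make the
seeding scale-equivariant: rescaling the features rescales η and leaves the
recovered structure unchanged.

*Winning-seed rule.* Candidates (density ≥ γ) compete by greedy non-maximum
suppression: the densest remaining candidate wins (density ties broken by
lowest record index) and suppresses every candidate within η. This is
deterministic, guarantees winners are pairwise separated by more than η, and
covers every candidate by some winner. K is the winner count — never a free
parameter.

*Seeded K-means.* Lloyd iterations from the winners, convergence when the
maximal centroid displacement is ≤ 1e−9 or the assignment partition repeats,
with an iteration cap of 300 (exact "no movement" is numerically fragile). A
centroid that loses all members keeps its position and competes again, so K
is preserved. The within-cluster sum of squared errors is non-increasing
across iterations by construction; the trace is stored on the model.

*Transduction.* In cross-validation the SSCL stage clusters the union of
training and held-out records (features only); centroid labels are then
derived from training labels alone. This matches the semi-supervised framing
in which unlabeled patterns participate in structure learning.

## Classification stage

*Centroid labeling.* R nearest labeled neighbors (default R = 7, mirroring
the KNN baseline's K = 7) vote on each centroid; a vote tie goes to the
label of the nearest neighbor among the tied classes; distance ties are
broken by stable training-set order.

*Continuous score.* The hard-label pipeline needs a score for ROC analysis.
Each centroid's score is the inverse-distance-weighted positive vote share
of its R neighbors (weights 1/(d + 1e−12)); records inherit their centroid's
score. This is one defensible construction of a score for a centroid-voting
classifier, chosen for being monotone in local label evidence; AUC values
computed from it are not comparable to scores from probabilistic
classifiers.

*Baselines.* KNN is implemented in-package (the documented tie rule differs
from off-the-shelf implementations); its score is the unweighted positive
vote fraction. The RBF-SVM baseline delegates to scikit-learn with
gamma = 1/(2σ²), σ = 4 by default, and Platt-calibrated scores.

## Evaluation

Confusion-matrix metrics: accuracy, recall, specificity, precision, F-score
(harmonic mean of precision and recall), Matthews correlation coefficient,
and Cohen's κ with the standard chance term
pe = [(TP+FP)(TP+FN) + (TN+FN)(TN+FP)]/n². Ratios with zero denominators are
reported as absent (None) with a warning, never silently as zero, and are
skipped in fold aggregation. Fold aggregation uses the sample SD (n−1).
ROC curves use a threshold sweep with tied scores grouped into single steps
and trapezoidal AUC; the pooled curve concatenates held-out scores across
folds.

Folds are stratified by class at record level by default. Because each
subject contributes three records, record-level folds leak speaker identity
(a test record's replicate siblings can sit in the training fold); a
subject-level grouped split (`split_level="subject"`) is provided for
leakage-free evaluation.

## Synthetic data generator

Each family is a one-factor model: parameter j of family f is
`scale · (√ρ_f · F + √(1−ρ_f) · ε_j)`, so every within-family pair has
expected correlation ρ_f (defaults 0.95 for jitter/shimmer/HNR, 0.5 for
MFCC/Delta, 0.1 for nonlinear). The latent-factor construction guarantees a
positive-semi-definite correlation structure for any family size and makes
the "dominant principal component carries the class signal" geometry
explicit — a direct Cholesky of an equicorrelation matrix would achieve the
correlations but not the factor interpretation. The factor splits into a
subject-level random effect (default share 25% of factor variance; the
source cohort reports no between/within-subject decomposition, so this is a
modeling choice exposed as `subject_effect_share`) and a record-level part.
Class 1 shifts the factor by the family's effect size in factor-SD units;
nonlinear parameters take independent per-parameter shifts (defaults: PPE
0.30, GNE 0.55; RPDE and DFA none), mimicking real data where only PPE and
GNE separate the groups. Default factor effect sizes (jitter 0.40, shimmer
0.45, HNR 0.55, MFCC 0.55, Delta 0.55) were chosen so that pooled
240-record rank tests land in the p ≈ 1e−4…4e−2 range observed for the
dominant features of the real cohort.

What the generator does **not** emulate: non-Gaussian marginals (real jitter
and shimmer are right-skewed), heterogeneous pairwise correlations within a
family, cross-family correlations, age effects, and any gender effect on the
features (gender is metadata only, drawn with the cohort's 55%/67.5% male
fractions). Tests passing on this generator therefore demonstrate
correctness of the algorithms under the stated correlation/effect structure,
not clinical performance on real voices.

## Calibration and recovery checks

*Null calibration.* On zero-effect data with **no** subject random effect
(exchangeable records), each candidate feature is selected in ≈ 5% of 2000
replicates, matching α. With the default 25% subject effect the pooled
240-record MWW test is anticonservative (replicate records of one subject
are positively correlated, inflating the rank statistic's variance relative
to the iid assumption; the empirical type-I rate is roughly double the
nominal level). This is a property of testing clustered records, not of the
implementation; analyses of replicated designs should aggregate to subject
level or use subject-level splits when calibration matters.

*Null cross-validation.* Mean 10-fold CV accuracy over 20 zero-effect
replicates (default subject effect retained) is within 0.5 ± 0.05 for both
SSCL and KNN.

*Signal recovery.* With a 4-SD class shift on the jitter and shimmer latent
factors and 20% labeled records, the transductive SSCL pipeline recovers
record labels with ≥ 95% accuracy.

Problem sizes used throughout the suite (240-record tables, 2000 null
replicates, 20 CV replicates, 3000-record correlation checks) were chosen as
the smallest designs that make the statistical assertions sharp.

## Known limitations

- Defaults for η, γ and R are package choices; published analyses of the
  real cohort do not report theirs, so end-to-end metric values on any
  particular dataset depend on this tuning.
- The SSCL ROC score is a construction, not part of the original hard-label
  formulation.
- The adjacency concept in the seeding formulation is consumed here as the
  suppression neighborhood of a winner; other readings are possible.
- Negative equicorrelation targets are infeasible under the one-factor model
  for families with more than two parameters and are rejected.
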