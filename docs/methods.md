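# Methods

## Labels and dataset arithmetic

Input manifests carry a three-way histopathological category: leukoplakia
with dysplasia, leukoplakia without dysplasia, and OSCC. The binary task
merges OSCC into the *presence of dysplasia* class (`P`); only leukoplakia
without dysplasia maps to *absence* (`A`). This is a labeling convention of
the task, not a pathological claim — OSCC need not exhibit dysplasia. With
the published composition (89 / 57 / 91) the merge yields 180 P / 57 A of
237 total: ~76% presence, a 3:1 imbalance. Percentages are stored unrounded;
integer rounding happens only in report-time accessors. Category strings are
matched case-insensitively against a fixed synonym vocabulary; anything else
is an error (fail-fast keeps manifests auditable). `image_path` is optional
because the pipeline is feature-first; only extraction backends need images.

## Per-view classifier

Each feature view trains an independent linear-kernel SVM (scikit-learn
`SVC(kernel="linear")`, regularization `C` default 1.0, exposed). Features
are z-scored per feature with statistics from the training rows only;
zero-variance features keep scale 1. The SVM margin is mapped to a
calibrated probability μ(P) = σ(a·margin + b) with a > 0, fitted by logistic
regression on *out-of-sample* margins from an internal seeded stratified
3-fold split of the training data; the final SVM is refitted on all training
rows. μ(A) = 1 − μ(P) by construction, and the predicted label is P exactly
when μ(P) ≥ 0.5 (a tie goes to P: the costly clinical error is a missed
dysplastic lesion).

Two calibration decisions matter:

* **Equal-prior calibration.** The sigmoid is fitted with balanced class
  weights, so μ is the posterior under a 50/50 prior. An unweighted fit
  absorbs the log prior odds (≈ log 3 here) into the intercept, which both
  drags the 0.5 threshold far from the SVM boundary (on imbalanced data the
  absence-view classifier then predicts P almost everywhere) and puts the
  two views' scores on prior-inflated scales, biasing the fusion's
  cross-classifier confidence comparison. Equal-prior scores are the common
  scale the comparison needs.
* **`score_mode="margin"`** is available for sensitivity analysis: the raw
  margin through a fixed unit-slope sigmoid, keeping scores complementary
  probabilities while bypassing the fitted calibration.

## Fusion by class selection

Rules (a)–(d) in the README. The printed rule set leaves three things open;
each is an explicit policy, never a silent default:

* **Score ties in the conflict case** (μ(A|CA) = μ(P|CP)): `tie_rule`,
  default `prefer_P` (sensitivity-first, as above).
* **The reversed disagreement** CP=A ∧ CA=P, where each classifier votes
  against its own specialty: `uncovered_rule`, default `confidence_vote` —
  the classifier with the larger score for its own predicted class wins,
  extending the conflict principle of rules (c)/(d) symmetrically; a
  confidence tie goes to CP's call (A), mirroring the specialist reading.
  The alternative `prefer_specialist` lets CP decide P-membership outright.
* **The fused ROC score**: `score_rule`, default `selected_classifier` (the
  winning classifier's μ(P)); `average` uses the mean of the two μ(P).

Structural properties (all tested): exactly one rule fires per sample;
consensus dominates regardless of scores or policy; fusing a classifier with
itself reproduces it; raising μ(P|CP) with everything else fixed never flips
a fused P to A; and the engine agrees with an independently coded exhaustive
interpreter over all label combinations × score orderings × policies.

## Evaluation

Stratified k-fold (default k = 5): samples are shuffled within class by a
seeded RNG and dealt round-robin, the simplest scheme that bounds per-fold
minority-class count differences by 1. Per fold, standardizer, SVM and
calibration are fitted on the training folds only — held-out scores are
leakage-free by construction, verified by a test that refits from physically
separate arrays.

Metrics use P as the positive class: SEN = TP/(TP+FN), SPE = TN/(TN+FP),
PRE = TP/(TP+FP), BAC = (SEN+SPE)/2 (an exact identity in the report, not a
rounded one), AUC as the normalized Mann–Whitney U on average ranks —
half-credit for ties, which matters because fused scores contain many
duplicates. A ratio with zero denominator is flagged `None` and excluded
from that metric's cross-fold aggregate with a warning, never coerced to 0.
Aggregates are mean and sample standard deviation (ddof = 1) across folds.

## Synthetic two-view generator

The generator emulates the statistical structure the method assumes, so all
logic is testable without the external image dataset:

* **Class-conditional Gaussians** with diagonal covariance per view; a
  fraction of axes (`overlap_axis_fraction`, default 0.25) carries a mean
  shift totalling `delta` (standardized units, default 2.0) split evenly
  across signal axes; remaining axes are pure noise. Under this model a
  linear SVM is Bayes-consistent, and closed-form expectations back the test
  oracles. Default dimensions d1 = 64, d2 = 48: high-dimensional enough to
  be representative, small enough for seconds-scale tests.
* **Complementary asymmetry.** A mean shift alone cannot split SEN from SPE
  at a symmetric threshold, so "view favors class c" is realized by
  class-conditional variance scaling: the favored class is drawn at
  0.35 × `noise_sd`, the disfavored at 1.1 ×. The tight class forms a
  compact, reliably classified cluster; the wide class spills across the
  boundary. View 1 favors P (a sensitivity specialist emerges), view 2
  favors A (a specificity specialist). The constants were fixed once from a
  one-dimensional Bayes analysis of where an equal-prior linear cut lands
  between a tight and a wide Gaussian under 3:1 imbalance.
* **Null consistency.** The variance asymmetry interpolates linearly to
  symmetric unit scaling as `delta` → 0, so a zero-separation configuration
  carries no class signal in means *or* variances and cross-validated BAC
  sits at chance (unequal variances alone would otherwise be linearly
  exploitable).
* `asymmetry_preset(ratio, strength)` builds a config with `n_A = 57`
  scaled by the imbalance ratio (counts can be pinned explicitly) and
  `delta1 = delta2 = strength`.

What the generator does **not** emulate: image content, staining artifacts,
within-class multimodality, feature correlations of real deep embeddings,
and any relationship between the two views beyond shared labels (real CNN
and ViT features of the same slide are correlated; here the views are
conditionally independent given the class). Passing tests therefore
demonstrate the correctness and the qualitative mechanism of the pipeline —
specialist base classifiers, fusion recovering balanced accuracy — not the
published headline numbers, which depend on the external dataset and
pretrained backbones.

## Problem sizes and seeds

The Monte-Carlo studies (tests and `scripts/acceptance.py`) use 20 generator
seeds at 180 P / 57 A with 5-fold cross-validation — large enough for stable
means (sd of mean BAC ≈ 0.008), small enough to run in seconds. Null-signal
tests use 90 P / 30 A for the same reason. A single run seed derives all
component seeds (fold shuffling, calibration splits, generation) by fixed
offsets, so every stage is independently reproducible and end-to-end output
is byte-identical across reruns.

## Known limitations

* The deep backends require the optional `torch`/`timm` extra and pretrained
  weights; they are deliberately frozen (no fine-tuning, augmentation or
  dropout at extraction), so two extractions of the same manifest are
  identical.
* The fusion is the stated rule set only; weighted averaging or stacking are
  out of scope.
* With very small folds, PRE (and AUC on single-class folds) can be
  undefined; they are excluded from aggregates with a warning rather than
  imputed, so aggregates on tiny datasets may average fewer than k folds.
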