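# Methods

## Problem setting

In clinically node-negative early tongue squamous cell carcinoma (cT1-2N0),
a fraction of patients (~25%) later develop lymph-node recurrence, and the
decision to perform elective neck dissection hinges on predicting who.
Depth of invasion (DOI) is the established clinical predictor but is
insufficient alone; histological patterns visible in the primary tumour
(e.g. tumour nests mixed with inflammatory cells) carry complementary
signal.  The package implements a three-arm prediction design — a
weakly-supervised image classifier over whole-slide-image (WSI) patch
features, clinicopathological machine-learning models, and their joint
fusion — together with the interpretation analyses that turn the image
model's attention into pathologist-reviewable evidence.

## Slide classifier (attention-MIL)

A slide is a bag of patch feature vectors; only the bag carries a label.
Patches are projected (`Linear + ReLU`, default 64→128), scored by a
single-branch gated attention module
`softmax(w^T(tanh(Vp) * sigmoid(Up)))`, pooled into a bag embedding, and
classified by a linear head.  An instance-clustering auxiliary branch
pseudo-labels the top-k attention patches with the bag class and the
bottom-k with its complement (k = min(8, ⌊n/2⌋)) and trains an instance
classifier with cross-entropy; this realizes the clustering constraint in
a fully specified form (the reference design's smooth-SVM instance loss is
an undocumented detail of the original; cross-entropy plays the same
inductive role).  Loss weights are c1 = 0.7 (bag) and c2 = 0.3 (instance).

Training: Adam, learning rate 2e-4, one optimization step per slide, no
data augmentation, shuffling fixed by seed.  Early stopping monitors the
validation loss; an epoch "improves" only if strictly below the running
minimum (ties do not reset patience), training stops after 20 consecutive
non-improving epochs or at epoch 200, and the best epoch's parameters are
restored.  Classifier weights initialize at zero so an untrained model
outputs probability 0.5; all other layers use scaled Gaussian init from
the seed.

The network is written in numpy with explicit backprop (a
finite-difference check in the test suite bounds the gradient error at
1e-6).  Gradients do not flow through the top-k/bottom-k selection, which
is treated as constant per step, as is standard for hard selections.

Attention interpretation uses the within-slide percentile rank of the raw
attention weights (average ranks for ties; a single patch scores 1.0), so
scores are comparable across slides and invariant to monotone transforms.

## Clinical models

Eight covariates: pT (1/2), DOI (mm), lymphatic/vascular/perineural
invasion, age, sex, side — used as nested sets "two", "five", "eight".
Encoding is numeric (booleans 0/1, sex M→0/F→1, side left→0/right→1).
Model selection is an exhaustive grid search over stratified 10-fold CV
maximizing mean AUC, ties to the earlier declared grid point.  Defaults
(the study reports none): RF trees {100, 300, 500} × depth {2, 4, ∞} ×
min-leaf {1, 3}; SVM kernel {linear, rbf} × C {0.1, 1, 10, 100} × γ
{scale, 0.01, 0.1}.  SVM features are standardized with training-fold
statistics and probabilities come from Platt-type sigmoid calibration
fitted within the training data (`CalibratedClassifierCV(SVC(),
ensemble=False)`); random forests use raw features and vote fractions.
The accuracy threshold is 0.5 throughout.

## Fusion

The fused design matrix is the clinical matrix plus one `wsi_score`
column.  For training cases the score is produced out-of-fold: stratified
k-fold over the training cohort, a MIL model per fold trained on the other
folds (with an inner ~10% stratified validation slice for early stopping)
scores the held-out fold.  Bookkeeping records which fold model scored each
case and asserts scorer == holder, so leakage-freeness is checked, not
assumed.  Unseen (test) cases receive the mean score of the k fold models.
The WSI score enters as a probability (bounded, interpretable); fusing the
logit instead is a trivial variant the API permits by transforming the
column.

## Evaluation

AUC is the tie-corrected Mann-Whitney statistic; accuracy/sensitivity/
specificity use threshold 0.5 with "positive iff score ≥ threshold".
The slide arm is evaluated by k repetitions of a random 80/10/10
train/validation/test split (val and test sizes = round(0.1 n), remainder
to training; resampled up to 100 times if a part is single-class), the
clinical arm by stratified 10-fold CV — the two harnesses are deliberately
distinct, matching how each arm is developed.  Across-fold dispersion is
the sample SD (n−1).

## Morphology statistics

Each mined high-attention patch carries five binary morphology flags
(tumour cells, inflammatory cells, muscle, adipocytes, salivary gland);
composites tumour∧inflammatory and muscle∧inflammatory are derived.  Each
feature is cross-tabulated by recurrence group and tested with a
two-sided Fisher's exact test under the point-probability convention (sum
of hypergeometric probabilities ≤ the observed table's, relative
tolerance 1e-7 — the convention of R's `fisher.test`, hence of EZR-style
analyses).  The p-value is computed directly from the vectorized
hypergeometric log-pmf, which keeps exhaustive sweeps cheap; agreement
with `scipy.stats.fisher_exact` and with exact integer enumeration is
asserted in the tests.  Percentages are rounded half-up to one decimal;
p-values below 0.001 print as "<0.001".  Continuous cohort comparisons
use Welch's unequal-variance t-test (the pooled-variance choice is
unreported upstream; Welch is the safer default).
`annotations_from_counts` reconstructs a patch-level table from published
summary counts, matching all primitive marginals and both pairwise joints
exactly, so summary tables can be pushed through the same code path.

## Synthetic cohort generator

The generator is the canonical input source and defines the study
conditions:

* **Cohort structure** — default 148 cases, recurrence fraction 34/148,
  stratified train/test tags at test fraction 39/148 (the original split
  was temporal; stratified tagging approximates its per-class counts).
* **Bags** — 100–300 patches per slide at feature dim 64 (desk-scale
  stand-ins for 1,024-dim CNN encodings; both are config knobs).
  Background patches are spherical standard Gaussians; signal patches are
  shifted by `signal_shift` (default 6) along the first feature axis —
  the simplest identifiable planted structure, and rotation-invariant in
  expectation for every downstream method.  Signal fractions default to
  0.2 in recurrence bags and 0.0 in non-recurrence bags: the planted
  signal models recurrence-specific morphology absent from non-recurrence
  slides.
* **Morphology truth** — per-patch flags drawn per (signal, label)
  stratum; inflammatory is drawn first and tumour/muscle conditionally so
  the pairwise joints are matched exactly.  Default rates are calibrated
  to the observed high-attention-patch proportions (recurrence column for
  the signal stratum, non-recurrence column elsewhere).
* **Clinical covariates** — DOI log-normal per label (medians ~3.0 vs
  ~5.5 mm), clipped to (0.1, 10] mm; pT is deterministic from DOI at the
  AJCC-8 5 mm threshold, keeping pT and DOI consistently correlated;
  invasion flags Bernoulli with label-dependent rates; age, sex, side
  label-independent.
* **Tumour masks** — the tiles whose patch is signal- or tumour-flagged,
  giving the localization analysis a known ground truth.
* `null_config()` zeroes every label-conditional effect for soundness
  checks.

What the generator does **not** emulate: pixel-level histology, stain and
scanner variation, encoder-specific feature geometry, spatial correlation
between neighbouring patches, and survival-time outcomes.  Passing tests
therefore demonstrate that the machinery recovers a planted signal under
the stated noise model, not that any particular AUC is attainable on real
slides.

## Problem sizes and numerical choices

Cohort-level checks use 400 cases (25% recurrence) so that held-out AUCs
have usable precision.  For those checks the slide classifier runs at a
reduced, converged scale — hidden 64, attention 32, max 20 epochs,
patience 8 — chosen because held-out AUC and attention AUROC saturate
within ~10 epochs on the planted-signal cohorts (library defaults remain
128/64/200/20).  Out-of-fold fusion in the repeated-seed comparison uses
k = 5 folds (the construction is identical; fewer fold models).  The
null-soundness check reads chance level as the per-model mean AUC across
seeds: with ~100-case test splits the per-seed null AUC has SE ≈ 0.075,
so single-seed bounds of ±0.1 would fail by chance roughly one run in
five, while the 5-seed mean (SE ≈ 0.03) is a sound criterion.

Degenerate inputs are handled explicitly: empty bags, single-class
splits, and zero-margin contingency tables raise (the last returns p = 1
with a warning, by convention); k in the instance loss shrinks to ⌊n/2⌋
on small bags; CV folds whose held-out part is single-class are excluded
from grid-search means with a warning.

## Known limitations

* The image arm is single-branch (one attention head); the multi-branch
  per-class variant is out of scope.
* Feature encoders are external by design: the package consumes feature
  bags and never touches pixels.
* UMAP runs with `random_state` set, which forces single-threaded layout;
  embeddings are deterministic but slower than the parallel default.
* k-means clusters the 2-D embedding by default (the interpretation
  operates on the projected map); clustering the raw features instead is
  a one-line change the API exposes.
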