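# Methods

`toximpute` studies when *imputation* models — models that use a compound's
known labels in other assays as inputs — outperform conventional QSAR on a
sparse binary compound × assay toxicity matrix. This note records the
models, the synthetic data they are validated on, and the numerical and
design choices a maintainer would want to know.

## The modelling problem

The data object is a sparse label matrix **Y** (compounds × assays, cells
in {toxic, non-toxic, missing}) plus a feature matrix **X** of 2048-bit
Morgan radius-2 fingerprints. Public panels of this kind (Ames strain
batteries, Tox21 receptor/stress panels, ToxCast screens) range from a few
percent to >90% complete per assay, with 3–32% toxic labels — so every
method here must cope with sparsity and class imbalance.

Two evaluation geometries matter:

* **compound-based split** — whole compounds held out; the conventional
  QSAR setting (predicting for novel/virtual compounds).
* **assay-based split** — each assay's observed cells split independently,
  so a compound can be a training example for assay A and a test case for
  assay B. This is the imputation / repurposing setting: fill the gaps of
  a matrix whose compounds are already partially characterised.

## Models

**Single-task baselines.** Per assay: random forest, gradient-boosted
trees (XGBoost, `tree_method="hist"`), or a feed-forward network (sklearn
`MLPClassifier`). All expose probability-of-toxic; the binary call is
`score >= threshold` with a shared default threshold of 0.5. Boosting
defaults include `subsample=0.8`, `colsample_bytree=0.8` so that the
multi-seed protocol (below) sees genuine between-seed variation; these
also act as mild regularisation.

**Masked multi-task network** (`MaskedMultiTaskNet`). One sigmoid output
per assay, ReLU hidden layers, Adam on shuffled minibatches, implemented
directly on numpy. The loss for one compound is the mean binary
cross-entropy over that compound's *observed* assays only; compounds with
no observed assay contribute zero loss and zero gradient. This masking is
what lets a dense network train on a sparse matrix. Fixed epoch budget
(default 60), seeded init and shuffling; `masked_bce` is exposed so the
loss can be checked cell-by-cell against a brute-force average.

**Feature Net** (`FeatureNetClassifier`) — the imputation model.
Step 1 fits a single-task model per assay on the training labels and
fills every unknown cell with its binary call, producing a dense matrix
with per-cell provenance (*experimental* = kept verbatim, *predicted*).
Step 2 refits one model per target assay on the compounds that have an
experimental training label for the target, appending the other
(auxiliary) assays' filled labels — one binary feature per auxiliary — to
the fingerprint. Step 2 reuses step 1's hyperparameters; step 1 and step 2
use distinct child seeds of the run seed. Auxiliary labels are plain 0/1
features with no missing-indicator, because the filled matrix has no
missing cells and experimental and predicted labels share one vocabulary.

Prediction modes:

* **predicted** — auxiliary features are step-1 predictions only; any
  supplied labels are ignored. This is the virtual-compound scenario.
* **experimental** — the test compounds' known labels are used where
  available, step-1 predictions elsewhere. This is the imputation
  scenario.

A target's own held-out label is never an input to its own prediction:
the per-target feature assembly excludes the target column, supplying it
explicitly raises `LeakageError`, and a test poisons all test-cell labels
and asserts the model outputs are unchanged.

Step-1 models are trained once on all training cells and shared by every
step-2 variant (full, pairwise, ranked subsets); only step 2 is refit per
variant.

## Assay relatedness

For assays A (target) and B (auxiliary), computed over the compounds
labelled in both:

* H(A) = −(P_A log₂ P_A + P_a log₂ P_a), with 0·log 0 := 0;
* MI(A,B) = H(A) + H(B) − H(A,B), H(A,B) from the four-cell joint;
* **MI-entropy ratio** = MI(A,B)/H(A) ∈ [0,1] — the fraction of the
  target's information already present in the auxiliary. Asymmetric in
  (A,B); the ranking score for auxiliary selection.

Numerical conventions: MI is clamped at ≥0 against floating-point
negatives; pairs with fewer than `min_overlap=20` co-labelled compounds,
or targets with zero entropy, return NaN (flagged-undefined) rather than
an unstable number. By default relatedness is computed on *training*
labels only (`label_scope="train"`), since ranking auxiliaries on held-out
labels would leak; `label_scope="all"` is available and neither scope is
claimed to be canonical.

## Evaluation protocol

MCC is the primary metric (F1 and ROC-AUC reported alongside; AUC uses
midrank ties). MCC's zero-denominator case returns 0 — standard practice
that keeps assay averages finite for degenerate predictors; an empty
confusion table is NaN.

**Multi-seed aggregation.** Final models are trained under several seeds
with the split held fixed. Within each seed the metric is averaged over
assays first; the median and IQR (linear-interpolation quartiles) are
then taken across seeds.

**GHOST threshold.** From training scores only: bootstrap resamples are
drawn; per resample, each candidate threshold in {0.05, …, 0.55} gets its
ROC point and the candidate closest to (0,1) wins (ties → lowest
candidate); the returned threshold is the median of the per-resample
optima. Defaults: 100 resamples (configurable); single-class resamples
are redrawn; a resample where all candidates are equidistant (constant
scores) contributes the 0.5 fallback. Thresholds are optimised per task.

**Binned analyses.** Test cells are sliced by (a) chemical similarity —
mean Tanimoto to the 5 nearest training compounds of that assay, bins
[0, 0.4), [0.4, 0.6), [0.6, 1], left-closed with the top bin closed (the
bin edges' half-open convention is a package choice; with fewer than five
training compounds all are used, with a warning); and (b) auxiliary-label
availability — the compound's count of train-cell labels in the *other*
assays: 0–1, 2–3, >3. Assays with any bin under `min_per_bin=100` test
cells are excluded from binned reporting (the threshold is configurable
and smaller panels use smaller minima, stated where used).

**Splits.** Fractional test counts round half-to-even with a minimum of
one cell (one per class in stratified mode). `sparsify_training` caps each
assay's training cells (default 1000) by uniform subsampling, never
touching test cells. CV folds for grid search are stratified and drawn
within training data only.

## Synthetic panels

Real Ames/Tox21/ToxCast matrices require downloads and heavy multi-seed
training, so validation runs on a generator with known ground truth.

Latent **mechanisms** drive everything: each assay *loads* a subset of
mechanisms; a compound is toxic in an assay, pre-noise, iff it activates
at least one loaded mechanism. Pairwise assay relatedness is therefore
controlled exactly by loading overlap (`make_related_pair` constructs
pairs with a chosen overlap fraction). Per-mechanism activation
probabilities are calibrated deterministically to per-assay prevalence
targets: the closed-form equal-share solution per assay, averaged per
mechanism, refined by a bounded least-squares pass when loadings overlap
(exact for disjoint loadings and for symmetric shared ones).

Fingerprints carry: structural-alert bits for activated mechanisms,
cluster (scaffold) bits, and sparse random background. The alert signal
is deliberately imperfect — per-bit dropout (0.25), a silent-activation
rate (0.3: an activation leaves no trace), and a spurious-alert rate
(0.1: alert bits without activation). This imperfection is essential to
the phenomenon under study: if fingerprints determined labels exactly, a
single-task model would be near-perfect and auxiliary assay labels could
carry no extra information. With it, an auxiliary assay that shares a
mechanism observes the activation directly and the Feature Net has
something real to gain. When the structured bit budget exceeds the
fingerprint length, bit sets are drawn independently with collisions —
the same aliasing a hashed fingerprint has.

Observed labels are a missing-completely-at-random mask (per-assay
completeness; optionally a per-compound tested-fraction weight emulating
panels where some compounds were screened broadly and others barely —
`compound_completeness_spread`) with independent label flips
(`label_flip_rate`) for experimental noise.

Defaults emulate the public panels' ranges: 2000 compounds, 6 assays with
cyclically overlapping loadings, completeness 0.5, prevalence 0.2, flip
rate 0.05, 2048 bits. Two optional regimes support specific analyses:

* `per_cluster_mechanism_bits` — each (mechanism, cluster) pair gets its
  own alert bits: different chemotypes express the same mechanism through
  different substructures, so models cannot extrapolate to unseen
  scaffolds; `singleton_fraction` adds scaffold singletons whose alert
  substructures are private (random bits), populating the low-similarity
  bin with compounds whose chemistry is genuinely uninformative. The
  similarity-bin study uses 60 scaffold bits at 0.9 incidence so that
  congeneric-series members land in the top similarity bin.
* Denser panels (completeness 0.8, Tox21-like) for the pairwise-heatmap
  and auxiliary-selection studies, where matched assay pairs occur in the
  denser public panels and auxiliary labels must be widely available.

What the generator does *not* emulate: real chemistry (no valid SMILES in
synthetic mode), mechanism correlations with scaffolds, systematic (non-
random) missingness, inter-laboratory batch effects, and continuous
potency values. Passing tests therefore show that each method behaves as
designed when its assumptions hold and that the qualitative orderings
(imputation benefit, its growth with relatedness and label availability,
its concentration outside the applicability domain) emerge from the
stated data-generating process — not that effect sizes transfer to any
particular real panel.

## Problem sizes used in the shipped studies

The test-suite studies use 2000-compound panels, 10 training seeds, and
60-tree boosted models; fingerprint lengths of 512–2048 bits are chosen
per study (shorter where a study sweeps many models). The acceptance
script uses the same panels with 5 training seeds (3 for the 30-model
pairwise sweep). These sizes give stable medians while keeping a full run
in the minutes range on one CPU; they are stated here so results can be
reproduced exactly.

## Known limitations

* The masked multi-task network is a compact numpy implementation: fixed
  epoch budget, no GPU, no early stopping by default. It is adequate for
  panels of thousands of compounds, not millions.
* Macau-style Bayesian matrix factorisation is supported only through the
  `external` learner registry, not reimplemented.
* Hyperparameter grids are configuration, not shipped defaults; the
  shipped defaults are fixed sensible values (recorded in
  `learners.make_estimator`).
* `RDKitBackend` uses RDKit MolStandardize's default normalisation and
  tautomer rules; the exact chemotype-normalisation rule set is therefore
  the toolkit's, documented by the toolkit version.
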