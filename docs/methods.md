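# Methods

This note documents the models and procedures implemented in
`panelboost`, the tunable parameters that matter, the synthetic-data
generator's scope, and the numerical and design choices made where the
design was genuinely open.

## Ensemble recursive feature elimination

Each of three boosted learners ranks genes by its own importance
criterion and RFE removes the weakest ⌈step_fraction × surviving⌉ genes
per iteration (never overshooting the target size; the last step removes
exactly enough to land on it). Defaults: `target_size=30`,
`step_fraction=0.1`, survivors ordered by final-model importance with
ties broken by earlier-iteration importance and then lexicographic gene
id, so results are fully deterministic given the learner seed.

Learner kinds are defined by their importance criterion, not by a vendor:

| kind            | criterion                 | backend  |
|-----------------|---------------------------|----------|
| `gbdt`          | split count ("weight")    | LightGBM |
| `catboost_like` | prediction value change   | XGBoost  |
| `xgboost_like`  | gain                      | XGBoost  |

"Prediction value change" is computed as the mean absolute change of the
model's predicted class probabilities when one feature column is permuted
(seeded, one permutation per feature) — a model-agnostic reading of the
criterion; the tree-internal variant used by CatBoost itself is an
approximation of the same quantity.

Learner hyperparameters default to 200 trees, depth 3, learning rate 0.1,
and per-tree feature subsampling `colsample_bytree=0.3`. The subsampling
term deserves comment: without it, boosting saturates on one or two
discriminative genes, every other informative gene receives zero
importance, and RFE eliminates genuinely discriminative genes early.
Forcing each tree to draw from 30 % of the features spreads importance
across redundant informative genes and makes elimination behave like the
ranking it is meant to be. Tree learners are scale-invariant, so no
standardization is applied before them; gene-wise standardization (zero
mean, unit variance) is applied before ANOVA-adjacent statistics and
clustering.

## Consensus voting

A gene enters the candidate pool with at least `vote_min=2` of 3 subset
memberships. Importance scores of different learners (counts, gains,
probability shifts) are incommensurable, so cross-learner aggregation
uses normalized ranks: a gene at 1-based position r in a subset of size m
scores (r−1)/(m−1) (0 if m=1), averaged over the subsets that contain it.
Final order: votes descending, mean normalized rank ascending, gene id.
If fewer than `final_size` genes reach the vote threshold the short panel
is returned with a warning — the threshold is never silently relaxed.

## Per-gene statistics

One-way ANOVA F per gene: F = (SSB/(g−1)) / (SSW/(n−g)). Constant genes
are degenerate with F = 0; genes with zero within-group variance but real
between-group spread are degenerate with F = ∞ (reported, not hidden).
Degeneracy thresholds use a relative tolerance of 1e−12 against the
gene's total sum of squares. The correlation diagnostic is the Pearson
matrix over the selected genes plus a numerically coded class column
(class-order positions 0, 1, 2 — the stage-progression direction);
zero-variance genes get explicit NaN entries flagged `undefined`.

## Class-conditional GAN

Generator: one-hot class ⊕ noise (dim 8) → two leaky-rectifier hidden
layers of 32 units → linear output on the standardized expression scale.
Discriminator: the mirror-image trunk with a sigmoid source head and a
softmax class head. Both networks are plain numpy with hand-written
backpropagation and Adam; features are standardized per gene on the
training fold and the scaling inverted at generation time.

Losses (probabilities clamped at ε = 1e−7 before logs):

- Loss_x = E log P(real | X_real) + E log P(fake | X_fake)
- Loss_c = E log P(c | X_real) + E log P(c | X_fake)

The discriminator ascends Loss_x + Loss_c. The default generator
objective (`ac_gan_standard`) ascends
E log P(real | X_fake) + E log P(c=intended | X_fake) — the standard
auxiliary-classifier generator. A literal alternative (`paper_literal`)
that descends Loss_x + Loss_c is selectable; note that it pushes fakes
*away* from their intended class (descending E log P(c | X_fake)), which
contradicts the purpose of class-conditional augmentation, so it is not
the default.

Adversarial games on 10–40-sample folds are unstable, so three standard
stabilizers are on by default and configurable:

- **Instance noise** (`instance_noise=1.0`): Gaussian noise added to the
  discriminator's inputs, annealed linearly to zero over the first 80 %
  of epochs; prevents the discriminator from memorizing the handful of
  real points early.
- **Two discriminator steps per generator step**
  (`d_steps_per_g_step=2`): keeps the source/class heads informative.
- **Generator weight averaging** (`ema_decay=0.999`): sampling uses an
  exponential moving average of the generator parameters, damping the
  oscillation of the game around its equilibrium. This was the single
  most important stabilizer in development: it moves class-conditional
  mean matching from roughly three-quarters of gene-class pairs within
  0.5 within-class SD to essentially all of them.

Remaining defaults: 8000 full-batch epochs (mini-batching is meaningless
at fold sizes of ~10–40), Adam at 5e−4. Augmentation volume defaults to
10× the real per-class fold count. An optional discriminator-confidence
filter (`filter_threshold`) rejects and resamples generated vectors whose
class probability falls below the threshold, with a bounded retry budget
and an explicit short-output warning.

## Cross-validation protocol

Stratified folds are dealt per class round-robin after a seeded
within-class shuffle, continuing across classes so fold sizes balance;
per-fold class proportions land within one sample of the global ones, and
classes smaller than k still spread one sample per fold as far as they
go. Inside each fold the GAN is retrained from scratch (fold seed =
base seed + fold index) on the training fold restricted to the panel;
synthetic samples carry an indelible `synthetic:` id prefix, and the run
aborts — it never merely warns — if a synthetic id reaches a test fold or
if the prediction count differs from the original sample count.
Prediction is soft voting: mean of the learners' class-probability
vectors, argmax, ties broken by class order. Accuracy is pooled
(100 × total correct / n) rather than averaged over folds, which stays
well-defined with unequal folds; per-fold accuracies are reported too.

Gene selection runs once on the full dataset before CV, matching the
single-pass flow (selection → augmentation → CV → clustering); this is
optimistic relative to nesting selection inside each fold, and the
pipeline runs each stage exactly once with no outer loop.

## Clustering verification

K-means (Euclidean, 10 restarts keeping the lowest within-cluster sum of
squares, seeded) and agglomerative clustering (ward/average/complete
linkage on Euclidean distances, cut at K) on standardized panel genes;
"agglomerative" and "hierarchical" clustering are one family here, with a
newick dendrogram exported for the latter view. Cluster ids are relabeled
by first appearance in sample order. Alignment to classes: when the
cluster count equals the class count, the cluster→class bijection
maximizing the matched count (Hungarian assignment — equivalent to the
exhaustive permutation maximum); otherwise each cluster maps to its
majority class. Purity is matched count / n under that mapping; the
adjusted Rand index is chance-corrected partition agreement. An optional
grouping map collapses sub-labels (e.g. substages IA and IC into stage I)
before scoring, so stage-level agreement can be computed on
substage-labelled cohorts.

## Synthetic-data generator

The simulator emulates the regime of a small tumour cohort on a large
cDNA array: p genes (default 9600) × (classes × n_per_class) samples
(default 3 × 5), baseline log-intensity-like means drawn once per gene
from N(7, 1), Gaussian within-class noise (`noise_sd`, default 1), and an
optional equicorrelated block structure (consecutive blocks of
`block_size` genes share correlation `block_rho`) standing in for
co-regulated transcripts. Informative genes get class means evenly spaced
by `effect × noise_sd` along the class order — a monotone,
stage-progression-like signal that gives clustering a three-group
structure. Planted genes are spread across distinct correlation blocks
when possible, so within-block redundancy does not blur the ground truth.

What it does **not** model: two-channel dye effects, missing spots, batch
structure, heavy-tailed noise, or realistic gene-gene networks. Passing
tests on this generator therefore demonstrate that the pipeline's
machinery is correct (selection recovers planted signal, augmentation
does not leak, clustering finds separable structure) — not that the
method will attain any particular accuracy on real cohorts.

## Problem sizes used in tests and the acceptance script

Test fixtures use p between 10 and 500 and 5–20 samples per class;
planted-recovery checks use p = 500 with 3 × 20 samples, the GAN checks a
10-gene panel with 20 samples per class, and the chance-level control
pools 20 label permutations of a 60-sample cohort. These sizes exercise
every code path of the full-scale problem (the 9600-gene default remains
available) while keeping a complete run in minutes on one CPU.

## Known limitations

- The three-learner trio shares one backend for two kinds; diversity
  comes from the importance criteria and per-learner seeds, not from
  three independent tree implementations.
- Out-of-fold gene selection (the default single-pass flow) overstates
  CV accuracy relative to fully nested selection; treat the pooled
  accuracy as a panel-quality score, not an unbiased generalization
  estimate.
- GAN quality is judged by class-conditional moment matching and an
  optional discriminator-confidence filter; higher-order structure
  (correlations between panel genes) is not explicitly validated.
- Expression values are taken as-is; any normalization must happen
  upstream or via the documented standardization switches.
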