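# Methods

`ddapre` predicts drug–disease associations (DDAs): given a catalogue of
drugs (SMILES), a catalogue of diseases (MeSH TreeNumbers), and a list
of verified positive pairs, it scores every drug × disease pair for the
probability of a therapeutic association. This note records the models,
the defaults and why, what the synthetic fixtures do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Featurization

**Drugs.** Each molecule is turned into a "sentence" of Morgan
substructure identifiers: for every heavy atom, the canonical hash of
its circular environment at each radius 0..r (default r = 1), in atom
order. When every environment is resolvable the sentence length is
exactly `heavy_atoms × (radius + 1)`; unresolvable environments
contribute a sentinel token so the law stays exact. Sentences train a
skip-gram model (300 dimensions, context window 10 by default) and a
molecule vector is the arithmetic mean of its substructure vectors.
Uniform weights were chosen over frequency weighting because the
unweighted aggregate is the reference behaviour for this family of
embeddings; a frequency-weighted mean is one configuration flag away.
An externally supplied per-drug embedding table (for example a
transformer-derived molecular fingerprint) can be concatenated onto the
skip-gram vector; the package deliberately does not train such a model —
its role is filled entirely by the input table.

**Diseases.** TreeNumbers are dotted hierarchical codes; truncating the
trailing segment of a code yields its parent concept. Repeated
truncation materializes every ancestor, producing a rooted DAG. A
catalogue disease is a single node carrying all of its codes, so a
disease filed under several branches is reachable from several roots and
needs no embedding averaging. Walks are uniform truncated random walks
(default 10 per node, length 40) over the *undirected* neighborhood —
directed walks would trap the walker at leaves, and the transition rule
only requires a neighbor set. Walk sequences train the same skip-gram
machinery at 64 dimensions (window 5). Only the dimension is fixed by
design; walks-per-node, length, and window follow the standard DeepWalk
reference settings and are all configurable.

**Skip-gram trainer.** Both embedders share one SGNS (skip-gram with
negative sampling) implementation: per-position window shrinking,
unigram^0.75 noise distribution, 5 negatives, linearly decaying learning
rate (0.025, floored at 10%), single-threaded and fully seeded. Updates
are applied in small chunks of 64 pairs with summed gradients; within a
chunk, each token's gradient is scaled by the inverse square root of its
multiplicity. Plain summed minibatch gradients diverge on the very small
vocabularies typical of walk corpora (a token can appear dozens of
times in one chunk), while per-token mean gradients undertrain; the
square-root compromise is stable on 10-node graphs and still converges
on larger vocabularies.

## AMDKSU undersampling

The verified-pair space is heavily imbalanced (≈1:7.7). The primary
balancing variant, `ksu_pairs`, clusters the majority class with
K-means (k defaults to `max(2, ⌊√(majority/2)⌋)`; unspecified upstream),
ranks within-cluster sample pairs by a configurable distance metric, and
repeatedly removes one member of each most-similar disjoint pair —
ascending distance, ties broken by row index, the removed member chosen
uniformly at random under the seed — until the retained majority count
equals the target (the minority count by default, i.e. exact 1:1).
Removal proceeds in rounds because a 1:1 target usually requires
deleting more than half the majority, which no single set of disjoint
pairs can do; when only singleton clusters remain, the residual
deletions are uniform random. Within a single round the selected pair
set is provably identical to the global greedy scan of all
intra-cluster pairs, which is what the O(n²) oracle in the test suite
checks.

A second variant, `enn_edit`, is an edited-nearest-neighbor rule:
a sample is marked when at least k/2 of its k nearest neighbors (self
excluded, default k = 5) carry the other label. As written the rule
would edit minority rows too; removal is restricted to the majority
class because the procedure's purpose here is majority filtering. Both
variants exist because the method's prose description and its pseudocode
describe genuinely different procedures; `ksu_pairs` is the default.

Five distance metrics are supported: Euclidean, Hamming, Chebyshev,
Manhattan, Minkowski (p ≥ 1, default 3). Hamming is defined on discrete
vectors, so on continuous embeddings each coordinate is first binarized
by a per-feature median split (the quantizer is configurable); with no
quantizer, raw coordinate inequality is counted. Adaptive metric
selection resamples under each candidate, scores a gradient-boosted-tree
probe by stratified cross-validated AUC on the balanced set, and keeps
the argmax (ties keep the earlier candidate). The pipeline default is
Hamming, which is the metric the adaptive procedure prioritizes for
tree-based models.

Grouped sampling partitions the majority rows by drug and applies KSU
per group under proportional quotas (largest-remainder rounding, capped
at group size with redistribution), so locally balanced groups sum to
the exact global target. Proportional rather than equal quotas were
chosen because equal quotas would annihilate small drug groups.

## F-test selection

Per feature, F is the classic one-way ANOVA ratio of between-group to
within-group variance with the binary label defining the groups.
Degenerate cases: zero within-variance with separated means → +∞ (a
perfect separator, ranked first); a globally constant feature (0/0) → 0,
ranked last. Selection keeps the top k features (default k = 140) by F
descending, ties by index; reported mean-F values ignore infinities.
Selection is applied to the full concatenated drug‖disease vector, since
selection follows feature fusion in the pipeline; a flag can restrict it
to the drug block.

## The training-free one-shot classifier

Fitting performs a single analytic pass: standardization (σ floored at
1e-8), a seeded Gaussian random feature map `z = relu(x̃R + b)` with
h = 1024, PCA to k = 128 components (clamped to the support size), then
weight generation from pooled support statistics. The two hidden layers
of a three-layer residual MLP receive seeded Gaussian matrices scaled by
the global-average-pooled RMS of the support activations, which keeps
the residual map well-conditioned for the support distribution; the
classification layer uses class-wise mean pooling — class prototypes as
weights with a bias of −‖μ_c‖²/2, placing the decision boundary on the
perpendicular bisector of the prototypes. No step anywhere is iterative
and no gradients flow, so refitting per stacking fold is cheap and
deterministic. The published system this mirrors generates weights with
a *pre-trained* hypernetwork; those weights are not reproducible from a
description, so the analytic poolers here are a documented stand-in that
preserves the one-shot, gradient-free contract but is not numerically
equivalent to the published model. Label-swapping the support set
complements the posteriors exactly, and row-order permutation leaves
generated weights unchanged up to float summation noise — both are
regression-tested.

## Stacking ensemble

Level-0: gradient-boosted trees (colsample 0.8, subsample 0.8, learning
rate 0.1, depth 5, 100 trees), CART (min leaf 5, min split 10, unlimited
depth), random forest (min leaf 10, min split 15, depth 5, 30 trees) —
all at random_state 42 — plus the one-shot classifier. Out-of-fold
probabilities from stratified K-fold (default K = 5; the published
10-fold figure refers to outer evaluation) form an (n × 4) matrix; a
logistic regression (L2, C = 1.0) meta-model fits on it, and its learned
coefficients are the ensemble's adaptive weighting. Base learners are
then refit on all rows for inference. The leakage contract — the meta
model sees only out-of-fold columns — is audited by refitting the meta
model from the stored OOF matrix and comparing coefficients.

## Evaluation

Accuracy, precision, sensitivity, specificity, MCC and F1 come from
confusion counts in closed form; zero denominators report 0 with a flag
so imbalanced-table reporting always yields a number. ROC-AUC is the
rank-based Mann–Whitney statistic with ties at half credit — the printed
summation formula upstream is not a computable ROC definition, while the
surrounding text describes the conventional ROC-AUC, so the conventional
statistic is implemented. AUPR is the trapezoidal area under the
threshold-swept precision–recall curve, integrated in sweep order
(recall-sorted integration mis-handles equal-recall ties). Hard labels
threshold at 0.5 unless configured.

In the pipeline, balancing applies to the **training split only**; the
held-out split keeps its natural imbalance. Resampling evaluation data
would inflate every threshold metric, so even if the original protocol
did so, this package deliberately does not.

## Local explanations

For one instance, features are discretized into background quartile
bins; perturbations resample bins uniformly and draw values from the
bin's background moments. Proximity weights are exp(−d²/w²) on the
binary same-bin-as-instance representation (w = 0.75·√d). A weighted
ridge on the binary indicators, after forward selection down to the
displayed feature count (default 25), yields signed contributions with
threshold rules rendered from the instance's bin edges. A constant
scorer produces all-zero contributions with a degeneracy flag. The
explainer targets the full stacked scorer, not an individual base
learner.

## Synthetic fixtures

The generators emulate the study conditions at desk scale: a default
inventory of 27 drugs × 60 diseases (one tenth of the benchmark's
269 × 598) with positive share 0.114 (the benchmark's 11.4%, ≈1:7.7),
toy SMILES from a guaranteed-parseable fragment grammar, and toy
TreeNumbers drawn from a random rooted tree so siblings share ancestor
prefixes. The planted pair dataset draws iid Normal(0, σ²) features and
shifts a known dimension subset by ±effect_size with the label (class
gap 2·effect_size; defaults: 5 planted dims of 64, effect 3, σ = 1),
which makes F-values analytically predictable and gives classifiers a
recoverable margin. What the fixtures do *not* emulate: any dependence
of the label on chemistry or ontology, correlated features, label noise,
or per-drug association structure. Passing tests therefore demonstrate
algorithmic correctness and signal recovery under the stated statistical
model — not predictive performance on curated biomedical data.

Test and acceptance problem sizes — 2,000-pair fixtures, 30–100 seeds
for selection statistics, 5–20 seeds for model medians, 3-fold inner
stacking — were chosen as the smallest sizes at which the checked
statistics are stable across seeds.

## Known limitations

- Pairwise distance ranking is O(n²) per cluster; the resampler targets
  desk-scale inputs (up to a few thousand majority rows).
- The SGNS trainer is a compact reference implementation, not a
  performance-tuned one; corpora in the millions of tokens are out of
  scope.
- The one-shot classifier is a documented analytic stand-in for a
  pre-trained hypernetwork (see above).
- Binary classification only; multi-class association typing is out of
  scope.
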