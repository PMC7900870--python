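# Methods

## The affinity objective

The package's core quantity is the affinity α between a hard clustering
**c** of *n* items and a soft pairwise similarity matrix **S**:

    alpha(c, S) = (1/P) * sum_{j>i observed} [ (c_i = c_j) s_ij + (c_i != c_j)(1 - s_ij) ]

with *P* the number of observed pairs.  For a binary **S** built from a
single partition this is exactly the Rand index, so α generalizes the Rand
index to soft (averaged) and sparse (same/different) similarity data.  For
sparse matrices the sum runs over observed pairs only and is normalized by
their count, keeping α a mean agreement per judged pair; pairs never judged
contribute nothing rather than being imputed.

Judgement counts are carried per pair but do not weight α: a pair judged
once and a pair judged fifty times each contribute one term, with the
fifty-trial pair's value simply better estimated.  (Weighting by counts
would let heavily sampled pairs dominate the objective; the trial-level
cross-validation already propagates their reliability.)

## Optimization

α is maximized by single-item coordinate ascent:

1. start from a uniform-random assignment of the *n* items to *k* clusters;
2. repeatedly propose moving a uniformly random item to a uniformly random
   *other* cluster, accepting iff α strictly increases (ties rejected);
3. after *n(k−1)* consecutive rejections — the maximum number of distinct
   single-item moves — run an exhaustive sweep over all single-item moves;
   apply the best strictly improving move and return to (2), or terminate.

Termination is therefore a *certified* local maximum: no single-item
reassignment improves α.  (The random-proposal process alone cannot certify
this; the sweep is a deliberate strengthening over a purely stochastic
stopping rule.)  The whole procedure restarts from `n_restarts` independent
random initializations and keeps the best α, first occurrence winning ties.

Bookkeeping makes proposals O(1): per item *i* and cluster *b* the sums
M[i,b] = Σ s_ij and O[i,b] = #observed(i,j) over j currently in *b* give the
move gain Δ = (2M[i,b] − O[i,b]) − (2M[i,a] − O[i,a]); an accepted move
updates one column pair in O(n).  Strictness uses an absolute tolerance of
1e−12 on the numerator, which also guarantees termination under floating
point.  The inner loop is numba-compiled, with an identical pure-Python
fallback (both draw the same MT19937 proposal stream, so results do not
depend on the backend).  All randomness flows from one seed: restart *r*
uses subseed *r* of a `SeedSequence`, so restart streams are prefixes — more
restarts can never lower the best α for a fixed seed — and runs are
reproducible.  Empirically the time to stationarity grows roughly linearly
in *n* at fixed *k* (checked as a positive rank correlation, not a slope).

`brute_force_best` enumerates all set partitions into ≤ k blocks
(restricted-growth strings, guarded at 10⁷ candidates) and serves as the
exact oracle in tests; coordinate ascent with 200 restarts matches it on
every random 8-item, 3-cluster instance tried.

## Agreement indices

- Rand index and Hubert–Arabie adjusted Rand index (ARI) are computed from
  the contingency table; `sklearn.metrics.adjusted_rand_score` is used in
  the tests as an independent cross-check, never as the implementation.
- The soft ARI scores a clustering against a *soft* validation matrix:
  `(RI_m − RI_r)/(1 − RI_r)` with RI_m the affinity and RI_r the mean
  affinity of `n_random` (default 1,000) random partitions drawn by uniform
  independent assignment into k clusters, k being the clustering's number of
  non-empty clusters.  An equal-sized-clusters null is available by flag;
  uniform assignment is the default (the simpler null consistent with the
  procedure's description).  RI_r = 1 is degenerate and raised as an error.
- Finite-size caveat: because the chance term conditions on the *observed*
  non-empty cluster count, the soft ARI of unrelated partitions has a small
  negative offset for very small item sets (about −0.03 at n = 14 with
  k = 3), vanishing by n ≈ 30.  On binary validation matrices the soft ARI
  tracks the hard ARI to within ~0.1 (the two chance models differ:
  Monte-Carlo uniform assignment versus the hypergeometric adjustment).

## Choosing the number of clusters

Two procedures, matching the two data paradigms:

- **Sorts, leave-one-participant-out.**  For each candidate k and each
  participant: fit on the averaged similarity matrix of the others, score
  the hard ARI against the left-out partition; choose the k with the best
  fold-averaged ARI.  Raw means are used (no smoothing), ties go to the
  smallest k (parsimony; the tie rule is a package choice).
- **Trials, k-fold.**  Trials are shuffled once (seeded) and dealt into
  folds whose sizes differ by at most one; per fold and k, fit on the
  training folds' accumulated matrix and score the soft ARI against the
  left-out fold's sparse matrix restricted to its observed pairs.  The mean
  curve is then smoothed by Nadaraya–Watson regression with a Gaussian
  kernel whose bandwidth minimizes leave-one-out squared error on the mean
  ARIs (log-spaced search from a quarter of the grid step to the grid
  range); the chosen k is the argmax of the smoothed curve.  A constant
  curve is degenerate: every bandwidth fits equally, the flat curve is
  returned and the smallest k chosen.

Restart budgets default to 100 per (fold, k) fit; 1,000 restarts mirror the
original study scale and are a flag away.  Standard errors across folds are
reported for plotting only.

## Label assignment

Free-sort participants attach 1–5 free-text labels to each of their
categories.  To name a group-level category *g*:

1. For every participant category *c*, binarize both partitions — the
   target category versus all other categories merged into one block — and
   take the hard ARI of the two two-block partitions ("partial" ARI).  A
   category spanning the whole item set has no complement block and is an
   error.
2. Credit every label of *c* with that ARI.  Labels are case-folded,
   whitespace-trimmed and suffix-stripped (plural/-ing/-ed variants share a
   stem; multi-word labels are stemmed per token), and credits are summed
   per stem across participants and uses.  The top stem is the primary
   label.
3. A secondary label is the best-scoring other stem whose embedding cosine
   to the primary is below 0.50 (it contributes a distinct meaning) and
   whose min–max-normalized credit within the category is at least 0.65 (it
   is still strongly associated).  Normalization is applied after summing
   across uses.  Embeddings come through a pluggable provider interface;
   tests ship a deterministic table-backed provider, and no real embedding
   model is required.

The stemmer is a deliberately small built-in suffix stripper (no external
NLP dependency); it handles the inflectional variants that occur in category
labels, not general morphology.

For same/different datasets where labels attach to single (left) images,
categories are named by the vocabulary word whose vector is closest in
cosine to the category's mean unit word-vector.  Category systems are scored
globally by the F-ratio F = (D_between/(k−1)) / (D_within/(N−k)), where
D_between sums squared distances from the grand-mean vector to the category
means — weighted by category size, so the decomposition matches the one-way
ANOVA between-group sum of squares (an unweighted variant is a flag) — and
D_within sums squared distances of members to their category mean.

## Association analyses

Item memberships along several dimensions (votes tallied across
participants, modal category per item, ties lexicographic for stability)
support: phi coefficients between binary category indicators (undefined
coefficients from constant indicators are reported missing, not zero);
Bayes classifiers in three modes — prior-only (always the most probable
category), naive (product of per-predictor posteriors), and joint (full
joint-conditional) — with add-one smoothing on all probability tables
(smoothing constant configurable; the original analyses do not state
their handling of unseen cells) and MAP ties broken toward the higher prior
then lexicographically; and typical/atypical/random item subsets of size m
per category ranked by interparticipant agreement.  LOOCV runs over items
(refit per held-out item on the remaining modal labels) or over participants
(refit on the remaining participants' modal labels; test-time predictors are
those training modes, and predictions are scored against the held-out
participant's raw responses — the source of test-time predictors is a
package choice).

## Baselines

The remove/merge refinement first drops categories whose within-category
"same" proportion is below 0.75 (with their images), then merges surviving
category pairs whose between-category proportion exceeds 0.5, transitively,
as connected components computed in a single pass on the original
proportions (an iterative-recompute variant is behind a flag; the original
description does not say whether proportions are recomputed after merges).
Removal strictly precedes merging.

Alternative clusterers satisfy the contract `(S, k, seed) -> Partition`:
spectral clustering via scikit-learn on the similarity matrix (unobserved
pairs imputed at 0.5, the uninformative value), and a compact
Voronoi-iteration k-medoids on the 1 − s dissimilarity with maxmin
(farthest-point) seeding — random seeding can place two medoids in one block
of a tie-heavy binary distance matrix and then never recover, failing even
noiseless instances.  The benchmark harness plants a truth, simulates
trials over a flip-noise grid, runs every method at the true k, and records
ARIs and fit times, fully seeded; a method raising on an instance is logged
as missing rather than aborting the grid.

## Synthetic data

The generator mirrors the free-sorting study conditions by default: 80
items, 20 participants, six planted categories, participants limited to
3–10 categories of at least two items.  Disagreement is modelled as *item
reassignment*: each simulated participant moves a fraction *d* of items
(exactly `round(d·n)`, uniformly chosen) to uniformly chosen *other*
clusters, so the expected off-truth fraction equals *d*; draws violating
the category-count bounds are resampled with a warning.  Reassignment
rather than pair-flipping is used because participants produce partitions,
and an arbitrary set of pair flips is generally not realizable as a
partition.  Two consequences worth knowing: with k = 2, d = 1 produces the
exact complement (an identical partition up to relabeling), and d = 0.5 is
the point of complete independence.

Same/different trials sample pairs at a configured density (uniformly, or
hub-biased by a product of Zipf-like item weights to emulate crowd-sourced
sparsity) and answer with the truth's co-membership flipped with probability
`flip_prob`.  "Response noise" of ν in the robustness comparisons means a
fraction ν of responses are coin flips, i.e. `flip_prob = ν/2`; at
`flip_prob = 0.5` the data carry no signal at all, so this mapping — which
is approximate, as the original noise mechanism is not fully specified — is
what makes a 50%-noise condition meaningful.  Label pools are disjoint
per-cluster word lists with stem variants (exercising the label-merging
rule) plus optional shared "confusable" words.

What the synthetic studies do *not* emulate: real participants' correlated
idiosyncrasies (noise here is independent across participants and items),
lapses and response times, heterogeneous category granularity, and
semantically meaningful labels.  Passing tests show the machinery recovers
planted structure under these idealized noise models, not that any
particular real dataset will yield a given ARI.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run at deliberately reduced
scale — e.g. the disagreement-robustness sweep plants 5 clusters in 48 items
with 10 participants, 50 restarts per fit and 5 replicates per disagreement
level in {5%, …, 35%} — sizes chosen so the full suite exercises every code
path on a single CPU in well under a minute while leaving the qualitative
conclusions (exact recovery at zero noise, correct-k recovery at ≥ 25%
disagreement, the affinity clusterer's noise robustness) intact.  Key
tolerances: strict-increase epsilon 1e−12; incremental-versus-recomputed α
agreement asserted at 1e−10; argmax ties resolved to the smallest k /
lexicographically throughout for run-to-run stability.
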