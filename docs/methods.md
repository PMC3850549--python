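# Methods

## The task

Gene-function prediction is a hierarchical multi-label classification (HMC)
problem: each gene carries a *set* of functional classes drawn from a
catalogue organised by subsumption — a tree (FunCat-style) or a DAG
(GO-style, classes with multiple parents) — and annotations obey the
*hierarchical constraint*: a class implies all of its ancestors.  Beyond the
genes' own attributes (expression profiles, sequence statistics, phenotypes,
…), protein–protein interaction (PPI) networks carry complementary signal
through guilt-by-association: interacting proteins tend to share function,
so functional annotations are *autocorrelated* across the network, violating
the i.i.d. assumption behind attribute-only learners.

`nhmc` learns predictive clustering trees (PCTs) that use such a network as
background knowledge **during training only**.  At prediction time only the
attributes are consulted, so the model applies to genes whose interactions
are unknown.

## Label representation and distances

A hierarchy of K classes assigns each class a weight

    w(c) = w0 * mean_j w(parent_j(c)),      w(c) = w0 for top-level classes,

with `0 < w0 < 1` (default **0.75**, the long-standing convention of the
CLUS-HMC family; the multi-parent case uses the arithmetic mean exactly as
stated by the recursion).  Weights decrease strictly with depth, so label
disagreements near the root dominate the weighted Euclidean distance

    d(L1, L2)^2 = sum_k w(c_k) * (L1,k - L2,k)^2

between ancestor-closed 0/1 label vectors.  The virtual root is not a vector
component: it is 1 for every example and carries no information.  A worked
check used throughout the tests: two 11-component vectors differing in
exactly 4 components have distance sqrt(4) = 2 under unit weights (a closed
form quoted elsewhere for that example, sqrt(3 w0^2 + 4 w0^3), implies seven
differing components and is inconsistent with the printed vectors; the
package follows the vectors).

## Split statistics

**Variance.**  `Var(U) = (1/|U|) sum_i d(L_i, Lbar)^2` with `Lbar` the mean
label vector.  Because bits are binary this has the exact closed form
`sum_k w_k S_k (1 - S_k/n) / n` in the per-class bit sums `S_k`, which is
what the incremental implementation maintains — it replaces the usual
one-pass mean-update correction and is validated against a brute-force
double loop to 1e-9 relative accuracy.

**Network autocorrelation.**  The Geary-style statistic

    A_Y(U) = 1 - ((N-1) * sum_ij w_ij d(L_i, L_j)^2)
                 / (4 * sum_ij w_ij * sum_i d(L_i, Lbar)^2)

lives on [0, 1]: 1 means linked examples are maximally more similar than the
partition's average spread, 0.5 means no autocorrelation, 0 strong negative.
Under random assignment of a fixed label multiset to nodes its expectation
is exactly 0.5 (the permutation-null acceptance check).  Conventions chosen
where the formula is silent:

* **Degenerate partitions** (no intra-partition edges, n < 2, or zero label
  scatter) score the neutral 0.5, so the heuristic neither rewards nor
  punishes unsupported partitions.
* **Clamping**: adversarial weight configurations can push the raw value
  outside [0, 1]; the result is clamped (logged at debug level).
* **Restriction semantics**: edges crossing a partition boundary contribute
  to neither side — each child's statistic is computed on the subgraph
  induced by its members.
* Squared distances for connected pairs are computed once per tree induction
  and cached per edge; an exact integer count of intra-partition edge terms
  guards the degeneracy test against floating-point residue after long
  sequences of incremental moves.

## Tree induction

Standard top-down PCT induction.  At a node over examples `U`, candidate
tests are

* continuous `X <= beta` with `beta` the midpoints between consecutive
  distinct observed values (b distinct values → b−1 thresholds), swept in
  sorted order so each successive threshold costs only a one-example
  incremental update of both children's statistics;
* discrete `X ∈ B` with `B` grown greedily one value at a time from the
  single best value, while the score keeps improving, never reaching the
  full active domain.

Candidates leaving a child below `min_leaf` (default **5**) are discarded.
Each candidate's variance reduction is then subjected to an F-test at the
configured significance level — the regression-style convention of the
reference PCT systems, `F = (n-2)(SS_parent - SS_pooled)/SS_pooled` with
(1, n−2) degrees of freedom (one parameter gained by a binary split, n−2
residual).  The two-sample variance-ratio convention with (n−1, n−2) df was
evaluated and rejected: at desk-scale n it demands >25 % variance reduction
from a single test and degenerates every tree to a single leaf.  Candidates
failing the test are ineligible; **a leaf is made iff no candidate passes**.
This per-candidate gating matters: gating only the finally chosen test would
couple tree size to the autocorrelation term, so that even a *random*
network shrinks trees — a regularisation artifact, not network information.

Eligible candidates are scored by

    h = alpha * ( Var'(U) - (|U1| Var'(U1) + |U2| Var'(U2)) / |U| )
      + (1 - alpha) * ( |U1| A_Y(U1) + |U2| A_Y(U2) ) / |U|

where `Var'` is the min-max normalisation of `Var` with the range taken over
the node variance together with *every* candidate child variance (two-pass
evaluation; this makes `Var'` well defined before any candidate is scored,
and because the same affine map is applied throughout, rankings at
`alpha = 1` coincide exactly with raw variance-reduction rankings — the
basis of the variance-only equivalence check).  `alpha = 1` reproduces the
classic hierarchy-only tree learner; `alpha = 0` uses autocorrelation alone;
the default is 0.5.  Ties break to the earliest candidate in enumeration
order (lower attribute index, then lower threshold / smaller subset), which
makes induction fully deterministic.

The greedy discrete subset growth needs a score before the normalisation
range exists (a circular dependency), so it uses a surrogate — raw variance
reduction scaled by the node variance plus the exact autocorrelation term —
and the recorded chain is then scored with the fully normalised `h`.

**Missing values.**  Thresholds are computed from non-missing values only;
during candidate scoring missing examples sit in the right child; once a
test is chosen, missing examples are routed to the child that received more
non-missing training examples, and that route is stored in the split for
prediction time.

**Leaves** store the mean label vector of their training examples.  Because
the vectors are ancestor-closed, the mean is automatically monotone along
the hierarchy (ancestor score ≥ descendant score).

## Prediction and evaluation

Scores are the reached leaf's prototype.  Binarisation predicts a class iff
its score strictly exceeds `tau`; any scalar `tau` — or any per-class
threshold map non-decreasing from ancestors to descendants (validated) —
yields ancestor-closed predictions.

Evaluation follows the standard HMC protocol: one precision–recall curve
per class, traced over thresholds 0 to 1 in steps of **0.02** (51 points,
both endpoints included), precision at zero predicted positives anchored at
1; areas by trapezoidal integration over recall after sorting and
de-duplication (best precision per recall); the summary is the average of
per-class areas, uniform `1/|C|` by default or frequency-weighted.  Classes
with no positive test examples have an undefined curve and are excluded
(the `|C|` of the weighting counts included classes).  The fixed grid can
deviate from the threshold-free PR area by up to the grid resolution; this
is a documented artifact, bounded in the tests.

Protocols: a seeded 2/3–1/3 holdout (or explicit id lists) with the network
restricted to training ids before induction, and internal 3-fold
cross-validation over the F-test significance candidates
{0.001, 0.005, 0.01, 0.05, 0.1, 0.125}, selecting the level with the best
mean averaged AUPRC (ties to the smaller level).

## Synthetic benchmark

The generator emulates the study conditions end to end: a complete b-ary
class tree of depth D (optionally DAG-ified by second parents with
probability `dag_prob`); labels by top-down Bernoulli path sampling
(`pi_child = 0.5`) followed by closure; per-class mean shifts of size
`delta` on `attrs_per_class = 2` randomly chosen continuous attributes over
unit-variance noise, plus category-tilted discrete attributes; label noise
as independent bit flips at rate `rho` followed by re-closure; and a
planted-partition network linking pairs sharing a most-specific class with
probability `p_in` (default 0.25) and all other pairs with `p_out` (default
0.02).  Sharing is judged on most-specific classes, so planted
autocorrelation is strongest for the deepest, most fragmented classes.  The
network is planted on the *noise-free* labels (kept as `Y_true`): real
interactomes reflect function itself, while annotation noise lives in the
labels — planting on noisy labels would make the network carry no
information beyond the labels.  One global seed fans out into independent
sub-streams for hierarchy, labels, attributes and network.

What the generator does **not** emulate: scale-free PPI degree
distributions, hundreds-to-thousands of classes with extreme positive-class
imbalance, correlated (assay-driven) edge errors, and systematic
missing-annotation bias.  Passing tests therefore certify the algorithmic
contracts and directional behaviour at desk scale, not performance on real
genomic corpora.

## Behaviour under planted autocorrelation

A dedicated check compares `alpha = 0.5` with `alpha = 1` over 10 seeded
planted-autocorrelation benchmarks (n = 150, 25 continuous attributes at
effect size 0.8, label noise 0.2, `p_in = 0.3 >> p_out = 0.02`; attribute
informativeness was set so the variance-only learner scores a mid-range
averaged AUPRC ≈ 0.55, the regime where background knowledge can matter).
Under this implementation the two settings are statistically
indistinguishable both there and in the matched `p_in = p_out` null — the
network term neither helps nor hurts systematically at this scale, and the
median paired difference is zero.  A node-level analysis explains why a
strict advantage is hard to realise: the per-child statistic is *lower* for
label-homogeneous children (their small scatter amplifies residual noise in
the numerator) and near 1 for mixed children with coherent edges, so
maximising it does not directly reward truth-aligned splits; any benefit
must come from multi-level effects such as keeping network communities
intact for later splits.  The per-candidate F-test gate confines the
autocorrelation term to choosing among statistically supported splits,
which is what keeps the null comparison clean.

## Problem sizes and determinism

All shipped tests and the acceptance script run on generated data with
n ≤ 1000, K ≤ 14, and at most a few hundred edges per instance; the full
suite completes in well under a minute except the planted-autocorrelation
comparison (≈ 1.5 minutes).  Every stochastic component is driven by an
explicit seed; tree induction itself is deterministic, and serialized
models round-trip bit-identically (JSON floats preserve the full double
precision).

## Known limitations

* DAG hierarchies cannot be declared inline in the ARFF dialect (slash
  paths express trees only); use the parent/child TSV.
* Class identifiers must be unique by leaf segment in path declarations.
* No post-pruning, ensembles, multi-way splits, or regression targets.
* `A_Y` significance testing and alternative autocorrelation indices
  (Moran's I, join counts) are out of scope.
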