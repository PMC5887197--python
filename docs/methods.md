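# Methods

## Scope and data model

`phyloclust` clusters a set Π of N phylogenetic trees sharing one leaf set
and summarises each cluster with a consensus tree. Trees are treated
purely topologically: unrooted, leaf-labeled, multifurcations allowed.
Branch lengths, support values and internal labels are accepted on input
and discarded, because the Robinson–Foulds (RF) distance that drives every
downstream computation ignores them. A rooted Newick input is unrooted by
ignoring the degree-2 root (it contributes no bipartition).

Internally a topology is its canonical split set: for each internal edge,
the side of the bipartition not containing the reference leaf (the
lexicographically smallest label), stored as a bitmask over the sorted
labels. Two trees are equal iff their split sets are equal; RF(a, b) is the
size of the symmetric difference of the two split sets. This is the
"both-directions" count, so the maximum over two binary trees on n leaves
is 2(n−3) = 2n−6 and RF between binary trees is always even. Canonical
Newick output orders children by their smallest descendant label, making
outputs diff-stable; `parse(write(T))` reproduces the split set exactly.

## Clustering

The N×N matrix of pairwise RF values (optionally squared, see *Variants*)
is computed once. k-medoids then minimises

    OF_med = Σ_k Σ_{i∈k} d(T^m_k, T_ki),

by Voronoi iteration: from K random distinct medoids, assign every tree to
its nearest medoid, recompute each cluster's medoid (the member minimising
the within-cluster distance sum), repeat until the medoid set is stable or
`max_iter` is reached. The objective is non-increasing across iterations
within a start. PAM-style pairwise swaps are not used: the alternating
iteration with multiple restarts reliably reaches the brute-force optimum
on the small instances where enumeration is feasible (the acceptance
script verifies this), at a fraction of the cost.

Determinism and tie-breaking. All randomness flows from one integer seed
through `numpy` Generators. Every tie breaks toward the smallest tree
index: nearest-medoid assignment, medoid update, the global medoid, and
the best start. A medoid always stays in its own cluster, which keeps all
K clusters nonempty even when two sampled medoids have identical topology
(initial samples avoid duplicate-topology medoids when possible).

Defaults: `n_starts = 30`, `max_iter = 100`. The number of restarts is
chosen so that small instances (N ≤ 8, K = 2) reliably attain the global
optimum of the objective under enumeration; iteration counts in practice
converge in well under 20 steps.

### The consensus-recomputation baseline

`kmeans_consensus_baseline` implements the classical characteristic-trees
formulation for comparison: the cluster centre is the majority-rule
consensus tree, the objective is Σ_k Σ_i RF(maj_k, T_ki) (squared per term
in its classical variant), and the consensus is recomputed after every
single relocation of a tree between clusters; a relocation that would
empty its source cluster is rejected. Starts are seeded like k-medoids
(K random distinct trees, nearest-neighbour assignment) so the comparison
isolates the per-iteration cost. This method exists to be measured
against, not to be fast; the second benchmark protocol records the
wall-clock ratio.

## Validity indices and the choice of K

Both indices consume the same distance matrix as the clustering.

**Silhouette (SH).** a(i) is the mean distance from tree i to the members
of its own cluster with the self term included and denominator N_k — not
the classical N_k − 1. Consequently a singleton cluster scores s(i) = 1
rather than 0. This convention is deliberate: it allows a single outlying
gene tree to be recognised as its own cluster, which real gene-tree
collections do produce. b(i) is the smallest mean distance to a foreign
cluster; s(i) = (b−a)/max(a,b), defined as 0 when max(a,b) = 0 (the tree
is identical to both its own and the nearest foreign cluster). sh(k) is
the mean over cluster k, and SH(K) is the unweighted mean of the K cluster
scores (not the mean over the N trees).

**Caliński–Harabasz (CH).** CH = (SS_B/SS_W)·(N−K)/(K−1), where
SS_W = OF_med for the same partition and SS_B = Σ_k N_k·d(T^m_k, T^m) with
T^m the global medoid. Degenerate cases: SS_W = 0 with SS_B > 0 scores +∞
(perfect separation); SS_B = 0 scores 0.

**Role of the index.** The index is used twice: at fixed K it selects the
best partition among the random starts (ties broken by lower objective,
then earlier start), and across the candidate range it selects K as the
argmax (ties toward smaller K). Neither index is defined for K = 1; a
homogeneous input cannot be diagnosed, and the tools say so rather than
guessing.

### Variants

The squared/unsquared choice is a property of the distance matrix and
propagates unchanged into the objective and into every index formula.
This yields the four method variants SH/CH × RF/RF². Squaring is applied
to matrix entries only; no formula is otherwise altered. (Whether the
squared variant should also square distances inside the indices is an
interpretation; applying the matrix uniformly everywhere is the simplest
consistent reading and is what the implementation does.)

## Consensus construction

Splits are counted across the profile. Strict consensus keeps splits with
count = N; majority keeps splits with count strictly greater than N/2
(an exactly-50% split is excluded), which are pairwise compatible by
construction; extended (greedy) majority appends residual splits in
decreasing frequency, each accepted iff compatible with everything
accepted so far. Equal-frequency residual ties are ordered by the sorted
label tuple of the canonical side, ascending — the classical description
leaves this choice arbitrary; fixing it makes runs reproducible. The
majority tree is also an RF median of its profile, which the test suite
verifies against complete enumeration of the 5-leaf tree space.

## Adjusted Rand Index

ARI is computed from the contingency table with exact integer binomial
arithmetic and a single rational division, so agreement with reference
implementations holds to full double precision. The degenerate case where
the chance-corrected denominator is zero (both partitions all-singletons,
or both a single cluster) is returned as 1: the partitions are then
identical up to relabeling.

## Synthetic data generator

The generator emulates the structure of gene-tree collections produced by
hybridisation/coalescent simulation, using purely topological operators:

* K cluster centres: centre 1 is a uniform-attachment random binary tree;
  each further centre applies h SPR moves to centre 1, h drawn uniformly
  from the divergence range (default 1–4, the hybridisation-rate
  analogue). Centres are resampled until pairwise distinct.
* Cluster members: each member applies m independent NNI moves to its
  centre, with m = max(1, round((n−3)(11−level)/10)) for noise level ≤ 9
  and, at level 10, m ∈ {0, 1} with equal probability. The 1–10 scale
  (10 = low noise) is the coalescence-rate analogue; only its
  monotonicity is meaningful.

What this emulates: the two-scale structure (large inter-cluster
rearrangements vs small intra-cluster perturbations) and seeded,
byte-reproducible output. What it does not: coalescent branch lengths,
sequence evolution and tree estimation error, and any calibrated mapping
from simulator rates to topological distance. Two consequences matter for
interpreting benchmark results. First, because every non-first centre is
derived from centre 1 and a single SPR can change as little as one split,
two centres can end up at RF 2 — no farther apart than the intra-cluster
noise — in which case no index can separate their clusters and merged
solutions are selected; the distinctness rule is deliberately the weakest
precondition rather than a separation guarantee. Second, at the lowest
noise level half the members coincide with their centre, and the
singleton-friendly SH convention can then favour splitting a tight
cluster into identical-topology subgroups. Both effects are visible in
the recovery rates the acceptance script reports, and both are properties
of the stated formulas and generator, not of the optimiser (which is
separately verified against brute force).

### Benchmark protocols

Protocol 1 (known K): for each (K, n, noise) cell, the four variants
cluster the same generated set at the true K, the index picking the best
start, and ARI against the generating labels is recorded. Protocol 2
(known K = 5, noise 5): k-medoids+SH+RF against the consensus-
recomputation baseline (squared RF), recording ARI and wall-clock; the
k-medoids time includes the RF-matrix precomputation, which is part of
the method. Default problem sizes in the shipped tests and acceptance
script are scaled down (20 or fewer trees per cluster, 2 replicates) to
keep full runs in seconds while preserving every qualitative contrast;
the JSON output records the sizes used.

## Known limitations

* All trees must share one leaf set; overlapping-but-unequal leaf sets
  are out of scope.
* K = 1 cannot be selected: both indices are undefined there.
* The RF distance saturates quickly under heavy noise (its maximum is
  2n−6), compressing cluster contrast for small n.
* The greedy consensus tie-break and all smallest-index tie rules are
  conventions chosen for reproducibility, not uniquely principled
  choices.
* k-medoids with restarts is a heuristic; optimality is verified only at
  enumeration scale.
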