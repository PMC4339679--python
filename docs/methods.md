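# Methods

This note records the models implemented in `homclust`, the parameters
that matter, the numerical choices, and what the synthetic benchmark does
and does not establish about real data.

## Similarity model

The input is an all-vs-all homology search result: either 12-column BLAST
tabular rows or a bare `id1 id2 evalue` edge list; profile-search rows
already reduced to `(query, subject, evalue)` triples enter through the
same path and are treated identically downstream. Raw hits violate two
assumptions every graph clusterer makes — one value per pair, and symmetry
— so hits for an unordered pair are collapsed by a user-chosen rule
(`lowest` e-value by default, i.e. the most significant hit, the most
permissive choice for remote homologs; `highest` and `average` are
available because search tools differ in which they effectively use).
Self-hits are dropped, and collapsed pairs with e-value above a permissive
threshold (default 100) are discarded. A missing pair means similarity 0,
not an error: thresholded all-vs-all searches are sparse by construction.

Scores are `s = clip(-log10 e, 0, cap)` with `cap = 350` for `e = 0`
(just below the smallest double-precision e-value's magnitude; its only
role is to keep zero e-values finite and maximal). The transform is
monotone, so any threshold on scores is a threshold on e-values.

## Clusterers

### Markov clustering

Similarities become a column-stochastic matrix; each iteration squares the
matrix (expansion) and then raises it entrywise to the inflation power `I`
with column renormalization. Defaults: convergence when the largest entry
change drops below 1e-6, at most 200 iterations, entries below 1e-8 pruned
during inflation (with a guard that restores a column's largest entry
rather than ever emitting a zero column). Self-loops are added before
normalization — by default each node receives its maximum incident
similarity — which is standard practice to damp the period-2 oscillation
of bipartite-like flow. Clusters are read out from attractor rows
(positive diagonal) of the limit matrix; a node pulled by several attractor
systems goes to the one holding the largest share of its column, ties to
the smallest roster index, so the output is deterministic. Inflation values
at or below 1 are accepted for sweep compatibility but flatten rather than
sharpen flow; they sit outside the classical regime and typically return a
single giant cluster.

### Transitivity clustering

The edit cost of a partition against the threshold graph at `T` is
`sum (T - s)` over same-cluster pairs with `s <= T` plus `sum (s - T)`
over cross-cluster pairs with `s > T`. (The cost of an edit is the margin
`|s - T|`, which penalizes cutting strong edges and adding weak ones;
a flat per-edge cost would make the threshold the only signal.) The
pipeline runs CAST — open a cluster at the unassigned node with most
threshold-graph neighbors, greedily add the unassigned node with highest
average similarity while that average exceeds `T`, evict members whose
average similarity to the rest falls to `T` or below, close when stable —
then refines by steepest-descent single-node moves (scan in roster order,
move a node to whichever cluster, or fresh singleton, most reduces cost,
strict decreases only). Instances with at most `n_max_exact = 10` nodes
additionally get the exact optimum by restricted-growth-string enumeration
(Bell(10) = 115 975 partitions); the exact path is primarily an oracle,
not a production solver. The cheapest candidate is returned, with ties in
the exact search broken toward the lexicographically smallest encoding for
reproducibility.

### Spectral (SCPS-style)

Components with fewer than `min_component_size = 5` proteins are emitted
as final clusters before the spectral stage — flow through a tiny
component cannot be usefully subdivided, and removing them keeps zero-degree
rows out of the operator. `S` is normalized by its global maximum (this
preserves sparsity and relative structure; degree-based pre-normalization
happens in the operator itself), and `L = D^{-1/2} S' D^{-1/2}` is
symmetric with spectrum in [-1, 1] and eigenvalue 1 once per connected
component. Rows of the top-`K` eigenvector matrix are scaled to unit
Euclidean norm — the standard choice; an L1 bound ("rows sum to at most
one") would also be defensible but changes the embedding geometry, and the
unit-sphere form is what K-means separability arguments assume. `K` is
either given or chosen at the largest eigengap with the search capped at
`n/2` to avoid degenerate near-singleton values. K-means runs with 10
k-means++ restarts under a fixed seed; the whole pipeline is deterministic
given that seed.

### HiFix-lite

Stage 1 accepts an edge when fractional identity exceeds `s_min` and
coverage exceeds `c_min` (hits without a coverage value pass only when
`c_min = 0`); connected components are the pre-families. Edges are
weighted by the `-log10` e-value score when positive, else 1, so stronger
homology binds communities more tightly. Stage 2 decomposes each
pre-family by modularity maximization:
`Q = sum_c (w_c / w - (d_c / 2w)^2)`. Because Louvain's node sweeps are
order-sensitive local optimizers — and small weighted graphs exist on
which single-seed Louvain, many-restart Louvain, and greedy agglomeration
all stall more than 10% below the exhaustive optimum at a partition that
no single node move, pair swap, or community merge improves — the stage is
multi-start: several seeded Louvain runs plus several random initial
partitions, each polished by a greedy ascent that applies fast
single-node-move passes and then the best cross-community pair swap
(deltas in closed form over a dense adjacency), repeating until no
operation raises `Q`. All restarts derive from one seed, so the stage is
deterministic. Stage 3 progressively merges the community pair with the
highest inter-connectivity `pi_ql` (ties: larger combined size, then
lexicographically smallest member), recomputing `pi` after each merge
until one cluster remains, and returns the partition with the highest
modularity seen along the trajectory, the starting partition included.
The original pipeline scores merge states with a model-based criterion
(integrated classification likelihood over per-cluster profile HMMs built
from multiple alignments); that requires alignment machinery outside this
package's scope, so modularity — already the stage-2 objective — serves as
the trajectory-selection criterion. Merging operates within pre-families;
nothing can rejoin proteins that stage 1 separated, which matches the
hierarchical intent (stage 1 errs toward over-merging, later stages only
split and re-merge inside).

## Evaluation

`weighted_prf` implements the family-size-weighted scores exactly as
defined in the README. Two reading notes: the per-family maxima for P and
R are taken independently of the F-maximizing cluster, so weighted P and R
may be witnessed by different clusters than F; and since the harmonic mean
of two positives lies between their minimum and maximum, F is bounded by
max(P, R) but not necessarily by each individually. Proteins present in
the reference but absent from the clustering are a hard error — silently
imputing singletons would distort F. Reference classes with one member can
be stripped first (`remove_singletons`); in remote-homology benchmarks
singletons are numerous enough that leaving them in rewards trivial
clusterings.

`grid_sweep` walks a parameter grid in order, evaluates every point, and
returns all rows plus the best (maximum F; ties broken toward fewer
clusters, then earlier grid position — a parsimony preference, since
nothing in the score itself separates tied grid points).

## Synthetic benchmark

The generator emulates the geometry that separates easy from hard
homology-detection regimes directly in e-value space; it does not simulate
sequences. Same-family pairs draw `log10 e` uniformly from [-80, -10] with
probability 0.8; cross-family pairs draw from [-8, 2] with probability
0.05; same-super-family cross-family pairs use the interval midway between
the two at the average of the densities (a weaker, two-level signal).
Log-uniform sampling is used because empirical nearest-neighbor e-value
curves are naturally viewed on a log axis and no parametric form is
implied by them. `difficulty` slides the inter interval down by
`d * (gap + margin)` where `gap = 2` decades is the difficulty-0
separation and `margin` equals the intra width (70 decades): at `d = 0`
the intervals are disjoint, so every intra nearest neighbor is strictly
more significant than every inter one; at `d = 1` the inter interval,
[-80, -70], sits at the most-significant edge of the intra interval and
the nearest-neighbor curves invert, the signature of the hardest
low-identity regime. Percent identity (bounded affine in the score, small
seeded Gaussian noise, capped at 98) and coverage (similar, capped at
0.99) are emitted so identity/coverage-threshold pipelines see a signal
consistent with the e-values. Every protein keeps at least one same-family
edge (re-sampled if density dropped them all): the planted structure is
always represented, so recovery failures are attributable to the method,
not to missing evidence. Defaults (6 families of 4–8 members, one family
per super-family) keep desk-scale runs in the tens of proteins; the
acceptance script states the sizes it uses next to each quantity.

What passing on this generator shows: that each clusterer recovers planted
structure when the e-value geometry permits it, and degrades as the
geometry degrades. What it does not show: behavior under real alignment
artifacts (asymmetric hit lists, length-dependent e-values, domain
chimeras, database-size effects), none of which the generator models.

## Known limitations

- The exact transitivity solver is exponential and capped at 10 nodes; all
  larger instances rely on CAST + local search, which the random-instance
  suite shows is optimal in roughly 90–95% of small cases but carries no
  guarantee.
- The MCL implementation is dense; it targets benchmark-scale matrices
  (hundreds of nodes), not proteome-scale graphs.
- The multi-start community stage is a local optimizer; the ≥95%-of-optimum
  behavior observed on small random graphs is empirical, not guaranteed.
- Profile-search ingestion expects rows already reduced to
  `(query, subject, evalue)`; native profile-search report parsing is out
  of scope.
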