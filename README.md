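# homclust

Graph-based clustering of protein similarity networks, built for the remote
homology regime, with a weighted F-measure benchmark harness and a synthetic
data generator that dials the benchmark from easy to adversarially hard.

## The problem

Detecting protein families — groups of homologous sequences — is usually
done by running an all-against-all similarity search (BLAST for
sequence–sequence comparisons, or a profile–profile search reduced to the
same tabular shape), turning the pairwise e-values into a similarity graph,
and clustering that graph. For close homologs this works well; for *remote*
homologs it breaks down, because a protein's most significant hit is often a
member of a different family: the cumulative curves of each protein's
nearest-neighbor e-value inside vs outside its own family overlap or even
invert. This package implements the full desk-scale machinery to study that
regime: similarity-matrix construction, four clusterers, evaluation, and a
generator that reproduces the separated-to-inverted e-value geometry
without needing any real sequence database.

## The methods

All clusterers consume a symmetric matrix of scores
`s(i,j) = min(-log10 evalue, cap) >= 0` (one value per unordered pair,
self-hits dropped, pairs with e-value > 100 discarded).

- **Markov clustering (MCL)** — similarities become a column-stochastic
  flow matrix; expansion (`M @ M`) alternates with inflation (entrywise
  power `I`, then column renormalization) until convergence; attractor
  systems of the limit matrix are the clusters. `I` controls granularity.
- **Transitivity clustering** — edits the threshold graph
  `{(i,j) : s(i,j) > T}` into a disjoint union of cliques at minimum cost,
  charging `T - s` to add a missing edge and `s - T` to cut a present one
  (weighted transitive graph projection). Pipeline: CAST greedy
  construction, steepest-descent single-node refinement, exact
  set-partition enumeration on small instances, cheapest candidate wins.
- **SCPS-style spectral clustering** — peels connected components smaller
  than 5 as finished clusters, builds `L = D^{-1/2} S' D^{-1/2}` (with `S'`
  the max-normalized similarity and `d_ii = sum_j s'_ij`), embeds proteins
  as the unit-normalized rows of the top-`K` eigenvectors, and groups them
  with seeded K-means; `K` comes from the largest eigengap when not given.
- **HiFix-lite** — low-stringency connected components (identity > s,
  coverage > c) form pre-families; each is split by multi-start Louvain
  modularity optimization; communities are then progressively merged, always
  joining the pair with the highest connectivity
  `pi_ql = (edges between q and l) / (|q| |l|)`, keeping the
  highest-modularity partition along the merge trajectory.

**Evaluation.** With `n_f`, `n_g`, `n_fg` the family, cluster and overlap
sizes, `p_fg = n_fg / n_g`, `r_fg = n_fg / n_f`, the scores are

    F = (1/n) * sum_f n_f * max_g [ 2 p_fg r_fg / (p_fg + r_fg) ]
    P = (1/n) * sum_f n_f * max_g p_fg
    R = (1/n) * sum_f n_f * max_g r_fg

all equal to 1 exactly when the clustering reproduces the reference
partition. Reference classes with a single member can be removed before
evaluation (`remove_singletons`), so trivial all-singleton clusterings are
not rewarded.

## Worked example

```python
import homclust as hc

cfg = hc.SynthConfig(n_families=4, family_size_range=(4, 6), difficulty=0.8, seed=42)
hits, gold = hc.synth_benchmark(cfg)
S = hc.build_matrix(hc.symmetrize(hits, rule="lowest", evalue_threshold=100.0))
print(f"{len(gold.roster)} proteins, {gold.n_classes('family')} families, {len(hits)} hits")

for method in ("mcl", "transclust", "scps", "hifix"):
    params = {"mcl": {"inflation": 2.0}, "transclust": {"threshold": 15.0},
              "scps": {"c": 4}, "hifix": {"s_min": 0.2}}[method]
    clustering = hc.run_method(method, matrix=S, hits=hits, params=params, seed=0)
    rep = hc.evaluate(clustering, gold, level="family")
    print(f"{method:10s}  clusters={rep.n_clusters:2d}  P={rep.weighted_precision:.3f} "
          f"R={rep.weighted_recall:.3f}  F={rep.weighted_f_measure:.3f}")

sweep = hc.grid_sweep("transclust", gold=gold, grid={"threshold": [5, 15, 30, 45, 60, 75]}, matrix=S)
print("best T =", sweep.best["param_threshold"], " best F =", round(sweep.best_f, 3))
```

prints

```
20 proteins, 4 families, 50 hits
mcl         clusters= 3  P=0.727 R=1.000  F=0.818
transclust  clusters= 3  P=0.727 R=1.000  F=0.818
scps        clusters= 4  P=1.000 R=1.000  F=1.000
hifix       clusters= 4  P=1.000 R=1.000  F=1.000
best T = 30  best F = 0.938
```

At difficulty 0.8 the cross-family e-values have slid deep into the
intra-family range, so MCL and transitivity clustering at fixed default
parameters merge two families (perfect recall, precision 0.727), while the
spectral and HiFix pipelines still separate all four; sweeping the
transitivity threshold recovers most, but not all, of the loss (best
F = 0.938 at T = 30). At difficulty 0 every method reaches F = 1.

The four clusterers are also available as scikit-learn-style estimators
(`MarkovClustering`, `TransitivityClustering`, `SCPSClustering`,
`HiFixLite`) with `fit` / `fit_predict`, `labels_` and `get_params`, and
through the `homclust` command line
(`simulate`, `convert`, `cluster`, `evaluate`, `sweep`, `nn-dist`):

```sh
homclust simulate --config synth.toml --out-prefix run1
homclust cluster --edges run1.edges.tsv --method mcl --inflation 2.0 --out run1.mcl.tsv
homclust evaluate --clusters run1.mcl.tsv --gold run1.labels.tsv --level family
```

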