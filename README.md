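# congruity

Split-based congruence analysis between concatenation (supermatrix) trees
and the single-gene trees underlying them.

## The problem

Phylogenomic practice concatenates many gene alignments into one
supermatrix, infers one tree, and reads its high bootstrap proportions (BP)
as confidence. Yet when the same genes are analysed individually — in
prokaryotes especially, where lateral gene transfer (LGT) reshuffles gene
histories — the deeper branches of the concatenation tree are often
recovered by *none* of the individual gene trees: a "tree of tips" whose
deep structure quietly disappears. `congruity` quantifies this, and provides
a seeded simulator to study its causes (sequence length, divergence, LGT
rate) under controlled conditions.

## Core statistics

All statistics are built on **informative splits**: the bipartitions `X|Y`
of the taxon set induced by internal edges of the unrooted topology, with
`|X|,|Y| ≥ 2`. A resolved tree on *n* taxa has exactly *n* − 3 of them.

- **Split pool** — the distinct informative splits across *T* gene trees,
  with per-tree occurrence counts. It ranges from *n* − 3 (all trees agree)
  to *T*(*n* − 3) (no shared split); for 48 trees on 100 taxa, from 97 to
  4,656. Two splits are **compatible** iff one of the four pairwise side
  intersections is empty — equivalently, iff some single binary tree
  contains both.
- **Node score** — for each internal node of the reference tree, the number
  of gene trees containing that node, where containment requires *all*
  informative splits incident to the node (up to three, on the unrooted
  topology; incident leaf edges are vacuously present). Reported as a count
  and as a fraction of *T*.
- **Topological distance to tips** — the mean number of edges from a node
  to its descendant leaves; separates "tip" nodes from deep ones.
- **Covariates and comparisons** — average pairwise percent identity, mean
  ungapped sequence length, alignment length and mean BP per family;
  length-sorted bins scored by distinct-split counts; Pearson correlations;
  one-way ANOVA with Tukey–Kramer pairwise comparison of node-score
  distributions; hierarchical clustering of trees under the
  Robinson–Foulds (shared-split) distance.

The simulator draws a Yule species tree, derives each gene tree by a
configurable number of SPR moves (the topological signature of LGT), and
evolves amino-acid alignments under WAG with 4-category discrete-gamma rate
variation and a zipf(1.6, max 100) indel process at rate 0.0011 per site
per unit branch length. A built-in NJ + bootstrap inferrer (Poisson-corrected
distances) closes the loop from alignments back to trees, so alignment
length and inference noise act exactly as they do in real pipelines.

## Worked example

```python
import congruity as cg

config = cg.SimConfig(
    n_taxa=50, n_families=48, root_length=(100, 800), lgt_events=3, seed=42
)
model = cg.CongruenceAnalysis.from_simulation(
    config, infer_trees=True, bootstrap_replicates=25
)
results = model.fit(bin_size=4)
print(results.summary())
results.save("report/")
```

prints

```
Congruence analysis
===================
taxa:            50
gene trees:      48
internal nodes:  48

split pool size: 665  (bounds: 47 total congruence, 2256 total incongruence)
mean node score: 26.73 of 48 (55.7% +/- 33.9%)
mean reference BP: 100.0

correlations (Pearson):
  bin_mean_sequence_length~distinct_splits: r = -0.457 (P = 0.135, n = 12)
  bin_mean_sequence_length~mean_support: r = +0.849 (P = 0.000472, n = 12)
  mean_sequence_length~mean_support: r = +0.717 (P = 9.98e-09, n = 48)
  alignment_length~mean_support: r = +0.696 (P = 3.85e-08, n = 48)
  pairwise_identity~mean_support: r = -0.241 (P = 0.0986, n = 48)
  mean_sequence_length~pairwise_identity: r = -0.100 (P = 0.497, n = 48)

node scores by depth class (ANOVA F = 26.15, P = 2.91e-08):
  shallow vs intermediate: diff = +0.463, P = 8.12e-06 *
  shallow vs deep: diff = +0.542, P = 8.46e-07 *
  intermediate vs deep: diff = +0.079, P = 0.749
```

Reading it: 48 gene trees with 3 LGT events each pool 665 distinct splits —
far from the 47 of perfect agreement — while the concatenation (NJ on the
supermatrix) tree is fully bootstrap-supported (mean BP 100). The average
internal node of the concatenation tree is recovered by only 56% of the
gene trees, and the recovery is strongly depth-structured: shallow nodes
are corroborated, deep nodes are not, although every one of them carries
high BP. Bootstrap support of individual families rises with sequence
length (r = +0.72), not with sequence conservation — the site-sampling
mechanism, not divergence, drives it.

`results.save()` writes `node_scores.tsv`, `split_pool.tsv`,
`split_depth.tsv`, `families.tsv`, `bins.tsv`, `correlations.tsv`,
`depth_comparison.tsv`, an annotated newick
(`[&node_score_count=...,node_score_fraction=...]` comments, readable by
common tree viewers) and a manifest; identical inputs reproduce the report
byte for byte.

The same analyses run from the shell:

```bash
congruity simulate --n-taxa 50 --families 48 --length 100:800 --lgt 3 --seed 42 --out data/
congruity analyze --trees 'data/fam*.nwk' --reference data/species_tree.nwk \
    --alignments 'data/fam*.fasta' --out report/
congruity full --n-taxa 50 --families 48 --length 300 --seed 1 --out report/
```

`analyze` accepts externally built trees (e.g. ML trees with bootstrap
labels) and alignments; covariate sections degrade gracefully when
alignments are absent.

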