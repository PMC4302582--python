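# Methods

## Splits and their algebra

Trees are held as `dendropy.Tree` objects; all congruence statistics are
computed on the unrooted topology. A split is stored as a bitmask over the
lexicographically sorted taxon labels, canonicalised to the side that
excludes the smallest taxon, so each bipartition has one representation and
the two root edges of a rooted binary tree collapse to one split. Only
informative splits (both sides ≥ 2) enter any statistic; trees with
polytomies simply contribute fewer splits. Compatibility uses the
four-intersection criterion (two splits can co-occur in a binary tree iff
one of the four side intersections is empty); the test suite checks this
against exhaustive enumeration of all resolved trees for up to 8 taxa, and
the Robinson–Foulds distance against dendropy's independent implementation.

## Node scores

An internal node of the reference tree is counted as present in a gene
tree when every informative split incident to it (parent edge plus child
edges, unrooted) occurs in that gene tree. Two conventions needed fixing:

- Incident edges leading to single leaves impose no condition — otherwise
  cherry ancestors could never be recovered.
- The root of a rooted reference contributes a node whose condition is its
  two child splits (one split if they coincide unrooted). A reference
  supplied in unrooted (trifurcating-root) form therefore yields n − 2
  internal rows, a strictly bifurcating rooted one n − 1.

Node depth is the mean edge count from the node to its descendant leaves
("topological distance to tips"); for the split depth/frequency table each
split's depth is taken at the child node of its edge in the source tree's
rooted representation, kept per tree and averaged over the trees containing
the split, with the shallower node used where a rooted tree's two root
edges name the same split.

## Statistical layer

Pairwise identity divides identical columns by columns ungapped in *both*
sequences (pairs with no co-ungapped column are excluded with a warning).
Length bins sort families by mean ungapped length ascending and drop a
trailing remainder explicitly. Pearson correlation and one-way ANOVA come
from scipy; the pairwise comparison of node-score distributions is
Tukey–Kramer (`scipy.stats.tukey_hsd`), the documented default of the usual
`multcompare`-style workflow, with simultaneous confidence intervals at the
chosen alpha (default 0.05). Tree clustering feeds the pairwise RF matrix
to `scipy.cluster.hierarchy` (average linkage by default; configurable —
no single linkage choice is canonical for this use). Within one fitted
analysis, node-score fractions are compared across depth classes (shallow
≤ 2 edges to tips, deep ≥ 4, intermediate between); the test suite
verifies the procedure's family-wise error rate by simulation.

## Synthetic data

The generator's defaults describe one study condition, chosen once:

- **Species tree**: Yule (birth rate 1, death 0), n = 50 taxa by default,
  branch lengths rescaled so the root height is `tree_scale` = 1
  substitution/site — leaf-to-leaf divergences up to ≈ 2, matching the
  divergence regime of deep bacterial datasets (average pairwise identities
  in the 30–60% range).
- **Gene trees**: each family's tree is the species tree after `lgt_events`
  SPR moves (default 0; fixed count or Poisson). A move prunes a uniformly
  chosen subtree and regrafts it onto a uniformly chosen edge outside it;
  edges on the unrooted edge of the pruning gap are excluded, so every
  accepted move changes the unrooted topology. The regraft point bisects
  the target edge; the moved subtree keeps its stem length. Ground truth
  (moved clade, landing clade) is logged per event.
- **Sequences**: WAG exchangeabilities and frequencies (bundled as plain
  text under `congruity/data/`, generator rescaled to one expected
  substitution per site per unit branch length), discrete-gamma rate
  variation with 4 equal-probability categories, shape 1.0 by default (a
  typical protein-family estimate; categories are assigned per site at
  creation and inherited). Transition matrices come from one spectral
  decomposition of the symmetrised generator, not per-branch expm calls.
  Indels: insertions and deletions each arrive as Poisson events at rate
  0.0011 per site per unit branch length (the single-rate convention of
  DAWG-style simulators, applied to both processes), with lengths drawn by
  inversion from a zipf distribution, exponent 1.6 truncated at 100.
  Insertion opportunities follow the immortal-link convention (L + 1 slots);
  deletions overhanging the sequence end are truncated. Indels are applied
  after substitutions within a branch — an approximation to the joint
  process that is immaterial at these rates. Insertion columns receive
  fresh column identities spliced into a global column order, so leaves
  emerge as a true multiple alignment; root length is an integer or a
  per-family uniform range.
- **Determinism**: one `SeedSequence` fans out to the species tree and each
  family; identical configs give byte-identical FASTA/newick output.

What the generator does *not* emulate: alignment error (sequences are
emitted aligned; the real MAFFT stage is bypassed, which the original
length-effect experiments showed to be immaterial), gene duplication/loss
and paralogy, compositional heterogeneity across lineages, and
model misspecification between simulation and inference beyond the
NJ-vs-truth gap. Passing tests therefore demonstrate the *mechanisms*
(length, LGT and depth effects) under a correctly specified model, not the
magnitudes of any particular empirical dataset.

## Internal inference

The built-in inferrer is distance-based: Poisson-corrected amino-acid
distances d = −ln(1 − p·20/19) over co-ungapped columns (saturated pairs
capped at 10 substitutions/site with a warning), neighbor joining with the
Studier–Keppler update, ties broken on the smallest index pair, negative
branch estimates clamped to zero. NJ is exact on additive matrices
(property-tested) and, unlike ML, desk-cheap — that is the deliberate
trade: the congruence claims under test concern tree *sets*, not the
inference engine, and externally built ML trees are accepted as inputs
everywhere. Bootstrap support resamples columns with replacement, re-infers
with NJ, and scores each informative split of the point tree by the
percentage of replicates containing it; a supplied point tree (e.g. an
externally built topology) can be scored the same way.

## Problem sizes

The shipped tests and the acceptance script run the simulations at 24–100
taxa, 12–50 families, alignment lengths 150–1000, bootstrap replicates ≤ 25
and ≤ 20 replicate datasets per experiment — sizes at which every reported
effect (pool inflation at short lengths, BP–length coupling, node-score
decline with LGT rate, the tip-vs-deep contrast) is already unambiguous
while the whole battery completes in a few minutes on one CPU.

## Known limitations

- NJ under-resolves saturated datasets more gracefully than ML would, so
  absolute split-pool sizes at extreme divergence are not comparable with
  ML-based numbers; directions and orderings are.
- The SPR model draws prune and regraft edges uniformly; real LGT is biased
  toward relatives, so the simulator's incongruence per event is, if
  anything, conservative (uniform moves displace larger clades more often).
- `evolve_alignment` requires branch lengths; ultrametricity is not
  assumed anywhere.
- Newick support values are read from numeric internal labels or bracketed
  branch comments; exotic annotation dialects (NHX, BEAST-style vectors)
  are not parsed.
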