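"""Bipartition (split) algebra on a fixed taxon set.

Every congruence statistic in this package reduces to operations on
*informative splits*: the bipartitions of the taxon set induced by internal
edges of the unrooted tree, restricted to those with at least two taxa on
each side. Splits are stored as bitmasks over the lexicographically sorted
taxon labels, canonicalised so that the stored side excludes the smallest
taxon — each bipartition then has exactly one representation and pools are
plain hash maps.

The *split pool* of a tree collection is the multiset of informative splits
across the collection, with per-tree occurrence counts. For T fully resolved
trees on n taxa the pool size ranges from n−3 (all trees identical) to
T·(n−3) (no shared split): e.g. 97 to 4,656 for 48 trees on 100 taxa.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import dendropy
import pandas as pd

from .io import ValidationError, check_common_taxa

__all__ = [
    "TaxonSet",
    "Split",
    "SplitPool",
    "extract_informative_splits",
    "are_compatible",
    "build_split_pool",
    "rf_split_distance",
]


class TaxonSet:
    """An ordered, deduplicated taxon-label collection (lexicographic order)."""

    __slots__ = ("labels", "index", "full_mask")

    def __init__(self, labels):
        self.labels: tuple[str, ...] = tuple(sorted(set(labels)))
        self.index: dict[str, int] = {t: i for i, t in enumerate(self.labels)}
        self.full_mask: int = (1 << len(self.labels)) - 1

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other) -> bool:
        return isinstance(other, TaxonSet) and self.labels == other.labels

    def __hash__(self) -> int:
        return hash(self.labels)

    def __repr__(self) -> str:
        return f"TaxonSet(n={len(self)})"

    def mask_of(self, taxa) -> int:
        m = 0
        for t in taxa:
            m |= 1 << self.index[t]
        return m

    def taxa_of(self, mask: int) -> tuple[str, ...]:
        return tuple(
            t for i, t in enumerate(self.labels) if mask >> i & 1
        )


class Split:
    """A canonical bipartition of a :class:`TaxonSet`.

    ``mask`` marks the side *not* containing the first (smallest) taxon.
    """

    __slots__ = ("taxon_set", "mask")

    def __init__(self, taxon_set: TaxonSet, mask: int):
        if mask & 1:
            mask = taxon_set.full_mask & ~mask
        self.taxon_set = taxon_set
        self.mask = mask

    @classmethod
    def from_taxa(cls, taxon_set: TaxonSet, taxa) -> "Split":
        return cls(taxon_set, taxon_set.mask_of(taxa))

    @property
    def side_sizes(self) -> tuple[int, int]:
        k = self.mask.bit_count()
        return (k, len(self.taxon_set) - k)

    @property
    def is_informative(self) -> bool:
        k = self.mask.bit_count()
        return 2 <= k <= len(self.taxon_set) - 2

    def smaller_side(self) -> tuple[str, ...]:
        k, other = self.side_sizes
        mask = self.mask if k <= other else self.taxon_set.full_mask & ~self.mask
        return self.taxon_set.taxa_of(mask)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Split)
            and self.mask == other.mask
            and self.taxon_set.labels == other.taxon_set.labels
        )

    def __hash__(self) -> int:
        return hash(self.mask)

    def __repr__(self) -> str:
        side = ",".join(self.smaller_side())
        return f"Split({side} | ...)"


def _require_same_taxa(s1: Split, s2: Split) -> None:
    if s1.taxon_set.labels != s2.taxon_set.labels:
        raise ValidationError("splits are over different taxon sets")


def are_compatible(s1: Split, s2: Split) -> bool:
    """Four-point compatibility: the two bipartitions can occur in one
    binary tree iff at least one of the four side intersections is empty."""
    _require_same_taxa(s1, s2)
    full = s1.taxon_set.full_mask
    a, b = s1.mask, s2.mask
    return (
        a & b == 0
        or a & ~b & full == 0
        or ~a & b & full == 0
        or ~a & ~b & full == 0
    )


def _clade_masks(tree: dendropy.Tree, taxon_set: TaxonSet) -> dict:
    """Postorder map node -> bitmask of leaves below it."""
    masks = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            masks[node] = 1 << taxon_set.index[node.taxon.label]
        else:
            m = 0
            for c in node.child_nodes():
                m |= masks[c]
            masks[node] = m
    return masks


def extract_informative_splits(
    tree: dendropy.Tree, taxon_set: TaxonSet | None = None
) -> frozenset[Split]:
    """Informative splits of the unrooted topology, one per internal edge.

    Rooted trees are treated as unrooted: the two edges at a bifurcating
    root induce the same bipartition and are counted once (canonicalisation
    collapses them). A fully resolved tree on n ≥ 4 taxa yields exactly
    n − 3 splits; trees with fewer than 4 leaves yield the empty set.
    """
    if taxon_set is None:
        taxon_set = TaxonSet(l.taxon.label for l in tree.leaf_node_iter())
    masks = _clade_masks(tree, taxon_set)
    out = set()
    for node, mask in masks.items():
        if node.parent_node is None or node.is_leaf():
            continue
        s = Split(taxon_set, mask)
        if s.is_informative:
            out.add(s)
    return frozenset(out)


@dataclass
class SplitPool:
    """Distinct informative splits of a tree set with occurrence counts."""

    taxon_set: TaxonSet
    n_trees: int
    counts: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.counts)

    @property
    def min_possible(self) -> int:
        """Pool size under total congruence of resolved trees: n − 3."""
        return len(self.taxon_set) - 3

    @property
    def max_possible(self) -> int:
        """Pool size under total incongruence of resolved trees: T·(n − 3)."""
        return self.n_trees * (len(self.taxon_set) - 3)

    def count(self, split: Split) -> int:
        return self.counts.get(split, 0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for split, c in self.counts.items():
            small = split.smaller_side()
            k, other = split.side_sizes
            rows.append(
                {
                    "split": ",".join(small),
                    "side_size": min(k, other),
                    "other_side_size": max(k, other),
                    "n_trees": c,
                    "fraction": c / self.n_trees,
                }
            )
        df = pd.DataFrame(
            rows,
            columns=["split", "side_size", "other_side_size", "n_trees", "fraction"],
        )
        return df.sort_values(
            ["n_trees", "split"], ascending=[False, True]
        ).reset_index(drop=True)


def build_split_pool(trees, taxon_set: TaxonSet | None = None) -> SplitPool:
    """Pool the informative splits of a tree collection.

    All trees must share one leaf set; each tree contributes its split set
    once (a split's count is the number of trees containing it).
    """
    trees = list(trees)
    labels = check_common_taxa(trees)
    if taxon_set is None:
        taxon_set = TaxonSet(labels)
    counter: Counter = Counter()
    for t in trees:
        counter.update(extract_informative_splits(t, taxon_set))
    return SplitPool(taxon_set=taxon_set, n_trees=len(trees), counts=dict(counter))


def rf_split_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson–Foulds distance: size of the symmetric difference of the
    two trees' informative split sets."""
    labels = check_common_taxa([t1, t2])
    ts = TaxonSet(labels)
    s1 = extract_informative_splits(t1, ts)
    s2 = extract_informative_splits(t2, ts)
    return len(s1 ^ s2)
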