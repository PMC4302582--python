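"""Covariates and statistical comparisons for gene-family sets.

Per-family covariates mirror the usual phylogenomic summaries: mean ungapped
sequence length, alignment length, average pairwise percent identity and mean
bootstrap proportion of the family tree. Families can be binned by mean
sequence length and each bin summarised by the number of distinct splits its
trees exhibit — the length-vs-incongruence analysis — alongside Pearson
correlations, one-way ANOVA with Tukey–Kramer pairwise comparisons of
node-score distributions, and hierarchical clustering of trees under the
split (RF) distance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as st
from scipy.spatial.distance import squareform

from .io import Alignment, ValidationError, check_common_taxa
from .splits import TaxonSet, extract_informative_splits

__all__ = [
    "GeneFamily",
    "LengthBin",
    "avg_pairwise_identity",
    "mean_tree_support",
    "bin_families_by_length",
    "distinct_splits_in_bin",
    "pearson",
    "compare_node_score_groups",
    "cluster_trees",
]


@dataclass
class GeneFamily:
    """One gene family: its alignment, its tree, and summary covariates."""

    family_id: str
    alignment: Alignment | None = None
    tree: dendropy.Tree | None = None
    mean_sequence_length: float | None = None
    alignment_length: int | None = None
    pairwise_identity: float | None = None
    mean_support: float | None = None

    def compute_covariates(self) -> "GeneFamily":
        if self.alignment is not None:
            self.mean_sequence_length = self.alignment.mean_ungapped_length
            self.alignment_length = self.alignment.length
            self.pairwise_identity = avg_pairwise_identity(self.alignment)
        if self.tree is not None:
            self.mean_support = mean_tree_support(self.tree)
        return self


def _encode(alignment: Alignment) -> np.ndarray:
    arr = np.frombuffer(
        "".join(alignment.seqs).encode("ascii"), dtype=np.uint8
    ).reshape(alignment.n_sequences, alignment.length)
    return arr


def avg_pairwise_identity(alignment: Alignment) -> float:
    """Mean percent identity over all unordered sequence pairs.

    For each pair, identity = identical columns / columns ungapped in both
    sequences × 100. Pairs with no co-ungapped column are excluded with a
    warning; if every pair is excluded a :class:`ValidationError` is raised.
    """
    if alignment.n_sequences < 2:
        raise ValidationError("pairwise identity needs at least 2 sequences")
    arr = _encode(alignment)
    gap = ord("-")
    ungapped = arr != gap
    idents = []
    skipped = 0
    for i, j in itertools.combinations(range(alignment.n_sequences), 2):
        both = ungapped[i] & ungapped[j]
        denom = int(both.sum())
        if denom == 0:
            skipped += 1
            continue
        same = int((arr[i][both] == arr[j][both]).sum())
        idents.append(100.0 * same / denom)
    if skipped:
        warnings.warn(
            f"{skipped} sequence pair(s) share no ungapped column; excluded"
        )
    if not idents:
        raise ValidationError("no sequence pair shares an ungapped column")
    return float(np.mean(idents))


def mean_tree_support(tree: dendropy.Tree) -> float | None:
    """Mean bootstrap proportion over internal nodes carrying a support
    value; ``None`` when no node does."""
    values = [
        node.support
        for node in tree.preorder_internal_node_iter()
        if getattr(node, "support", None) is not None
    ]
    if not values:
        return None
    return float(np.mean(values))


@dataclass
class LengthBin:
    """A length-sorted bin of gene families with its split summary."""

    index: int
    families: list = field(default_factory=list)
    mean_sequence_length: float = 0.0
    distinct_splits: int | None = None
    mean_support: float | None = None

    @property
    def size(self) -> int:
        return len(self.families)


def bin_families_by_length(families, bin_size: int = 5) -> list[LengthBin]:
    """Sort families by mean ungapped sequence length (ascending) and
    partition into consecutive bins of ``bin_size``; a trailing remainder
    is dropped with a warning."""
    if bin_size < 2:
        raise ValidationError("bin_size must be at least 2")
    families = sorted(families, key=lambda f: f.mean_sequence_length)
    n_bins, remainder = divmod(len(families), bin_size)
    if remainder:
        warnings.warn(
            f"{remainder} famil{'y' if remainder == 1 else 'ies'} dropped "
            f"from the last (incomplete) length bin"
        )
        families = families[: n_bins * bin_size]
    bins = []
    for b in range(n_bins):
        members = families[b * bin_size : (b + 1) * bin_size]
        supports = [
            f.mean_support for f in members if f.mean_support is not None
        ]
        bins.append(
            LengthBin(
                index=b,
                families=members,
                mean_sequence_length=float(
                    np.mean([f.mean_sequence_length for f in members])
                ),
                distinct_splits=distinct_splits_in_bin(members),
                mean_support=float(np.mean(supports)) if supports else None,
            )
        )
    return bins


def distinct_splits_in_bin(families) -> int:
    """Size of the union of the member trees' informative split sets."""
    trees = [f.tree for f in families]
    labels = check_common_taxa(trees)
    ts = TaxonSet(labels)
    union = set()
    for t in trees:
        union |= extract_informative_splits(t, ts)
    return len(union)


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided P value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValidationError("pearson needs two equal-length series, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined: a series has zero variance")
    r, p = st.pearsonr(x, y)
    return float(r), float(p)


def compare_node_score_groups(
    groups, alpha: float = 0.05, labels=None
) -> pd.DataFrame:
    """One-way ANOVA with Tukey–Kramer pairwise comparisons.

    ``groups`` is a sequence of ≥ 2 collections of node-score fractions.
    Returns one row per group pair: mean difference, simultaneous
    (1 − alpha) confidence interval, adjusted P, and a significance flag.
    The overall ANOVA F and P are attached as ``DataFrame.attrs['anova']``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    for g in groups:
        if g.size < 2:
            raise ValidationError("each group needs at least 2 values")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    f_stat, f_p = st.f_oneway(*groups)
    res = st.tukey_hsd(*groups)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "mean_diff": float(np.mean(groups[i]) - np.mean(groups[j])),
                "ci_low": float(ci.low[i, j]),
                "ci_high": float(ci.high[i, j]),
                "p_adj": float(res.pvalue[i, j]),
                "significant": bool(res.pvalue[i, j] < alpha),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["anova"] = {"F": float(f_stat), "P": float(f_p)}
    return df


def cluster_trees(trees, linkage: str = "average", n_clusters: int | None = None):
    """Hierarchically cluster trees by pairwise split (RF) distance.

    Returns ``(Z, flat_labels, dist_matrix)``: the scipy linkage matrix, a
    flat cluster assignment (at ``n_clusters`` if given, else clusters of
    topologically identical trees, i.e. a zero-height cut), and the square
    distance matrix.
    """
    from .splits import rf_split_distance

    trees = list(trees)
    if len(trees) < 2:
        raise ValidationError("need at least two trees to cluster")
    labels = check_common_taxa(trees)
    ts = TaxonSet(labels)
    split_sets = [extract_informative_splits(t, ts) for t in trees]
    n = len(trees)
    dist = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = len(split_sets[i] ^ split_sets[j])
        dist[i, j] = dist[j, i] = d
    Z = sch.linkage(squareform(dist, checks=False), method=linkage)
    if n_clusters is not None:
        flat = sch.fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        flat = sch.fcluster(Z, t=0, criterion="distance")
    return Z, flat, dist
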