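"""Node-score congruence between a reference tree and a set of gene trees.

An internal node of the reference (typically concatenation) tree is *present*
in a gene tree when every informative split incident to that node — its
parent-edge split and its child-edge splits, on the unrooted topology — is
present in the gene tree. Incident edges leading to single leaves carry no
informative split and are vacuously present, so cherry ancestors can match.
The *node score* of a reference node is the number of gene trees in which it
is present; it is reported both as a count and as a fraction of the gene-tree
set.

Node depth is summarised as the topological distance to the tips: the mean
number of edges from the node to its descendant leaves. Shallow nodes
("tips") have distance near 1; deep nodes sit many edges above their leaves.
"""

from __future__ import annotations

import dendropy
import pandas as pd

from .io import ValidationError, check_common_taxa, _min_descendant_label
from .splits import Split, TaxonSet, _clade_masks, extract_informative_splits

__all__ = [
    "internal_nodes",
    "node_adjacent_splits",
    "node_score",
    "topo_distance_to_tips",
    "split_depth_distribution",
    "annotate_reference_tree",
]


def internal_nodes(tree: dendropy.Tree) -> list:
    """Internal nodes in a deterministic order (preorder over children
    sorted by smallest descendant label), each assigned a ``congruity_id``
    of the form ``N001``."""
    nodes = []

    def visit(node):
        if node.is_leaf():
            return
        nodes.append(node)
        for c in sorted(node.child_nodes(), key=_min_descendant_label):
            visit(c)

    visit(tree.seed_node)
    for i, node in enumerate(nodes, start=1):
        node.congruity_id = f"N{i:03d}"
    return nodes


def node_adjacent_splits(
    tree: dendropy.Tree,
    node,
    taxon_set: TaxonSet | None = None,
    _masks: dict | None = None,
) -> frozenset[Split]:
    """The informative splits of the (up to three) edges incident to an
    internal node on the unrooted topology.

    The parent edge contributes the node's own clade split; each child edge
    contributes the child's clade split. At the root only child edges exist
    (the root's two edges are one unrooted edge, already covered by its
    children). Edges to single leaves contribute nothing.
    """
    if node.is_leaf():
        raise ValidationError("node_adjacent_splits requires an internal node")
    if taxon_set is None:
        taxon_set = TaxonSet(l.taxon.label for l in tree.leaf_node_iter())
    masks = _masks if _masks is not None else _clade_masks(tree, taxon_set)
    out = set()
    candidates = []
    if node.parent_node is not None:
        candidates.append(masks[node])
    candidates.extend(masks[c] for c in node.child_nodes())
    for m in candidates:
        s = Split(taxon_set, m)
        if s.is_informative:
            out.add(s)
    return frozenset(out)


def topo_distance_to_tips(tree: dendropy.Tree, node=None) -> float:
    """Mean number of edges from a node to its descendant leaves (0 for a
    leaf). With ``node=None`` the tree's root is used."""
    if node is None:
        node = tree.seed_node

    def agg(n):
        if n.is_leaf():
            return 1, 0
        total_leaves, total_depth = 0, 0
        for c in n.child_nodes():
            nl, td = agg(c)
            total_leaves += nl
            total_depth += td + nl  # one more edge from n down to c's leaves
        return total_leaves, total_depth

    n_leaves, depth_sum = agg(node)
    return depth_sum / n_leaves


def node_score(
    ref_tree: dendropy.Tree, gene_trees, taxon_set: TaxonSet | None = None
) -> pd.DataFrame:
    """Score every internal node of the reference tree against gene trees.

    Returns one row per internal node: ``node_id``, ``clade`` (smallest
    descendant label, a human-readable anchor), ``n_descendants``,
    ``score_count``, ``score_fraction``, ``support`` (the node's own
    bootstrap proportion, if any) and ``tip_distance``.
    """
    gene_trees = list(gene_trees)
    labels = check_common_taxa(gene_trees, ref_tree)
    if taxon_set is None:
        taxon_set = TaxonSet(labels)
    gene_split_sets = [
        extract_informative_splits(t, taxon_set) for t in gene_trees
    ]
    masks = _clade_masks(ref_tree, taxon_set)
    T = len(gene_trees)
    rows = []
    for node in internal_nodes(ref_tree):
        required = node_adjacent_splits(ref_tree, node, taxon_set, _masks=masks)
        count = sum(1 for gs in gene_split_sets if required <= gs)
        rows.append(
            {
                "node_id": node.congruity_id,
                "clade": _min_descendant_label(node),
                "n_descendants": masks[node].bit_count(),
                "score_count": count,
                "score_fraction": count / T,
                "support": getattr(node, "support", None),
                "tip_distance": topo_distance_to_tips(ref_tree, node),
            }
        )
    return pd.DataFrame(rows)


def split_depth_distribution(
    gene_trees, taxon_set: TaxonSet | None = None
) -> pd.DataFrame:
    """For every pooled split: the number of gene trees containing it and
    the mean topological distance to the tips of its defining node.

    Within each tree the split's defining node is the child node of the
    split edge in the tree's (rooted) representation; its tip distance is
    averaged over the trees containing the split.
    """
    gene_trees = list(gene_trees)
    labels = check_common_taxa(gene_trees)
    if taxon_set is None:
        taxon_set = TaxonSet(labels)
    depths: dict[Split, list[float]] = {}
    for tree in gene_trees:
        masks = _clade_masks(tree, taxon_set)
        seen: dict[Split, float] = {}
        for node, mask in masks.items():
            if node.parent_node is None or node.is_leaf():
                continue
            s = Split(taxon_set, mask)
            if not s.is_informative:
                continue
            d = topo_distance_to_tips(tree, node)
            # a rooted tree's two root edges map to one split: keep the
            # shallower defining node
            if s not in seen or d < seen[s]:
                seen[s] = d
        for s, d in seen.items():
            depths.setdefault(s, []).append(d)
    rows = [
        {
            "split": ",".join(s.smaller_side()),
            "n_trees": len(ds),
            "mean_tip_distance": sum(ds) / len(ds),
        }
        for s, ds in depths.items()
    ]
    df = pd.DataFrame(rows, columns=["split", "n_trees", "mean_tip_distance"])
    return df.sort_values(["n_trees", "split"], ascending=[False, True]).reset_index(
        drop=True
    )


def annotate_reference_tree(
    ref_tree: dendropy.Tree, scores: pd.DataFrame
) -> dendropy.Tree:
    """Attach node-score annotations to a copy of the reference tree.

    Each internal node gains ``node_score_count``, ``node_score_fraction``
    and (when known) ``bp`` in its ``congruity_annotations``, ready for
    :func:`congruity.io.write_newick` with ``include_annotations=True``.
    """
    tree = ref_tree.clone(depth=1)
    by_id = {row["node_id"]: row for _, row in scores.iterrows()}
    for node in internal_nodes(tree):
        if node.congruity_id not in by_id:
            raise ValidationError(
                f"score table missing internal node {node.congruity_id}"
            )
        row = by_id[node.congruity_id]
        ann = {
            "node_score_count": int(row["score_count"]),
            "node_score_fraction": f"{row['score_fraction']:.4f}",
        }
        support = getattr(node, "support", None)
        if support is not None:
            ann["bp"] = f"{support:g}"
        node.congruity_annotations = ann
    return tree
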