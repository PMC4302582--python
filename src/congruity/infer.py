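"""Distance-based tree inference: Poisson-corrected distances, neighbor
joining and nonparametric bootstrap support.

This is the package's internal stand-in for an external ML inference stage:
fast, dependency-free and adequate to reproduce the congruence phenomena
under study (tree accuracy and bootstrap support as functions of alignment
length). Externally built trees remain first-class inputs everywhere else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .io import Alignment, ValidationError
from .splits import TaxonSet, extract_informative_splits, _clade_masks, Split

__all__ = [
    "DistanceMatrix",
    "poisson_corrected_distance",
    "neighbor_joining",
    "bootstrap_support",
    "nj_tree",
]

MAX_DISTANCE = 10.0  # cap for saturated pairs, substitutions/site


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative pairwise distances over an ordered taxon list."""

    taxa: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValidationError("distance matrix shape does not match taxa")
        if not np.allclose(m, m.T):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(m < 0):
            raise ValidationError("distances must be nonnegative")
        self.matrix = m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.taxa, columns=self.taxa)


def _encode(alignment: Alignment) -> np.ndarray:
    return np.frombuffer(
        "".join(alignment.seqs).encode("ascii"), dtype=np.uint8
    ).reshape(alignment.n_sequences, alignment.length)


def poisson_corrected_distance(
    alignment: Alignment, max_distance: float = MAX_DISTANCE
) -> DistanceMatrix:
    """Amino-acid Poisson-corrected distances.

    Per pair, p is the mismatch fraction over co-ungapped columns and
    d = −ln(1 − p·20/19), the 20-state Poisson correction. Saturated pairs
    (argument ≤ 0) are capped at ``max_distance`` with a warning; a pair
    with no co-ungapped column is an error.
    """
    if alignment.n_sequences < 3:
        raise ValidationError("distance matrix needs at least 3 sequences")
    arr = _encode(alignment)
    gap = ord("-")
    ungapped = arr != gap
    n = alignment.n_sequences
    d = np.zeros((n, n))
    capped = 0
    for i in range(n):
        for j in range(i + 1, n):
            both = ungapped[i] & ungapped[j]
            denom = int(both.sum())
            if denom == 0:
                raise ValidationError(
                    f"sequences {alignment.ids[i]!r} and {alignment.ids[j]!r} "
                    "share no ungapped column"
                )
            p = float((arr[i][both] != arr[j][both]).sum()) / denom
            arg = 1.0 - p * 20.0 / 19.0
            if arg <= 0:
                capped += 1
                dist = max_distance
            else:
                dist = min(-np.log(arg), max_distance)
            d[i, j] = d[j, i] = dist
    if capped:
        warnings.warn(f"{capped} saturated pair(s) capped at {max_distance}")
    return DistanceMatrix(taxa=tuple(alignment.ids), matrix=d)


def neighbor_joining(dist: DistanceMatrix) -> dendropy.Tree:
    """Neighbor joining (Saitou–Nei with the Studier–Keppler update).

    Returns an unrooted tree (trifurcating seed node). Q-matrix ties break
    deterministically on the smallest (row, column) index pair; negative
    branch-length estimates are clamped to zero.
    """
    n = len(dist.taxa)
    if n < 4:
        raise ValidationError("neighbor joining needs at least 4 taxa")
    D = dist.matrix.copy()
    tns = dendropy.TaxonNamespace()
    nodes = []
    for label in dist.taxa:
        taxon = tns.new_taxon(label)
        nodes.append(dendropy.Node(taxon=taxon))
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        Q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(Q, np.inf)
        # row-major argmin -> smallest (i, j) on ties
        i_loc, j_loc = np.unravel_index(np.argmin(Q), Q.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        dij = sub[i_loc, j_loc]
        li = 0.5 * dij + (totals[i_loc] - totals[j_loc]) / (2 * (m - 2))
        lj = dij - li
        gi, gj = active[i_loc], active[j_loc]
        parent = dendropy.Node()
        ni, nj = nodes[gi], nodes[gj]
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = max(li, 0.0)
        nj.edge.length = max(lj, 0.0)
        # Studier–Keppler distance from the new node to the rest
        new_row = np.zeros(D.shape[0] + 1)
        for k_loc, gk in enumerate(active):
            if gk in (gi, gj):
                continue
            new_row[gk] = 0.5 * (D[gi, gk] + D[gj, gk] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(new_row) - 1] = new_row[:-1]
        D[: len(new_row) - 1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [g for g in active if g not in (gi, gj)] + [len(nodes) - 1]

    ga, gb, gc = active
    dab = D[ga, gb]
    dac = D[ga, gc]
    dbc = D[gb, gc]
    seed = dendropy.Node()
    for g, length in (
        (ga, 0.5 * (dab + dac - dbc)),
        (gb, 0.5 * (dab + dbc - dac)),
        (gc, 0.5 * (dac + dbc - dab)),
    ):
        seed.add_child(nodes[g])
        nodes[g].edge.length = max(length, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=seed)
    tree.is_rooted = False
    for node in tree:
        node.support = None
    return tree


def nj_tree(alignment: Alignment) -> dendropy.Tree:
    """Distance + NJ in one step: the package's default tree inferrer."""
    return neighbor_joining(poisson_corrected_distance(alignment))


def bootstrap_support(
    alignment: Alignment,
    replicates: int = 100,
    seed: int | None = None,
    point_tree: dendropy.Tree | None = None,
) -> tuple[dendropy.Tree, float]:
    """Nonparametric bootstrap of the NJ tree.

    Columns are resampled with replacement ``replicates`` times; each
    internal edge of the point-estimate tree is annotated (``node.support``)
    with the percentage of replicate trees containing its split. Returns
    the annotated tree and its mean bootstrap proportion.
    """
    if replicates < 1:
        raise ValidationError("need at least one bootstrap replicate")
    rng = np.random.default_rng(seed)
    if point_tree is None:
        point_tree = nj_tree(alignment)
    ts = TaxonSet(alignment.ids)
    point_splits = extract_informative_splits(point_tree, ts)
    hits: dict[Split, int] = {s: 0 for s in point_splits}
    L = alignment.length
    arr = _encode(alignment)
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        res = arr[:, cols]
        pseudo = Alignment(
            ids=list(alignment.ids),
            seqs=[row.tobytes().decode("ascii") for row in res],
        )
        rep_splits = extract_informative_splits(nj_tree(pseudo), ts)
        for s in point_splits & rep_splits:
            hits[s] += 1
    # attach support to the node below each informative edge
    masks = _clade_masks(point_tree, ts)
    supports = []
    for node, mask in masks.items():
        if node.parent_node is None or node.is_leaf():
            continue
        s = Split(ts, mask)
        if s in hits:
            node.support = 100.0 * hits[s] / replicates
            supports.append(node.support)
    mean_bp = float(np.mean(supports)) if supports else float("nan")
    return point_tree, mean_bp
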