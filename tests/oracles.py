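"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's own split machinery: trees are
enumerated as adjacency maps and splits recovered by cutting edges, so the
package's bitmask algebra is checked against a representation it shares
nothing with.
"""

from __future__ import annotations

import itertools


def enumerate_unrooted_trees(n: int):
    """Yield every resolved unrooted tree on leaves 0..n-1 as an adjacency
    dict (leaves are 0..n-1, internal nodes are negative ints).

    Built by the standard stepwise-addition recursion: each tree on k
    leaves grows by attaching leaf k to each of its edges, which counts
    (2n-5)!! trees, each exactly once.
    """
    if n < 3:
        raise ValueError("need at least 3 leaves")
    adj = {-1: [0, 1, 2], 0: [-1], 1: [-1], 2: [-1]}

    def edges(a):
        for u, nbrs in a.items():
            for v in nbrs:
                if u < v:
                    yield (u, v)

    def grow(a, next_leaf, next_internal):
        if next_leaf == n:
            yield a
            return
        for u, v in list(edges(a)):
            b = {k: list(vs) for k, vs in a.items()}
            w = next_internal
            b[u].remove(v)
            b[v].remove(u)
            b[u].append(w)
            b[v].append(w)
            b[w] = [u, v, next_leaf]
            b[next_leaf] = [w]
            yield from grow(b, next_leaf + 1, next_internal - 1)

    yield from grow(adj, 3, -2)


def splits_of_adjacency(adj, n: int) -> frozenset[int]:
    """Informative splits of an adjacency-map tree as canonical bitmasks
    (the side not containing leaf 0)."""
    full = (1 << n) - 1
    out = set()
    for u in adj:
        for v in adj[u]:
            if u >= v:
                continue
            # leaves on v's side of edge (u, v)
            stack, seen, mask = [v], {u, v}, 0
            while stack:
                x = stack.pop()
                if 0 <= x < n:
                    mask |= 1 << x
                for y in adj[x]:
                    if y not in seen:
                        seen.add(y)
                        stack.append(y)
            if mask & 1:
                mask = full & ~mask
            if 2 <= mask.bit_count() <= n - 2:
                out.add(mask)
    return frozenset(out)


def informative_masks(n: int):
    """All canonical informative split masks on n taxa."""
    full = (1 << n) - 1
    out = []
    for mask in range(1, full):
        if mask & 1:
            continue
        if 2 <= mask.bit_count() <= n - 2:
            out.append(mask)
    return out


def realizable_pairs(n: int) -> set[tuple[int, int]]:
    """All unordered pairs of informative split masks that co-occur in at
    least one resolved unrooted tree on n taxa (exhaustive enumeration)."""
    pairs = set()
    for adj in enumerate_unrooted_trees(n):
        masks = sorted(splits_of_adjacency(adj, n))
        for a, b in itertools.combinations(masks, 2):
            pairs.add((a, b))
        for a in masks:
            pairs.add((a, a))
    return pairs


def path_distance_matrix(adj, lengths, taxa):
    """Leaf-to-leaf path-length matrix of an adjacency tree with edge
    lengths keyed by sorted node pair."""
    import numpy as np

    n = len(taxa)
    D = np.zeros((n, n))
    for i, a in enumerate(taxa):
        # BFS accumulating distances
        dist = {a: 0.0}
        stack = [a]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y not in dist:
                    key = (min(x, y), max(x, y))
                    dist[y] = dist[x] + lengths[key]
                    stack.append(y)
        for j, b in enumerate(taxa):
            D[i, j] = dist[b]
    return D
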