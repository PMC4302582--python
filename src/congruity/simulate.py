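"""Synthetic gene-family datasets with controlled incongruence.

The generator emulates the structure of a phylogenomic single-copy dataset:
one species tree; T gene trees derived from it by a configurable number of
SPR moves (the topological signature of lateral gene transfer by orthologous
replacement); and per-family amino-acid alignments evolved along each gene
tree under the WAG replacement model with discrete-gamma rate variation and
a zipf-length indel process (exponent 1.6, maximum length 100, rate 0.0011
per site per unit branch length — the regime of typical prokaryotic protein
alignments). Every dataset is fully reproducible from its seed.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .io import Alignment, ValidationError, write_fasta_alignment, write_newick
from .stats import GeneFamily

__all__ = [
    "SimConfig",
    "LgtEvent",
    "SimulatedDataset",
    "load_wag",
    "WagModel",
    "discrete_gamma_rates",
    "zipf_truncated_pmf",
    "zipf_truncated_mean",
    "simulate_species_tree",
    "apply_lgt_events",
    "evolve_alignment",
    "generate_dataset",
]

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"


# ---------------------------------------------------------------------------
# substitution model
# ---------------------------------------------------------------------------


def load_wag() -> tuple[np.ndarray, np.ndarray]:
    """Load the bundled WAG exchangeabilities (symmetric 20×20) and
    equilibrium frequencies from plain text."""
    text = (
        resources.files("congruity.data").joinpath("wag.txt").read_text()
    )
    lines = [l.strip() for l in text.splitlines() if l.strip() and not l.startswith("#")]
    order = lines[0].split()
    if "".join(order) != AMINO_ACIDS:
        raise ValidationError("unexpected amino-acid order in wag.txt")
    S = np.zeros((20, 20))
    for i, line in enumerate(lines[1:20], start=1):
        vals = [float(x) for x in line.split()]
        S[i, : len(vals)] = vals
        S[: len(vals), i] = vals
    freqs = np.array([float(x) for x in lines[20].split()])
    freqs = freqs / freqs.sum()
    return S, freqs


class WagModel:
    """Reversible amino-acid CTMC scaled to one expected substitution per
    site per unit branch length; transition matrices via spectral
    decomposition of the symmetrised generator."""

    def __init__(self):
        S, pi = load_wag()
        self.freqs = pi
        R = S * pi[None, :]
        np.fill_diagonal(R, 0.0)
        np.fill_diagonal(R, -R.sum(axis=1))
        mu = -float(np.sum(pi * np.diag(R)))
        Q = R / mu
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        evals, evecs = np.linalg.eigh((B + B.T) / 2)
        self._evals = evals
        self._left = evecs / sq[:, None]
        self._right = evecs.T * sq[None, :]

    def transition(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt), rows renormalised against round-off."""
        P = (self._left * np.exp(self._evals * t)) @ self._right
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=1, keepdims=True)

    @property
    def identity_floor(self) -> float:
        """Expected pairwise identity at saturation: Σ πᵢ²."""
        return float(np.sum(self.freqs**2))


_MODEL_CACHE: dict[str, WagModel] = {}


def _wag() -> WagModel:
    if "wag" not in _MODEL_CACHE:
        _MODEL_CACHE["wag"] = WagModel()
    return _MODEL_CACHE["wag"]


def discrete_gamma_rates(shape: float, k: int = 4) -> np.ndarray:
    """Mean rates of k equal-probability discrete gamma categories
    (mean-one gamma with the given shape)."""
    from scipy.special import gammainc
    from scipy.stats import gamma as gamma_dist

    cuts = gamma_dist.ppf(np.arange(1, k) / k, a=shape, scale=1.0 / shape)
    cuts = np.concatenate([[0.0], cuts, [np.inf]])
    upper = gammainc(shape + 1, shape * cuts[1:])
    lower = gammainc(shape + 1, shape * cuts[:-1])
    return k * (upper - lower)


# ---------------------------------------------------------------------------
# indel length distribution
# ---------------------------------------------------------------------------


def zipf_truncated_pmf(exponent: float, max_length: int) -> np.ndarray:
    if exponent <= 1:
        raise ValidationError("zipf exponent must exceed 1")
    if max_length < 1:
        raise ValidationError("max indel length must be >= 1")
    k = np.arange(1, max_length + 1, dtype=float)
    w = k**-exponent
    return w / w.sum()


def zipf_truncated_mean(exponent: float, max_length: int) -> float:
    pmf = zipf_truncated_pmf(exponent, max_length)
    return float(np.sum(pmf * np.arange(1, max_length + 1)))


def _sample_zipf(pmf_cum: np.ndarray, rng: np.random.Generator) -> int:
    return int(np.searchsorted(pmf_cum, rng.random())) + 1


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Full description of one synthetic dataset.

    ``root_length`` may be an int (all families equal) or a ``(lo, hi)``
    pair (per-family length drawn uniformly, emulating the length spread of
    real gene families). ``lgt_events`` is the SPR count per gene tree —
    fixed, or Poisson-distributed with that mean when ``lgt_poisson``.
    """

    n_taxa: int = 50
    n_families: int = 50
    root_length: int | tuple[int, int] = 300
    tree_scale: float = 1.0
    birth_rate: float = 1.0
    death_rate: float = 0.0
    gamma_shape: float = 1.0
    gamma_categories: int = 4
    indel_rate: float = 0.0011
    indel_zipf_exponent: float = 1.6
    indel_max_length: int = 100
    lgt_events: float = 0
    lgt_poisson: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValidationError("need at least 4 taxa")
        if self.indel_rate < 0 or self.tree_scale <= 0:
            raise ValidationError("rates and scales must be nonnegative")
        if self.indel_zipf_exponent <= 1 or self.indel_max_length < 1:
            raise ValidationError("invalid indel length distribution")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        if isinstance(d["root_length"], tuple):
            d["root_length"] = list(d["root_length"])
        return d


@dataclass
class LgtEvent:
    """One SPR move: the transferred (pruned) clade and where it landed."""

    family_id: str
    event_index: int
    moved_clade: tuple[str, ...]
    target_clade: tuple[str, ...]


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------


def simulate_species_tree(
    n_taxa: int,
    seed: int | None = None,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    tree_scale: float = 1.0,
) -> dendropy.Tree:
    """A rooted, fully resolved birth–death (default Yule) species tree on
    taxa ``T001..Tn``, rescaled so the maximum root-to-tip path equals
    ``tree_scale`` substitutions per site."""
    if n_taxa < 4:
        raise ValidationError("need at least 4 taxa")
    rng = random.Random(None if seed is None else int(seed))
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=death_rate,
        num_extant_tips=n_taxa,
        rng=rng,
    )
    # deterministic relabelling
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"T{i:03d}"
    height = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
    factor = tree_scale / height
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    for node in tree:
        node.support = None
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# lateral transfer as SPR
# ---------------------------------------------------------------------------


def _leaf_tuple(node) -> tuple[str, ...]:
    return tuple(sorted(l.taxon.label for l in node.leaf_iter()))


def _spr_once(tree: dendropy.Tree, rng: np.random.Generator):
    """One uniform SPR move in place; returns (moved_clade, target_clade).

    The pruned subtree is regrafted onto an edge outside itself. Edges on
    the unrooted edge the subtree was pruned from are excluded — regrafting
    there recreates the starting topology (the root being a fake node of
    the unrooted topology, this covers the sibling edge, the root's other
    child edge when pruning below a root child, and the new root's child
    edges when pruning a root child itself). Every accepted move therefore
    changes the unrooted topology.
    """
    seed_node = tree.seed_node
    all_nodes = [nd for nd in tree.preorder_node_iter() if nd is not seed_node]
    order = rng.permutation(len(all_nodes))
    chosen = None
    for idx in order:
        v = all_nodes[idx]
        u = v.parent_node
        sibs = [c for c in u.child_nodes() if c is not v]
        if len(sibs) != 1:
            continue
        s = sibs[0]
        if u is seed_node and s.is_leaf():
            continue  # splicing would leave a leaf as root
        excluded = {v, u, s}
        if u is seed_node:
            # gap sits at node s (the new root): its child edges span the
            # unrooted edges adjacent to the original attachment
            excluded.update(s.child_nodes())
        elif u.parent_node is seed_node:
            # the merged edge continues through the fake root
            excluded.update(
                c for c in seed_node.child_nodes() if c is not u
            )
        subtree = set(v.preorder_iter())
        targets = [
            q
            for q in tree.preorder_node_iter()
            if q.parent_node is not None
            and q not in subtree
            and q not in excluded
        ]
        if targets:
            chosen = (v, u, s, targets)
            break
    if chosen is None:
        raise ValidationError("no valid SPR move exists on this tree")
    v, u, s, targets = chosen
    q = targets[int(rng.integers(len(targets)))]
    moved, landed = _leaf_tuple(v), _leaf_tuple(q)

    # detach v, splice out u
    pu = u.parent_node
    u.remove_child(v)
    u.remove_child(s)
    if pu is None:
        s.edge.length = None
        tree.seed_node = s
    else:
        lu = u.edge.length or 0.0
        ls = s.edge.length or 0.0
        pu.remove_child(u)
        pu.add_child(s)
        s.edge.length = lu + ls

    # regraft v on the edge above q
    pq = q.parent_node
    lq = q.edge.length
    w = dendropy.Node()
    w.support = None
    pq.remove_child(q)
    pq.add_child(w)
    w.add_child(q)
    if lq is not None:
        w.edge.length = lq / 2.0
        q.edge.length = lq / 2.0
    w.add_child(v)
    return moved, landed


def apply_lgt_events(
    species_tree: dendropy.Tree,
    k: int,
    rng: np.random.Generator | int | None = None,
    family_id: str = "",
) -> tuple[dendropy.Tree, list[LgtEvent]]:
    """Derive a gene tree by k sequential SPR moves on a copy of the
    species tree. The leaf set is preserved; each move is logged."""
    if k < 0:
        raise ValidationError("number of LGT events must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    tree = species_tree.clone(depth=1)
    for node in tree:
        node.support = None
    events = []
    for e in range(int(k)):
        moved, landed = _spr_once(tree, rng)
        events.append(
            LgtEvent(
                family_id=family_id,
                event_index=e,
                moved_clade=moved,
                target_clade=landed,
            )
        )
    return tree, events


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------


def evolve_alignment(
    tree: dendropy.Tree,
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
) -> Alignment:
    """Evolve an amino-acid alignment along a tree with branch lengths.

    The root sequence (length ``config.root_length``, which must be an int
    here) is drawn from the WAG equilibrium frequencies; each site carries a
    discrete-gamma rate category inherited by its descendants. Along every
    branch, substitutions follow the WAG CTMC and insertions/deletions each
    arrive as Poisson events at ``indel_rate`` per site per unit branch
    length with zipf-distributed lengths; insertion columns are padded with
    gaps in the other rows, yielding a true multiple alignment.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    L = config.root_length
    if not isinstance(L, (int, np.integer)):
        raise ValidationError("evolve_alignment needs an integer root_length")
    if L < 1:
        raise ValidationError("root length must be >= 1")
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            raise ValidationError("tree has missing branch lengths")

    model = _wag()
    rates = discrete_gamma_rates(config.gamma_shape, config.gamma_categories)
    pmf_cum = np.cumsum(
        zipf_truncated_pmf(config.indel_zipf_exponent, config.indel_max_length)
    )
    freq_cum = np.cumsum(model.freqs)

    next_col = L
    master: list[int] = list(range(L))
    root_states = np.searchsorted(freq_cum, rng.random(L)).tolist()
    root_cats = rng.integers(0, config.gamma_categories, size=L).tolist()
    root_ids = list(range(L))

    leaf_rows: dict[str, tuple[list[int], list[int]]] = {}

    def step(node, ids, states, cats):
        nonlocal next_col
        t = node.edge.length
        if t > 0 and states:
            st = np.asarray(states)
            ct = np.asarray(cats)
            new = np.empty_like(st)
            for c in range(config.gamma_categories):
                sel = np.nonzero(ct == c)[0]
                if sel.size == 0:
                    continue
                P = model.transition(t * rates[c])
                cum = np.cumsum(P, axis=1)
                u = rng.random(sel.size)
                rows = cum[st[sel]]
                new[sel] = (rows < u[:, None]).sum(axis=1)
            states = new.tolist()
        if t > 0 and config.indel_rate > 0:
            n_del = rng.poisson(config.indel_rate * t * len(states))
            for _ in range(n_del):
                if not states:
                    break
                start = int(rng.integers(len(states)))
                length = _sample_zipf(pmf_cum, rng)
                del ids[start : start + length]
                del states[start : start + length]
                del cats[start : start + length]
            n_ins = rng.poisson(config.indel_rate * t * (len(states) + 1))
            for _ in range(n_ins):
                pos = int(rng.integers(len(states) + 1))
                length = _sample_zipf(pmf_cum, rng)
                new_ids = list(range(next_col, next_col + length))
                next_col += length
                new_states = np.searchsorted(
                    freq_cum, rng.random(length)
                ).tolist()
                new_cats = rng.integers(
                    0, config.gamma_categories, size=length
                ).tolist()
                anchor = master.index(ids[pos - 1]) + 1 if pos > 0 else (
                    master.index(ids[0]) if ids else len(master)
                )
                master[anchor:anchor] = new_ids
                ids[pos:pos] = new_ids
                states[pos:pos] = new_states
                cats[pos:pos] = new_cats
        return ids, states, cats

    def visit(node, ids, states, cats):
        children = node.child_nodes()
        if not children:
            leaf_rows[node.taxon.label] = (ids, states)
            return
        for child in children:
            cid, cst, cct = step(child, list(ids), list(states), list(cats))
            visit(child, cid, cst, cct)

    visit(tree.seed_node, root_ids, root_states, root_cats)

    col_pos = {cid: i for i, cid in enumerate(master)}
    labels = sorted(leaf_rows)
    seqs = []
    for label in labels:
        ids, states = leaf_rows[label]
        row = ["-"] * len(master)
        for cid, s in zip(ids, states):
            row[col_pos[cid]] = AMINO_ACIDS[s]
        seqs.append("".join(row))
    # drop columns that became all-gap through deletions of inserted material
    keep = [i for i in range(len(master)) if any(s[i] != "-" for s in seqs)]
    if len(keep) != len(master):
        seqs = ["".join(s[i] for i in keep) for s in seqs]
    return Alignment(ids=labels, seqs=seqs)


# ---------------------------------------------------------------------------
# whole datasets
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    """T gene families plus their generating ground truth."""

    config: SimConfig
    species_tree: dendropy.Tree
    families: list[GeneFamily] = field(default_factory=list)
    events: list[LgtEvent] = field(default_factory=list)

    @property
    def gene_trees(self) -> list[dendropy.Tree]:
        return [f.tree for f in self.families]

    @property
    def alignments(self) -> list[Alignment]:
        return [f.alignment for f in self.families]

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "species_tree.nwk", "w") as fh:
            fh.write(write_newick(self.species_tree) + "\n")
        for fam in self.families:
            with open(outdir / f"{fam.family_id}.nwk", "w") as fh:
                fh.write(write_newick(fam.tree) + "\n")
            if fam.alignment is not None:
                write_fasta_alignment(
                    fam.alignment, outdir / f"{fam.family_id}.fasta"
                )
        with open(outdir / "events.tsv", "w") as fh:
            fh.write("family_id\tevent_index\tmoved_clade\ttarget_clade\n")
            for ev in self.events:
                fh.write(
                    f"{ev.family_id}\t{ev.event_index}\t"
                    f"{','.join(ev.moved_clade)}\t"
                    f"{','.join(ev.target_clade)}\n"
                )
        with open(outdir / "manifest.json", "w") as fh:
            json.dump({"config": self.config.to_dict()}, fh, indent=2)
            fh.write("\n")


def _resolve_lgt_count(config: SimConfig, rng: np.random.Generator) -> int:
    if config.lgt_poisson:
        return int(rng.poisson(config.lgt_events))
    return int(config.lgt_events)


def _resolve_length(config: SimConfig, rng: np.random.Generator) -> int:
    if isinstance(config.root_length, tuple):
        lo, hi = config.root_length
        return int(rng.integers(lo, hi + 1))
    return int(config.root_length)


def generate_dataset(
    config: SimConfig,
    species_tree: dendropy.Tree | None = None,
    evolve: bool = True,
    compute_covariates: bool = True,
) -> SimulatedDataset:
    """Generate the full dataset a congruence analysis consumes.

    ``evolve=False`` skips sequence simulation (gene trees only), which is
    enough for purely topological experiments. A pre-built species tree may
    be supplied; otherwise one is simulated from the config.
    """
    ss = np.random.SeedSequence(config.seed)
    tree_seed, *family_seeds = ss.spawn(config.n_families + 1)
    if species_tree is None:
        species_tree = simulate_species_tree(
            config.n_taxa,
            seed=int(tree_seed.generate_state(1)[0] % 2**31),
            birth_rate=config.birth_rate,
            death_rate=config.death_rate,
            tree_scale=config.tree_scale,
        )
    families, all_events = [], []
    for i, fam_seed in enumerate(family_seeds, start=1):
        rng = np.random.default_rng(fam_seed)
        fam_id = f"fam{i:03d}"
        k = _resolve_lgt_count(config, rng)
        gene_tree, events = apply_lgt_events(
            species_tree, k, rng, family_id=fam_id
        )
        alignment = None
        if evolve:
            fam_config = replace(config, root_length=_resolve_length(config, rng))
            alignment = evolve_alignment(gene_tree, fam_config, rng)
        fam = GeneFamily(family_id=fam_id, alignment=alignment, tree=gene_tree)
        if compute_covariates and alignment is not None:
            fam.compute_covariates()
        families.append(fam)
        all_events.extend(events)
    return SimulatedDataset(
        config=config,
        species_tree=species_tree,
        families=families,
        events=all_events,
    )
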