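"""Reading and writing trees and alignments.

Trees are represented as :class:`dendropy.Tree` objects throughout the
package. Bootstrap/support values live on ``node.support`` (a float in
[0, 100] or ``None``); per-node annotations destined for newick output live
in the ``node.congruity_annotations`` dict. Two support dialects are accepted
on input — numeric internal-node labels (``)95:0.5``) and bracketed branch
comments (``):0.5[95]`` or ``[&support=95]``) — and internal-node labels are
emitted on output.

Alignments are gapped amino-acid alignments over a shared taxon set; the
canonical gap character is ``-`` (``.`` is normalised on input).
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field

import dendropy
from Bio import SeqIO

__all__ = [
    "Alignment",
    "NewickParseError",
    "ValidationError",
    "parse_newick",
    "read_newick",
    "write_newick",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "check_common_taxa",
]

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
GAP = "-"
_VALID_CHARS = frozenset(AMINO_ACIDS + GAP + "X")


class NewickParseError(ValueError):
    """Raised when a newick string cannot be parsed."""


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

_NUMERIC_RE = re.compile(r"^[+-]?\d+(\.\d*)?([eE][+-]?\d+)?$")
_SUPPORT_COMMENT_RE = re.compile(
    r"^\s*&?\s*(?:support\s*=\s*)?([+-]?\d+(?:\.\d*)?)\s*$"
)


def _check_balanced(text: str) -> None:
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(
                    f"unbalanced ')' at character offset {offset}"
                )
    if depth != 0:
        raise NewickParseError(
            f"unbalanced '(': {depth} unclosed at end of string "
            f"(length {len(text.rstrip())})"
        )


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a single newick string into a :class:`dendropy.Tree`.

    Numeric internal-node labels and bare-number (or ``support=``) branch
    comments are both interpreted as support values and stored on
    ``node.support``. Duplicate leaf labels raise :class:`ValidationError`;
    malformed structure raises :class:`NewickParseError` naming the offset
    of the offending character where determinable.
    """
    _check_balanced(text)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            extract_comment_metadata=False,
        )
    except Exception as exc:  # dendropy raises several error types
        if "duplicate taxon labels" in str(exc).lower():
            raise ValidationError(f"duplicate leaf labels: {exc}") from exc
        raise NewickParseError(f"newick parse failed: {exc}") from exc
    _attach_support(tree)
    _validate_tree(tree)
    return tree


def read_newick(path) -> dendropy.Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


def _attach_support(tree: dendropy.Tree) -> None:
    for node in tree:
        support = None
        if node.is_internal() and node.label is not None:
            if _NUMERIC_RE.match(node.label.strip()):
                support = float(node.label.strip())
                node.label = None
        if support is None and node.comments:
            for comment in node.comments:
                m = _SUPPORT_COMMENT_RE.match(comment)
                if m and node.is_internal():
                    support = float(m.group(1))
                    break
        node.comments = []
        node.support = support


def _validate_tree(tree: dendropy.Tree) -> None:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    seen, dups = set(), set()
    for lab in labels:
        if lab in seen:
            dups.add(lab)
        seen.add(lab)
    if dups:
        raise ValidationError(f"duplicate leaf labels: {sorted(dups)}")
    for edge in tree.edges():
        if edge.length is not None and edge.length < 0:
            raise ValidationError(
                f"negative branch length {edge.length} on edge to "
                f"{_node_name(edge.head_node)}"
            )


def _node_name(node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label or "<internal>"


def _min_descendant_label(node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return min(_min_descendant_label(c) for c in node.child_nodes())


def _format_length(x: float) -> str:
    return f"{x:.10g}"


def _format_support(x: float) -> str:
    if float(x).is_integer():
        return str(int(x))
    return f"{x:g}"


def _quote_label(label: str) -> str:
    if re.search(r"[\s(),:;\[\]']", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(
    tree: dendropy.Tree,
    include_support: bool = True,
    include_annotations: bool = False,
) -> str:
    """Serialise a tree to newick with a canonical child ordering.

    Children are ordered by their smallest descendant taxon label, so output
    is deterministic for a given topology. Support values are written as
    internal-node labels; when ``include_annotations`` is set, each node's
    ``congruity_annotations`` dict is emitted as a ``[&key=value,...]``
    comment (the dialect common tree viewers read).
    """

    def render(node) -> str:
        parts = []
        children = sorted(node.child_nodes(), key=_min_descendant_label)
        if children:
            inner = ",".join(render(c) for c in children)
            parts.append(f"({inner})")
            support = getattr(node, "support", None)
            if include_support and support is not None:
                parts.append(_format_support(support))
            elif node.label:
                parts.append(_quote_label(node.label))
        else:
            parts.append(_quote_label(node.taxon.label))
        if include_annotations:
            ann = getattr(node, "congruity_annotations", None)
            if ann:
                body = ",".join(f"{k}={v}" for k, v in ann.items())
                parts.append(f"[&{body}]")
        if node.edge.length is not None and node.parent_node is not None:
            parts.append(":" + _format_length(node.edge.length))
        return "".join(parts)

    return render(tree.seed_node) + ";"


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------


@dataclass
class Alignment:
    """A gapped amino-acid alignment: parallel lists of ids and sequences."""

    ids: list[str]
    seqs: list[str]
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if not self.ids:
            raise ValidationError("alignment has no sequences")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            offending = [
                f"{i} (length {len(s)})"
                for i, s in zip(self.ids, self.seqs)
                if len(s) != len(self.seqs[0])
            ]
            raise ValidationError(
                "ragged alignment; records differing from first record's "
                f"length {len(self.seqs[0])}: {offending}"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate sequence ids in alignment")
        self._index = {tid: i for i, tid in enumerate(self.ids)}

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        """Number of columns."""
        return len(self.seqs[0])

    def ungapped_length(self, taxon: str) -> int:
        return len(self.seqs[self._index[taxon]].replace(GAP, ""))

    @property
    def ungapped_lengths(self) -> dict[str, int]:
        return {tid: self.ungapped_length(tid) for tid in self.ids}

    @property
    def mean_ungapped_length(self) -> float:
        return sum(self.ungapped_lengths.values()) / self.n_sequences

    def sequence(self, taxon: str) -> str:
        return self.seqs[self._index[taxon]]

    def taxon_labels(self) -> list[str]:
        return sorted(self.ids)


def _normalise(seq: str, record_id: str) -> str:
    seq = seq.upper().replace(".", GAP)
    bad = set(seq) - _VALID_CHARS
    if bad:
        raise ValidationError(
            f"record {record_id!r}: invalid characters {sorted(bad)} "
            "(expected the 20 amino acids, X, or a gap)"
        )
    return seq


def read_fasta_alignment(source) -> Alignment:
    """Read an aligned FASTA file (path, or text) into an :class:`Alignment`.

    All records must share one gapped length; ragged input raises
    :class:`ValidationError` listing the offending records.
    """
    if isinstance(source, str) and "\n" in source:
        handle = _io.StringIO(source)
    elif isinstance(source, str) or hasattr(source, "__fspath__"):
        handle = open(source)
    else:
        handle = source
    try:
        records = list(SeqIO.parse(handle, "fasta"))
    except ValueError as exc:
        raise ValidationError(f"empty or malformed FASTA input: {exc}") from exc
    finally:
        if handle is not source:
            handle.close()
    if not records:
        raise ValidationError("empty FASTA input")
    ids = [r.id for r in records]
    seqs = [_normalise(str(r.seq), r.id) for r in records]
    return Alignment(ids=ids, seqs=seqs)


def write_fasta_alignment(alignment: Alignment, path) -> None:
    with open(path, "w") as fh:
        for tid, seq in zip(alignment.ids, alignment.seqs):
            fh.write(f">{tid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# taxon-set consistency
# ---------------------------------------------------------------------------


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())


def check_common_taxa(trees, reference: dendropy.Tree | None = None) -> tuple[str, ...]:
    """Verify all trees (and optional reference) share one leaf set.

    Returns the shared taxon labels in sorted canonical order; a mismatch
    raises :class:`ValidationError` naming the differing taxa and trees.
    """
    trees = list(trees)
    if reference is not None:
        trees = trees + [reference]
    if not trees:
        raise ValidationError("no trees supplied")
    ref_set = leaf_labels(trees[0])
    for i, t in enumerate(trees[1:], start=1):
        other = leaf_labels(t)
        if other != ref_set:
            missing = sorted(ref_set - other)
            extra = sorted(other - ref_set)
            raise ValidationError(
                f"tree {i} leaf set differs from tree 0: "
                f"missing {missing}, unexpected {extra}"
            )
    return tuple(sorted(ref_set))
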