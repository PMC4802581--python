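"""Newick tree I/O, bipartition extraction, and chronogram arithmetic.

Trees are held as :class:`dendropy.Tree` objects; this module adds the split
and node-age operations the concordance pipeline needs. Gene trees are
treated as *unrooted* for all split work (their stored rootings are
artifacts of estimation), while chronograms are rooted ultrametric trees
whose edge lengths are absolute time in millions of years (Ma).

Coordinate convention: ages increase toward the root; every leaf sits at
age 0.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import dendropy

__all__ = [
    "Bipartition",
    "BranchDuration",
    "NewickError",
    "NotUltrametricError",
    "parse_newick",
    "read_newick_file",
    "write_newick",
    "leaf_labels",
    "extract_bipartitions",
    "node_ages",
    "branch_durations",
]


class NewickError(ValueError):
    """Malformed Newick input (unbalanced parentheses, duplicate leaves...)."""


class NotUltrametricError(ValueError):
    """A chronogram whose leaves are not contemporaneous within tolerance."""


def _norm_label(label: str) -> str:
    return " ".join(label.split())


class Bipartition:
    """An unordered split of a taxon label set into two disjoint blocks.

    Equality and hashing are orientation-free: ``(A|B) == (B|A)``. This is
    the unit of gene-tree support — one bipartition per internal edge of an
    unrooted tree, or one per clade of a rooted chronogram (the clade's
    leaves versus everything else).
    """

    __slots__ = ("side_a", "side_b", "_key")

    def __init__(self, side_a: Iterable[str], side_b: Iterable[str]):
        a = frozenset(_norm_label(x) for x in side_a)
        b = frozenset(_norm_label(x) for x in side_b)
        if not a or not b:
            raise ValueError("both sides of a bipartition must be non-empty")
        if a & b:
            raise ValueError(f"bipartition sides overlap: {sorted(a & b)}")
        self.side_a = a
        self.side_b = b
        self._key = frozenset((a, b))

    @property
    def taxa(self) -> frozenset[str]:
        return self.side_a | self.side_b

    def smaller_side(self) -> frozenset[str]:
        """The side with fewer taxa (ties broken lexicographically)."""
        if len(self.side_a) != len(self.side_b):
            return min(self.side_a, self.side_b, key=len)
        return min(self.side_a, self.side_b, key=lambda s: tuple(sorted(s)))

    def restrict(self, present: Iterable[str]) -> "Bipartition | None":
        """Intersect both sides with ``present``; None if a side empties.

        A side reduced to a single taxon still yields a Bipartition; the
        *trivial* judgement (either side < 2) is made by the concordance
        layer, which needs to distinguish the two cases.
        """
        p = frozenset(_norm_label(x) for x in present)
        a, b = self.side_a & p, self.side_b & p
        if not a or not b:
            return None
        return Bipartition(a, b)

    def is_compatible_with(self, other: "Bipartition") -> bool:
        """Split compatibility on a shared leaf set: some cross-intersection empty."""
        return (
            not (self.side_a & other.side_a)
            or not (self.side_a & other.side_b)
            or not (self.side_b & other.side_a)
            or not (self.side_b & other.side_b)
        )

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Bipartition) and self._key == other._key

    def __hash__(self) -> int:
        return hash(self._key)

    def __repr__(self) -> str:
        a, b = sorted(map(sorted, (self.side_a, self.side_b)))
        return f"Bipartition({','.join(a)} | {','.join(b)})"


@dataclass(frozen=True)
class BranchDuration:
    """A chronogram branch: the clade below it, and its span in Ma."""

    bipartition: Bipartition
    clade: frozenset[str]
    duration_ma: float


def parse_newick(text: str, rooted_hint: bool | None = None) -> dendropy.Tree:
    """Parse a single Newick statement into a dendropy Tree.

    Quoted labels are honoured, bracketed comments stripped, and underscores
    taken literally (not converted to spaces). Internal node labels are
    retained as plain text. Raises :class:`NewickError` on unbalanced
    parentheses, empty input, or duplicate leaf labels.
    """
    if not text or not text.strip():
        raise NewickError("empty newick input")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"newick parse failure: {exc}") from exc
    if rooted_hint is not None:
        tree.is_rooted = rooted_hint
    _validate(tree)
    return tree


def read_newick_file(path) -> list[dendropy.Tree]:
    """Read one or more Newick trees (one per statement) from a file."""
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    try:
        trees = dendropy.TreeList.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickError(f"{path}: newick parse failure: {exc}") from exc
    out = []
    for t in trees:
        t2 = t.clone(depth=1)
        t2.taxon_namespace = t.taxon_namespace
        _validate(t2)
        out.append(t2)
    if not out:
        raise NewickError(f"{path}: no trees found")
    return out


def _validate(tree: dendropy.Tree) -> None:
    seen: set[str] = set()
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not str(leaf.taxon.label).strip():
            raise NewickError("leaf with empty label")
        label = _norm_label(str(leaf.taxon.label))
        if label in seen:
            raise NewickError(f"duplicate leaf label: {label!r}")
        seen.add(label)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            ln = float(edge.length)
            if not (ln == ln) or ln in (float("inf"), float("-inf")) or ln < 0:
                raise NewickError(f"edge length {edge.length!r} is not finite and >= 0")


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to a single Newick statement ending in ';'."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        preserve_spaces=True,
    ).strip()
    return s if s.endswith(";") else s + ";"


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(_norm_label(str(l.taxon.label)) for l in tree.leaf_node_iter())


def extract_bipartitions(tree: dendropy.Tree, min_side: int = 2) -> set[Bipartition]:
    """All splits induced by the edges of the tree's unrooted form.

    Each internal edge contributes the split {leaves below} | {the rest};
    splits with either side smaller than ``min_side`` are dropped (with the
    default 2, only nontrivial splits survive, and a fully binary unrooted
    tree on n leaves yields exactly n-3). Rooting is ignored: the two edges
    meeting a degree-2 root induce the same split and are deduplicated.
    """
    all_taxa = leaf_labels(tree)
    splits: set[Bipartition] = set()
    for node, below in _leafsets(tree):
        other = all_taxa - below
        if len(below) >= min_side and len(other) >= min_side:
            splits.add(Bipartition(below, other))
    return splits


def _leafsets(tree: dendropy.Tree) -> Iterator[tuple[dendropy.Node, frozenset[str]]]:
    """Postorder (node, descendant-leaf-label set) pairs, excluding the root."""
    cache: dict[dendropy.Node, frozenset[str]] = {}
    root = tree.seed_node
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            cache[node] = frozenset({_norm_label(str(node.taxon.label))})
        else:
            cache[node] = frozenset().union(*(cache[c] for c in node.child_nodes()))
        if node is not root:
            yield node, cache[node]


def node_ages(
    chronogram: dendropy.Tree, tolerance: float = 1e-6
) -> dict[dendropy.Node, float]:
    """Node ages (Ma) of a rooted ultrametric tree; leaves are pinned to 0.

    The age of a node is root age minus its root-to-node path length, so a
    branch's span is exactly its edge length. Leaves must be contemporaneous
    within ``tolerance`` (relative to root age), otherwise
    :class:`NotUltrametricError` reports the most discrepant leaf pair.
    """
    depths: dict[dendropy.Node, float] = {chronogram.seed_node: 0.0}
    for node in chronogram.preorder_node_iter():
        if node is chronogram.seed_node:
            continue
        if node.edge.length is None:
            raise ValueError("chronogram edge without a length")
        depths[node] = depths[node.parent_node] + float(node.edge.length)
    leaves = [n for n in chronogram.leaf_node_iter()]
    if not leaves:
        raise ValueError("tree has no leaves")
    leaf_depths = {n: depths[n] for n in leaves}
    root_age = max(leaf_depths.values())
    shallow = min(leaves, key=lambda n: leaf_depths[n])
    deep = max(leaves, key=lambda n: leaf_depths[n])
    if root_age > 0 and (leaf_depths[deep] - leaf_depths[shallow]) > tolerance * root_age:
        raise NotUltrametricError(
            "leaves are not contemporaneous: "
            f"{deep.taxon.label!r} at depth {leaf_depths[deep]:g} vs "
            f"{shallow.taxon.label!r} at depth {leaf_depths[shallow]:g} "
            f"(tolerance {tolerance:g} relative to root age {root_age:g})"
        )
    ages = {}
    for node, d in depths.items():
        ages[node] = 0.0 if node.is_leaf() else root_age - d
    return ages


def branch_durations(
    chronogram: dendropy.Tree,
    include_terminal: bool = False,
    tolerance: float = 1e-6,
) -> list[BranchDuration]:
    """One entry per non-root branch: clade-vs-rest split and span in Ma.

    By default only internal branches are returned; ``include_terminal``
    adds each leaf's subtending branch (its "clade" is the single taxon).
    Root has no parent branch and never appears.
    """
    ages = node_ages(chronogram, tolerance=tolerance)
    all_taxa = leaf_labels(chronogram)
    out: list[BranchDuration] = []
    for node, below in _leafsets(chronogram):
        if node.is_leaf() and not include_terminal:
            continue
        duration = ages[node.parent_node] - ages[node]
        rest = all_taxa - below
        if not rest:
            continue  # degree-2 root child spanning all taxa
        out.append(BranchDuration(Bipartition(below, rest), below, duration))
    return out
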