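"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
import dendropy

from phyloconcord import Bipartition, leaf_labels
from phyloconcord.concordance import Verdict


@pytest.fixture
def rng():
    return np.random.default_rng(20160915)


def random_binary_tree(labels, rng) -> dendropy.Tree:
    """Random rooted binary tree with unit branch lengths (random joins)."""
    taxa = dendropy.TaxonNamespace()
    nodes = []
    for lab in labels:
        n = dendropy.Node()
        n.taxon = taxa.require_taxon(lab)
        n.edge.length = 1.0
        nodes.append(n)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = 1.0
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = nodes[0]
    tree.is_rooted = True
    return tree


def dendropy_splits(tree: dendropy.Tree) -> set[Bipartition]:
    """Nontrivial splits via dendropy's bipartition bitmask machinery.

    Independent of phyloconcord.extract_bipartitions: uses dendropy's
    encode_bipartitions() and decodes leafset bitmasks against the taxon
    namespace.
    """
    t = tree.clone(depth=1)
    t.is_rooted = False
    t.update_bipartitions(suppress_unifurcations=True)
    ns = t.taxon_namespace
    present = leaf_labels(t)
    all_bits = 0
    for taxon in ns:
        if taxon.label in present:
            all_bits |= ns.taxon_bitmask(taxon)
    out = set()
    for bp in t.bipartition_encoding:
        mask = bp.leafset_bitmask
        side = frozenset(
            tx.label for tx in ns if ns.taxon_bitmask(tx) & mask
        ) & present
        other = present - side
        if len(side) >= 2 and len(other) >= 2:
            out.add(Bipartition(side, other))
    return out


def oracle_verdict(gene_tree: dendropy.Tree, bip: Bipartition) -> Verdict:
    """Brute-force support oracle: enumerate every induced split via dendropy.

    Restricts the constraint to the gene tree's taxa by set intersection,
    then checks literal membership among the splits enumerated by dendropy's
    bipartition encoding. Shares no code with gene_tree_supports.
    """
    present = leaf_labels(gene_tree)
    a = bip.side_a & present
    b = bip.side_b & present
    if len(a) < 2 or len(b) < 2:
        return Verdict.TRIVIAL
    if Bipartition(a, b) in dendropy_splits(gene_tree):
        return Verdict.SUPPORTS
    return Verdict.CONFLICTS_OR_UNRESOLVED
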