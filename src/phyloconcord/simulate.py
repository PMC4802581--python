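"""Synthetic phylogenomic data with the structure the pipeline assumes.

Three layers, composable per locus:

* gene trees under the multispecies coalescent (MSC) on a species
  chronogram, with incomplete lineage sorting controlled by per-branch
  coalescent-unit lengths (default: branch duration in Ma times one global
  scale factor);
* per-locus taxon dropout emulating sequence-capture inefficiency (each
  taxon retained i.i.d. with probability p; loci falling below a minimum
  taxon count are discarded);
* Jukes-Cantor sequence evolution along the gene tree, with optional
  end-masking of sequences by N runs to emulate ragged capture edges.

One root seed drives everything; per-locus generators are spawned
deterministically (numpy SeedSequence with the locus index as spawn key),
so any single locus can be regenerated in isolation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .locus_profile import LocusAlignment, make_alignment
from .tree_io import Bipartition, leaf_labels, node_ages, write_newick

__all__ = [
    "MSCModel",
    "DropoutModel",
    "SeqSimModel",
    "simulate_gene_tree",
    "apply_dropout",
    "simulate_alignment",
    "make_fixture_dataset",
    "yule_chronogram",
]

_NUCS = np.array(list("ACGT"))


@dataclass
class MSCModel:
    """Species chronogram plus the coalescent intensity of each branch.

    ``scale`` converts branch durations (Ma) to coalescent units; entries in
    ``branch_coalescent_lengths`` — keyed by the frozenset of descendant
    leaf labels — override the scaled duration for specific branches. The
    branch above the root is infinite: all lineages coalesce there.
    """

    species_tree: dendropy.Tree
    scale: float = 0.5  # coalescent units per Ma
    branch_coalescent_lengths: Mapping[frozenset, float] = field(default_factory=dict)

    def branch_cu(self, node: dendropy.Node, clade: frozenset[str]) -> float:
        if clade in self.branch_coalescent_lengths:
            return float(self.branch_coalescent_lengths[clade])
        if node.edge.length is None:
            raise ValueError("species tree branch without a length")
        return float(node.edge.length) * self.scale


@dataclass
class DropoutModel:
    """I.i.d. per-taxon-per-locus retention; loci below min_taxa are discarded."""

    retention_prob: float = 121.0 / 131.0
    min_taxa: int = 4

    def __post_init__(self):
        if not 0.0 <= self.retention_prob <= 1.0:
            raise ValueError("retention_prob must be in [0, 1]")


@dataclass
class SeqSimModel:
    """Jukes-Cantor sequence evolution: equal rates between all nucleotides.

    ``rate`` converts gene-tree coalescent-unit branch lengths into expected
    substitutions per site. Expected pairwise difference at distance d is
    (3/4)(1 - exp(-4d/3)).
    """

    locus_length: int = 482
    rate: float = 0.01  # substitutions/site per coalescent unit

    def __post_init__(self):
        if self.locus_length < 1:
            raise ValueError("locus_length must be >= 1")


class _Lineage:
    __slots__ = ("node", "age")

    def __init__(self, node: dendropy.Node, age: float):
        self.node = node
        self.age = age  # cu-age at which this lineage's subtree node was created


def simulate_gene_tree(model: MSCModel, rng: np.random.Generator) -> dendropy.Tree:
    """One gene tree under the multispecies coalescent, one lineage per species.

    Within each species-tree branch of coalescent length L, the k extant
    gene lineages coalesce with exponential waiting times at rate
    k(k-1)/2; lineages still distinct after L are passed toward the root.
    The root branch is infinite, so the result is always a rooted binary
    tree on the retained taxa, with branch lengths in coalescent units.
    When all branch intensities come from one global scale the tree is
    ultrametric in coalescent units and every coalescence is at least as
    old as the corresponding species divergence.
    """
    taxa = dendropy.TaxonNamespace()
    sp_root = model.species_tree.seed_node
    pools: dict[dendropy.Node, list[_Lineage]] = {}
    leafset: dict[dendropy.Node, frozenset[str]] = {}
    start: dict[dendropy.Node, float] = {}  # cu age at the bottom of each branch
    branch_len: dict[dendropy.Node, float] = {}
    for sp_node in model.species_tree.postorder_node_iter():
        if sp_node.is_leaf():
            label = " ".join(str(sp_node.taxon.label).split())
            leafset[sp_node] = frozenset({label})
            gnode = dendropy.Node()
            gnode.taxon = taxa.require_taxon(label)
            pools[sp_node] = [_Lineage(gnode, 0.0)]
            start[sp_node] = 0.0
        else:
            leafset[sp_node] = frozenset().union(
                *(leafset[c] for c in sp_node.child_nodes())
            )
            pool = [ln for c in sp_node.child_nodes() for ln in pools[c]]
            pools[sp_node] = pool
            start[sp_node] = max(
                start[c] + branch_len[c] for c in sp_node.child_nodes()
            )
        cu = (
            math.inf
            if sp_node is sp_root
            else model.branch_cu(sp_node, leafset[sp_node])
        )
        branch_len[sp_node] = cu
        _coalesce(pools[sp_node], start[sp_node], cu, rng)
    (root_lineage,) = pools[sp_root]
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root_lineage.node
    tree.is_rooted = True
    return tree


def _coalesce(
    pool: list[_Lineage], start: float, cu: float, rng: np.random.Generator
) -> None:
    """Coalesce lineages in place within a branch spanning [start, start+cu].

    Each lineage's ``age`` is the cu-age at which its subtree node was
    created (0 for leaves), so the edge length assigned at a coalescence is
    the full span from that node up to the coalescence time.
    """
    t = start
    while len(pool) > 1:
        k = len(pool)
        t += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        if t > start + cu:
            break
        i, j = rng.choice(k, size=2, replace=False)
        a, b = pool[i], pool[j]
        parent = dendropy.Node()
        for child in (a, b):
            child.node.edge.length = t - child.age
            parent.add_child(child.node)
        merged = _Lineage(parent, t)
        pool[:] = [ln for idx, ln in enumerate(pool) if idx not in (i, j)]
        pool.append(merged)


def apply_dropout(
    tree: dendropy.Tree, model: DropoutModel, rng: np.random.Generator
) -> dendropy.Tree | None:
    """Retain each leaf i.i.d. with probability p; None when < min_taxa remain.

    The returned tree is the induced subtree on the retained leaves with
    degree-2 nodes suppressed (their branch lengths merged).
    """
    leaves = sorted(tree.leaf_node_iter(), key=lambda n: str(n.taxon.label))
    keep = [lf for lf in leaves if rng.random() < model.retention_prob]
    if len(keep) < model.min_taxa:
        return None
    if len(keep) == len(leaves):
        return tree.clone(depth=1)
    pruned = tree.clone(depth=1)
    labels = {str(lf.taxon.label) for lf in keep}
    pruned.retain_taxa_with_labels(sorted(labels))
    return pruned


def simulate_alignment(
    gene_tree: dendropy.Tree,
    model: SeqSimModel,
    rng: np.random.Generator,
    mask_fraction: float = 0.0,
) -> LocusAlignment:
    """Evolve sequences along the gene tree under Jukes-Cantor.

    The root sequence is uniform over {A,C,G,T}; each branch substitutes
    each site with probability (3/4)(1 - exp(-4d/3)) for d = branch length
    in coalescent units times the model rate, drawing uniformly among the
    other three nucleotides. ``mask_fraction`` > 0 additionally replaces a
    random-length run at each sequence end with N (mean total masked share
    per sequence = mask_fraction), emulating ragged capture edges.
    """
    L = model.locus_length
    seqs: dict[str, np.ndarray] = {}
    root_seq = rng.integers(0, 4, size=L)
    stack = [(gene_tree.seed_node, root_seq)]
    while stack:
        node, seq = stack.pop()
        for child in node.child_nodes():
            if child.edge.length is None:
                raise ValueError("gene tree branch without a length")
            d = float(child.edge.length) * model.rate
            p_sub = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
            child_seq = seq.copy()
            hits = rng.random(L) < p_sub
            n_hits = int(hits.sum())
            if n_hits:
                child_seq[hits] = (child_seq[hits] + rng.integers(1, 4, size=n_hits)) % 4
            stack.append((child, child_seq))
        if node.is_leaf():
            seqs[" ".join(str(node.taxon.label).split())] = seq
    out = {}
    for label in sorted(seqs):
        chars = _NUCS[seqs[label]]
        if mask_fraction > 0.0:
            # two geometric-ish end runs; mean combined share ~= mask_fraction
            n_left = int(rng.exponential(mask_fraction * L / 2.0))
            n_right = int(rng.exponential(mask_fraction * L / 2.0))
            chars = chars.copy()
            if n_left:
                chars[: min(n_left, L)] = "N"
            if n_right:
                chars[max(L - n_right, 0):] = "N"
        out[label] = "".join(chars)
    return make_alignment("locus", out)


def yule_chronogram(
    n_taxa: int, root_age: float, rng: np.random.Generator
) -> dendropy.Tree:
    """A random ultrametric species tree (pure-birth shape) scaled to root_age.

    Built by successive random coalescences with pure-birth node depths,
    then rescaled so the root sits at ``root_age`` Ma. Leaf labels are
    t001..tNNN.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    import random as _random

    seed = int(rng.integers(0, 2**31 - 1))
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=_random.Random(seed),
    )
    for i, leaf in enumerate(
        sorted(tree.leaf_node_iter(), key=lambda n: str(n.taxon.label))
    ):
        leaf.taxon.label = f"t{i + 1:03d}"
    ages = _depths(tree)
    max_depth = max(ages.values())
    if max_depth <= 0:
        raise ValueError("degenerate simulated tree")
    f = root_age / max_depth
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(edge.length) * f
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    return tree


def _depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    d = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        d[node] = d[node.parent_node] + float(node.edge.length or 0.0)
    return {lf: d[lf] for lf in tree.leaf_node_iter()}


# ---------------------------------------------------------------------------
# fixture datasets

_DEFAULT_CLASSES = (("uce", 541), ("protein_coding", 44))
# per-class emulation targets: retention prob, mean length, length bounds, JC rate
_CLASS_PARAMS = {
    "uce": {"retention": 121.0 / 131.0, "len_mean": 482, "len_sd": 75,
            "len_lo": 284, "len_hi": 713, "rate": 0.01},
    "protein_coding": {"retention": 118.0 / 131.0, "len_mean": 538, "len_sd": 55,
                       "len_lo": 355, "len_hi": 664, "rate": 0.02},
}


def _locus_rng(seed: int, locus_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(locus_index,)))


def make_fixture_dataset(
    out_dir,
    seed: int,
    n_loci: int | None = None,
    n_taxa: int = 131,
    root_age: float = 37.0,
    scale: float = 0.5,
    min_taxa: int = 4,
    mask_fraction: float = 0.08,
    species_tree: dendropy.Tree | None = None,
    class_counts: Sequence[tuple[str, int]] | None = None,
) -> dict:
    """Write a complete synthetic dataset and return its manifest.

    Defaults emulate a targeted-sequence-capture study of a rapid
    radiation: 585 loci (541 ultraconserved elements and 44 protein-coding
    loci) over 131 taxa on a 37-Ma chronogram, with class-specific taxon
    retention (means 121/131 and 118/131), alignment lengths, and
    substitution rates. Outputs: ``chronogram.nwk``, per-locus
    ``gene_trees/*.nwk`` and ``alignments/*.fasta``, ``manifest.tsv``
    (locus id, class, status, retained taxa), and ``params.json``
    recording every parameter and the root seed. Byte-identical across
    reruns with the same seed.
    """
    out = Path(out_dir)
    if class_counts is None:
        class_counts = _DEFAULT_CLASSES
    if n_loci is not None:
        total = sum(c for _, c in class_counts)
        class_counts = [
            (name, max(0, round(c * n_loci / total))) for name, c in class_counts
        ]
        short = n_loci - sum(c for _, c in class_counts)
        if short and class_counts:
            name0, c0 = class_counts[0]
            class_counts[0] = (name0, c0 + short)
    if sum(c for _, c in class_counts) < 1:
        raise ValueError("n_loci must be >= 1")
    (out / "gene_trees").mkdir(parents=True, exist_ok=True)
    (out / "alignments").mkdir(parents=True, exist_ok=True)

    root_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0xC0FFEE,)))
    if species_tree is None:
        species_tree = yule_chronogram(n_taxa, root_age, root_rng)
    (out / "chronogram.nwk").write_text(write_newick(species_tree) + "\n")
    msc = MSCModel(species_tree=species_tree, scale=scale)

    manifest_rows = []
    idx = 0
    for cls_name, count in class_counts:
        params = _CLASS_PARAMS.get(cls_name, _CLASS_PARAMS["uce"])
        dropout = DropoutModel(retention_prob=params["retention"], min_taxa=min_taxa)
        for _ in range(count):
            idx += 1
            locus_id = f"locus_{idx:04d}"
            rng = _locus_rng(seed, idx)
            gt = simulate_gene_tree(msc, rng)
            kept = apply_dropout(gt, dropout, rng)
            if kept is None:
                manifest_rows.append((locus_id, cls_name, "DISCARDED", 0))
                continue
            length = int(
                np.clip(
                    round(rng.normal(params["len_mean"], params["len_sd"])),
                    params["len_lo"],
                    params["len_hi"],
                )
            )
            aln = simulate_alignment(
                kept,
                SeqSimModel(locus_length=length, rate=params["rate"]),
                rng,
                mask_fraction=mask_fraction,
            )
            (out / "gene_trees" / f"{locus_id}.nwk").write_text(
                write_newick(kept) + "\n"
            )
            with open(out / "alignments" / f"{locus_id}.fasta", "w") as fh:
                for name in sorted(aln.sequences):
                    fh.write(f">{name}\n{aln.sequences[name]}\n")
            manifest_rows.append((locus_id, cls_name, "OK", len(leaf_labels(kept))))

    with open(out / "manifest.tsv", "w") as fh:
        fh.write("locus_id\tlocus_class\tstatus\tn_taxa\n")
        for row in manifest_rows:
            fh.write("\t".join(map(str, row)) + "\n")
    params_log = {
        "seed": seed,
        "n_taxa": n_taxa,
        "root_age_ma": root_age,
        "coalescent_scale_per_ma": scale,
        "min_taxa": min_taxa,
        "mask_fraction": mask_fraction,
        "class_counts": [list(c) for c in class_counts],
        "class_params": {k: _CLASS_PARAMS[k] for k, _ in class_counts
                         if k in _CLASS_PARAMS},
    }
    (out / "params.json").write_text(json.dumps(params_log, indent=2, sort_keys=True) + "\n")
    manifest = {
        "out_dir": str(out),
        "n_loci": len(manifest_rows),
        "n_ok": sum(1 for r in manifest_rows if r[2] == "OK"),
        "n_discarded": sum(1 for r in manifest_rows if r[2] == "DISCARDED"),
        "rows": manifest_rows,
    }
    return manifest
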