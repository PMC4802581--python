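"""Gene-tree support for species-tree bipartitions, with missing-taxon pruning.

The procedure mirrors monophyly-constraint filtering as done in PAUP*: each
reference bipartition is treated as a monophyly constraint, taxa absent from
a gene tree are removed from the constraint, and the gene tree either
contains the restricted split (SUPPORTS) or does not. A constraint whose
restricted form has fewer than two taxa on either side is vacuous (TRIVIAL).
Tallies across loci keep a fixed denominator — the total number of gene
trees — matching a "k of N loci" report.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import pandas as pd

from .tree_io import (
    Bipartition,
    BranchDuration,
    extract_bipartitions,
    leaf_labels,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Verdict",
    "PrunedConstraint",
    "prune_constraint",
    "gene_tree_supports",
    "tally",
    "congruence_report",
    "write_table",
]


class Verdict(enum.Enum):
    """Outcome of testing one gene tree against one bipartition."""

    SUPPORTS = "supports"
    CONFLICTS_OR_UNRESOLVED = "conflicts_or_unresolved"
    TRIVIAL = "trivial"


@dataclass(frozen=True)
class PrunedConstraint:
    """A bipartition restricted to the taxa actually present in a gene tree."""

    original: Bipartition
    restricted: Bipartition | None  # None when a side vanished entirely
    taxa_removed: frozenset[str]

    @property
    def trivial(self) -> bool:
        """Vacuous constraint: either restricted side has < 2 taxa."""
        if self.restricted is None:
            return True
        return min(len(self.restricted.side_a), len(self.restricted.side_b)) < 2


def prune_constraint(bip: Bipartition, present: Iterable[str]) -> PrunedConstraint:
    """Remove taxa absent from a gene tree from a monophyly constraint.

    ``present`` is the gene tree's leaf label set. Each side of ``bip`` is
    intersected with it; the result is flagged trivial when either side
    drops below two taxa, because a one-taxon (or empty) monophyly
    constraint is satisfied by every tree.
    """
    p = frozenset(present)
    if not p:
        raise ValueError("present taxon set is empty")
    restricted = bip.restrict(p)
    return PrunedConstraint(bip, restricted, bip.taxa - p)


def gene_tree_supports(
    gene_tree: dendropy.Tree,
    bip: Bipartition,
    mode: str = "hard",
    _splits: set[Bipartition] | None = None,
) -> Verdict:
    """Does one gene tree support one reference bipartition?

    The gene tree is treated as unrooted. The constraint is first pruned to
    the gene tree's taxa; a vacuous constraint is TRIVIAL. Under the default
    ``hard`` mode the verdict is SUPPORTS iff the restricted split is
    literally one of the gene tree's splits — a polytomy that merely fails
    to resolve the split counts as CONFLICTS_OR_UNRESOLVED, which is the
    containment semantics of constraint filtering on a resolved tree. Under
    ``soft`` mode, SUPPORTS additionally requires only compatibility: the
    restricted split conflicts with no split of the gene tree.

    ``_splits`` lets callers that test many bipartitions against the same
    tree pass a precomputed ``extract_bipartitions`` result.
    """
    if mode not in ("hard", "soft"):
        raise ValueError(f"unknown support mode {mode!r}")
    present = leaf_labels(gene_tree)
    extra = present - bip.taxa
    if extra:
        raise ValueError(
            f"gene tree contains taxa outside the reference set: {sorted(extra)}"
        )
    pruned = prune_constraint(bip, present)
    if pruned.trivial:
        return Verdict.TRIVIAL
    splits = _splits if _splits is not None else extract_bipartitions(gene_tree)
    assert pruned.restricted is not None
    if pruned.restricted in splits:
        return Verdict.SUPPORTS
    if mode == "soft" and all(
        pruned.restricted.is_compatible_with(s) for s in splits
    ):
        return Verdict.SUPPORTS
    return Verdict.CONFLICTS_OR_UNRESOLVED


def tally(
    gene_trees: Sequence[dendropy.Tree],
    bips: Sequence[Bipartition],
    trivial_policy: str = "count_as_support",
    mode: str = "hard",
) -> pd.DataFrame:
    """Tally support for each bipartition across all gene trees.

    Returns one row per bipartition with columns ``bipartition`` (the
    object), ``clade_taxa`` (smaller side, ';'-joined), ``n_support``,
    ``n_trivial``, ``n_other``, ``denominator``, ``fraction``. The
    denominator is always the full gene-tree count. Under the default
    ``count_as_support`` policy a vacuously satisfied constraint counts
    toward the fraction, i.e. fraction = (n_support + n_trivial)/N; under
    ``exclude`` it is n_support/N.
    """
    if not len(gene_trees):
        raise ValueError("no gene trees given")
    if not len(bips):
        raise ValueError("no bipartitions given")
    if trivial_policy not in ("count_as_support", "exclude"):
        raise ValueError(f"unknown trivial policy {trivial_policy!r}")
    split_cache = [extract_bipartitions(t) for t in gene_trees]
    n = len(gene_trees)
    rows = []
    for i, bip in enumerate(bips):
        n_support = n_trivial = 0
        for tree, splits in zip(gene_trees, split_cache):
            v = gene_tree_supports(tree, bip, mode=mode, _splits=splits)
            if v is Verdict.SUPPORTS:
                n_support += 1
            elif v is Verdict.TRIVIAL:
                n_trivial += 1
        n_other = n - n_support - n_trivial
        numer = n_support + (n_trivial if trivial_policy == "count_as_support" else 0)
        rows.append(
            {
                "bipartition_id": f"bip_{i + 1:03d}",
                "bipartition": bip,
                "clade_taxa": ";".join(sorted(bip.smaller_side())),
                "n_support": n_support,
                "n_trivial": n_trivial,
                "n_other": n_other,
                "denominator": n,
                "fraction": numer / n,
            }
        )
    return pd.DataFrame(rows)


def congruence_report(
    table: pd.DataFrame, durations: Sequence[BranchDuration]
) -> pd.DataFrame:
    """Attach chronogram branch durations (Ma) to a congruence table.

    Branches are matched to table rows by their unordered split of the full
    taxon set. The two branches meeting a rooted chronogram's root induce
    the same split; their durations are summed, that being the length of the
    single corresponding unrooted edge. Rows with no matching branch keep an
    empty duration and are counted in the log.
    """
    dur_by_split: dict[Bipartition, float] = {}
    for bd in durations:
        dur_by_split[bd.bipartition] = dur_by_split.get(bd.bipartition, 0.0) + bd.duration_ma
    out = table.copy()
    out["duration_ma"] = [dur_by_split.get(b) for b in out["bipartition"]]
    n_unmatched = int(out["duration_ma"].isna().sum())
    if n_unmatched:
        logger.warning(
            "%d of %d bipartitions have no matching chronogram branch",
            n_unmatched,
            len(out),
        )
    return out


def write_table(table: pd.DataFrame, path) -> None:
    """Write a congruence table as TSV, dropping the in-memory split objects."""
    cols = [c for c in table.columns if c != "bipartition"]
    table[cols].to_csv(path, sep="\t", index=False, lineterminator="\n")
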