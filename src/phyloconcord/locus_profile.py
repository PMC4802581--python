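"""Per-locus alignment statistics: taxa, length, variation, PIC, missing data.

A parsimony-informative character (PIC) is an alignment column with at
least two unambiguous nucleotide states each present in at least two
sequences. Ambiguity codes and missing symbols never count as states;
'-', 'N' and '?' count as missing cells. Summaries are rendered in
"mean (min-max)" form, grouped by locus class (e.g. ultraconserved
elements vs protein-coding loci).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO

from .stats import RegressionFit, linear_fit

__all__ = [
    "LocusAlignment",
    "SiteClass",
    "LocusProfile",
    "AlignmentFormatError",
    "read_alignment",
    "classify_site",
    "profile_locus",
    "summarize_profiles",
    "length_vs_informative",
]

_UNAMBIGUOUS = frozenset("ACGT")
_MISSING = frozenset("-N?")
_AMBIGUITY = frozenset("RYSWKMBDHV")
_LEGAL = _UNAMBIGUOUS | _MISSING | _AMBIGUITY

_FORMAT_MAP = {
    "fasta": "fasta",
    "phylip_relaxed": "phylip-relaxed",
    "nexus": "nexus",
}


class AlignmentFormatError(ValueError):
    pass


class SiteClass(enum.Enum):
    CONSTANT = "constant"
    VARIABLE_UNINFORMATIVE = "variable_uninformative"
    PARSIMONY_INFORMATIVE = "parsimony_informative"
    ALL_MISSING = "all_missing"


@dataclass(frozen=True)
class LocusAlignment:
    """One locus: equal-length upper-case sequences keyed by taxon label."""

    locus_id: str
    sequences: Mapping[str, str]
    length: int

    def column(self, i: int) -> list[str]:
        return [s[i] for s in self.sequences.values()]


@dataclass(frozen=True)
class LocusProfile:
    locus_id: str
    n_taxa: int
    length: int
    n_variable: int
    pct_variation: float
    n_pic: int
    pct_missing: float


def make_alignment(locus_id: str, sequences: Mapping[str, str]) -> LocusAlignment:
    """Validate and normalize a taxon->sequence mapping into a LocusAlignment."""
    if len(sequences) < 2:
        raise AlignmentFormatError(f"{locus_id}: fewer than 2 sequences")
    seqs = {}
    length = None
    for name, seq in sequences.items():
        name = " ".join(str(name).split())
        if not name:
            raise AlignmentFormatError(f"{locus_id}: empty taxon label")
        if name in seqs:
            raise AlignmentFormatError(f"{locus_id}: duplicate taxon {name!r}")
        s = str(seq).upper()
        if length is None:
            length = len(s)
        elif len(s) != length:
            raise AlignmentFormatError(
                f"{locus_id}: ragged alignment — {name!r} has length "
                f"{len(s)}, expected {length}"
            )
        bad = set(s) - _LEGAL
        if bad:
            raise AlignmentFormatError(
                f"{locus_id}: illegal characters {sorted(bad)} in {name!r}"
            )
        seqs[name] = s
    if not length:
        raise AlignmentFormatError(f"{locus_id}: zero-length alignment")
    return LocusAlignment(locus_id, seqs, length)


def read_alignment(path, format: str = "fasta", locus_id: str | None = None) -> LocusAlignment:
    """Read one multiple sequence alignment (FASTA, relaxed PHYLIP, or NEXUS)."""
    if format not in _FORMAT_MAP:
        raise ValueError(
            f"unknown format {format!r}; expected one of {sorted(_FORMAT_MAP)}"
        )
    path = Path(path)
    lid = locus_id if locus_id is not None else path.stem
    try:
        msa = AlignIO.read(str(path), _FORMAT_MAP[format])
    except Exception as exc:
        raise AlignmentFormatError(f"{lid}: cannot parse as {format}: {exc}") from exc
    return make_alignment(lid, {rec.id: str(rec.seq) for rec in msa})


def classify_site(column: Sequence[str]) -> SiteClass:
    """Classify one alignment column for the variation/PIC counts.

    Only unambiguous A/C/G/T count as states. A column is
    PARSIMONY_INFORMATIVE iff >= 2 states each occur >= 2 times; CONSTANT
    with <= 1 distinct state (ALL_MISSING if zero); otherwise variable but
    uninformative (some state is a singleton).
    """
    counts: dict[str, int] = {}
    for ch in column:
        c = ch.upper()
        if c not in _LEGAL:
            raise ValueError(f"illegal character {ch!r} in column")
        if c in _UNAMBIGUOUS:
            counts[c] = counts.get(c, 0) + 1
    if not counts:
        return SiteClass.ALL_MISSING
    if len(counts) == 1:
        return SiteClass.CONSTANT
    if sum(1 for v in counts.values() if v >= 2) >= 2:
        return SiteClass.PARSIMONY_INFORMATIVE
    return SiteClass.VARIABLE_UNINFORMATIVE


def profile_locus(aln: LocusAlignment) -> LocusProfile:
    """Column-by-column statistics for one locus.

    n_variable counts both informative and uninformative variable columns;
    pct_variation is n_variable / length * 100; pct_missing is the share of
    '-', 'N', '?' cells among all n_taxa * length cells.
    """
    mat = np.array([list(s) for s in aln.sequences.values()])
    n_missing_cells = int(np.isin(mat, list(_MISSING)).sum())
    n_var = n_pic = 0
    for i in range(aln.length):
        cls = classify_site(mat[:, i])
        if cls is SiteClass.PARSIMONY_INFORMATIVE:
            n_pic += 1
            n_var += 1
        elif cls is SiteClass.VARIABLE_UNINFORMATIVE:
            n_var += 1
    n_taxa = len(aln.sequences)
    return LocusProfile(
        locus_id=aln.locus_id,
        n_taxa=n_taxa,
        length=aln.length,
        n_variable=n_var,
        pct_variation=100.0 * n_var / aln.length,
        n_pic=n_pic,
        pct_missing=100.0 * n_missing_cells / (n_taxa * aln.length),
    )


def profiles_frame(profiles: Iterable[LocusProfile]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in profiles])


_METRICS = ["n_taxa", "length", "pct_variation", "n_pic", "pct_missing"]


def summarize_profiles(
    profiles: Sequence[LocusProfile],
    classes: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-class mean/min/max of each locus metric, plus "mean (min-max)" text.

    ``classes`` maps locus_id to a class label (e.g. "uce" /
    "protein_coding"); unlisted loci fall into class "all".
    """
    if not profiles:
        raise ValueError("no profiles to summarize")
    df = profiles_frame(profiles)
    df["locus_class"] = (
        df["locus_id"].map(classes).fillna("all") if classes else "all"
    )
    rows = []
    for cls, grp in df.groupby("locus_class", sort=True):
        row: dict[str, object] = {"locus_class": cls, "n_loci": len(grp)}
        for m in _METRICS:
            mean, lo, hi = grp[m].mean(), grp[m].min(), grp[m].max()
            row[f"{m}_mean"] = mean
            row[f"{m}_min"] = lo
            row[f"{m}_max"] = hi
            row[f"{m}_report"] = f"{mean:.0f} ({lo:.0f}-{hi:.0f})"
        rows.append(row)
    return pd.DataFrame(rows)


def length_vs_informative(profiles: Sequence[LocusProfile]) -> RegressionFit:
    """OLS of informative-site count on alignment length across loci."""
    if len(profiles) < 3:
        raise ValueError("need at least 3 loci for a regression")
    x = [p.length for p in profiles]
    y = [p.n_pic for p in profiles]
    return linear_fit(x, y)
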