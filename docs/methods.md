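# Methods

## The concordance procedure

The unit of analysis is the **taxon bipartition**: the split of the full
taxon set induced by removing one edge of the species tree (equivalently,
a clade versus everything else on a rooted chronogram). For each
bipartition and each per-locus gene tree the package renders one of three
verdicts:

1. **Prune.** The bipartition is treated as a monophyly constraint.
   Taxa absent from the gene tree are removed from both sides of the
   constraint (sequence-capture loci routinely miss taxa, so this step is
   load-bearing, not cosmetic).
2. **Trivial?** If either side of the restricted constraint has fewer than
   two taxa the constraint is vacuous — every tree on the remaining taxa
   satisfies it — and the verdict is TRIVIAL.
3. **Support.** Otherwise the verdict is SUPPORTS exactly when the
   restricted split is literally one of the gene tree's splits, the gene
   tree being treated as unrooted throughout (estimated gene trees carry
   arbitrary rootings). Everything else — including a polytomy that merely
   fails to resolve the split — is CONFLICTS_OR_UNRESOLVED. This is the
   containment semantics of constraint-based tree filtering on a resolved
   tree ("hard" mode). A "soft" mode that also accepts splits merely
   *compatible* with the gene tree is exposed for sensitivity analysis;
   under it an unresolved polytomy counts as support.

Tallies report `n_support`, `n_trivial`, `n_other` per bipartition with a
**fixed denominator** equal to the total number of gene trees, so results
read as "k of N loci". By default trivial verdicts count toward the
supporting fraction (`count_as_support`), mirroring the vacuous
satisfaction of a ≤ 1-taxon monophyly constraint; the `exclude` policy is
available because either bookkeeping is defensible and the counts to
reconstruct both are always printed. Row conservation
(`n_support + n_trivial + n_other = N`) holds identically under both.

Key invariant (tested): deleting taxa from a gene tree can never turn
SUPPORTS into CONFLICTS_OR_UNRESOLVED while the restricted constraint
remains nontrivial, because the restriction of a displayed split is
displayed.

## Branch durations and the duration-concordance association

Chronograms are rooted ultrametric trees with edge lengths in Ma. Node age
is defined as root age minus root-to-node path length, leaves pinned to 0;
ultrametricity is enforced within a relative tolerance (default 1e-6 of
root age; violations report the worst leaf pair). A branch's duration is
its edge length, i.e. parent age minus node age.

When joining durations to bipartition tallies, the two branches meeting
the root induce the same unordered split; their durations are summed,
that sum being the length of the single corresponding edge of the
unrooted tree. The association is then an ordinary least squares fit of
the raw support count on duration (`fraction` is available as an
alternative response when denominators differ across datasets). Whether
terminal branches enter the duration set is a caller choice
(`include_terminal`); internal-only is the default since terminal-branch
"monophyly" is vacuous for single-taxon clades.

The OLS layer has pinned-down edge semantics: p-value from the slope's
two-sided t test on n − 2 df, clamped into (0, 1] on underflow;
R² defined as 0 (not NaN) for a zero-variance response;
adjusted R² = 1 − (1 − R²)(n − 1)/(n − 2).

## Locus profiles

Only unambiguous `A/C/G/T` count as character states. A column is
parsimony-informative iff ≥ 2 states each occur ≥ 2 times; constant with
≤ 1 distinct state (all-missing if none); otherwise variable but
uninformative. IUPAC ambiguity codes are excluded from state counts but
are **not** missing data; `-`, `N`, `?` are missing (the `?` is accepted
for robustness even though capture alignments rarely contain it).
"% variation" is variable columns over total alignment length — the
plainest reading; an alternative denominator excluding all-missing
columns was considered and rejected as harder to reconcile with reported
alignment lengths. Summaries render as "mean (min–max)" per locus class.

## The synthetic-data generator

The generator produces data with the statistical structure the analysis
assumes, not a mimic of any particular empirical dataset.

**Gene trees.** Standard multispecies coalescent with one sampled lineage
per species: within a species-tree branch of length L coalescent units,
k lineages coalesce with Exp(k(k−1)/2) waiting times; survivors pass
rootward; the root branch is infinite. Branch coalescent lengths default
to duration (Ma) × one global scale factor; per-branch overrides (keyed
by clade) allow geometry like "all coalescence opportunity concentrated
in one internal branch", which is how the closed-form quartet checks are
constructed. With a uniform scale the output is ultrametric in coalescent
units and every coalescence is at least as old as the corresponding
species divergence (tested). With overrides the timescale is
branch-local: branch *start* times are taken as the maximum cumulative
coalescent length over descendant paths, and no global clock is claimed.
No population-size or generation-time machinery is built, because the
analysis consumes only topologies and Ma durations; a single Ma→cu scale
is the entire knob. An independent implementation (msprime, with
population sizes chosen so one generation equals one coalescent unit)
reproduces the same quartet frequencies in the test suite.

**Dropout.** Each taxon is retained i.i.d. with probability p per locus;
loci with fewer than `min_taxa` retained taxa are discarded and listed in
the manifest. Defaults emulate capture data in which alignments of
131 individuals averaged 121 (UCE-style loci, p = 121/131) or 118
(protein-coding loci, p = 118/131). Real capture dropout is taxon-biased
(library quality, divergence from probes); the i.i.d. model reproduces
mean occupancy but not the long lower tail, so tests passing here say
nothing about taxon-correlated missingness.

**Sequences.** Jukes-Cantor along the gene tree: root drawn uniformly,
each site substituting independently with probability
(3/4)(1 − e^(−4d/3)) per branch of length d expected substitutions/site
(gene-tree coalescent units × a rate scalar). Optional end-masking
replaces exponential-length runs at both sequence ends with `N` (mean
combined share `mask_fraction`), emulating ragged capture edges; there is
no indel or rate-heterogeneity model, so simulated alignments are cleaner
than real ones — the profiling statistics exercise their definitions, not
empirical distributions.

**Defaults as study conditions.** The stock fixture writes 585 loci
(541 "uce" + 44 "protein_coding") over 131 taxa on a 37-Ma chronogram,
with class-specific clipped-normal alignment lengths
(482 bp mean, 284–713 for UCE; 538 bp mean, 355–664 for protein-coding)
and substitution rates 0.01 / 0.02 substitutions per site per coalescent
unit (protein-coding loci carry roughly twice the variation of UCEs).
The Ma→cu scale defaults to 0.5/Ma, which puts typical backbone branches
of such a chronogram in the 0.1–5 cu range — deep enough that long
branches approach full concordance, short enough that radiation-like
branches show heavy discordance. The species tree shape is pure-birth,
rescaled to the requested root age. Mean end-masking is 0.08.

**Reproducibility.** One root seed; per-locus generators are spawned as
`SeedSequence(seed, spawn_key=(locus_index,))`, so any locus regenerates
in isolation and a fixed seed fixes every output byte (tested at the
hash level).

## Problem sizes

The acceptance computations use 10,000 gene trees per branch length for
the quartet closed-form comparison (binomial 3-SE bands), 500 random
trees for the support-oracle equivalence, 1,000 random columns for the
site classifier, 20 seeded end-to-end runs of 300 loci on 12 taxa for the
duration-association sign check, 100 random datasets for OLS exactness,
and 1,000 loci at 131 taxa for dropout calibration. These sizes give
tolerance bands a few times tighter than the effects being checked while
keeping a full run in the tens of seconds.

## Known limitations

* Concordance is a containment count; it does not separate discordance
  caused by ILS from discordance caused by weak per-locus signal, and no
  quartet-frequency or internode-certainty machinery is included.
* Only Newick trees are parsed (no NEXUS translate tables); alignments may
  be FASTA, relaxed PHYLIP, or NEXUS data blocks.
* The simulator has no migration, hybridization, gene duplication, or
  multi-individual sampling; dropout is taxon-unbiased by default.
* The regression layer is simple OLS; branches of one tree are not
  independent data points, so p-values there are descriptive, not
  phylogenetically corrected.
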