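"""Multispecies-coalescent simulation, dropout, and sequence evolution."""

import hashlib
import math
import os

import numpy as np
import pytest

from phyloconcord import (
    Bipartition,
    DropoutModel,
    MSCModel,
    SeqSimModel,
    apply_dropout,
    extract_bipartitions,
    leaf_labels,
    make_fixture_dataset,
    node_ages,
    parse_newick,
    simulate_alignment,
    simulate_gene_tree,
    tally,
    yule_chronogram,
)


def quartet_model(t_cu: float) -> MSCModel:
    """Species tree where the only coalescent opportunity below the root is
    the (A,B) branch of length t_cu: quartet concordance is 1-(2/3)e^-t."""
    sp = parse_newick("(((A:1,B:1):1,C:2):1,D:3);", rooted_hint=True)
    return MSCModel(
        sp,
        scale=1.0,
        branch_coalescent_lengths={
            frozenset({"A", "B"}): t_cu,
            frozenset({"A", "B", "C"}): 0.0,
        },
    )


def quartet_frequencies(model, n, rng):
    splits = {
        "AB|CD": Bipartition({"A", "B"}, {"C", "D"}),
        "AC|BD": Bipartition({"A", "C"}, {"B", "D"}),
        "AD|BC": Bipartition({"A", "D"}, {"B", "C"}),
    }
    counts = dict.fromkeys(splits, 0)
    for _ in range(n):
        g = simulate_gene_tree(model, rng)
        found = extract_bipartitions(g)
        for name, s in splits.items():
            if s in found:
                counts[name] += 1
    return {k: v / n for k, v in counts.items()}


class TestMSC:
    def test_deep_branch_always_concordant(self, rng):
        freqs = quartet_frequencies(quartet_model(50.0), 300, rng)
        assert freqs["AB|CD"] == 1.0

    def test_zero_branch_uniform_topologies(self, rng):
        n = 3000
        freqs = quartet_frequencies(quartet_model(0.0), n, rng)
        se = 3 * math.sqrt((1 / 3) * (2 / 3) / n)
        for f in freqs.values():
            assert abs(f - 1 / 3) < se

    def test_unit_branch_matches_closed_form(self, rng):
        n = 4000
        expected = 1 - (2 / 3) * math.exp(-1)
        freqs = quartet_frequencies(quartet_model(1.0), n, rng)
        se = 3 * math.sqrt(expected * (1 - expected) / n)
        assert abs(freqs["AB|CD"] - expected) < se
        # the two discordant topologies are equifrequent
        d = (1 - expected) / 2
        se_d = 3 * math.sqrt(d * (1 - d) / n)
        assert abs(freqs["AC|BD"] - d) < se_d
        assert abs(freqs["AD|BC"] - d) < se_d

    def test_matches_msprime_oracle(self, rng):
        """Independent MSC implementation agrees on quartet frequencies.

        msprime simulates the same species tree with population sizes set
        so one generation equals one coalescent unit (haploid samples,
        initial_size=1).
        """
        msprime = pytest.importorskip("msprime")
        t = 0.8
        expected = 1 - (2 / 3) * math.exp(-t)
        n = 2000

        # internal branch above the (A,B) ancestor has length t; the branch
        # above the (A,B,C) ancestor is effectively zero
        nwk = f"(((A:1,B:1):{t},C:{1 + t}):0.0001,D:{1 + t + 0.0001});"
        sp = parse_newick(nwk, rooted_hint=True)
        mine = quartet_frequencies(MSCModel(sp, scale=1.0), n, rng)["AB|CD"]

        demography = msprime.Demography.from_species_tree(nwk, initial_size=1)
        target = {frozenset({"A", "B"}), frozenset({"C", "D"})}
        pop_name = {}
        conc = 0
        reps = msprime.sim_ancestry(
            samples={"A": 1, "B": 1, "C": 1, "D": 1},
            demography=demography,
            ploidy=1,
            num_replicates=n,
            random_seed=1234,
        )
        for ts in reps:
            tree = ts.first()
            names = {
                s: ts.population(ts.node(s).population).metadata["name"]
                for s in ts.samples()
            }
            clades = {
                frozenset(names[s] for s in tree.samples(u))
                for u in tree.nodes()
                if len(list(tree.samples(u))) == 2
            }
            if clades & target:
                conc += 1
        se = 3 * math.sqrt(expected * (1 - expected) / n)
        assert abs(mine - expected) < se
        assert abs(conc / n - expected) < se

    def test_no_time_travel(self, rng):
        """Gene-tree coalescences are never younger than species divergences."""
        sp = yule_chronogram(8, 20.0, rng)
        model = MSCModel(sp, scale=0.3)
        sp_ages = {
            frozenset(lbl for lbl in _clade_labels(n)): age * model.scale
            for n, age in node_ages(sp).items()
        }
        for _ in range(40):
            g = simulate_gene_tree(model, rng)
            g_ages = node_ages(g, tolerance=1e-6)
            for node, age in g_ages.items():
                if node.is_leaf():
                    continue
                clade = frozenset(_clade_labels(node))
                # species MRCA age of the clade
                mrca = min(
                    (a for c, a in sp_ages.items() if clade <= c),
                    default=0.0,
                )
                assert age >= mrca - 1e-9


def _clade_labels(node):
    return [str(l.taxon.label) for l in node.leaf_iter()]


class TestDropout:
    def test_full_retention_is_identity(self, rng):
        t = yule_chronogram(10, 5.0, rng)
        kept = apply_dropout(t, DropoutModel(retention_prob=1.0, min_taxa=2), rng)
        assert leaf_labels(kept) == leaf_labels(t)
        assert extract_bipartitions(kept) == extract_bipartitions(t)

    def test_total_loss_discarded(self, rng):
        t = yule_chronogram(6, 5.0, rng)
        assert apply_dropout(t, DropoutModel(retention_prob=0.0, min_taxa=3), rng) is None

    def test_mean_retention_matches_target(self, rng):
        """N=131, p=121/131: mean retained taxa tracks the expectation."""
        t = yule_chronogram(131, 37.0, rng)
        model = DropoutModel()  # default p = 121/131
        n_loci = 400
        kept = [
            len(leaf_labels(apply_dropout(t, model, rng))) for _ in range(n_loci)
        ]
        se = math.sqrt(131 * model.retention_prob * (1 - model.retention_prob) / n_loci)
        assert abs(np.mean(kept) - 121.0) < 4 * se

    def test_pruned_tree_branch_lengths_merge(self, rng):
        t = parse_newick("(((A:1,B:1):1,C:2):1,D:3);", rooted_hint=True)
        model = DropoutModel(retention_prob=0.5, min_taxa=2)
        for _ in range(20):
            kept = apply_dropout(t, model, rng)
            if kept is None or len(leaf_labels(kept)) == 4:
                continue
            ages = node_ages(kept)  # still ultrametric after suppression
            assert max(ages.values()) <= 3.0 + 1e-9


class TestSequenceSim:
    def test_zero_lengths_identical_sequences(self, rng):
        g = parse_newick("((A:0,B:0):0,C:0);", rooted_hint=True)
        aln = simulate_alignment(g, SeqSimModel(locus_length=100, rate=0.01), rng)
        assert len(set(aln.sequences.values())) == 1

    def test_jc_pairwise_distance(self, rng):
        """Observed p-distance matches (3/4)(1-exp(-4d/3)) at d=0.1."""
        g = parse_newick("(A:5,B:5);", rooted_hint=True)
        L = 20000
        aln = simulate_alignment(g, SeqSimModel(locus_length=L, rate=0.01), rng)
        a, b = (aln.sequences[k] for k in ("A", "B"))
        p_obs = sum(x != y for x, y in zip(a, b)) / L
        p_exp = 0.75 * (1 - math.exp(-4 * 0.1 / 3))
        assert abs(p_obs - p_exp) < 3 * math.sqrt(p_exp * (1 - p_exp) / L)

    def test_saturation_limit(self, rng):
        g = parse_newick("(A:5000,B:5000);", rooted_hint=True)
        L = 20000
        aln = simulate_alignment(g, SeqSimModel(locus_length=L, rate=1.0), rng)
        a, b = (aln.sequences[k] for k in ("A", "B"))
        ident = sum(x == y for x, y in zip(a, b)) / L
        assert abs(ident - 0.25) < 3 * math.sqrt(0.25 * 0.75 / L)

    def test_missing_branch_length_rejected(self, rng):
        g = parse_newick("((A,B),C);", rooted_hint=True)
        with pytest.raises(ValueError):
            simulate_alignment(g, SeqSimModel(locus_length=10), rng)

    def test_end_masking_adds_missing_data(self, rng):
        g = parse_newick("(A:1,B:1);", rooted_hint=True)
        aln = simulate_alignment(
            g, SeqSimModel(locus_length=2000, rate=0.001), rng, mask_fraction=0.2
        )
        from phyloconcord import profile_locus

        assert profile_locus(aln).pct_missing > 0


class TestFixtureDataset:
    def _digest(self, d):
        h = hashlib.sha256()
        for root, _, files in sorted(os.walk(d)):
            for f in sorted(files):
                h.update((f + "\0").encode())
                h.update(open(os.path.join(root, f), "rb").read())
        return h.hexdigest()

    def test_fixed_seed_byte_identical(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        make_fixture_dataset(a, seed=11, n_loci=8, n_taxa=10, root_age=10.0)
        make_fixture_dataset(b, seed=11, n_loci=8, n_taxa=10, root_age=10.0)
        assert self._digest(a) == self._digest(b)

    def test_different_seed_differs(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        make_fixture_dataset(a, seed=11, n_loci=8, n_taxa=10, root_age=10.0)
        make_fixture_dataset(b, seed=12, n_loci=8, n_taxa=10, root_age=10.0)
        assert self._digest(a) != self._digest(b)

    def test_file_inventory_and_manifest(self, tmp_path):
        d = tmp_path / "fx"
        m = make_fixture_dataset(d, seed=5, n_loci=10, n_taxa=12, root_age=10.0)
        assert m["n_loci"] == 10
        assert (d / "chronogram.nwk").exists()
        assert (d / "params.json").exists()
        n_trees = len(list((d / "gene_trees").glob("*.nwk")))
        n_alns = len(list((d / "alignments").glob("*.fasta")))
        assert n_trees == n_alns == m["n_ok"]

    def test_aggressive_dropout_lists_discarded(self, tmp_path):
        d = tmp_path / "fx"
        # min_taxa above the taxon count forces universal discards
        m = make_fixture_dataset(
            d, seed=5, n_loci=5, n_taxa=6, root_age=10.0, min_taxa=7
        )
        assert m["n_discarded"] == 5
        lines = (d / "manifest.tsv").read_text().splitlines()
        assert sum("DISCARDED" in l for l in lines) == 5

    def test_zero_loci_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            make_fixture_dataset(tmp_path / "z", seed=1, n_loci=0)


class TestEndToEndMSCPattern:
    def test_concordance_tracks_branch_length(self, rng):
        """Tallied support rises with coalescent branch length (ILS signal)."""
        fractions = []
        target = Bipartition({"A", "B"}, {"C", "D"})
        for t_cu in (0.1, 1.0, 3.0):
            model = quartet_model(t_cu)
            trees = [simulate_gene_tree(model, rng) for _ in range(400)]
            table = tally(trees, [target])
            fractions.append(table["fraction"].iloc[0])
        assert fractions[0] < fractions[1] < fractions[2]
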