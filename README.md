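# phyloconcord

Tools for diagnosing a rapid evolutionary radiation from phylogenomic data.
Rapid radiations pack speciation events into short time intervals, leaving
individual loci little opportunity to accumulate substitutions; the result
is pervasive gene-tree discordance driven by low per-locus signal and by
incomplete lineage sorting (ILS). `phyloconcord` implements the desk-side
computations of that diagnosis:

* **Per-locus informativeness profiling** — for each multiple sequence
  alignment: taxon count, length, % variable sites, parsimony-informative
  characters (PIC: columns with ≥ 2 states each in ≥ 2 sequences), and
  missing data (gaps, `N`, `?`), with "mean (min–max)" summaries per locus
  class and the length-vs-PIC regression.
* **Gene-tree concordance tallying** — for each taxon bipartition of a
  reference species tree, the number of per-locus gene trees that contain
  it. Each bipartition acts as a monophyly constraint; taxa absent from a
  gene tree are removed from the constraint first, and a constraint reduced
  below two taxa on either side is vacuously satisfied. Tallies are
  reported as "k of N loci" with a fixed denominator.
* **Concordance vs branch duration** — joins each bipartition to its branch
  duration in Ma on an ultrametric chronogram and fits the ordinary least
  squares regression of support on duration. Under ILS, branches spanning
  short intervals should attract little gene-tree support: for a quartet
  separated by an internal branch of t coalescent units, the gene tree
  matches the species tree with probability 1 − (2/3)e⁻ᵗ.
* **Synthetic data** — a multispecies-coalescent gene-tree simulator
  (lineages coalesce within each species-tree branch at rate k(k−1)/2 per
  coalescent unit), i.i.d. per-taxon-per-locus dropout emulating
  sequence-capture inefficiency, and Jukes-Cantor sequence evolution, so
  the whole pipeline is exercisable without any external data.

## Worked example

```bash
cd examples
python 01_simulate_dataset.py      # 40 loci, 20 taxa, 20-Ma chronogram
python 02_locus_profiles.py
python 03_concordance_vs_duration.py
python 04_msc_closed_form.py
```

`02_locus_profiles.py` prints, for the simulated dataset:

```
   locus_class  n_loci n_taxa_report length_report pct_variation_report  n_pic_report
protein_coding       3    19 (18-20) 574 (521-610)           82 (81-83) 336 (327-347)
           uce      37    18 (16-20) 471 (307-664)           60 (55-70)  152 (90-236)

PIC ~ length: slope=0.541, adjusted R^2=0.518, p=9.99e-08 over 40 loci
```

Each row summarizes one locus class as "mean (min–max)" across loci; the
regression says each extra alignment column adds about half a
parsimony-informative site in this simulation. `03_concordance_vs_duration.py`
then tallies gene-tree support per chronogram bipartition and reports

```
support ~ duration: slope=1.051 loci/Ma, R^2=0.357, p=0.0113 (n=17 branches)
```

— a positive slope: branches spanning longer intervals are recovered by
more gene trees, while the shortest branches (the radiation itself) attract
the least support. `04_msc_closed_form.py` compares simulated quartet
concordance with 1 − (2/3)e⁻ᵗ:

```
 t (cu)  simulated  1-(2/3)e^-t
    0.0      0.339        0.333
    1.0      0.757        0.755
    2.0      0.903        0.910
```

## Command line

The same pipeline is available from a shell:

```bash
phyloconcord simulate    --n-loci 100 --n-taxa 20 --root-age 20 --seed 1 --out data/
phyloconcord profile     --alignments data/alignments --out prof/
phyloconcord concordance --gene-trees data/gene_trees \
    --species-tree data/chronogram.nwk --chronogram data/chronogram.nwk --out conc/
```

Outputs are TSV tables plus a `run_config.json` that makes every run
reproducible. Exit codes: 0 success, 2 input error, 3 empty result.

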