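# symarch

Comparative genome-architecture and gene-family-enrichment analyses for
dinoflagellate genomes, built around the genus *Symbiodinium* — the
photosynthetic endosymbionts of reef-building corals. Dinoflagellate genomes
are unusual among eukaryotes: genes tend to lie on the same strand in long
unidirectional runs, splice donors use non-canonical dinucleotides (GC and GA
alongside GT), gene order is barely conserved even between congeneric
species, and gene families — notably bicarbonate and ammonium transporters —
expand by lineage-specific duplication. `symarch` packages the statistics
used to quantify each of these observations as a tested, reusable library
with a thin CLI, plus seeded synthetic-data generators that plant known
parameters so every analysis stage can be validated by recovery.

It is aimed at comparative genomicists who have assemblies (FASTA), gene
models (GFF3), homology-search tables (blast outfmt-6), domain hits
(HMMER-style), and gene trees (Newick) in hand, and want the downstream
summary statistics — not at users looking for an assembler or gene predictor.

## What it computes

* **Assembly and gene architecture** (`symarch.stats`): N50 (smallest length
  L such that sequences ≥ L cover ≥ 50% of the assembly), GC content with
  ambiguous bases excluded, contig splitting at N-gaps, exon/intron/intergenic
  length statistics, splice-site donor/acceptor dinucleotide profiles read
  5′→3′ on the coding strand, gene density per Mb, and the
  bitscore/e-value/coverage filter for contaminant scaffolds (total bitscore
  > 1000, e ≤ 1e−20, > 50% of non-N sequence covered).
* **Gene-orientation directionality** (`symarch.orientation`): the number of
  strand changes between adjacent genes, counted in 10-gene windows with a
  10-gene step and averaged; two genomes are compared with a Pearson χ² test
  on the pooled change counts. Under independent flips with probability *p*,
  the expected mean is (w−1)·*p* — the analytic anchor for recovery tests.
* **Taxonomic composition** (`symarch.composition`): best-hit binning into
  seven kingdom-level groups, with intra-genus reassignment when a congeneric
  hit scores a strictly higher bitscore (bitscores, not e-values, since they
  are independent of database size); the tiered SwissProt → TrEMBL → nr GO
  annotation cascade; and core-eukaryotic-gene (CEG) completeness against the
  458-gene universe.
* **Protein-domain enrichment** (`symarch.enrichment`): domain ratios
  x = count / per-species total, Fisher's exact test of each in-group species
  against the averaged outgroup counts, Benjamini–Hochberg FDR within each
  species' test family, z = (x − u)/s standardization across species, screen
  intersection for genus-specific domains, and Euclidean-distance
  hierarchical clustering orders for heatmap display.
* **Duplication and synteny** (`symarch.evolution`): collapse of gene-tree
  edges with bootstrap support < 50 into polytomies, counting of maximal
  monospecific (species-specific duplication) clades, a simplified
  collinear-block finder (chains of ≥ 5 homologous genes monotone in both
  genomes, same or inverted orientation), and per-family cross-species count
  contrasts.
* **Synthetic data** (`symarch.simulate`): seeded generators for every input
  above, each emitting a `SyntheticTruth` record of its planted parameters.

## Worked example

```python
import symarch as sa

config = sa.SyntheticGenomeConfig(
    n_scaffolds=5, genes_per_scaffold=400, p_switch=0.258, gc_target=0.505, seed=1
)
genome, truth = sa.simulate_genome(config)

report = sa.assembly_report(genome.scaffolds)
stats = sa.gene_statistics(genome)
orient = sa.orientation_result_for_genome(genome)

print(f"scaffolds: {report.n_scaffolds}, total {report.total_scaffold_bp:,} bp, "
      f"N50 {report.scaffold_n50_bp:,} bp, GC {report.gc_percent_n_excluded:.1f}%")
print(f"genes: {stats.n_genes:,}, density {stats.gene_density_per_mb:.1f}/Mb, "
      f"donor sites {dict((k, round(v, 3)) for k, v in stats.donor_dinucleotide_freqs.items())}")
print(f"orientation changes per 10-gene window: {orient.mean_changes_per_window:.2f} "
      f"(expected {sa.expected_mean_changes(config.p_switch):.2f})")
```

prints

```
scaffolds: 5, total 3,117,770 bp, N50 627,069 bp, GC 50.5%
genes: 2,000, density 641.5/Mb, donor sites {'GT': 0.506, 'GC': 0.289, 'GA': 0.205}
orientation changes per 10-gene window: 2.12 (expected 2.32)
```

The genome was planted with a 0.258 per-adjacent-pair strand-switch
probability, a 50.5% GC target and a GT/GC/GA = 0.5/0.3/0.2 donor dialect;
the measured GC, donor frequencies and windowed orientation mean recover the
planted values (the orientation mean for a single 2,000-gene genome sits
within sampling error of the 2.32 expectation). Comparing against a second
genome simulated with a much lower switch probability,

```python
uniform, _ = sa.simulate_genome(
    sa.SyntheticGenomeConfig(n_scaffolds=5, genes_per_scaffold=400, p_switch=0.071, seed=2)
)
chi2, p = sa.orientation_chi_square(orient, sa.orientation_result_for_genome(uniform))
print(f"chi-square vs a strongly unidirectional genome: {chi2:.1f} (p = {p:.2e})")
```

```
chi-square vs a strongly unidirectional genome: 191.1 (p = 1.79e-43)
```

— the two genomes differ decisively in their degree of unidirectionality.

The same analyses are available from the shell:

```sh
symarch simulate genome --seed 1 --out sim/
symarch stats  --fasta sim/genome.fasta --gff sim/genes.gff3 --out out/
symarch orient --fasta sim/genome.fasta --gff sim/genes.gff3 --out out/
```

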