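# Methods

This note documents the statistical procedures, conventions and design
choices implemented in `symarch`, and what the synthetic-data experiments do
and do not demonstrate.

## Data model and conventions

All coordinates are 1-based inclusive (GFF3 native); half-open intervals
appear only inside serialization code. Sequences are uppercase-normalized on
input and IUPAC ambiguity codes other than N are mapped to N with a logged
count, so that GC content (computed with N excluded) never counts an
ambiguous base as G or C. When a GFF3 gene carries several mRNAs, the
representative transcript is the one with the longest summed CDS (summed
exon length as fallback): every locus contributes exactly one gene model to
the architecture statistics. Completeness evidence (start/stop codon
presence, UTR status) is carried as input flags on the gene model, not
inferred from sequence, because the upstream annotation pipeline is the
authority on them.

## Assembly and gene-architecture statistics

* **Nx**: smallest length L such that sequences of length ≥ L jointly cover
  ≥ x% of the total. Permutation-invariant; N50 of k equal lengths L is L.
* **Contigs**: scaffolds are split at runs of ≥ `min_gap_n` consecutive Ns
  (default 10, configurable and recorded in the report, since scaffolding
  gap conventions differ between assemblers); shorter N runs stay inside
  contigs and count toward contig length.
* **Intergenic lengths** are gaps between consecutive gene spans on the same
  scaffold; overlapping neighbors contribute no interval and are counted
  separately. Scaffold ends contribute no interval either. Gene density uses
  total scaffold length.
* **Splice profiles** pool all introns (not per-gene averages). For each
  intron the donor is its first two bases and the acceptor its last two,
  read 5′→3′ on the coding strand (reverse-complemented for minus-strand
  genes). Introns shorter than 4 nt are excluded with a logged count.
  Predominant dinucleotides are reported in frequency order, ties broken
  lexicographically.
* **Contamination**: a scaffold is flagged only when all three cutoffs hold
  — summed bitscore of significant hits (e ≤ 1e−20) above 1000, best
  e-value ≤ 1e−20, and more than half of the non-N sequence covered by
  merged significant-hit intervals.

## Gene-orientation statistic

Strand changes between adjacent genes are counted in `window`-gene windows
advanced by `step` genes (defaults 10/10, i.e. disjoint windows). Scaffolds
with fewer genes than a window contribute nothing (counted in the log), and
trailing genes that do not fill a window are dropped. Windows are pooled
across scaffolds with equal weight; the per-scaffold-mean alternative was
considered and rejected because it would weight short scaffolds heavily.
The two-genome comparison is a Pearson χ² without continuity correction on
the 2×2 table of changes vs non-changes over all adjacent pairs in windows
(Yates correction available by flag; with pair counts in the tens of
thousands the correction is immaterial). Under independent flips with
probability p there are (window−1) adjacent pairs per window, so the
expected mean is (window−1)·p; this closed form is what the recovery tests
check against.

## Taxonomic composition and annotation

Best hits are selected per query among hits with e ≤ 1e−5 by highest
bitscore, ties broken by lower e-value then subject id. Intra-genus
reassignment requires a *strictly* higher bitscore — ties keep the reference
assignment. Taxonomy resolution uses a user-supplied species→group table
rather than a live service, for offline reproducibility; species missing
from the table either raise an error listing offenders (default) or fall
into an `unresolved` category. The GO cascade considers up to 20 qualifying
hits per database in score order, takes the first with any GO annotation,
and falls through SwissProt → TrEMBL → nr; tier counts always partition the
gene universe. CEG completeness marks a core gene found iff its best
e-value ≤ 1e−5; percentages are printed at one decimal, rounded half away
from zero (the convention that reproduces printed values such as 95.4%).

## Domain-enrichment screen

Counts are normalized to each species' total domain count ("domain ratio"
x). For each in-group species and domain, a 2×2 Fisher's exact test compares
[count, total−count] against the outgroup average: arithmetic means of
outgroup counts and totals, each rounded half away from zero to an integer
before the exact test (the averaging rule is not standardized anywhere;
raw-count averaging is the default and a ratio-rescaled variant would be a
one-line change at the call site). Enrichment screens are one-sided
(greater) by default and additionally require the in-group ratio to exceed
the mean outgroup ratio; the within-genus differential screen is typically
run two-sided at FDR < 0.01. BH-FDR correction is applied within one
in-group species' family of tests, not pooled across species. z-scores use
the cross-species mean u and *sample* (n−1) standard deviation s of the
ratios; domains constant across species (s = 0) get z = 0, carrying no
signal. Heatmap orders come from agglomerative clustering with Euclidean
distance and complete linkage (average linkage by flag); scipy's
deterministic tie-breaking makes leaf orders reproducible.

The domain-count policy defaults to counting every qualifying domain
instance (i-e-value ≤ 1e−5), with a per-protein alternative; instance
counting matches how expanded families with internal repeats are usually
reported.

## Trees and synteny

Gene-tree edges with bootstrap support below 50 are contracted into
polytomies (unlabeled edges count as fully supported; tips are never
touched). Species-specific duplication clades are the *maximal* clades whose
tips all belong to one species, of size ≥ 2; maximality makes the reported
clades disjoint, so each tip is counted at most once. No additional support
threshold is imposed on the clade's own edge beyond surviving the collapse.

The collinear-block finder works in gene-rank coordinates. Homolog pairs are
mapped to (rankA, rankB) anchors per scaffold pair; tandem-duplicate matches
(one gene matching a consecutive run in the other genome) are collapsed to
the highest-bitscore pair. Chains must be strictly monotone in genome A,
monotone (increasing or decreasing) in genome B, with at most
`max_gap_genes` (default 25, a common collinearity default) intervening
genes between consecutive anchors in both genomes. Blocks of ≥ 5 anchors
are extracted greedily, longest first, consuming their anchors. The
dynamic-programming chain search is checked against exhaustive enumeration
on small instances. Note a consequence of the chaining definition: planted
or real blocks separated by fewer than `max_gap_genes` genes are merged by
construction, so the synthetic generator places blocks farther apart than
the gap limit.

The transporter-family gene filter keeps proteins with a family-domain hit
at e ≤ 1e−15 and protein length > 150 aa. The e-value threshold direction
is implemented as "at most" — a "keep only hits weaker than 1e−15" rule
would contradict the purpose of selecting confident family members — with
the literal greater-than reading available behind a flag, and the length
criterion applies to the protein, not the domain alignment (also
flag-switchable).

## Synthetic-data generators

All generators are pure functions of config + seed; one global seed expands
into fixed per-component substreams (`rng_for`) so stages can be regenerated
independently. Each emits a `SyntheticTruth` with the planted parameters.

The genome generator plants: per-adjacent-pair strand-switch probability
(independent Bernoulli flips), GC target, donor/acceptor splice dialects
(defaults GT/GC/GA = 0.5/0.3/0.2 and AG/AC = 0.9/0.1 — the donor set
mirrors the qualitative GC/GT/GA observation in these genomes; no published
frequencies exist, so the proportions are configurable), and mid-spacer N
gaps. Splice dinucleotides are written onto the coding strand after layout;
because the dialect dinucleotides are GC-biased relative to a typical
target, the random background composition is compensated exactly so the
expected overall non-N GC equals the target. Gene geometry defaults
(≈5 exons/gene, 30–190 bp exons, 20–280 bp introns, 50–750 bp spacers) are
deliberately compact relative to real multi-kb dinoflagellate genes so that
10,000-gene genomes build in ~2 s; the recovery targets (switch
probability, dialects, GC) are geometry-independent, so nothing about those
checks depends on the compression.

The domain-count generator draws each species' counts from a multinomial
over domains with baseline frequencies multiplied by planted per-species
folds and renormalized. The hit-table generator draws a category per query
and then bitscores such that the intended winner wins under the
strict-inequality reassignment rule. The gene-tree generator places planted
monospecific clades (supports ≥ 50) on a caterpillar backbone whose
innermost pair always mixes species, so no unplanted monospecific clade of
size ≥ 2 can form; backbone supports span 10–100 to exercise the collapse
rule. The synteny generator plants non-overlapping collinear blocks plus
uniform noise pairs at a configurable rate.

What the generators do *not* emulate: real sequence evolution (no
substitution model, no repeats, no paralog sequence similarity), assembly
error, fragmented gene models, or correlated hit structure. Passing the
recovery tests therefore demonstrates that each statistic measures what it
claims under its own model assumptions — not that the pipeline is robust to
annotation artifacts in real data.

## Calibration and problem sizes

The enrichment screen's error control is checked by simulation: on null
matrices (5 species × 200 domains, multinomial totals 20,000) the realized
false-discovery proportion at q < 0.05, averaged over 500 replicates, stays
below 0.05 within Monte-Carlo error (Fisher's exact test is conservative,
so the realized rate is far below nominal); a planted 5-fold enrichment of
a 1e−3-frequency domain at totals 50,000 is detected at FDR < 0.001 in
≥ 95% of 200 replicates. Orientation recovery uses 10,000-gene genomes;
splice-dialect recovery ≥ 10,000 introns; composition recovery 10,000
queries — at these sizes every planted parameter sits within three standard
errors of its estimate. The acceptance script runs the same experiments at
moderately reduced replicate counts (150 null / 100 power) as its standard
problem size.

## Known limitations

* The GFF3 reader supports the gene/mRNA/exon/CDS dialect only — enough for
  gene-architecture statistics, not a general GFF3 library.
* The collinearity finder is a deliberate simplification of full synteny
  tools: unit gene-rank distances, no scoring function, greedy extraction;
  it is meant for counting conserved blocks, not for fine-grained synteny
  mapping.
* Greedy longest-first block extraction can, in dense noise, absorb an
  anchor of a minimum-size neighboring block and push it below the
  reporting threshold; with blocks separated by more than the gap limit and
  noise below 5% this was never observed in calibration.
* EST-support percentages and repeat content are out of scope (they require
  transcript alignments and repeat annotations, which are upstream inputs
  this package does not compute).
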