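"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its configuration plus a seed and
emits, alongside its outputs, a :class:`SyntheticTruth` record of the
planted parameters so that the corresponding analysis stage can be scored
automatically: genomes with a known orientation-switch probability, GC
target and splice-site dialect; domain-count matrices with planted
enrichment folds; best-hit tables with planted taxonomic composition; gene
trees with planted monospecific duplication clades; and genome pairs with
planted collinear blocks.

A single global seed expands into fixed per-component substreams (component
ids below) so stages can be regenerated independently of each other.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .enrichment import DomainCountMatrix
from .errors import ConfigError
from .model import (
    AnnotatedGenome,
    GeneModel,
    HitRecord,
    Scaffold,
    ScaffoldSet,
    SupportTree,
    reverse_complement,
)

#: Fixed substream keys: rng_for(seed, component) is reproducible and the
#: streams for different components are independent.
COMPONENT_IDS = {
    "genome": 1,
    "domain_counts": 2,
    "hit_tables": 3,
    "gene_tree": 4,
    "synteny": 5,
}


def rng_for(seed: int, component: str) -> np.random.Generator:
    """Per-component substream of one global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(COMPONENT_IDS[component],))
    )


@dataclass
class SyntheticTruth:
    """Planted parameters of one generator run, serializable next to outputs."""

    generator: str
    params: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"generator": self.generator, "params": self.params}, fh,
                      indent=2, default=str)


# ---------------------------------------------------------------------------
# Genomes
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenomeConfig:
    """Geometry and composition of a simulated annotated genome.

    Per-gene geometry (exon count/length, intron length, intergenic
    spacing) is deliberately compact relative to the multi-kb genes of real
    dinoflagellate assemblies so that genomes with tens of thousands of
    genes stay fast to build; the recovery targets (``p_switch``, splice
    dialect frequencies, ``gc_target``) do not depend on the geometry.
    """

    n_scaffolds: int = 5
    genes_per_scaffold: int = 200
    p_switch: float = 0.258  # adjacent-gene orientation flip probability
    gc_target: float = 0.505
    mean_exons: int = 5  # exon count ~ 1 + Poisson(mean_exons - 1)
    exon_len_range: tuple[int, int] = (30, 190)
    intron_len_range: tuple[int, int] = (20, 280)
    intergenic_len_range: tuple[int, int] = (50, 750)
    donor_freqs: Mapping[str, float] = field(
        default_factory=lambda: {"GT": 0.5, "GC": 0.3, "GA": 0.2}
    )
    acceptor_freqs: Mapping[str, float] = field(
        default_factory=lambda: {"AG": 0.9, "AC": 0.1}
    )
    n_gap_rate: float = 0.1  # probability of an N gap inside an intergenic spacer
    n_gap_length: int = 30
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p_switch <= 1.0):
            raise ConfigError("p_switch must be in [0, 1]")
        if not (0.0 < self.gc_target < 1.0):
            raise ConfigError("gc_target must be in (0, 1)")
        for freqs, name in ((self.donor_freqs, "donor"), (self.acceptor_freqs, "acceptor")):
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} dialect frequencies must sum to 1")
            if any(len(k) != 2 for k in freqs):
                raise ConfigError(f"{name} dialect keys must be dinucleotides")
        if not (0.0 <= self.n_gap_rate <= 1.0):
            raise ConfigError("n_gap_rate must be in [0, 1]")
        if self.intron_len_range[0] < 4:
            raise ConfigError("introns must be at least 4 nt for splice dinucleotides")
        if self.mean_exons < 1 or self.genes_per_scaffold < 1 or self.n_scaffolds < 1:
            raise ConfigError("counts must be positive")


def _draw_dialect(rng: np.random.Generator, freqs: Mapping[str, float]) -> str:
    keys = list(freqs)
    return keys[rng.choice(len(keys), p=np.array([freqs[k] for k in keys]))]


def simulate_genome(config: SyntheticGenomeConfig) -> tuple[AnnotatedGenome, SyntheticTruth]:
    """Simulate a multi-scaffold annotated genome with planted parameters.

    Adjacent-gene strand flips are independent Bernoulli(p_switch) draws;
    splice dinucleotides are drawn per intron from the dialect tables and
    written onto the coding strand; N gaps are inserted mid-spacer at
    ``n_gap_rate``. Deterministic under a fixed config (seed included).
    """
    rng = rng_for(config.seed, "genome")
    bases = np.frombuffer(b"ACGT", dtype="S1")

    scaffolds = ScaffoldSet()
    genes: list[GeneModel] = []
    n_introns_total = 0
    gene_counter = 0
    for s_idx in range(config.n_scaffolds):
        sid = f"scaffold_{s_idx + 1}"
        pos = 1  # next free 1-based coordinate
        gene_specs: list[tuple[str, str, tuple[tuple[int, int], ...]]] = []
        n_runs: list[tuple[int, int]] = []  # (start, end) of N gaps
        splice_edits: list[tuple[int, str]] = []  # (0-based offset, dinucleotide)
        strand = "+" if rng.random() < 0.5 else "-"
        for g_idx in range(config.genes_per_scaffold):
            if g_idx > 0 and rng.random() < config.p_switch:
                strand = "-" if strand == "+" else "+"
            # intergenic spacer before the gene
            spacer = int(rng.integers(*config.intergenic_len_range, endpoint=True))
            if rng.random() < config.n_gap_rate and spacer >= config.n_gap_length + 2:
                gap_off = (spacer - config.n_gap_length) // 2
                n_runs.append(
                    (pos + gap_off, pos + gap_off + config.n_gap_length - 1)
                )
            pos += spacer
            n_exons = 1 + int(rng.poisson(config.mean_exons - 1))
            exons: list[tuple[int, int]] = []
            for e_idx in range(n_exons):
                if e_idx > 0:
                    intron_len = int(rng.integers(*config.intron_len_range, endpoint=True))
                    intron_start = pos
                    pos += intron_len
                    donor = _draw_dialect(rng, config.donor_freqs)
                    acceptor = _draw_dialect(rng, config.acceptor_freqs)
                    if strand == "+":
                        splice_edits.append((intron_start - 1, donor))
                        splice_edits.append((pos - 1 - 2, acceptor))
                    else:
                        # coding strand reads the reverse complement
                        splice_edits.append((pos - 1 - 2, reverse_complement(donor)))
                        splice_edits.append((intron_start - 1, reverse_complement(acceptor)))
                    n_introns_total += 1
                exon_len = int(rng.integers(*config.exon_len_range, endpoint=True))
                exons.append((pos, pos + exon_len - 1))
                pos += exon_len
            gene_counter += 1
            gene_specs.append((f"g{gene_counter:06d}", strand, tuple(exons)))
        pos += int(rng.integers(*config.intergenic_len_range, endpoint=True))
        scaffold_len = pos - 1

        # Splice-site overwrites carry their own (dialect-determined) GC, so
        # the random background compensates exactly: expected overall GC of
        # the non-N sequence equals gc_target.
        n_gap_bases = sum(ne - ns + 1 for ns, ne in n_runs)
        edit_gc = sum(d.count("G") + d.count("C") for _off, d in splice_edits)
        edit_bases = 2 * len(splice_edits)
        non_n_total = scaffold_len - n_gap_bases
        background = non_n_total - edit_bases
        gc_b = (config.gc_target * non_n_total - edit_gc) / background \
            if background > 0 else config.gc_target
        gc_b = min(max(gc_b, 0.0), 1.0)
        base_probs = np.array([(1 - gc_b) / 2, gc_b / 2, gc_b / 2, (1 - gc_b) / 2])
        arr = rng.choice(bases, size=scaffold_len, p=base_probs)
        for ns, ne in n_runs:
            arr[ns - 1 : ne] = b"N"
        seq = bytearray(arr.tobytes())
        for off, dinuc in splice_edits:
            seq[off : off + 2] = dinuc.encode()
        scaffolds.add(Scaffold(sid, seq.decode("ascii")))
        for gid, strand_, exons_ in gene_specs:
            genes.append(GeneModel(id=gid, scaffold_id=sid, strand=strand_, exons=exons_))

    genome = AnnotatedGenome(scaffolds=scaffolds, genes=genes)
    truth = SyntheticTruth(
        generator="genome",
        params={
            "p_switch": config.p_switch,
            "gc_target": config.gc_target,
            "donor_freqs": dict(config.donor_freqs),
            "acceptor_freqs": dict(config.acceptor_freqs),
            "n_scaffolds": config.n_scaffolds,
            "genes_per_scaffold": config.genes_per_scaffold,
            "n_genes": len(genes),
            "n_introns": n_introns_total,
            "seed": config.seed,
        },
    )
    return genome, truth


# ---------------------------------------------------------------------------
# Domain-count matrices
# ---------------------------------------------------------------------------

@dataclass
class SyntheticEnrichmentConfig:
    n_species: int = 5
    n_domains: int = 200
    total_counts: int | Sequence[int] = 20_000
    baseline_freqs: Sequence[float] | None = None  # default uniform
    planted_effects: Sequence[tuple[str, Sequence[str], float]] = ()
    # each: (domain, species affected, fold multiplier on the baseline freq)
    seed: int = 0

    def species_names(self) -> list[str]:
        return [f"sp{i + 1}" for i in range(self.n_species)]

    def domain_names(self) -> list[str]:
        return [f"PF{i + 1:05d}" for i in range(self.n_domains)]

    def __post_init__(self):
        totals = (
            [self.total_counts] * self.n_species
            if isinstance(self.total_counts, int)
            else list(self.total_counts)
        )
        if any(t <= 0 for t in totals) or len(totals) != self.n_species:
            raise ConfigError("total counts must be positive, one per species")
        self._totals = totals
        if self.baseline_freqs is not None:
            bf = np.asarray(self.baseline_freqs, dtype=float)
            if bf.size != self.n_domains or abs(bf.sum() - 1.0) > 1e-9:
                raise ConfigError("baseline frequencies must sum to 1 over domains")
        domains = set(self.domain_names())
        species = set(self.species_names())
        for dom, sps, fold in self.planted_effects:
            if dom not in domains:
                raise ConfigError(f"planted fold on unknown domain {dom!r}")
            if not set(sps) <= species:
                raise ConfigError(f"planted effect on unknown species in {sps!r}")
            if fold <= 0:
                raise ConfigError("planted folds must be > 0")


def simulate_domain_counts(
    config: SyntheticEnrichmentConfig,
) -> tuple[DomainCountMatrix, SyntheticTruth]:
    """Multinomial domain counts with planted per-species enrichment folds.

    Each species' counts are a multinomial draw over domains with baseline
    frequencies multiplied by that species' planted folds and renormalized.
    """
    rng = rng_for(config.seed, "domain_counts")
    species = config.species_names()
    domains = config.domain_names()
    if config.baseline_freqs is None:
        base = np.full(config.n_domains, 1.0 / config.n_domains)
    else:
        base = np.asarray(config.baseline_freqs, dtype=float)
    dom_index = {d: j for j, d in enumerate(domains)}

    rows: dict[str, dict[str, int]] = {}
    for i, sp in enumerate(species):
        probs = base.copy()
        for dom, sps, fold in config.planted_effects:
            if sp in sps:
                probs[dom_index[dom]] *= fold
        probs /= probs.sum()
        draw = rng.multinomial(config._totals[i], probs)
        rows[sp] = dict(zip(domains, draw.tolist()))
    matrix = DomainCountMatrix.from_rows(rows)
    truth = SyntheticTruth(
        generator="domain_counts",
        params={
            "planted_effects": [
                {"domain": d, "species": list(s), "fold": f}
                for d, s, f in config.planted_effects
            ],
            "totals": config._totals,
            "n_domains": config.n_domains,
            "seed": config.seed,
        },
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Best-hit tables with planted taxonomic composition
# ---------------------------------------------------------------------------

def simulate_hit_tables(
    composition_probs: Mapping[str, float],
    n_queries: int,
    seed: int = 0,
    bitscore_range: tuple[float, float] = (100.0, 300.0),
    genus_margin: float = 20.0,
) -> tuple[list[HitRecord], list[HitRecord], dict[str, str], SyntheticTruth]:
    """Reference (nr) and intra-genus hit tables with a planted composition.

    ``composition_probs`` maps categories (kingdom groups,
    ``"Symbiodinium:<species>"``, or ``"none"``) to probabilities summing
    to 1. Per query a category is drawn; bitscores are then drawn so that
    the intended winner wins under the strict-inequality reassignment rule.
    Returns (nr hits, intra-genus hits, taxonomy map, truth).
    """
    probs = np.array(list(composition_probs.values()), dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
        raise ConfigError("composition probabilities must be >= 0 and sum to 1")
    categories = list(composition_probs)
    rng = rng_for(seed, "hit_tables")
    lo, hi = bitscore_range

    nr_hits: list[HitRecord] = []
    genus_hits: list[HitRecord] = []
    taxonomy: dict[str, str] = {}
    draws = rng.choice(len(categories), size=n_queries, p=probs)
    for qi in range(n_queries):
        cat = categories[draws[qi]]
        q = f"q{qi + 1:06d}"
        if cat == "none":
            continue
        if cat.startswith("Symbiodinium:"):
            sp = cat.split(":", 1)[1]
            genus_bits = float(rng.uniform(lo + genus_margin, hi + genus_margin))
            genus_hits.append(
                HitRecord(q, f"{sp}_gene{qi}", 80.0, 200, 1e-30, genus_bits,
                          subject_species=sp)
            )
            # a weaker nr hit for most such queries, never tying
            if rng.random() < 0.8:
                ref_sp = "ref_protist"
                taxonomy[ref_sp] = "Protista"
                nr_hits.append(
                    HitRecord(q, f"nr{qi}", 60.0, 180, 1e-10,
                              float(rng.uniform(lo, genus_bits - 1.0)),
                              subject_species=ref_sp)
                )
        else:
            ref_sp = f"ref_{cat.lower()}"
            taxonomy[ref_sp] = cat
            ref_bits = float(rng.uniform(lo, hi))
            nr_hits.append(
                HitRecord(q, f"nr{qi}", 60.0, 180, 1e-10, ref_bits,
                          subject_species=ref_sp)
            )
            # an intra-genus hit that must lose (equal or lower bitscore)
            if rng.random() < 0.3:
                genus_hits.append(
                    HitRecord(q, f"Sminutum_gene{qi}", 50.0, 150, 1e-8,
                              float(rng.uniform(lo * 0.5, ref_bits)),
                              subject_species="Sminutum")
                )
    truth = SyntheticTruth(
        generator="hit_tables",
        params={
            "composition_probs": dict(composition_probs),
            "n_queries": n_queries,
            "seed": seed,
        },
    )
    return nr_hits, genus_hits, taxonomy, truth


# ---------------------------------------------------------------------------
# Gene trees with planted monospecific clades
# ---------------------------------------------------------------------------

def simulate_gene_tree(
    n_species: int = 3,
    clades_per_species: Mapping[str, int] | int = 2,
    clade_size_range: tuple[int, int] = (2, 5),
    support_range: tuple[int, int] = (60, 100),
    n_background_tips: int = 12,
    seed: int = 0,
) -> tuple[SupportTree, SyntheticTruth]:
    """A gene tree containing exactly the planted monospecific clades.

    Planted clades receive supports >= 50 drawn from ``support_range``;
    background tips are interleaved on a caterpillar backbone alternating
    species so no accidental monospecific clade of size >= 2 can form, and
    backbone supports span [10, 100] so the collapse rule is exercised.
    """
    if clade_size_range[0] < 2:
        raise ConfigError("planted clades must have size >= 2")
    if support_range[0] < 50:
        raise ConfigError("planted clade supports must be >= 50")
    if n_species < 2:
        raise ConfigError("need at least two species for a mixed background")
    rng = rng_for(seed, "gene_tree")
    species = [f"SP{chr(ord('A') + i)}" for i in range(n_species)]
    if isinstance(clades_per_species, int):
        clades_per_species = {sp: clades_per_species for sp in species}

    counters = {sp: 0 for sp in species}

    def new_tip(sp: str) -> str:
        counters[sp] += 1
        return f"{sp}_{counters[sp]:04d}"

    planted: dict[str, list[list[str]]] = {sp: [] for sp in species}
    items: list[tuple[str, str]] = []  # (newick fragment, species or "" for clades)
    for sp in species:
        for _ in range(clades_per_species.get(sp, 0)):
            size = int(rng.integers(clade_size_range[0], clade_size_range[1], endpoint=True))
            tips = [new_tip(sp) for _ in range(size)]
            planted[sp].append(tips)
            frag = f"({tips[0]},{tips[1]})"
            frag += str(int(rng.integers(*support_range, endpoint=True)))
            for t in tips[2:]:
                frag = f"({frag},{t}){int(rng.integers(*support_range, endpoint=True))}"
            items.append((frag, sp))
    for i in range(n_background_tips):
        sp = species[i % n_species]
        items.append((new_tip(sp), sp))

    order = rng.permutation(len(items))
    # interleave so adjacent backbone items never share a species
    arranged: list[tuple[str, str]] = []
    pool = [items[i] for i in order]
    while pool:
        prev_sp = arranged[-1][1] if arranged else None
        pick = next((k for k, it in enumerate(pool) if it[1] != prev_sp), 0)
        arranged.append(pool.pop(pick))
    if len(arranged) < 2:
        raise ConfigError("tree needs at least two backbone items")
    # The innermost caterpillar pair must mix species, otherwise it would
    # form (or extend) a monospecific clade not in the plant list. Deeper
    # same-species adjacency is harmless: a caterpillar node's clade is a
    # backbone prefix, which always contains the mixed innermost pair.
    if arranged[0][1] == arranged[1][1]:
        k = next((k for k, it in enumerate(arranged[2:], 2)
                  if it[1] != arranged[0][1]), None)
        if k is None:
            raise ConfigError(
                "all backbone items share one species; add background tips"
            )
        arranged[1], arranged[k] = arranged[k], arranged[1]
    newick = arranged[0][0]
    for frag, _sp in arranged[1:]:
        newick = f"({newick},{frag}){int(rng.integers(10, 100, endpoint=True))}"
    newick += ";"

    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)
    tip_species = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        tip_species[label] = label.split("_", 1)[0]
    stree = SupportTree(tree=tree, tip_species=tip_species)
    truth = SyntheticTruth(
        generator="gene_tree",
        params={
            "clades_per_species": {sp: len(planted[sp]) for sp in species},
            "planted_clades": {sp: planted[sp] for sp in species},
            "newick": newick,
            "seed": seed,
        },
    )
    return stree, truth


# ---------------------------------------------------------------------------
# Genome pairs with planted collinear blocks
# ---------------------------------------------------------------------------

def simulate_synteny_pair(
    n_genes: int,
    planted_blocks: Sequence[tuple[int, int, int, str]],
    noise_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[str], list[str], list[tuple[str, str, float]], SyntheticTruth]:
    """Two gene orders plus homolog pairs with planted collinear blocks.

    ``planted_blocks`` are (start_a, start_b, size, orientation) tuples in
    0-based gene-rank coordinates; blocks must not overlap in either genome.
    Noise adds ``round(noise_rate * n_genes)`` uniform random pairs at lower
    bitscore. Returns (order_a, order_b, homolog pairs with bitscores,
    truth).
    """
    if not (0.0 <= noise_rate <= 1.0):
        raise ConfigError("noise_rate must be in [0, 1]")
    used_a: set[int] = set()
    used_b: set[int] = set()
    for sa, sb, size, orient in planted_blocks:
        if orient not in ("same", "inverted"):
            raise ConfigError(f"bad orientation {orient!r}")
        if size < 1 or sa < 0 or sb < 0 or sa + size > n_genes or sb + size > n_genes:
            raise ConfigError("planted block outside gene range")
        ra = set(range(sa, sa + size))
        rb = set(range(sb, sb + size))
        if ra & used_a or rb & used_b:
            raise ConfigError("planted blocks overlap")
        used_a |= ra
        used_b |= rb

    rng = rng_for(seed, "synteny")
    order_a = [f"a{i:05d}" for i in range(n_genes)]
    order_b = [f"b{i:05d}" for i in range(n_genes)]
    pairs: list[tuple[str, str, float]] = []
    for sa, sb, size, orient in planted_blocks:
        for i in range(size):
            j = i if orient == "same" else size - 1 - i
            pairs.append((order_a[sa + i], order_b[sb + j],
                          float(rng.uniform(500, 1000))))
    n_noise = int(round(noise_rate * n_genes))
    for _ in range(n_noise):
        ia = int(rng.integers(0, n_genes))
        ib = int(rng.integers(0, n_genes))
        pairs.append((order_a[ia], order_b[ib], float(rng.uniform(50, 400))))
    truth = SyntheticTruth(
        generator="synteny",
        params={
            "planted_blocks": [list(b) for b in planted_blocks],
            "n_genes": n_genes,
            "noise_rate": noise_rate,
            "n_noise_pairs": n_noise,
            "seed": seed,
        },
    )
    return order_a, order_b, pairs, truth
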