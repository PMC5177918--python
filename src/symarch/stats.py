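"""Assembly- and gene-level summary statistics plus the contamination filter.

Reproduces the per-genome architecture quantities reported for the three
*Symbiodinium* genomes: total scaffold/contig length, N50, GC content with
N excluded, gene/exon/intron/intergenic length statistics, splice-site
dinucleotide profiles, and gene density per Mb; plus the bitscore/e-value/
coverage filter used to flag bacterial or viral contaminant scaffolds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import CoordinateError, SymarchError
from .model import AnnotatedGenome, HitRecord, Scaffold, ScaffoldSet, reverse_complement
from .util import round_half_away

logger = logging.getLogger(__name__)


@dataclass
class AssemblyReport:
    total_scaffold_bp: int
    total_contig_bp: int
    scaffold_n50_bp: int
    contig_n50_bp: int
    gc_percent_n_excluded: float
    n_scaffolds: int
    n_contigs: int
    min_gap_n: int  # contig-splitting convention in effect

    def __post_init__(self):
        if self.total_contig_bp > self.total_scaffold_bp:
            raise SymarchError("total contig length exceeds scaffold length")
        if not (0.0 <= self.gc_percent_n_excluded <= 100.0):
            raise SymarchError("GC percent outside [0, 100]")


@dataclass
class GeneStatsReport:
    n_genes: int
    mean_gene_length_bp: float
    mean_coding_length_bp: float
    exons_per_gene: float
    mean_exon_length_bp: float
    total_exon_mb: float
    percent_genes_with_introns: float
    mean_intron_length_bp: float
    total_intron_mb: float
    mean_intergenic_bp: float
    gene_density_per_mb: float
    donor_dinucleotide_freqs: dict[str, float] = field(default_factory=dict)
    acceptor_dinucleotide_freqs: dict[str, float] = field(default_factory=dict)
    n_overlapping_gene_pairs: int = 0  # excluded from the intergenic mean


@dataclass
class ContaminationVerdict:
    scaffold_id: str
    flagged: bool
    total_bitscore: float
    best_e_value: float
    covered_fraction_of_non_n: float

    def __post_init__(self):
        if not (0.0 <= self.covered_fraction_of_non_n <= 1.0):
            raise SymarchError("covered fraction outside [0, 1]")


def split_into_contigs(scaffold: Scaffold | str, min_gap_n: int = 10) -> list[int]:
    """Lengths of the contigs obtained by splitting at runs of >= min_gap_n Ns.

    N runs shorter than ``min_gap_n`` stay inside contigs and count toward
    contig length. An all-N scaffold yields an empty list.
    """
    if min_gap_n < 1:
        raise SymarchError("min_gap_n must be >= 1")
    seq = scaffold.seq if isinstance(scaffold, Scaffold) else scaffold
    lengths: list[int] = []
    contig_len = 0
    n_run = 0
    for base in seq:
        if base == "N":
            n_run += 1
        else:
            if n_run:
                if n_run >= min_gap_n:
                    if contig_len:
                        lengths.append(contig_len)
                    contig_len = 0
                else:
                    contig_len += n_run
                n_run = 0
            contig_len += 1
    # trailing: an N run at the end never extends a contig
    if contig_len:
        lengths.append(contig_len)
    return lengths


def nx_statistic(lengths: Iterable[int], x: float = 50.0) -> int:
    """Nx: smallest length L such that sequences >= L cover >= x% of the total."""
    lengths = sorted(lengths, reverse=True)
    if not lengths:
        raise ValueError("Nx of an empty length list is undefined")
    if not (0 < x <= 100):
        raise ValueError("x must be in (0, 100]")
    if min(lengths) <= 0:
        raise ValueError("lengths must be positive")
    target = sum(lengths) * x / 100.0
    acc = 0
    for length in lengths:
        acc += length
        if acc >= target:
            return length
    return lengths[-1]  # unreachable


def gc_content_n_excluded(scaffolds: ScaffoldSet | Iterable[Scaffold | str]) -> float:
    """Percent GC pooled over all scaffolds, ambiguous (N) bases excluded."""
    gc = acgt = 0
    for sc in scaffolds:
        seq = sc.seq if isinstance(sc, Scaffold) else sc
        g = seq.count("G")
        c = seq.count("C")
        gc += g + c
        acgt += g + c + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise ValueError("no non-N bases: GC content undefined")
    return 100.0 * gc / acgt


def assembly_report(scaffolds: ScaffoldSet, min_gap_n: int = 10) -> AssemblyReport:
    scaffold_lengths = [len(sc) for sc in scaffolds]
    contig_lengths: list[int] = []
    for sc in scaffolds:
        contig_lengths.extend(split_into_contigs(sc, min_gap_n))
    return AssemblyReport(
        total_scaffold_bp=sum(scaffold_lengths),
        total_contig_bp=sum(contig_lengths),
        scaffold_n50_bp=nx_statistic(scaffold_lengths, 50),
        contig_n50_bp=nx_statistic(contig_lengths, 50) if contig_lengths else 0,
        gc_percent_n_excluded=gc_content_n_excluded(scaffolds),
        n_scaffolds=len(scaffolds),
        n_contigs=len(contig_lengths),
        min_gap_n=min_gap_n,
    )


def genes_per_mb(n_genes: int, total_scaffold_bp: int) -> float:
    """Gene density in genes per megabase of total scaffold length."""
    if total_scaffold_bp <= 0:
        raise ValueError("total scaffold length must be positive")
    return n_genes / (total_scaffold_bp / 1e6)


def splice_site_profile(
    genome: AnnotatedGenome,
) -> tuple[dict[str, float], dict[str, float]]:
    """Donor and acceptor dinucleotide frequency tables, pooled over introns.

    For every intron the donor is its first two bases and the acceptor its
    last two, both read 5'->3' on the coding strand (reverse-complemented for
    minus-strand genes). Introns shorter than 4 nt are excluded (logged).
    """
    donors: dict[str, int] = {}
    acceptors: dict[str, int] = {}
    n_introns = 0
    n_short = 0
    for g in genome.genes:
        if g.n_exons < 2:
            continue
        seq = genome.scaffolds[g.scaffold_id].seq
        for s, e in g.introns:
            if e - s + 1 < 4:
                n_short += 1
                continue
            plus = seq[s - 1 : e]
            if g.strand == "+":
                donor, acceptor = plus[:2], plus[-2:]
            else:
                rc = reverse_complement(plus)
                donor, acceptor = rc[:2], rc[-2:]
            donors[donor] = donors.get(donor, 0) + 1
            acceptors[acceptor] = acceptors.get(acceptor, 0) + 1
            n_introns += 1
    if n_short:
        logger.info("splice_site_profile: excluded %d introns shorter than 4 nt", n_short)
    if n_introns == 0:
        return {}, {}
    donor_f = {k: v / n_introns for k, v in sorted(donors.items(), key=lambda kv: (-kv[1], kv[0]))}
    accept_f = {k: v / n_introns for k, v in sorted(acceptors.items(), key=lambda kv: (-kv[1], kv[0]))}
    return donor_f, accept_f


def gene_statistics(genome: AnnotatedGenome) -> GeneStatsReport:
    """All gene-architecture summary statistics for one annotated genome.

    Intergenic lengths are gaps between consecutive gene spans on the same
    scaffold; overlapping neighbors contribute no interval (counted
    separately). Gene density uses total scaffold length.
    """
    genes = genome.genes
    if not genes:
        raise ValueError("gene_statistics requires at least one gene")
    span_lengths = np.array([g.span_length for g in genes], dtype=float)
    coding_lengths = np.array([g.coding_length for g in genes], dtype=float)
    exon_counts = np.array([g.n_exons for g in genes], dtype=float)
    exon_lengths = np.array(
        [e - s + 1 for g in genes for s, e in g.exons], dtype=float
    )
    intron_lengths = np.array(
        [e - s + 1 for g in genes for s, e in g.introns], dtype=float
    )
    with_introns = sum(1 for g in genes if g.n_exons >= 2)

    intergenic: list[int] = []
    n_overlap = 0
    for _sid, glist in genome.genes_by_scaffold().items():
        for a, b in zip(glist, glist[1:]):
            gap = b.start - a.end - 1
            if gap >= 0:
                intergenic.append(gap)
            else:
                n_overlap += 1

    donor_f, accept_f = splice_site_profile(genome)
    total_bp = genome.scaffolds.total_length
    return GeneStatsReport(
        n_genes=len(genes),
        mean_gene_length_bp=float(span_lengths.mean()),
        mean_coding_length_bp=float(coding_lengths.mean()),
        exons_per_gene=float(exon_counts.mean()),
        mean_exon_length_bp=float(exon_lengths.mean()),
        total_exon_mb=float(exon_lengths.sum() / 1e6),
        percent_genes_with_introns=100.0 * with_introns / len(genes),
        mean_intron_length_bp=float(intron_lengths.mean()) if intron_lengths.size else 0.0,
        total_intron_mb=float(intron_lengths.sum() / 1e6),
        mean_intergenic_bp=float(np.mean(intergenic)) if intergenic else 0.0,
        gene_density_per_mb=genes_per_mb(len(genes), total_bp),
        donor_dinucleotide_freqs=donor_f,
        acceptor_dinucleotide_freqs=accept_f,
        n_overlapping_gene_pairs=n_overlap,
    )


def merged_interval_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total bp covered by a set of 1-based inclusive intervals after merging."""
    ivs = sorted(intervals)
    total = 0
    cur_s = cur_e = None
    for s, e in ivs:
        if s > e:
            raise CoordinateError(f"bad interval ({s}, {e})")
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s + 1
    return total


def flag_contaminants(
    per_scaffold_hits: Mapping[str, Sequence[HitRecord]],
    non_n_lengths: Mapping[str, int],
    covered_non_n_bp: Mapping[str, int],
    min_total_bitscore: float = 1000.0,
    max_best_evalue: float = 1e-20,
    min_covered_fraction: float = 0.5,
) -> list[ContaminationVerdict]:
    """Flag scaffolds whose similarity to contaminant databases is decisive.

    A scaffold is flagged iff the summed bitscore of its significant hits
    (e-value <= ``max_best_evalue``) exceeds ``min_total_bitscore``, its best
    e-value is <= ``max_best_evalue``, and the fraction of its non-N sequence
    covered by significant hits exceeds ``min_covered_fraction``.
    ``covered_non_n_bp`` must come from merged hit intervals restricted to
    significant hits (see :func:`merged_interval_length`).
    """
    out: list[ContaminationVerdict] = []
    for sid in per_scaffold_hits:
        hits = per_scaffold_hits[sid]
        non_n = non_n_lengths[sid]
        covered = covered_non_n_bp.get(sid, 0)
        if covered > non_n:
            raise CoordinateError(
                f"scaffold {sid!r}: covered bp {covered} exceeds non-N length {non_n}"
            )
        significant = [h for h in hits if h.e_value <= max_best_evalue]
        total_bits = sum(h.bitscore for h in significant)
        best_e = min((h.e_value for h in hits), default=float("inf"))
        frac = covered / non_n if non_n else 0.0
        flagged = (
            total_bits > min_total_bitscore
            and best_e <= max_best_evalue
            and frac > min_covered_fraction
        )
        out.append(
            ContaminationVerdict(
                scaffold_id=sid,
                flagged=flagged,
                total_bitscore=total_bits,
                best_e_value=best_e if best_e != float("inf") else float("nan"),
                covered_fraction_of_non_n=frac,
            )
        )
    return out


def format_percent(value: float, decimals: int = 1) -> str:
    """Percent formatting used in reports: round half away from zero."""
    return f"{round_half_away(value, decimals):.{decimals}f}"
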