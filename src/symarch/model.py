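"""Core data model and text-format I/O for genome-architecture analyses.

The package operates on four substrates: assembled scaffolds (FASTA), gene
models (GFF3), ranked homology hits (12-column blast-style tables), protein
domain hits (HMMER-style TSV), and gene trees (Newick with integer support
values). This module defines the in-memory containers for each, the readers
and writers that connect them to their standard text formats, and the
stringency filter used to build *bona fide* gene-model training sets.

Coordinates are 1-based inclusive throughout (GFF3 native); any half-open
convention appears only inside serialization code.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import CoordinateError, FormatError, UnresolvedReferenceError

logger = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")
# IUPAC nucleotide codes other than ACGTN collapse to N (GC is computed with
# N excluded, so ambiguity codes must not count as G/C).
_IUPAC_TO_N = str.maketrans({c: "N" for c in "RYSWKMBDHVU"})

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def normalize_sequence(seq: str, record_id: str = "?") -> str:
    """Uppercase a nucleotide string and collapse non-ACGTN IUPAC codes to N."""
    up = seq.upper()
    cleaned = up.translate(_IUPAC_TO_N)
    n_mapped = sum(1 for a, b in zip(up, cleaned) if a != b)
    if n_mapped:
        logger.info("%s: mapped %d non-ACGTN IUPAC bases to N", record_id, n_mapped)
    bad = set(cleaned) - _VALID_BASES
    if bad:
        raise FormatError(
            f"record {record_id!r}: invalid characters {sorted(bad)} in sequence"
        )
    return cleaned


@dataclass(frozen=True)
class Scaffold:
    """A single assembled scaffold: an id and an ACGTN sequence."""

    id: str
    seq: str

    def __post_init__(self):
        if not self.id:
            raise FormatError("scaffold id must be non-empty")
        if len(self.seq) < 1:
            raise FormatError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def non_n_length(self) -> int:
        return len(self.seq) - self.seq.count("N")


class ScaffoldSet:
    """Ordered collection of scaffolds with unique ids."""

    def __init__(self, scaffolds: Iterable[Scaffold] = ()):
        self._by_id: dict[str, Scaffold] = {}
        for sc in scaffolds:
            self.add(sc)

    def add(self, scaffold: Scaffold) -> None:
        if scaffold.id in self._by_id:
            raise FormatError(f"duplicate scaffold id {scaffold.id!r}")
        self._by_id[scaffold.id] = scaffold

    def __iter__(self):
        return iter(self._by_id.values())

    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, scaffold_id: str) -> bool:
        return scaffold_id in self._by_id

    def __getitem__(self, scaffold_id: str) -> Scaffold:
        try:
            return self._by_id[scaffold_id]
        except KeyError:
            raise UnresolvedReferenceError(f"unknown scaffold {scaffold_id!r}") from None

    @property
    def ids(self) -> list[str]:
        return list(self._by_id)

    @property
    def total_length(self) -> int:
        return sum(len(sc) for sc in self)

    @property
    def total_non_n_length(self) -> int:
        return sum(sc.non_n_length for sc in self)


@dataclass(frozen=True)
class GeneModel:
    """One gene locus: stranded, multi-exon, 1-based inclusive coordinates.

    ``has_start_codon`` / ``has_stop_codon`` / ``utr_status`` carry the
    completeness evidence used by the training-set filter; they are input
    flags, not inferred from sequence.
    """

    id: str
    scaffold_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    has_start_codon: bool = True
    has_stop_codon: bool = True
    utr_status: str = "complete"  # {"complete", "ambiguous"}

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.id!r}: strand must be '+' or '-'")
        if not self.exons:
            raise CoordinateError(f"gene {self.id!r}: no exons")
        prev_end = 0
        for start, end in self.exons:
            if start > end or start < 1:
                raise CoordinateError(
                    f"gene {self.id!r}: bad exon interval ({start}, {end})"
                )
            if start <= prev_end:
                raise CoordinateError(
                    f"gene {self.id!r}: exons overlap or are unsorted at ({start}, {end})"
                )
            prev_end = end
        if self.utr_status not in ("complete", "ambiguous"):
            raise FormatError(f"gene {self.id!r}: bad utr_status {self.utr_status!r}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span_length(self) -> int:
        return self.end - self.start + 1

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def coding_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Intron intervals (1-based inclusive) between consecutive exons."""
        return tuple(
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        )


@dataclass
class AnnotatedGenome:
    """Scaffolds plus gene models; the substrate of all architecture statistics."""

    scaffolds: ScaffoldSet
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self):
        for g in self.genes:
            sc = self.scaffolds[g.scaffold_id]  # raises if unresolved
            if g.end > len(sc):
                raise CoordinateError(
                    f"gene {g.id!r} extends past scaffold {g.scaffold_id!r} "
                    f"({g.end} > {len(sc)})"
                )

    def genes_on(self, scaffold_id: str) -> list[GeneModel]:
        """Genes on one scaffold in positional order (start, end, id)."""
        if scaffold_id not in self.scaffolds:
            raise UnresolvedReferenceError(f"unknown scaffold {scaffold_id!r}")
        sub = [g for g in self.genes if g.scaffold_id == scaffold_id]
        return sorted(sub, key=lambda g: (g.start, g.end, g.id))

    def genes_by_scaffold(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {sid: [] for sid in self.scaffolds.ids}
        for g in self.genes:
            out[g.scaffold_id].append(g)
        for sid in out:
            out[sid].sort(key=lambda g: (g.start, g.end, g.id))
        return out


@dataclass(frozen=True)
class HitRecord:
    """One ranked homology hit (blast outfmt-6 row, optionally with taxon)."""

    query: str
    subject: str
    percent_identity: float
    align_length: int
    e_value: float
    bitscore: float
    subject_species: str | None = None

    def __post_init__(self):
        if self.e_value < 0:
            raise FormatError(f"hit {self.query}->{self.subject}: e_value < 0")
        if self.bitscore < 0:
            raise FormatError(f"hit {self.query}->{self.subject}: bitscore < 0")


@dataclass(frozen=True)
class DomainHit:
    """One protein-domain instance (one record per domain region per protein)."""

    protein: str
    domain_accession: str
    domain_name: str
    i_evalue: float
    ali_length_aa: int
    score: float


@dataclass
class SupportTree:
    """A gene tree with tip->species labels and integer edge supports.

    Wraps a :class:`dendropy.Tree`. Internal-node supports live on
    ``node.label`` (Newick internal labels) parsed as integers in [0, 100];
    absent labels are treated as fully supported.
    """

    tree: dendropy.Tree
    tip_species: dict[str, str]

    def __post_init__(self):
        for leaf in self.tree.leaf_node_iter():
            name = leaf.taxon.label if leaf.taxon else leaf.label
            if name not in self.tip_species:
                raise UnresolvedReferenceError(f"tip {name!r} has no species assignment")
        for node in self.tree.preorder_internal_node_iter():
            s = node_support(node)
            if s is not None and not (0 <= s <= 100):
                raise FormatError(f"support {s} outside [0, 100]")

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]


def node_support(node: dendropy.Node) -> int | None:
    """Bootstrap support of an internal node, or None when unlabeled."""
    if node.label is None or node.label == "":
        return None
    try:
        return int(round(float(node.label)))
    except ValueError:
        raise FormatError(f"non-numeric support label {node.label!r}") from None


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> ScaffoldSet:
    """Read a multi-record FASTA into a ScaffoldSet (order preserved).

    Sequences are uppercase-normalized; IUPAC ambiguity codes other than N
    are mapped to N (logged). Empty sequences or blank headers raise
    :class:`FormatError` naming the record.
    """
    path = Path(path)
    out = ScaffoldSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
        out.add(Scaffold(rec.id, normalize_sequence(seq, rec.id)))
    return out


def write_fasta(scaffolds: ScaffoldSet, path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(sc.seq), id=sc.id, description="") for sc in scaffolds
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r"([^=;]+)=([^;]*)")


def _parse_attrs(col9: str) -> dict[str, str]:
    return {k.strip(): v for k, v in _ATTR_RE.findall(col9)}


def read_gff3(path: str | Path, scaffolds: ScaffoldSet) -> AnnotatedGenome:
    """Read gene/mRNA/exon/CDS features from a GFF3 file.

    When a gene has several mRNAs, the representative transcript is the one
    with the longest summed CDS (summed exon length when no CDS rows exist),
    so each locus yields exactly one :class:`GeneModel`. The optional
    attributes ``has_start_codon``, ``has_stop_codon`` and ``utr_status``
    (emitted by :func:`write_gff3`) are honored; they default to
    true/true/complete.
    """
    path = Path(path)
    genes: dict[str, dict] = {}
    mrnas: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seqid, _src, ftype, start_s, end_s, _score, strand, _phase, attrs_s = cols
            if ftype not in ("gene", "mRNA", "exon", "CDS"):
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            attrs = _parse_attrs(attrs_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if not gid:
                    raise FormatError(f"{path}:{lineno}: gene without ID")
                genes[gid] = {
                    "scaffold": seqid,
                    "strand": strand,
                    "attrs": attrs,
                    "mrna_ids": [],
                    "exons": [],  # exons attached directly to the gene
                    "cds_len": 0,
                }
            elif ftype == "mRNA":
                mid = attrs.get("ID")
                parent = attrs.get("Parent")
                if not mid or not parent:
                    raise FormatError(f"{path}:{lineno}: mRNA without ID/Parent")
                mrnas[mid] = {"gene": parent, "exons": [], "cds_len": 0}
                if parent in genes:
                    genes[parent]["mrna_ids"].append(mid)
            else:  # exon / CDS
                parent = attrs.get("Parent")
                if not parent:
                    raise FormatError(f"{path}:{lineno}: {ftype} without Parent")
                for pid in parent.split(","):
                    target = mrnas.get(pid) or genes.get(pid)
                    if target is None:
                        raise UnresolvedReferenceError(
                            f"{path}:{lineno}: {ftype} Parent {pid!r} not seen"
                        )
                    if ftype == "exon":
                        target["exons"].append((start, end))
                    else:
                        target["cds_len"] += end - start + 1

    out: list[GeneModel] = []
    for gid, g in genes.items():
        if g["mrna_ids"]:
            # representative = longest summed CDS, tie-broken by exon sum then id
            best = max(
                g["mrna_ids"],
                key=lambda mid: (
                    mrnas[mid]["cds_len"],
                    sum(e - s + 1 for s, e in mrnas[mid]["exons"]),
                    mid,
                ),
            )
            exons = mrnas[best]["exons"]
        else:
            exons = g["exons"]
        if not exons:
            raise FormatError(f"{path}: gene {gid!r} has no exon features")
        attrs = g["attrs"]
        model = GeneModel(
            id=gid,
            scaffold_id=g["scaffold"],
            strand=g["strand"],
            exons=tuple(sorted(exons)),
            has_start_codon=attrs.get("has_start_codon", "true") == "true",
            has_stop_codon=attrs.get("has_stop_codon", "true") == "true",
            utr_status=attrs.get("utr_status", "complete"),
        )
        out.append(model)
    return AnnotatedGenome(scaffolds=scaffolds, genes=out)


def write_gff3(genome: AnnotatedGenome, path: str | Path, source: str = "symarch") -> None:
    """Write gene/mRNA/exon features (1-based inclusive, GFF3 native)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for sid, glist in genome.genes_by_scaffold().items():
            for g in glist:
                flags = (
                    f"has_start_codon={'true' if g.has_start_codon else 'false'};"
                    f"has_stop_codon={'true' if g.has_stop_codon else 'false'};"
                    f"utr_status={g.utr_status}"
                )
                fh.write(
                    f"{sid}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                    f"ID={g.id};{flags}\n"
                )
                mid = f"{g.id}.t1"
                fh.write(
                    f"{sid}\t{source}\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                    f"ID={mid};Parent={g.id}\n"
                )
                for i, (s, e) in enumerate(g.exons, 1):
                    fh.write(
                        f"{sid}\t{source}\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                        f"ID={mid}.exon{i};Parent={mid}\n"
                    )


# ---------------------------------------------------------------------------
# Hit tables (blast outfmt-6 style)
# ---------------------------------------------------------------------------

def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Read a 12-column tab-separated hit table (optional 13th taxon column).

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore [staxon]. Records are returned in file order.
    """
    path = Path(path)
    out: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) not in (12, 13):
                raise FormatError(
                    f"{path}:{lineno}: expected 12 or 13 columns, got {len(cols)}"
                )
            try:
                rec = HitRecord(
                    query=cols[0],
                    subject=cols[1],
                    percent_identity=float(cols[2]),
                    align_length=int(cols[3]),
                    e_value=float(cols[10]),
                    bitscore=float(cols[11]),
                    subject_species=cols[12] if len(cols) == 13 else None,
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            out.append(rec)
    return out


def write_hit_table(hits: Sequence[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            cols = [
                h.query, h.subject, f"{h.percent_identity:g}", str(h.align_length),
                "0", "0", "1", str(h.align_length), "1", str(h.align_length),
                f"{h.e_value:g}", f"{h.bitscore:g}",
            ]
            if h.subject_species is not None:
                cols.append(h.subject_species)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Domain-hit tables (HMMER domain-table style TSV)
# ---------------------------------------------------------------------------

_DOMAIN_COLUMNS = ["protein", "domain_accession", "domain_name", "i_evalue",
                   "ali_length_aa", "score"]


def read_domain_table(path: str | Path) -> list[DomainHit]:
    """Read a per-domain-instance TSV with a one-line header."""
    path = Path(path)
    out: list[DomainHit] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _DOMAIN_COLUMNS:
            raise FormatError(f"{path}: expected header {_DOMAIN_COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns")
            try:
                out.append(DomainHit(cols[0], cols[1], cols[2],
                                     float(cols[3]), int(cols[4]), float(cols[5])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return out


def write_domain_table(hits: Sequence[DomainHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_DOMAIN_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.protein}\t{h.domain_accession}\t{h.domain_name}\t"
                f"{h.i_evalue:g}\t{h.ali_length_aa}\t{h.score:g}\n"
            )


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def read_newick(
    source: str | Path,
    tip_species: Mapping[str, str] | None = None,
    species_of: Callable[[str], str] | None = None,
) -> SupportTree:
    """Read a Newick tree (integer supports as internal labels).

    Species assignments come from ``tip_species`` (explicit mapping) or
    ``species_of`` (a function of the tip label); the default derives the
    species as the label prefix before the first underscore, the convention
    used by this package's simulators (e.g. ``Smic_0007`` -> ``Smic``).
    """
    text = str(source)
    if "(" not in text:  # a path, not inline newick
        text = Path(source).read_text()
    tree = dendropy.Tree.get(data=text, schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if tip_species is None:
        fn = species_of or (lambda label: label.split("_", 1)[0])
        tip_species = {label: fn(label) for label in labels}
    return SupportTree(tree=tree, tip_species=dict(tip_species))


def write_newick(stree: SupportTree, path: str | Path) -> None:
    stree.tree.write(path=str(path), schema="newick",
                     suppress_rooting=True, unquoted_underscores=True)


# ---------------------------------------------------------------------------
# Training-set stringency filter
# ---------------------------------------------------------------------------

FILTER_CRITERIA = (
    "missing_start_or_stop",
    "fewer_than_3_exons",
    "ambiguous_utr",
    "shorter_cluster_member",
    "repeat_overlap",
)


def filter_training_genes(
    genes: Sequence[GeneModel],
    cluster_map: Mapping[str, str] | None = None,
    repeat_overlap_flags: Mapping[str, bool] | Iterable[str] | None = None,
    protein_lengths: Mapping[str, int] | None = None,
) -> tuple[list[GeneModel], dict[str, int]]:
    """Apply the five training-set stringency criteria, in order.

    (1) drop genes lacking a start or stop codon; (2) drop genes with fewer
    than 3 exons; (3) drop genes with ambiguous UTRs; (4) within each protein
    cluster keep only the longest protein (summed CDS length unless
    ``protein_lengths`` is supplied); (5) drop genes overlapping repeats.

    Returns (survivors in input order, per-criterion removal tally). The
    retained set is independent of the input gene order.
    """
    by_id = {g.id: g for g in genes}
    if len(by_id) != len(genes):
        raise FormatError("duplicate gene ids in training-filter input")
    cluster_map = dict(cluster_map or {})
    for gid in cluster_map:
        if gid not in by_id:
            raise UnresolvedReferenceError(
                f"cluster_map references unknown gene {gid!r}"
            )
    if repeat_overlap_flags is None:
        repeats: set[str] = set()
    elif isinstance(repeat_overlap_flags, Mapping):
        repeats = {gid for gid, flag in repeat_overlap_flags.items() if flag}
    else:
        repeats = set(repeat_overlap_flags)

    tally = dict.fromkeys(FILTER_CRITERIA, 0)
    alive = {g.id for g in genes}

    for g in genes:
        if not (g.has_start_codon and g.has_stop_codon):
            alive.discard(g.id)
            tally["missing_start_or_stop"] += 1
    for g in genes:
        if g.id in alive and g.n_exons < 3:
            alive.discard(g.id)
            tally["fewer_than_3_exons"] += 1
    for g in genes:
        if g.id in alive and g.utr_status == "ambiguous":
            alive.discard(g.id)
            tally["ambiguous_utr"] += 1

    def plen(gid: str) -> int:
        if protein_lengths is not None:
            try:
                return protein_lengths[gid]
            except KeyError:
                raise UnresolvedReferenceError(
                    f"no protein length for gene {gid!r}"
                ) from None
        return by_id[gid].coding_length

    clusters: dict[str, list[str]] = {}
    for gid in sorted(alive):
        clusters.setdefault(cluster_map.get(gid, f"__singleton__{gid}"), []).append(gid)
    for members in clusters.values():
        if len(members) < 2:
            continue
        keep = max(members, key=lambda gid: (plen(gid), gid))
        for gid in members:
            if gid != keep:
                alive.discard(gid)
                tally["shorter_cluster_member"] += 1

    for g in genes:
        if g.id in alive and g.id in repeats:
            alive.discard(g.id)
            tally["repeat_overlap"] += 1

    return [g for g in genes if g.id in alive], tally
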