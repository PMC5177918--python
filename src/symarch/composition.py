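"""Taxonomic best-hit composition, GO-annotation cascade, CEG completeness.

Gene models are classified by the taxonomy of their best homology hit into
seven kingdom/subkingdom groups (Archaea, Bacteria, Fungi, Metazoa, Plantae,
Protista, Viruses); an optional intra-genus search can take over a gene's
assignment when it scores a strictly higher bitscore (bitscores rather than
e-values, since they are independent of database size). The GO cascade
annotates genes from SwissProt first, then TrEMBL, then nr; CEG completeness
summarizes hits against the 458 core eukaryotic genes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ConfigError, FormatError, UnresolvedReferenceError
from .model import HitRecord
from .util import percent

KINGDOM_GROUPS = (
    "Archaea",
    "Bacteria",
    "Fungi",
    "Metazoa",
    "Plantae",
    "Protista",
    "Viruses",
)

NONE_CATEGORY = "none"
UNRESOLVED_CATEGORY = "unresolved"


@dataclass(frozen=True)
class TaxonAssignment:
    query: str
    category: str  # kingdom group, "Symbiodinium:<species>", "none", "unresolved"
    source_bitscore: float = 0.0


@dataclass
class CompositionMatrix:
    """Per-category tallies and fractions for one species' gene set."""

    species_label: str
    tallies: dict[str, int]
    fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        total = sum(self.tallies.values())
        if total == 0:
            raise ValueError("composition of an empty assignment list is undefined")
        self.fractions = {cat: n / total for cat, n in self.tallies.items()}

    @property
    def n_queries(self) -> int:
        return sum(self.tallies.values())


@dataclass
class CompletenessReport:
    ceg_universe: int
    found_counts: dict[str, int]
    found_percents: dict[str, float]
    shared_count: int
    exclusive_counts: dict[str, int]


def _hit_rank_key(h: HitRecord) -> tuple:
    # best first: highest bitscore, then lowest e-value, then subject id
    return (-h.bitscore, h.e_value, h.subject)


def best_hit_per_query(
    hits: Iterable[HitRecord], max_e: float = 1e-5
) -> dict[str, HitRecord]:
    """Best qualifying hit per query (highest bitscore among e <= max_e).

    Ties break by lower e-value, then lexicographic subject id. Queries with
    no qualifying hit are absent from the mapping.
    """
    best: dict[str, HitRecord] = {}
    for h in hits:
        if h.e_value > max_e:
            continue
        cur = best.get(h.query)
        if cur is None or _hit_rank_key(h) < _hit_rank_key(cur):
            best[h.query] = h
    return best


def classify_composition(
    best_hits: Mapping[str, HitRecord],
    taxonomy_map: Mapping[str, str],
    intra_genus_hits: Mapping[str, HitRecord] | None = None,
    queries: Iterable[str] | None = None,
    strict: bool = True,
) -> list[TaxonAssignment]:
    """Assign each query a kingdom-group (or intra-genus) category.

    The category comes from ``taxonomy_map`` applied to the reference best
    hit's subject species. When an intra-genus best hit for the same query
    has a *strictly* higher bitscore, the assignment switches to
    ``Symbiodinium:<species>`` (ties keep the reference assignment). Queries
    present in neither table are assigned ``"none"``.

    With ``strict=True`` (default) a subject species missing from
    ``taxonomy_map`` raises an error listing all offenders; otherwise such
    queries get the ``"unresolved"`` category.
    """
    intra_genus_hits = intra_genus_hits or {}
    if queries is None:
        queries = sorted(set(best_hits) | set(intra_genus_hits))
    else:
        queries = list(queries)

    missing: set[str] = set()
    out: list[TaxonAssignment] = []
    for q in queries:
        ref = best_hits.get(q)
        genus = intra_genus_hits.get(q)
        if ref is None and genus is None:
            out.append(TaxonAssignment(q, NONE_CATEGORY, 0.0))
            continue
        ref_bits = ref.bitscore if ref is not None else float("-inf")
        if genus is not None and genus.bitscore > ref_bits:
            sp = genus.subject_species or genus.subject
            out.append(TaxonAssignment(q, f"Symbiodinium:{sp}", genus.bitscore))
            continue
        species = ref.subject_species or ref.subject
        category = taxonomy_map.get(species)
        if category is None:
            missing.add(species)
            out.append(TaxonAssignment(q, UNRESOLVED_CATEGORY, ref.bitscore))
        else:
            out.append(TaxonAssignment(q, category, ref.bitscore))
    if missing and strict:
        raise UnresolvedReferenceError(
            "subject species missing from taxonomy map: "
            + ", ".join(sorted(missing))
        )
    return out


def composition_matrix(
    assignments: Sequence[TaxonAssignment], species_label: str
) -> CompositionMatrix:
    """Tally assignments into a per-category composition (fractions sum to 1)."""
    if not assignments:
        raise ValueError("composition of an empty assignment list is undefined")
    tallies: dict[str, int] = {}
    for a in assignments:
        tallies[a.category] = tallies.get(a.category, 0) + 1
    return CompositionMatrix(species_label=species_label, tallies=tallies)


_GO_RE = re.compile(r"^GO:\d{7}$")

TIER_SWISSPROT = "swissprot"
TIER_TREMBL = "trembl"
TIER_NR_NO_GO = "nr_annotated_no_go"
TIER_UNANNOTATED = "unannotated"


def _ranked(hits: Iterable[HitRecord]) -> dict[str, list[HitRecord]]:
    per_query: dict[str, list[HitRecord]] = {}
    for h in hits:
        per_query.setdefault(h.query, []).append(h)
    for q in per_query:
        per_query[q].sort(key=_hit_rank_key)
    return per_query


def go_annotation_cascade(
    swissprot_hits: Iterable[HitRecord],
    trembl_hits: Iterable[HitRecord],
    nr_hits: Iterable[HitRecord],
    go_maps: Mapping[str, Iterable[str]],
    queries: Iterable[str],
    max_rank: int = 20,
    max_e: float = 1e-5,
) -> tuple[dict[str, tuple[str, frozenset[str]]], dict[str, int]]:
    """Tiered GO annotation: SwissProt, then TrEMBL, then nr.

    Within each database a gene takes the GO terms of its best-scoring hit
    that has any GO annotation, considering up to ``max_rank`` hits with
    e-value <= ``max_e``. Genes with no GO from either protein database but
    a qualifying nr hit are tagged nr-annotated (no GO terms); the remainder
    are unannotated. Returns (per-gene (tier, terms), per-tier counts).
    """
    go_sets: dict[str, frozenset[str]] = {}
    for subject, terms in go_maps.items():
        fs = frozenset(terms)
        for t in fs:
            if not _GO_RE.match(t):
                raise FormatError(f"malformed GO identifier {t!r} for {subject!r}")
        go_sets[subject] = fs

    sp = _ranked(swissprot_hits)
    tr = _ranked(trembl_hits)
    nr = _ranked(nr_hits)

    def tier_terms(ranked: dict[str, list[HitRecord]], q: str) -> frozenset[str] | None:
        qualifying = [h for h in ranked.get(q, []) if h.e_value <= max_e][:max_rank]
        for h in qualifying:
            terms = go_sets.get(h.subject)
            if terms:
                return terms
        return None

    result: dict[str, tuple[str, frozenset[str]]] = {}
    counts = {TIER_SWISSPROT: 0, TIER_TREMBL: 0, TIER_NR_NO_GO: 0, TIER_UNANNOTATED: 0}
    for q in queries:
        terms = tier_terms(sp, q)
        if terms is not None:
            result[q] = (TIER_SWISSPROT, terms)
        else:
            terms = tier_terms(tr, q)
            if terms is not None:
                result[q] = (TIER_TREMBL, terms)
            elif any(h.e_value <= max_e for h in nr.get(q, [])):
                result[q] = (TIER_NR_NO_GO, frozenset())
            else:
                result[q] = (TIER_UNANNOTATED, frozenset())
        counts[result[q][0]] += 1
    return result, counts


def ceg_completeness(
    per_species_ceg_hits: Mapping[str, Mapping[str, float]],
    ceg_universe: Iterable[str],
    max_e: float = 1e-5,
) -> CompletenessReport:
    """Summarize presence of core eukaryotic genes (CEGs) per species.

    ``per_species_ceg_hits`` maps species -> {CEG id: best e-value}. A CEG is
    found iff its best e-value is <= ``max_e``. Percents are over the CEG
    universe, one decimal, rounded half away from zero. ``shared_count`` is
    the all-species intersection and ``exclusive_counts`` the CEGs found in
    exactly one species.
    """
    universe = set(ceg_universe)
    if not universe:
        raise ConfigError("empty CEG universe")
    found: dict[str, set[str]] = {}
    for species, table in per_species_ceg_hits.items():
        outside = set(table) - universe
        if outside:
            raise UnresolvedReferenceError(
                f"{species}: CEG ids outside the universe: {sorted(outside)[:5]}"
            )
        found[species] = {ceg for ceg, e in table.items() if e <= max_e}

    species_list = list(found)
    shared = set(universe)
    for s in species_list:
        shared &= found[s]
    exclusives = {
        s: len(found[s] - set().union(*(found[t] for t in species_list if t != s)))
        if len(species_list) > 1
        else len(found[s])
        for s in species_list
    }
    return CompletenessReport(
        ceg_universe=len(universe),
        found_counts={s: len(found[s]) for s in species_list},
        found_percents={s: percent(len(found[s]), len(universe)) for s in species_list},
        shared_count=len(shared),
        exclusive_counts=exclusives,
    )
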