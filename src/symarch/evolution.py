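"""Species-specific duplication clades on gene trees and collinear blocks.

Lineage-specific gene-family expansion leaves two genomic signatures probed
here: (1) gene-tree clades whose tips all belong to one species, counted
after collapsing poorly supported edges (bootstrap < 50) into polytomies;
and (2) the near-absence of collinear (synteny) blocks between genomes,
detected with a simplified anchor-chaining collinearity finder requiring at
least five homologous genes in conserved (possibly inverted) order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy

from .enrichment import DomainCountMatrix, bh_fdr, domain_ratios, fisher_vs_outgroup
from .errors import ConfigError, SymarchError, UnresolvedReferenceError
from .model import DomainHit, SupportTree, node_support


@dataclass
class TreeConfig:
    support_collapse_threshold: int = 50
    min_clade_size: int = 2

    def __post_init__(self):
        if not (0 <= self.support_collapse_threshold <= 100):
            raise ConfigError("support threshold must be in [0, 100]")
        if self.min_clade_size < 2:
            raise ConfigError("min_clade_size must be >= 2")


@dataclass
class TransporterFilter:
    max_domain_evalue: float = 1e-15
    min_length_aa: int = 150
    literal_evalue_filter: bool = False  # keep e > cutoff instead (literal reading)
    length_on_domain_alignment: bool = False  # use domain hit length, not protein

    def __post_init__(self):
        if self.max_domain_evalue <= 0:
            raise ConfigError("max_domain_evalue must be > 0")


@dataclass
class SyntenyConfig:
    min_block_genes: int = 5
    max_gap_genes: int = 25
    homology_max_e: float = 1e-5

    def __post_init__(self):
        if self.min_block_genes < 2:
            raise ConfigError("min_block_genes must be >= 2")
        if self.max_gap_genes < 0:
            raise ConfigError("max_gap_genes must be >= 0")


@dataclass
class SyntenyBlock:
    scaffold_a: str
    scaffold_b: str
    anchors: tuple[tuple[str, str], ...]  # ordered (geneA, geneB) pairs
    orientation: str  # "same" or "inverted"

    @property
    def size(self) -> int:
        return len(self.anchors)


def filter_transporter_genes(
    domain_hits: Iterable[DomainHit],
    protein_lengths: Mapping[str, int],
    filt: TransporterFilter | None = None,
) -> set[str]:
    """Select transporter-family genes for phylogenetic analysis.

    Keeps proteins with a qualifying family-domain hit (e-value <=
    ``max_domain_evalue``) and length above ``min_length_aa``. The
    ``literal_evalue_filter`` flag applies the caption-literal reading
    (e-value strictly greater than the cutoff) instead.
    """
    filt = filt or TransporterFilter()
    kept: set[str] = set()
    for h in domain_hits:
        if filt.literal_evalue_filter:
            e_ok = h.i_evalue > filt.max_domain_evalue
        else:
            e_ok = h.i_evalue <= filt.max_domain_evalue
        if not e_ok:
            continue
        if filt.length_on_domain_alignment:
            length = h.ali_length_aa
        else:
            if h.protein not in protein_lengths:
                raise UnresolvedReferenceError(f"no length for protein {h.protein!r}")
            length = protein_lengths[h.protein]
        if length > filt.min_length_aa:
            kept.add(h.protein)
    return kept


def collapse_low_support(stree: SupportTree, config: TreeConfig | None = None) -> SupportTree:
    """Contract every internal edge with support below the threshold.

    Works on a clone; tips are untouched; unlabeled internal edges are
    treated as fully supported. Chains of weak edges dissolve into a single
    polytomy.
    """
    config = config or TreeConfig()
    tree = stree.tree.clone(depth=1)
    changed = True
    while changed:
        changed = False
        for node in tree.postorder_internal_node_iter():
            if node is tree.seed_node:
                continue
            s = node_support(node)
            if s is not None and s < config.support_collapse_threshold:
                parent = node.parent_node
                for child in list(node.child_nodes()):
                    node.remove_child(child)
                    parent.add_child(child)
                parent.remove_child(node)
                changed = True
                break
    return SupportTree(tree=tree, tip_species=dict(stree.tip_species))


def _leaf_label(leaf: dendropy.Node) -> str:
    return leaf.taxon.label if leaf.taxon else leaf.label


def species_specific_clades(
    stree: SupportTree, config: TreeConfig | None = None
) -> tuple[dict[str, int], dict[str, list[frozenset[str]]]]:
    """Maximal monospecific clades of size >= min_clade_size, per species.

    Operates on the tree as given (collapse weak edges first with
    :func:`collapse_low_support`). A clade is reported iff all its tips are
    one species and no larger monospecific clade contains it, so each tip
    belongs to at most one reported clade. Returns (counts per species,
    memberships per species).
    """
    config = config or TreeConfig()
    tree = stree.tree
    species_of: dict[int, set[str]] = {}
    tips_of: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = _leaf_label(node)
            sp = stree.tip_species.get(label)
            if sp is None:
                raise UnresolvedReferenceError(f"tip {label!r} has no species assignment")
            species_of[id(node)] = {sp}
            tips_of[id(node)] = frozenset([label])
        else:
            sps: set[str] = set()
            tps: set[str] = set()
            for c in node.child_nodes():
                sps |= species_of[id(c)]
                tps |= set(tips_of[id(c)])
            species_of[id(node)] = sps
            tips_of[id(node)] = frozenset(tps)

    memberships: dict[str, list[frozenset[str]]] = {}
    for node in tree.preorder_internal_node_iter():
        sps = species_of[id(node)]
        if len(sps) != 1:
            continue
        parent = node.parent_node
        if parent is not None and len(species_of[id(parent)]) == 1:
            continue  # not maximal
        if len(tips_of[id(node)]) >= config.min_clade_size:
            sp = next(iter(sps))
            memberships.setdefault(sp, []).append(tips_of[id(node)])
    counts = {sp: len(clades) for sp, clades in memberships.items()}
    return counts, memberships


# ---------------------------------------------------------------------------
# Collinear (synteny) blocks
# ---------------------------------------------------------------------------

def _rank_map(order: Sequence[str], genome_name: str) -> dict[str, int]:
    ranks = {g: i for i, g in enumerate(order)}
    if len(ranks) != len(order):
        raise SymarchError(f"duplicate gene ids in genome {genome_name} order")
    return ranks


def _dedupe_tandem(
    anchors: list[tuple[int, int, str, str, float]]
) -> list[tuple[int, int, str, str]]:
    """Resolve tandem-duplicate matches: when one gene matches a consecutive
    run of genes in the other genome, keep only the highest-bitscore pair."""

    def collapse(items, key_pos, other_pos):
        by_key: dict[int, list] = {}
        for a in items:
            by_key.setdefault(a[key_pos], []).append(a)
        out = []
        for _k, group in by_key.items():
            group.sort(key=lambda a: a[other_pos])
            run = [group[0]]
            for a in group[1:]:
                if a[other_pos] == run[-1][other_pos] + 1:
                    run.append(a)
                else:
                    out.append(max(run, key=lambda r: (r[4], -r[0], -r[1])))
                    run = [a]
            out.append(max(run, key=lambda r: (r[4], -r[0], -r[1])))
        return out

    anchors = collapse(anchors, 0, 1)
    anchors = collapse(anchors, 1, 0)
    return [(pa, pb, ga, gb) for pa, pb, ga, gb, _bits in sorted(anchors)]


def _longest_chain(
    anchors: list[tuple[int, int, str, str]], direction: int, max_gap: int
) -> list[int]:
    """Indices of the longest chain, strictly monotone in A, monotone in B
    (direction +1 increasing, -1 decreasing), rank gaps <= max_gap in both."""
    n = len(anchors)
    best_len = [1] * n
    pred = [-1] * n
    for i in range(n):
        pa_i, pb_i = anchors[i][0], anchors[i][1]
        for j in range(i):
            pa_j, pb_j = anchors[j][0], anchors[j][1]
            if pa_i <= pa_j:
                continue
            if direction * (pb_i - pb_j) <= 0:
                continue
            if pa_i - pa_j - 1 > max_gap or abs(pb_i - pb_j) - 1 > max_gap:
                continue
            if best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                pred[i] = j
    if not best_len:
        return []
    end = max(range(n), key=lambda i: (best_len[i], -anchors[i][0]))
    chain = []
    while end != -1:
        chain.append(end)
        end = pred[end]
    return chain[::-1]


def find_collinear_blocks(
    gene_order_a: Mapping[str, Sequence[str]] | Sequence[str],
    gene_order_b: Mapping[str, Sequence[str]] | Sequence[str],
    homolog_pairs: Iterable[tuple],
    config: SyntenyConfig | None = None,
) -> tuple[list[SyntenyBlock], dict[int, int]]:
    """Greedy longest-first extraction of collinear anchor chains.

    ``gene_order_a``/``b`` map scaffold -> ordered gene ids (a bare sequence
    is one unnamed scaffold). ``homolog_pairs`` are (geneA, geneB) or
    (geneA, geneB, bitscore) tuples, pre-filtered at the homology e-value
    cutoff. Within each scaffold pair, chains must be strictly monotone in
    genome A and monotone (increasing or decreasing) in genome B with at
    most ``max_gap_genes`` intervening genes between consecutive anchors in
    both genomes. Chains of at least ``min_block_genes`` anchors are
    reported longest-first, consuming their anchors. Returns (blocks,
    histogram of block sizes).
    """
    config = config or SyntenyConfig()
    if not isinstance(gene_order_a, Mapping):
        gene_order_a = {"A": list(gene_order_a)}
    if not isinstance(gene_order_b, Mapping):
        gene_order_b = {"B": list(gene_order_b)}
    pos_a: dict[str, tuple[str, int]] = {}
    for scaf, order in gene_order_a.items():
        for g, r in _rank_map(order, "A").items():
            if g in pos_a:
                raise SymarchError(f"duplicate gene id {g!r} in genome A")
            pos_a[g] = (scaf, r)
    pos_b: dict[str, tuple[str, int]] = {}
    for scaf, order in gene_order_b.items():
        for g, r in _rank_map(order, "B").items():
            if g in pos_b:
                raise SymarchError(f"duplicate gene id {g!r} in genome B")
            pos_b[g] = (scaf, r)

    by_pair: dict[tuple[str, str], list[tuple[int, int, str, str, float]]] = {}
    for pair in homolog_pairs:
        ga, gb = pair[0], pair[1]
        bits = float(pair[2]) if len(pair) > 2 else 0.0
        if ga not in pos_a or gb not in pos_b:
            continue
        sa, ra = pos_a[ga]
        sb, rb = pos_b[gb]
        by_pair.setdefault((sa, sb), []).append((ra, rb, ga, gb, bits))

    blocks: list[SyntenyBlock] = []
    for (sa, sb), raw in sorted(by_pair.items()):
        anchors = _dedupe_tandem(raw)
        while True:
            best_chain: list[int] = []
            best_dir = 1
            for direction in (1, -1):
                chain = _longest_chain(anchors, direction, config.max_gap_genes)
                if len(chain) > len(best_chain):
                    best_chain, best_dir = chain, direction
            if len(best_chain) < config.min_block_genes:
                break
            chosen = [anchors[i] for i in best_chain]
            blocks.append(
                SyntenyBlock(
                    scaffold_a=sa,
                    scaffold_b=sb,
                    anchors=tuple((ga, gb) for _pa, _pb, ga, gb in chosen),
                    orientation="same" if best_dir == 1 else "inverted",
                )
            )
            used = set(best_chain)
            anchors = [a for i, a in enumerate(anchors) if i not in used]

    histogram: dict[int, int] = {}
    for b in blocks:
        histogram[b.size] = histogram.get(b.size, 0) + 1
    return blocks, histogram


@dataclass
class ContrastRecord:
    domain: str
    counts: dict[str, int]
    ratios: dict[str, float]
    pairwise_p: dict[tuple[str, str], float]
    pairwise_q: dict[tuple[str, str], float]


def domain_family_contrast(
    matrix: DomainCountMatrix,
    domain: str,
    species_list: Sequence[str] | None = None,
    sidedness: str = "two-sided",
) -> ContrastRecord:
    """Pairwise Fisher contrasts of one domain family across species.

    Each species pair is tested with :func:`fisher_vs_outgroup` using the
    partner as a singleton outgroup; p-values are BH-corrected within the
    pairwise family.
    """
    if domain not in matrix.counts.columns:
        raise UnresolvedReferenceError(f"domain {domain!r} absent from matrix")
    species = list(species_list or matrix.species)
    for sp in species:
        if sp not in matrix.counts.index:
            raise UnresolvedReferenceError(f"species {sp!r} absent from matrix")
    totals = matrix.totals
    ratios = domain_ratios(matrix)
    pairs = [(a, b) for i, a in enumerate(species) for b in species[i + 1 :]]
    ps = [
        fisher_vs_outgroup(
            int(matrix.counts.at[a, domain]),
            int(totals[a]),
            [int(matrix.counts.at[b, domain])],
            [int(totals[b])],
            sidedness,
        )
        for a, b in pairs
    ]
    qs = bh_fdr(ps) if ps else []
    return ContrastRecord(
        domain=domain,
        counts={sp: int(matrix.counts.at[sp, domain]) for sp in species},
        ratios={sp: float(ratios.at[sp, domain]) for sp in species},
        pairwise_p=dict(zip(pairs, map(float, ps))),
        pairwise_q=dict(zip(pairs, map(float, qs))),
    )
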