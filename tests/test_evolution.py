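"""Tree collapse, duplication-clade counting, and collinear-block detection."""

from __future__ import annotations

import numpy as np
import pytest

import symarch as sa
from symarch.errors import ConfigError, SymarchError, UnresolvedReferenceError
from symarch.evolution import _longest_chain

from oracles import clades_oracle, exhaustive_longest_chain


def dh(protein, e, length=300, acc="PF00955"):
    return sa.DomainHit(protein, acc, "HCO3_cotransp", e, 120, 80.0)


class TestTransporterFilter:
    LENGTHS = {"p1": 300, "p2": 300, "p3": 100}

    def test_strong_hit_long_protein_retained(self):
        assert sa.filter_transporter_genes([dh("p1", 1e-20)], self.LENGTHS) == {"p1"}

    def test_weak_evalue_excluded(self):
        assert sa.filter_transporter_genes([dh("p2", 1e-10)], self.LENGTHS) == set()

    def test_short_protein_excluded(self):
        assert sa.filter_transporter_genes([dh("p3", 1e-20)], self.LENGTHS) == set()

    def test_literal_reading_flag_inverts_evalue_rule(self):
        filt = sa.TransporterFilter(literal_evalue_filter=True)
        assert sa.filter_transporter_genes([dh("p2", 1e-10)], self.LENGTHS, filt) == {"p2"}
        assert sa.filter_transporter_genes([dh("p1", 1e-20)], self.LENGTHS, filt) == set()

    def test_missing_length_is_reference_error(self):
        with pytest.raises(UnresolvedReferenceError):
            sa.filter_transporter_genes([dh("ghost", 1e-20)], self.LENGTHS)


class TestCollapse:
    def test_weak_edge_becomes_polytomy(self):
        stree = sa.read_newick("((A_1,A_2)30,B_1);")
        out = sa.collapse_low_support(stree)
        root = out.tree.seed_node
        assert len(root.child_nodes()) == 3  # polytomy a, b, c

    def test_strong_edge_unchanged(self):
        stree = sa.read_newick("((A_1,A_2)90,B_1);")
        out = sa.collapse_low_support(stree)
        assert len(out.tree.seed_node.child_nodes()) == 2

    def test_chain_of_weak_edges_fully_contracted(self):
        stree = sa.read_newick("(((A_1,A_2)30,B_1)40,B_2);")
        out = sa.collapse_low_support(stree)
        assert len(out.tree.seed_node.child_nodes()) == 4

    def test_tip_set_and_strong_clades_preserved(self):
        stree, _ = sa.simulate_gene_tree(seed=8)
        collapsed = sa.collapse_low_support(stree)
        assert sorted(collapsed.tip_labels) == sorted(stree.tip_labels)
        # every clade with support >= 50 in the original survives intact
        from symarch.model import node_support

        for node in stree.tree.preorder_internal_node_iter():
            s = node_support(node)
            if s is not None and s >= 50:
                tips = frozenset(l.taxon.label for l in node.leaf_iter())
                found = any(
                    frozenset(l.taxon.label for l in n.leaf_iter()) == tips
                    for n in collapsed.tree.preorder_internal_node_iter()
                )
                assert found


class TestSpeciesClades:
    def test_collapse_dissolves_weak_grouping(self):
        stree = sa.read_newick("((A_1,A_2)95,((A_3,B_1)30,B_2)80);")
        collapsed = sa.collapse_low_support(stree)
        counts, members = sa.species_specific_clades(collapsed)
        assert counts == {"A": 1}
        assert members["A"] == [frozenset({"A_1", "A_2"})]

    def test_interleaved_species_have_no_clades(self):
        stree = sa.read_newick("((A_1,B_1)90,(A_2,B_2)90);")
        counts, _ = sa.species_specific_clades(stree)
        assert counts == {}

    def test_maximality_single_species_tree(self):
        newick = "(((A_1,A_2)90,(A_3,A_4)90)90,((A_5,A_6)90,(A_7,A_8)90)90);"
        counts, members = sa.species_specific_clades(sa.read_newick(newick))
        assert counts == {"A": 1}
        assert len(members["A"][0]) == 8

    def test_reported_clades_are_disjoint(self):
        for seed in range(5):
            stree, _ = sa.simulate_gene_tree(seed=seed)
            _, members = sa.species_specific_clades(sa.collapse_low_support(stree))
            all_tips = [t for cl in members.values() for c in cl for t in c]
            assert len(all_tips) == len(set(all_tips))

    def test_matches_brute_force_on_random_trees(self):
        rng = np.random.default_rng(12)
        for _ in range(40):
            n_tips = int(rng.integers(4, 17))
            counts, clades = _random_tree_counts(rng, n_tips)
            assert counts == clades


def _random_tree_counts(rng, n_tips):
    """Build a random binary tree over <=16 tips with random 2-species
    labels, then compare implementation vs containment-filter oracle."""
    labels = [f"{'AB'[rng.integers(0, 2)]}_{i:03d}" for i in range(n_tips)]
    frags = list(labels)
    while len(frags) > 1:
        i, j = sorted(rng.choice(len(frags), size=2, replace=False))
        b = frags.pop(j)
        a = frags.pop(i)
        frags.append(f"({a},{b}){int(rng.integers(0, 101))}")
    stree = sa.read_newick(frags[0] + ";")
    collapsed = sa.collapse_low_support(stree)
    counts, _ = sa.species_specific_clades(collapsed)
    clade_sets = [
        frozenset(l.taxon.label for l in node.leaf_iter())
        for node in collapsed.tree.preorder_internal_node_iter()
    ]
    oracle = clades_oracle(clade_sets, collapsed.tip_species, min_size=2)
    return counts, oracle


class TestCollinearBlocks:
    def _identity_pairs(self, n, offset=0):
        return [(f"a{i:05d}", f"b{i + offset:05d}") for i in range(n)]

    def test_identity_block(self):
        oa = [f"a{i:05d}" for i in range(10)]
        ob = [f"b{i:05d}" for i in range(10)]
        blocks, hist = sa.find_collinear_blocks(oa, ob, self._identity_pairs(5))
        assert len(blocks) == 1
        assert blocks[0].size == 5 and blocks[0].orientation == "same"
        assert hist == {5: 1}

    def test_four_anchors_below_minimum(self):
        oa = [f"a{i:05d}" for i in range(10)]
        ob = [f"b{i:05d}" for i in range(10)]
        blocks, _ = sa.find_collinear_blocks(oa, ob, self._identity_pairs(4))
        assert blocks == []

    def test_inverted_block(self):
        oa = [f"a{i:05d}" for i in range(6)]
        ob = [f"b{i:05d}" for i in range(6)]
        pairs = [(f"a{i:05d}", f"b{5 - i:05d}") for i in range(6)]
        blocks, _ = sa.find_collinear_blocks(oa, ob, pairs)
        assert len(blocks) == 1
        assert blocks[0].size == 6 and blocks[0].orientation == "inverted"

    def test_gap_constraint_breaks_chain(self):
        oa = [f"a{i:05d}" for i in range(100)]
        ob = [f"b{i:05d}" for i in range(100)]
        pairs = [(f"a{i * 30:05d}", f"b{i * 30:05d}") for i in range(3)]
        cfg = sa.SyntenyConfig(min_block_genes=2, max_gap_genes=10)
        blocks, _ = sa.find_collinear_blocks(oa, ob, pairs, cfg)
        assert blocks == []

    def test_duplicate_gene_id_rejected(self):
        with pytest.raises(SymarchError):
            sa.find_collinear_blocks(["a1", "a1"], ["b1"], [("a1", "b1")])

    def test_matches_exhaustive_chain_search(self):
        rng = np.random.default_rng(5)
        cfg_gap = 4
        for _ in range(60):
            n = int(rng.integers(2, 13))
            anchors = sorted(
                {(int(rng.integers(0, 15)), int(rng.integers(0, 15)))
                 for _ in range(n)}
            )
            anchors4 = [(pa, pb, f"a{pa}", f"b{pb}") for pa, pb in anchors]
            best = max(
                len(_longest_chain(anchors4, 1, cfg_gap)),
                len(_longest_chain(anchors4, -1, cfg_gap)),
            )
            assert best == exhaustive_longest_chain(
                [(pa, pb) for pa, pb in anchors], cfg_gap
            )

    def test_planted_blocks_recovered(self):
        oa, ob, pairs, truth = sa.simulate_synteny_pair(
            200, [(0, 50, 6, "same"), (100, 10, 5, "inverted"), (150, 150, 7, "same")],
            noise_rate=0.0, seed=1,
        )
        blocks, _ = sa.find_collinear_blocks(oa, ob, pairs)
        assert sorted(b.size for b in blocks) == [5, 6, 7]


class TestDomainContrast:
    def test_transporter_like_counts(self):
        m = sa.DomainCountMatrix.from_rows({
            "Smic": {"PF00955": 52, "rest": 30_000 - 52},
            "Smin": {"PF00955": 15, "rest": 30_000 - 15},
            "Skaw": {"PF00955": 4, "rest": 30_000 - 4},
        })
        rec = sa.domain_family_contrast(m, "PF00955")
        assert rec.counts == {"Smic": 52, "Smin": 15, "Skaw": 4}
        assert rec.pairwise_q[("Smic", "Skaw")] < 0.001

    def test_equal_counts_are_null(self):
        m = sa.DomainCountMatrix.from_rows({
            "x": {"d": 10, "rest": 1000},
            "y": {"d": 10, "rest": 1000},
        })
        rec = sa.domain_family_contrast(m, "d")
        assert rec.pairwise_p[("x", "y")] == pytest.approx(1.0)

    def test_unknown_domain_rejected(self):
        m = sa.DomainCountMatrix.from_rows({"x": {"d": 1}})
        with pytest.raises(UnresolvedReferenceError):
            sa.domain_family_contrast(m, "ghost")
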