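"""Domain-enrichment machinery: ratios, Fisher, BH-FDR, z-scores, clustering."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import symarch as sa
from symarch.errors import ConfigError

from oracles import bh_stepup_oracle, fisher_exact_oracle


def dh(protein, acc, e=1e-10, length=100):
    return sa.DomainHit(protein, acc, acc, e, length, 50.0)


class TestCountDomains:
    def test_instance_policy_counts_repeats(self):
        hits = [dh("p1", "PF00955"), dh("p1", "PF00955")]
        assert sa.count_domains(hits) == {"PF00955": 2}

    def test_per_protein_policy_counts_once(self):
        hits = [dh("p1", "PF00955"), dh("p1", "PF00955")]
        assert sa.count_domains(hits, per_protein=True) == {"PF00955": 1}

    def test_empty_hits_give_empty_row(self):
        assert sa.count_domains([]) == {}

    def test_insignificant_hits_excluded(self):
        assert sa.count_domains([dh("p1", "PF1", e=1e-3)]) == {}


class TestRatios:
    def test_simple_ratios(self):
        m = sa.DomainCountMatrix.from_rows({"s": {"a": 2, "b": 8}})
        ratios = sa.domain_ratios(m)
        assert ratios.loc["s"].tolist() == [0.2, 0.8]

    def test_zero_total_rejected(self):
        m = sa.DomainCountMatrix.from_rows({"s": {"a": 0, "b": 0}})
        with pytest.raises(ValueError):
            sa.domain_ratios(m)

    @given(st.lists(st.lists(st.integers(0, 50), min_size=4, max_size=4),
                    min_size=2, max_size=5))
    def test_rows_sum_to_one(self, counts):
        rows = {
            f"s{i}": {f"d{j}": c + (1 if j == 0 else 0) for j, c in enumerate(row)}
            for i, row in enumerate(counts)
        }
        ratios = sa.domain_ratios(sa.DomainCountMatrix.from_rows(rows))
        assert np.allclose(ratios.sum(axis=1), 1.0)


class TestFisher:
    def test_empty_table_is_null(self):
        assert sa.fisher_vs_outgroup(0, 10, [0], [10], "two-sided") == pytest.approx(1.0)

    def test_known_two_sided_value(self):
        # table [[1,9],[11,3]]: full hypergeometric enumeration gives 0.002759
        p = sa.fisher_vs_outgroup(1, 10, [11], [14], "two-sided")
        assert p == pytest.approx(0.0027594561852, rel=1e-9)

    def test_strong_enrichment_one_sided(self):
        # mirrors the bicarbonate-transporter scale: 52 vs outgroup mean ~9.5
        p = sa.fisher_vs_outgroup(52, 10_000, [9, 10], [10_000, 10_000], "greater")
        assert p < 1e-6  # far below any screening threshold

    def test_outgroup_averaging_rounds_half_away(self):
        # outgroup counts (1, 2) -> mean 1.5 -> 2 after rounding
        p_avg = sa.fisher_vs_outgroup(5, 100, [1, 2], [100, 100], "greater")
        p_two = sa.fisher_vs_outgroup(5, 100, [2], [100], "greater")
        assert p_avg == pytest.approx(p_two)

    def test_rounded_count_above_total_rejected(self):
        with pytest.raises(ValueError):
            sa.fisher_vs_outgroup(1, 10, [10], [4], "greater")

    @given(
        st.integers(0, 20), st.integers(0, 20), st.integers(0, 20), st.integers(0, 20),
        st.sampled_from(["greater", "less", "two-sided"]),
    )
    def test_matches_exact_enumeration(self, a, b, c, d, sidedness):
        if a + b == 0 or c + d == 0:
            return
        p = sa.fisher_vs_outgroup(a, a + b, [c], [c + d], sidedness)
        assert p == pytest.approx(fisher_exact_oracle(a, b, c, d, sidedness), rel=1e-7)


class TestBhFdr:
    def test_single_p(self):
        assert sa.bh_fdr([0.04]).tolist() == [pytest.approx(0.04)]

    def test_step_up_example(self):
        assert sa.bh_fdr([0.01, 0.02, 0.03]).tolist() == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert sa.bh_fdr([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sa.bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_brute_force_and_is_monotone(self, ps):
        q = sa.bh_fdr(ps)
        assert np.allclose(q, bh_stepup_oracle(ps), atol=1e-12)
        order = np.argsort(ps)
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()


class TestZscores:
    def test_linear_example(self):
        df = pd.DataFrame({"d": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        assert sa.zscore_matrix(df)["d"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_domain_gets_zero(self):
        df = pd.DataFrame({"d": [0.5, 0.5, 0.5]}, index=["a", "b", "c"])
        assert sa.zscore_matrix(df)["d"].tolist() == [0.0, 0.0, 0.0]

    def test_single_species_rejected(self):
        with pytest.raises(ValueError):
            sa.zscore_matrix(pd.DataFrame({"d": [1.0]}, index=["a"]))

    def test_standardization_property(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.random((6, 10)))
        z = sa.zscore_matrix(df)
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-12)


class TestScreen:
    def test_planted_tenfold_enrichment_detected(self):
        cfg = sa.SyntheticEnrichmentConfig(
            n_species=5, n_domains=100, total_counts=50_000,
            planted_effects=[("PF00007", ["sp1"], 10.0)], seed=9,
        )
        matrix, _ = sa.simulate_domain_counts(cfg)
        enriched, records = sa.enrichment_screen(
            matrix,
            sa.ScreenConfig(in_group=("sp1",), out_group=("sp2", "sp3", "sp4", "sp5")),
        )
        assert "PF00007" in enriched
        rec = next(r for r in records if r.domain == "PF00007")
        assert rec.q_values["sp1"] >= rec.p_values["sp1"]
        assert rec.z["sp1"] > 0

    def test_empty_in_group_rejected(self):
        with pytest.raises(ConfigError):
            sa.ScreenConfig(in_group=(), out_group=("a",))

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ConfigError):
            sa.ScreenConfig(in_group=("a",), out_group=("a", "b"))


class TestSpecificSet:
    def test_intersection_with_provenance(self):
        shared, prov = sa.specific_set({"A", "B", "C"}, {"B", "C", "D"})
        assert shared == {"B", "C"}
        assert prov["B"] == ["screen_a", "screen_b"]
        assert prov["D"] == ["screen_b"]

    def test_disjoint_sets(self):
        assert sa.specific_set({"A"}, {"B"})[0] == set()

    def test_doubly_planted_domains_intersect(self):
        common = [("PF00001", ["sp1"], 8.0)]
        m1, _ = sa.simulate_domain_counts(sa.SyntheticEnrichmentConfig(
            n_species=5, n_domains=50, total_counts=50_000,
            planted_effects=common + [("PF00002", ["sp1"], 8.0)], seed=21))
        m2, _ = sa.simulate_domain_counts(sa.SyntheticEnrichmentConfig(
            n_species=5, n_domains=50, total_counts=50_000,
            planted_effects=common + [("PF00003", ["sp1"], 8.0)], seed=22))
        cfg = sa.ScreenConfig(in_group=("sp1",), out_group=("sp2", "sp3", "sp4", "sp5"))
        e1, _ = sa.enrichment_screen(m1, cfg)
        e2, _ = sa.enrichment_screen(m2, cfg)
        assert sa.specific_set(e1, e2)[0] == {"PF00001"}


class TestClusterOrder:
    def test_identical_columns_adjacent(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(4, 5)),
                          columns=[f"d{i}" for i in range(5)])
        df["d4"] = df["d0"]
        _, cols = sa.cluster_order(df)
        i, j = cols.index("d0"), cols.index("d4")
        assert abs(i - j) == 1

    def test_close_pair_merges_first(self):
        df = pd.DataFrame([[0.0], [1.0], [10.0]], index=["a", "b", "c"])
        rows, _ = sa.cluster_order(df)
        assert rows.index("c") in (0, 2)  # outlier is a leaf-edge singleton

    def test_permutation_keeps_closest_pair_adjacent(self):
        # the tightest pair merges first, so it stays adjacent under any
        # input permutation (dendrogram flips cannot separate siblings)
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(scale=5.0, size=(6, 4)),
                          index=[f"s{i}" for i in range(6)])
        df.loc["s1"] = df.loc["s0"] + 0.01
        for state in (3, 4, 5):
            rows, _ = sa.cluster_order(df.sample(frac=1.0, random_state=state))
            assert abs(rows.index("s0") - rows.index("s1")) == 1

    def test_rerun_is_deterministic(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.normal(size=(8, 5)))
        assert sa.cluster_order(df) == sa.cluster_order(df)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            sa.cluster_order(pd.DataFrame([[np.nan, 1.0], [0.0, 2.0]]))
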