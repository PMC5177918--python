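"""Data-model and I/O tests: FASTA/GFF3/hit-table parsing, training filter."""

from __future__ import annotations

import pytest
from hypothesis import given
from hypothesis import strategies as st

import symarch as sa
from symarch.errors import CoordinateError, FormatError, UnresolvedReferenceError

from conftest import gene, make_genome


class TestFasta:
    def test_lowercase_normalized(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">s1\nacgtn\n")
        sc = sa.read_fasta(p)
        assert sc["s1"].seq == "ACGTN"
        assert len(sc["s1"]) == 5

    def test_total_length_two_records(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">s1\n" + "A" * 10 + "\n>s2\n" + "C" * 20 + "\n")
        sc = sa.read_fasta(p)
        assert sc.total_length == 30
        assert sc.ids == ["s1", "s2"]

    def test_iupac_codes_mapped_to_n(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">s1\nACGRYT\n")
        assert sa.read_fasta(p)["s1"].seq == "ACGNNT"

    def test_empty_sequence_is_format_error(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">bad\n\n>ok\nACGT\n")
        with pytest.raises(FormatError, match="bad"):
            sa.read_fasta(p)

    @given(
        seqs=st.lists(
            st.text(alphabet="ACGTN", min_size=1, max_size=40),
            min_size=1,
            max_size=6,
        )
    )
    def test_round_trip_preserves_content_and_order(self, seqs, tmp_path_factory):
        tmp = tmp_path_factory.mktemp("fa")
        sc = sa.ScaffoldSet(
            sa.Scaffold(f"s{i}", s) for i, s in enumerate(seqs)
        )
        path = tmp / "rt.fa"
        sa.write_fasta(sc, path)
        back = sa.read_fasta(path)
        assert [x.id for x in back] == [x.id for x in sc]
        assert [x.seq for x in back] == [x.seq for x in sc]


class TestGff3:
    def _write(self, tmp_path, body: str):
        p = tmp_path / "g.gff3"
        p.write_text("##gff-version 3\n" + body)
        return p

    def _scaffolds(self, length=2000):
        return sa.ScaffoldSet([sa.Scaffold("s1", "A" * length)])

    def test_single_exon_gene(self, tmp_path):
        p = self._write(
            tmp_path,
            "s1\t.\tgene\t1\t300\t.\t+\t.\tID=g1\n"
            "s1\t.\tmRNA\t1\t300\t.\t+\t.\tID=m1;Parent=g1\n"
            "s1\t.\texon\t1\t300\t.\t+\t.\tID=e1;Parent=m1\n",
        )
        genome = sa.read_gff3(p, self._scaffolds())
        (g,) = genome.genes
        assert g.exons == ((1, 300),) and g.introns == ()

    def test_intron_length(self, tmp_path):
        p = self._write(
            tmp_path,
            "s1\t.\tgene\t1\t300\t.\t+\t.\tID=g1\n"
            "s1\t.\tmRNA\t1\t300\t.\t+\t.\tID=m1;Parent=g1\n"
            "s1\t.\texon\t1\t100\t.\t+\t.\tID=e1;Parent=m1\n"
            "s1\t.\texon\t201\t300\t.\t+\t.\tID=e2;Parent=m1\n",
        )
        (g,) = sa.read_gff3(p, self._scaffolds()).genes
        (intron,) = g.introns
        assert intron[1] - intron[0] + 1 == 100  # 201 - 100 - 1

    def test_overlapping_exons_rejected(self, tmp_path):
        p = self._write(
            tmp_path,
            "s1\t.\tgene\t1\t300\t.\t+\t.\tID=g1\n"
            "s1\t.\tmRNA\t1\t300\t.\t+\t.\tID=m1;Parent=g1\n"
            "s1\t.\texon\t1\t150\t.\t+\t.\tID=e1;Parent=m1\n"
            "s1\t.\texon\t100\t300\t.\t+\t.\tID=e2;Parent=m1\n",
        )
        with pytest.raises(CoordinateError):
            sa.read_gff3(p, self._scaffolds())

    def test_gene_past_scaffold_end_rejected(self, tmp_path):
        p = self._write(
            tmp_path,
            "s1\t.\tgene\t1\t5000\t.\t+\t.\tID=g1\n"
            "s1\t.\tmRNA\t1\t5000\t.\t+\t.\tID=m1;Parent=g1\n"
            "s1\t.\texon\t1\t5000\t.\t+\t.\tID=e1;Parent=m1\n",
        )
        with pytest.raises(CoordinateError):
            sa.read_gff3(p, self._scaffolds(2000))

    def test_unknown_scaffold_rejected(self, tmp_path):
        p = self._write(
            tmp_path,
            "sX\t.\tgene\t1\t100\t.\t+\t.\tID=g1\n"
            "sX\t.\texon\t1\t100\t.\t+\t.\tID=e1;Parent=g1\n",
        )
        with pytest.raises(UnresolvedReferenceError):
            sa.read_gff3(p, self._scaffolds())

    def test_longest_cds_transcript_is_representative(self, tmp_path):
        p = self._write(
            tmp_path,
            "s1\t.\tgene\t1\t900\t.\t+\t.\tID=g1\n"
            "s1\t.\tmRNA\t1\t900\t.\t+\t.\tID=m1;Parent=g1\n"
            "s1\t.\texon\t1\t900\t.\t+\t.\tID=e1;Parent=m1\n"
            "s1\t.\tCDS\t1\t300\t.\t+\t0\tID=c1;Parent=m1\n"
            "s1\t.\tmRNA\t1\t900\t.\t+\t.\tID=m2;Parent=g1\n"
            "s1\t.\texon\t1\t400\t.\t+\t.\tID=e2;Parent=m2\n"
            "s1\t.\texon\t500\t900\t.\t+\t.\tID=e3;Parent=m2\n"
            "s1\t.\tCDS\t1\t400\t.\t+\t0\tID=c2;Parent=m2\n"
            "s1\t.\tCDS\t500\t900\t.\t+\t0\tID=c3;Parent=m2\n",
        )
        (g,) = sa.read_gff3(p, self._scaffolds()).genes
        assert g.n_exons == 2  # m2 has the longer summed CDS

    def test_round_trip_through_writer(self, tmp_path):
        genome, _ = sa.simulate_genome(
            sa.SyntheticGenomeConfig(n_scaffolds=2, genes_per_scaffold=15, seed=11)
        )
        fa, gff = tmp_path / "g.fa", tmp_path / "g.gff3"
        sa.write_fasta(genome.scaffolds, fa)
        sa.write_gff3(genome, gff)
        back = sa.read_gff3(gff, sa.read_fasta(fa))
        assert sorted((g.id, g.strand, g.exons) for g in back.genes) == sorted(
            (g.id, g.strand, g.exons) for g in genome.genes
        )

    def test_coordinate_sanity_exons_plus_introns_equal_span(self):
        genome, _ = sa.simulate_genome(
            sa.SyntheticGenomeConfig(n_scaffolds=1, genes_per_scaffold=50, seed=2)
        )
        for g in genome.genes:
            exon_bp = sum(e - s + 1 for s, e in g.exons)
            intron_bp = sum(e - s + 1 for s, e in g.introns)
            assert exon_bp + intron_bp == g.span_length


class TestHitTable:
    def test_basic_row(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("g1\ts1\t90.0\t100\t0\t0\t1\t100\t1\t100\t1e-30\t200\n")
        (h,) = sa.read_hit_table(p)
        assert h.e_value == 1e-30 and h.bitscore == 200 and h.subject == "s1"

    def test_empty_file(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("")
        assert sa.read_hit_table(p) == []

    def test_order_preserved(self, tmp_path):
        rows = "".join(
            f"q1\ts{i}\t90\t100\t0\t0\t1\t100\t1\t100\t1e-{10 + i}\t{100 + i}\n"
            for i in range(3)
        )
        p = tmp_path / "h.tsv"
        p.write_text(rows)
        hits = sa.read_hit_table(p)
        assert [h.subject for h in hits] == ["s0", "s1", "s2"]

    def test_non_numeric_field_names_line(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(
            "q1\ts1\t90\t100\t0\t0\t1\t100\t1\t100\t1e-30\t200\n"
            "q2\ts2\t90\t100\t0\t0\t1\t100\t1\t100\tBAD\t200\n"
        )
        with pytest.raises(FormatError, match=":2"):
            sa.read_hit_table(p)

    def test_taxon_column(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("q1\ts1\t90\t100\t0\t0\t1\t100\t1\t100\t1e-30\t200\tEcoli\n")
        assert sa.read_hit_table(p)[0].subject_species == "Ecoli"


def _training_genes():
    mk = lambda gid, n_exons, **kw: gene(
        gid, "s1", "+",
        [(1 + i * 200, 100 + i * 200) for i in range(n_exons)], **kw
    )
    return [
        mk("keep", 3),
        mk("no_stop", 3, has_stop_codon=False),
        mk("two_exons", 2),
        mk("ambig", 3, utr_status="ambiguous"),
        mk("clusA_long", 4),
        mk("clusA_short", 3),
        mk("repeaty", 3),
    ]


class TestTrainingFilter:
    def test_criteria_applied_in_order(self):
        genes = _training_genes()
        kept, tally = sa.filter_training_genes(
            genes,
            cluster_map={"clusA_long": "c1", "clusA_short": "c1"},
            repeat_overlap_flags={"repeaty"},
        )
        assert {g.id for g in kept} == {"keep", "clusA_long"}
        assert tally == {
            "missing_start_or_stop": 1,
            "fewer_than_3_exons": 1,
            "ambiguous_utr": 1,
            "shorter_cluster_member": 1,
            "repeat_overlap": 1,
        }

    def test_longest_protein_kept_with_explicit_lengths(self):
        genes = _training_genes()
        kept, _ = sa.filter_training_genes(
            genes,
            cluster_map={"clusA_long": "c1", "clusA_short": "c1"},
            protein_lengths={g.id: 100 for g in genes} | {"clusA_short": 500},
        )
        ids = {g.id for g in kept}
        assert "clusA_short" in ids and "clusA_long" not in ids

    def test_order_independence(self):
        genes = _training_genes()
        kwargs = dict(
            cluster_map={"clusA_long": "c1", "clusA_short": "c1"},
            repeat_overlap_flags={"repeaty"},
        )
        kept_fwd, _ = sa.filter_training_genes(genes, **kwargs)
        kept_rev, _ = sa.filter_training_genes(genes[::-1], **kwargs)
        assert {g.id for g in kept_fwd} == {g.id for g in kept_rev}

    def test_unknown_cluster_gene_is_reference_error(self):
        with pytest.raises(UnresolvedReferenceError):
            sa.filter_training_genes(_training_genes(), cluster_map={"ghost": "c1"})


class TestNewick:
    def test_supports_and_species_parsed(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A_1,A_2)95,(B_1,B_2)40);\n")
        stree = sa.read_newick(p)
        assert set(stree.tip_labels) == {"A_1", "A_2", "B_1", "B_2"}
        assert stree.tip_species["A_1"] == "A"

    def test_out_of_range_support_rejected(self):
        with pytest.raises(FormatError):
            sa.read_newick("((A_1,A_2)150,B_1);")
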