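"""Alignment reading, column filters, gene selection and concatenation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phylosample as ps
from phylosample.alignment_io import GeneAlignment


def aln(gene_id="g", **seqs):
    return GeneAlignment.from_seqs(gene_id, seqs)


def write_fasta(path, seqs):
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


class TestReadGeneAlignments:
    def test_reads_back_simple_file(self, tmp_path):
        p = tmp_path / "g1.fasta"
        write_fasta(p, {"T1": "acgt-n", "T2": "ACGTAC"})
        (gene,) = ps.read_gene_alignments([p])
        assert gene.gene_id == "g1"
        assert gene.length == 6
        assert gene.seqs == {"T1": "ACGT-N", "T2": "ACGTAC"}  # case-normalized

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(ValueError, match="no records"):
            ps.read_gene_alignments([p])

    def test_ragged_alignment_names_file_and_record(self, tmp_path):
        p = tmp_path / "bad.fasta"
        write_fasta(p, {"T1": "ACGTAC", "T2": "ACGTA"})
        with pytest.raises(ValueError, match=r"bad\.fasta.*ragged.*T2"):
            ps.read_gene_alignments([p])

    def test_duplicate_taxon_rejected(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">T1\nACGT\n>T1\nACGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            ps.read_gene_alignments([p])


class TestGapFreeBlocks:
    def test_identity_on_gapless_alignment(self):
        a = aln(T1="ACGTACGTAC", T2="ACGTACGTAC", T3="ACGAACGTAC")
        out = ps.filter_gap_free_blocks(a, min_block_len=1, min_conserved_frac=0.0)
        assert out.seqs == a.seqs

    def test_runs_split_by_gap_columns(self):
        # gaps in columns 3-4 leave runs {0,1,2} and {5..9}
        a = aln(T1="ACG--ACGTA", T2="ACGT-ACGTA")
        out = ps.filter_gap_free_blocks(a, min_block_len=3, min_conserved_frac=0.0)
        assert out.length == 8
        assert out.seqs["T1"] == "ACG" + "ACGTA"

    def test_short_runs_dropped(self):
        a = aln(T1="AC-ACGTACGTA", T2="AC-ACGTACGTA")
        out = ps.filter_gap_free_blocks(a, min_block_len=3, min_conserved_frac=0.0)
        assert out.length == 9  # leading 2-column run removed

    def test_all_gap_columns_empty_result(self):
        a = aln(T1="----", T2="----")
        assert ps.filter_gap_free_blocks(a, 1, 0.0).length == 0

    def test_output_has_no_missing_characters(self):
        rng = np.random.default_rng(0)
        chars = np.array(list("ACGT-N?"))
        seqs = {f"T{i}": "".join(rng.choice(chars, size=200)) for i in range(6)}
        out = ps.filter_gap_free_blocks(aln(**seqs), min_block_len=2, min_conserved_frac=0.0)
        assert not out.missing_mask().any()

    def test_unconserved_runs_dropped(self):
        # 4 taxa, every column has a 2-2 tie: no majority > 50%
        a = aln(T1="AAAA", T2="AAAA", T3="CCCC", T4="CCCC")
        assert ps.filter_gap_free_blocks(a, 1, 0.5).length == 0
        # unanimous columns are conserved
        b = aln(T1="AAAA", T2="AAAA", T3="AAAA", T4="AAAA")
        assert ps.filter_gap_free_blocks(b, 1, 0.5).length == 4

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        chars = np.array(list("ACGT-"))
        seqs = {f"T{i}": "".join(rng.choice(chars, size=120)) for i in range(5)}
        once = ps.filter_gap_free_blocks(aln(**seqs), 3, 0.5)
        twice = ps.filter_gap_free_blocks(once, 3, 0.5)
        assert once.seqs == twice.seqs


class TestGapFractionFilter:
    def test_boundary_all_gap_columns_dropped_at_one(self):
        a = aln(T1="A-C-", T2="A--C")
        out = ps.filter_columns_by_gap_fraction(a, 1.0)
        # only the all-gap column (index 3? none here) ... columns with frac<1 kept
        assert out.length == 3

    def test_exactly_half_gaps_dropped(self):
        a = aln(T1="A", T2="-", T3="C", T4="-")
        assert ps.filter_columns_by_gap_fraction(a, 0.5).length == 0

    def test_hand_counted_column_selection(self):
        # per-column gap counts (0,1,2,3,0,4) over 4 taxa, max 0.5 -> cols 0,1,4
        cols = ["AAAA", "AAA-", "AA--", "A---", "CCCC", "----"]
        seqs = {f"T{i}": "".join(col[i] for col in cols) for i in range(4)}
        out = ps.filter_columns_by_gap_fraction(aln(**seqs), 0.5)
        assert out.length == 3
        assert out.seqs["T0"] == "AAC"

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.sampled_from("ACGT-N?"), min_size=8, max_size=40),
           st.floats(min_value=0.0, max_value=1.0))
    def test_idempotent_property(self, columns, max_gap):
        # two-taxon alignment built from a random character stream
        half = len(columns) // 2
        a = aln(T1="".join(columns[:half]), T2="".join(columns[half : 2 * half]))
        once = ps.filter_columns_by_gap_fraction(a, max_gap)
        twice = ps.filter_columns_by_gap_fraction(once, max_gap)
        assert once.seqs == twice.seqs


class TestSelectGenes:
    def test_strictly_longer_than_threshold(self, rng):
        genes = [
            aln("a", T1="A" * 999, T2="A" * 999),
            aln("b", T1="A" * 1000, T2="A" * 1000),
            aln("c", T1="A" * 1001, T2="A" * 1001),
        ]
        assert [g.gene_id for g in ps.select_genes(genes, 1000)] == ["c"]

    def test_identity_with_zero_threshold(self):
        genes = [aln("a", T1="ACGT"), aln("b", T1="AC")]
        assert ps.select_genes(genes, 0) == genes

    def test_taxon_membership_required(self):
        genes = [aln("a", T1="ACGT", T2="ACGT"), aln("b", T2="ACGT")]
        assert [g.gene_id for g in ps.select_genes(genes, 0, require_taxa={"T1"})] == ["a"]


class TestNoMissingDataset:
    def test_already_complete_unchanged(self):
        genes = [aln("a", T1="AC", T2="AC"), aln("b", T1="GT", T2="GT")]
        out, taxa = ps.build_no_missing_dataset(genes, {"T1", "T2"})
        assert taxa == ["T1", "T2"]
        assert len(out) == 2

    def test_sparse_taxon_dropped(self):
        genes = [
            aln("a", T1="AC", T2="AC"),
            aln("b", T1="GT", T2="GT"),
            aln("c", T1="AA", T2="AA", T3="AA"),
        ]
        out, taxa = ps.build_no_missing_dataset(genes, {"T1", "T2", "T3"})
        assert taxa == ["T1", "T2"]
        assert len(out) == 3

    def test_protected_taxon_never_removed(self):
        genes = [
            aln("a", T1="AC", T2="AC"),
            aln("b", T1="GT", T2="GT"),
            aln("c", T1="AA", T2="AA", T3="AA"),
        ]
        out, taxa = ps.build_no_missing_dataset(genes, {"T1", "T2", "T3"},
                                                protected_taxa={"T3"})
        assert taxa == ["T1", "T2", "T3"]
        assert [g.gene_id for g in out] == ["c"]

    def test_protected_taxon_absent_everywhere_rejected(self):
        genes = [aln("a", T1="AC")]
        with pytest.raises(ValueError, match="absent from every gene"):
            ps.build_no_missing_dataset(genes, {"T1", "TX"}, protected_taxa={"TX"})

    def test_output_has_zero_missing_entries(self, small_fixture):
        genes = small_fixture.genes
        out, taxa = ps.build_no_missing_dataset(genes, small_fixture.taxa)
        assert out, "greedy procedure should recover at least one complete gene"
        for g in out:
            assert g.taxa == taxa


class TestConcatenation:
    def test_lengths_additive_and_partitions_half_open(self):
        genes = [aln("g1", A="ACG", B="ACG"), aln("g2", A="TTTT", B="TTTT")]
        bundle = ps.concatenate_supermatrix(genes, ["A", "B"])
        assert bundle.length == 7
        assert [(p.gene_id, p.start, p.end) for p in bundle.partitions] == [
            ("g1", 0, 3), ("g2", 3, 7)]

    def test_absent_taxon_padded(self):
        genes = [aln("g1", A="ACG", B="ACG"), aln("g2", A="TTTT")]
        bundle = ps.concatenate_supermatrix(genes, ["A", "B"], missing_char="?")
        assert bundle.matrix.seqs["B"] == "ACG" + "????"

    def test_undeclared_taxon_rejected(self):
        genes = [aln("g1", A="ACG", B="ACG")]
        with pytest.raises(ValueError, match="universe"):
            ps.concatenate_supermatrix(genes, ["A"])

    def test_slicing_recovers_gene_rows(self, small_fixture):
        genes = small_fixture.genes[:10]
        bundle = ps.concatenate_supermatrix(genes, small_fixture.taxa)
        for gene in genes:
            piece = bundle.gene_slice(gene.gene_id)
            for taxon in gene.taxa:
                assert piece.sequence(taxon) == gene.sequence(taxon)


class TestSupermatrixIO:
    def test_round_trip(self, tmp_path):
        genes = [aln("g1", A="ACG", B="AC-"), aln("g2", A="TTTT")]
        bundle = ps.concatenate_supermatrix(genes, ["A", "B"])
        ps.write_supermatrix(bundle, tmp_path / "sm.fasta", tmp_path / "sm.part")
        back = ps.read_supermatrix(tmp_path / "sm.fasta", tmp_path / "sm.part")
        assert back.matrix.seqs == bundle.matrix.seqs
        assert [(p.gene_id, p.start, p.end) for p in back.partitions] == [
            (p.gene_id, p.start, p.end) for p in bundle.partitions]

    def test_partition_line_is_one_based_inclusive(self, tmp_path):
        genes = [aln("g1", A="ACG", B="ACG")]
        bundle = ps.concatenate_supermatrix(genes, ["A", "B"])
        ps.write_supermatrix(bundle, tmp_path / "sm.fasta", tmp_path / "sm.part")
        assert (tmp_path / "sm.part").read_text() == "DNA, g1 = 1-3\n"

    def test_empty_bundle_rejected(self, tmp_path):
        bundle = ps.SupermatrixBundle(
            GeneAlignment("supermatrix", [], np.empty((0, 0), dtype=np.uint8)), [])
        with pytest.raises(ValueError, match="empty"):
            ps.write_supermatrix(bundle, tmp_path / "a", tmp_path / "b")
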