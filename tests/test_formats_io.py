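import gzip

import pytest

from sbcis.formats_io import (
    AnnotatedSite, BarcodeSpec, FormatError, GeneTranscript, Genome,
    SequenceRead, parse_annotation_table, parse_barcode_table, parse_refflat,
    read_sequences, write_annotation_table, write_barcode_table, write_refflat,
)


class TestSequenceRead:
    def test_invariants(self):
        with pytest.raises(FormatError):
            SequenceRead("r", "")
        with pytest.raises(FormatError):
            SequenceRead("r", "ACGX")
        with pytest.raises(FormatError):
            SequenceRead("r", "ACGT", quality="II")
        assert SequenceRead("r", "ACGTN", quality="IIIII").sequence == "ACGTN"


class TestReadSequences:
    def test_fasta_in_order(self, tmp_path):
        path = tmp_path / "in.fa"
        path.write_text(">r1\nACGT\n>r2\nTTAA\n")
        reads = list(read_sequences(path))
        assert [(r.read_id, r.sequence) for r in reads] == [("r1", "ACGT"), ("r2", "TTAA")]

    def test_empty_file_yields_nothing(self, tmp_path):
        path = tmp_path / "empty.fa"
        path.write_text("")
        assert list(read_sequences(path)) == []

    def test_gzip_fastq(self, tmp_path):
        path = tmp_path / "in.fastq.gz"
        with gzip.open(path, "wt") as fh:
            fh.write("@r1\nACGT\n+\nIIII\n")
        (read,) = list(read_sequences(path))
        assert read.sequence == "ACGT" and read.quality == "IIII"

    def test_mismatched_quality_length_errors(self, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@r1\nACGT\n+\nII\n")
        with pytest.raises(FormatError):
            list(read_sequences(path))

    def test_streaming_is_lazy(self, tmp_path):
        path = tmp_path / "many.fa"
        with open(path, "wt") as fh:
            for i in range(5000):
                fh.write(f">r{i}\nACGTACGT\n")
        stream = read_sequences(path)
        assert next(stream).read_id == "r0"  # consumable without full load
        assert sum(1 for _ in stream) == 4999


class TestBarcodeTable:
    HEADER = "barcode\ttumor_id\tir_end\tenzyme\texpected_flank\n"

    def test_four_row_table(self, tmp_path):
        path = tmp_path / "bc.tsv"
        rows = [
            ("AAAAAA", "T1", "IRL", "AluI"), ("CCCCCC", "T1", "IRR", "AluI"),
            ("GGGGGG", "T1", "IRL", "NlaIII"), ("TTTTTT", "T1", "IRR", "NlaIII"),
        ]
        path.write_text(self.HEADER + "".join(
            f"{b}\t{t}\t{e}\t{z}\tTGTATGTA\n" for b, t, e, z in rows))
        specs = parse_barcode_table(path)
        assert len(specs) == 4
        assert {s.library for s in specs} == {
            ("AluI", "IRL"), ("AluI", "IRR"), ("NlaIII", "IRL"), ("NlaIII", "IRR")}

    def test_ten_base_barcode_rejected(self, tmp_path):
        path = tmp_path / "bc.tsv"
        path.write_text(self.HEADER + "AAAAAAAAAA\tT1\tIRL\tAluI\tTGTA\n")
        with pytest.raises(FormatError, match="6"):
            parse_barcode_table(path)

    def test_duplicate_barcode_rejected(self, tmp_path):
        path = tmp_path / "bc.tsv"
        path.write_text(self.HEADER
                        + "AAAAAA\tT1\tIRL\tAluI\tTGTA\n"
                        + "AAAAAA\tT2\tIRL\tAluI\tTGTA\n")
        with pytest.raises(FormatError, match="duplicate"):
            parse_barcode_table(path)

    def test_round_trip(self, tmp_path):
        specs = [BarcodeSpec("ACACAC", "T9", "IRR", "NlaIII", "TGTATG")]
        path = tmp_path / "bc.tsv"
        write_barcode_table(specs, path)
        assert parse_barcode_table(path) == specs


class TestRefFlat:
    def test_single_exon_row(self, tmp_path):
        path = tmp_path / "rf.txt"
        path.write_text("GeneA\tNM_1\tchr1\t+\t100\t500\t100\t500\t1\t100,\t500,\n")
        (tx,) = parse_refflat(path)
        assert tx.gene_name == "GeneA" and tx.exon_starts == (100,)

    def test_two_transcripts_share_gene(self, tmp_path):
        path = tmp_path / "rf.txt"
        path.write_text(
            "GeneA\tNM_1\tchr1\t+\t100\t500\t100\t500\t1\t100,\t500,\n"
            "GeneA\tNM_2\tchr1\t+\t300\t900\t300\t900\t1\t300,\t900,\n")
        txs = parse_refflat(path)
        assert len(txs) == 2 and {t.gene_name for t in txs} == {"GeneA"}

    def test_wrong_column_count_errors(self, tmp_path):
        path = tmp_path / "rf.txt"
        path.write_text("GeneA\tNM_1\tchr1\t+\t100\t500\n")
        with pytest.raises(FormatError, match="11 columns"):
            parse_refflat(path)

    def test_exon_list_mismatch_errors(self, tmp_path):
        path = tmp_path / "rf.txt"
        path.write_text("GeneA\tNM_1\tchr1\t+\t100\t500\t100\t500\t2\t100,\t200,400,\n")
        with pytest.raises(FormatError):
            parse_refflat(path)

    def test_round_trip(self, tmp_path):
        tx = GeneTranscript("GeneB", "NM_9", "chr2", "-", 10, 400, (10, 300), (100, 400))
        path = tmp_path / "rf.txt"
        write_refflat([tx], path)
        assert parse_refflat(path) == [tx]


class TestAnnotationTable:
    SITE = AnnotatedSite("T1", "GeneA", "intron", "disrupting", 0, "chr1",
                         41, 12.5, "sense")

    def test_nine_columns_and_one_based_address(self, tmp_path):
        path = tmp_path / "ann.tsv"
        write_annotation_table([self.SITE], path)
        lines = path.read_text().splitlines()
        assert len(lines[0].split("\t")) == 9
        assert lines[1].split("\t")[6] == "42"  # 0-based 41 -> 1-based 42

    def test_empty_writes_header_only(self, tmp_path):
        path = tmp_path / "ann.tsv"
        write_annotation_table([], path)
        assert len(path.read_text().splitlines()) == 1

    def test_round_trip(self, tmp_path):
        path = tmp_path / "ann.tsv"
        write_annotation_table([self.SITE], path)
        assert parse_annotation_table(path) == [self.SITE]


class TestSamImport:
    def test_top_two_hits_ordered_and_ta_flagged(self, tmp_path, toy_genome):
        from sbcis.formats_io import read_sam_alignments

        # chr2 = CCCC TA GGGGGGGG TA AAAA; forward hit at the TA (pos 4),
        # secondary hit elsewhere with more mismatches
        sam = tmp_path / "hits.sam"
        sam.write_text(
            "@HD\tVN:1.6\n"
            "@SQ\tSN:chr1\tLN:86\n"
            "@SQ\tSN:chr2\tLN:20\n"
            "r1\t0\tchr2\t5\t30\t10M\t*\t0\t0\tTAGGGGGGGG\t*\tNM:i:0\n"
            "r1\t256\tchr2\t1\t3\t10M\t*\t0\t0\tTAGGGGGGGG\t*\tNM:i:4\n"
            "r2\t16\tchr2\t1\t30\t6M\t*\t0\t0\tTAGGGG\t*\tNM:i:1\n"
        )
        hits = read_sam_alignments(sam, toy_genome)
        best, second = hits["r1"]
        assert (best.chrom, best.position, best.strand, best.mismatches) == \
            ("chr2", 4, "+", 0)
        assert best.starts_with_TA
        assert second.mismatches == 4
        # reverse-strand junction: TA must sit at the alignment end
        (r2,) = hits["r2"]
        assert r2.strand == "-" and r2.starts_with_TA


class TestGenome:
    def test_fasta_round_trip(self, tmp_path, toy_genome):
        path = tmp_path / "g.fa"
        toy_genome.to_fasta(path)
        again = Genome.from_fasta(path)
        assert again.sequences == toy_genome.sequences

    def test_has_ta(self, toy_genome):
        assert toy_genome.has_ta("chr2", 4)
        assert not toy_genome.has_ta("chr2", 0)
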