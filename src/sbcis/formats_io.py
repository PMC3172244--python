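"""Readers and writers for the external formats the pipeline touches.

Covers FASTA/FASTQ reads (optionally gzipped), the barcode metadata table,
UCSC refFlat gene models, a minimal SAM import (only the fields the
alignment filter needs), and the 9-column per-insertion annotation table.

All coordinates held in memory are 0-based, half-open.  The ``address``
column written to annotation tables is the 1-based position of the T of the
TA dinucleotide, matching genome-browser convention.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd
from Bio import SeqIO

DNA_ALPHABET = set("ACGTN")

IR_ENDS = ("IRL", "IRR")
ENZYMES = ("AluI", "NlaIII")

#: Restriction-enzyme recognition sequences.  Both are reverse-complement
#: palindromes, so a forward-strand motif scan is complete.
ENZYME_MOTIFS = {"AluI": "AGCT", "NlaIII": "CATG"}

ANNOTATION_COLUMNS = [
    "tumor_id",
    "gene_name",
    "gene_region_hit",
    "predicted_effect",
    "distance_from_gene",
    "chromosome",
    "address",
    "percent_of_reads",
    "orientation_vs_gene",
]


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass(frozen=True)
class SequenceRead:
    """A single sequencing read (amplicon: barcode + flank + junction)."""

    read_id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"read {self.read_id!r}: empty sequence")
        if not set(self.sequence) <= DNA_ALPHABET:
            bad = set(self.sequence) - DNA_ALPHABET
            raise FormatError(f"read {self.read_id!r}: non-DNA characters {bad}")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise FormatError(
                f"read {self.read_id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class BarcodeSpec:
    """One LM-PCR library: a (tumor, transposon end, enzyme) barcode."""

    barcode: str
    tumor_id: str
    ir_end: str
    enzyme: str
    expected_flank: str

    def __post_init__(self) -> None:
        if len(self.barcode) != 6:
            raise FormatError(
                f"barcode {self.barcode!r} has length {len(self.barcode)}; "
                "exactly 6 bases are required"
            )
        if self.ir_end not in IR_ENDS:
            raise FormatError(f"ir_end must be one of {IR_ENDS}, got {self.ir_end!r}")
        if self.enzyme not in ENZYMES:
            raise FormatError(f"enzyme must be one of {ENZYMES}, got {self.enzyme!r}")
        if not self.expected_flank:
            raise FormatError("expected_flank must be non-empty")

    @property
    def library(self) -> tuple[str, str]:
        return (self.enzyme, self.ir_end)

    @property
    def label(self) -> str:
        return f"{self.tumor_id}_{self.enzyme}_{self.ir_end}"


@dataclass(frozen=True)
class GeneTranscript:
    """One refFlat row: a transcript of a named gene."""

    gene_name: str
    transcript_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"bad strand {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise FormatError(
                f"{self.transcript_id}: tx_start {self.tx_start} >= tx_end {self.tx_end}"
            )
        if len(self.exon_starts) != len(self.exon_ends):
            raise FormatError(
                f"{self.transcript_id}: exonStarts/exonEnds length mismatch"
            )
        prev_end = self.tx_start
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not (self.tx_start <= s < e <= self.tx_end) or s < prev_end:
                raise FormatError(
                    f"{self.transcript_id}: exon [{s},{e}) invalid or out of order"
                )
            prev_end = e


@dataclass(frozen=True)
class AlignmentRecord:
    """One candidate placement of a trimmed genomic segment."""

    read_id: str
    chrom: str
    position: int
    strand: str
    aligned_length: int
    mismatches: int
    starts_with_TA: bool

    def __post_init__(self) -> None:
        if self.position < 0:
            raise FormatError(f"{self.read_id}: negative position")
        if self.mismatches > self.aligned_length:
            raise FormatError(f"{self.read_id}: mismatches exceed aligned length")

    @property
    def percent_identity(self) -> float:
        return (self.aligned_length - self.mismatches) / self.aligned_length * 100.0


@dataclass
class AnnotatedSite:
    """A clonal insertion site with its gene annotation (one output row)."""

    tumor_id: str
    gene_name: str
    gene_region_hit: str
    predicted_effect: str
    distance_from_gene: int
    chromosome: str
    ta_position: int  # 0-based; written as 1-based "address"
    percent_of_reads: float
    orientation_vs_gene: str


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_sequences(path: str | Path, format: str | None = None) -> Iterator[SequenceRead]:
    """Stream reads from a FASTA or FASTQ file (gzip transparently supported).

    The format is inferred from the file name when not given.  Records are
    yielded lazily in file order; malformed records raise :class:`FormatError`.
    """
    path = Path(path)
    if format is None:
        stem = path.name[:-3] if path.name.endswith(".gz") else path.name
        if stem.endswith((".fq", ".fastq")):
            format = "FASTQ"
        else:
            format = "FASTA"
    format = format.upper()
    if format not in ("FASTA", "FASTQ"):
        raise ValueError(f"unsupported format {format!r}")
    with _open_text(path) as handle:
        try:
            for rec in SeqIO.parse(handle, format.lower()):
                qual = None
                if format == "FASTQ":
                    phred = rec.letter_annotations["phred_quality"]
                    qual = "".join(chr(q + 33) for q in phred)
                yield SequenceRead(rec.id, str(rec.seq).upper(), qual)
        except ValueError as exc:  # Biopython's parse error
            raise FormatError(f"{path}: {exc}") from exc


def write_fasta(reads: Sequence[SequenceRead], path: str | Path) -> None:
    with open(path, "wt") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.sequence}\n")


BARCODE_COLUMNS = ["barcode", "tumor_id", "ir_end", "enzyme", "expected_flank"]


def parse_barcode_table(path: str | Path) -> list[BarcodeSpec]:
    """Parse the tab-delimited barcode metadata table.

    Requires the header columns ``barcode, tumor_id, ir_end, enzyme,
    expected_flank``; rejects duplicate barcodes and duplicate
    (tumor, end, enzyme) combinations.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = set(BARCODE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    specs = [
        BarcodeSpec(
            barcode=row.barcode.upper(),
            tumor_id=row.tumor_id,
            ir_end=row.ir_end,
            enzyme=row.enzyme,
            expected_flank=row.expected_flank.upper(),
        )
        for row in df.itertuples()
    ]
    seen: dict[str, str] = {}
    for s in specs:
        if s.barcode in seen:
            raise FormatError(f"duplicate barcode {s.barcode!r}")
        seen[s.barcode] = s.tumor_id
    combos = {(s.tumor_id, s.ir_end, s.enzyme) for s in specs}
    if len(combos) != len(specs):
        raise FormatError("duplicate (tumor_id, ir_end, enzyme) combination")
    return specs


def write_barcode_table(specs: Sequence[BarcodeSpec], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "barcode": s.barcode,
                "tumor_id": s.tumor_id,
                "ir_end": s.ir_end,
                "enzyme": s.enzyme,
                "expected_flank": s.expected_flank,
            }
            for s in specs
        ],
        columns=BARCODE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def parse_refflat(path: str | Path) -> list[GeneTranscript]:
    """Parse a UCSC refFlat table (11 tab-delimited columns, 0-based half-open).

    Columns: geneName, name, chrom, strand, txStart, txEnd, cdsStart, cdsEnd,
    exonCount, exonStarts, exonEnds.  Promoter extension is NOT applied here;
    the parser stays format-faithful.
    """
    transcripts: list[GeneTranscript] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 11:
                raise FormatError(
                    f"{path}:{lineno}: expected 11 columns, found {len(fields)}"
                )
            (gene, name, chrom, strand, tx_start, tx_end,
             _cds_s, _cds_e, exon_count, exon_starts, exon_ends) = fields
            starts = tuple(int(x) for x in exon_starts.rstrip(",").split(",") if x)
            ends = tuple(int(x) for x in exon_ends.rstrip(",").split(",") if x)
            if len(starts) != int(exon_count) or len(ends) != int(exon_count):
                raise FormatError(
                    f"{path}:{lineno}: exon list length != exonCount"
                )
            try:
                transcripts.append(
                    GeneTranscript(gene, name, chrom, strand,
                                   int(tx_start), int(tx_end), starts, ends)
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return transcripts


def write_refflat(transcripts: Sequence[GeneTranscript], path: str | Path) -> None:
    with open(path, "wt") as fh:
        for t in transcripts:
            starts = ",".join(str(s) for s in t.exon_starts) + ","
            ends = ",".join(str(e) for e in t.exon_ends) + ","
            fh.write(
                "\t".join(
                    [t.gene_name, t.transcript_id, t.chrom, t.strand,
                     str(t.tx_start), str(t.tx_end), str(t.tx_start),
                     str(t.tx_end), str(len(t.exon_starts)), starts, ends]
                )
                + "\n"
            )


def write_annotation_table(sites: Sequence[AnnotatedSite], path: str | Path) -> None:
    """Write the 9-column per-insertion annotation table (tab-delimited)."""
    rows = [
        {
            "tumor_id": s.tumor_id,
            "gene_name": s.gene_name,
            "gene_region_hit": s.gene_region_hit,
            "predicted_effect": s.predicted_effect,
            "distance_from_gene": s.distance_from_gene,
            "chromosome": s.chromosome,
            "address": s.ta_position + 1,  # 1-based T of the TA
            "percent_of_reads": s.percent_of_reads,
            "orientation_vs_gene": s.orientation_vs_gene,
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def parse_annotation_table(path: str | Path) -> list[AnnotatedSite]:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ANNOTATION_COLUMNS:
        raise FormatError(f"{path}: unexpected columns {list(df.columns)}")
    return [
        AnnotatedSite(
            tumor_id=str(r.tumor_id),
            gene_name=str(r.gene_name),
            gene_region_hit=str(r.gene_region_hit),
            predicted_effect=str(r.predicted_effect),
            distance_from_gene=int(r.distance_from_gene),
            chromosome=str(r.chromosome),
            ta_position=int(r.address) - 1,
            percent_of_reads=float(r.percent_of_reads),
            orientation_vs_gene=str(r.orientation_vs_gene),
        )
        for r in df.itertuples()
    ]


class Genome:
    """An in-memory reference genome (uppercase sequences keyed by chromosome)."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences = {c: s.upper() for c, s in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        with _open_text(path) as fh:
            seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}
        if not seqs:
            raise FormatError(f"{path}: no sequences found")
        return cls(seqs)

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "wt") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def has_ta(self, chrom: str, position: int) -> bool:
        seq = self.sequences[chrom]
        return seq[position : position + 2] == "TA"


def read_sam_alignments(path: str | Path, genome: Genome) -> dict[str, list[AlignmentRecord]]:
    """Import a SAM file as per-read candidate alignments (top hits).

    Only the fields the downstream filter needs are kept: read id, chromosome,
    0-based position, strand (from FLAG 0x10), aligned length (sequence
    length) and the NM-tag mismatch count.  ``starts_with_TA`` is evaluated
    against the supplied reference at the junction end of the alignment.
    Candidates per read are ordered best-first by mismatch count.
    """
    import pysam

    by_read: dict[str, list[AlignmentRecord]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            strand = "-" if aln.is_reverse else "+"
            length = aln.query_length or len(aln.query_sequence or "")
            if length == 0:
                continue
            try:
                nm = int(aln.get_tag("NM"))
            except KeyError:
                nm = 0
            chrom = aln.reference_name
            pos = aln.reference_start
            if strand == "+":
                ta = genome.has_ta(chrom, pos)
            else:
                ta = genome.has_ta(chrom, pos + length - 2)
            rec = AlignmentRecord(aln.query_name, chrom, pos, strand, length, nm, ta)
            by_read.setdefault(aln.query_name, []).append(rec)
    for recs in by_read.values():
        recs.sort(key=lambda r: (r.mismatches, r.chrom, r.position, r.strand))
    return by_read
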