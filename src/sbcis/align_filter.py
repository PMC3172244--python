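"""Post-alignment filtering and per-library insertion-site aggregation.

The external aligner (or the built-in exhaustive toy aligner) reports the
top two candidate placements per trimmed read.  The filter retains a read
only when the best placement is at least 90% identical, begins on a perfect
TA, beats the second-best placement by at least 5 percent-identity points,
and carries at most 2 mismatches.  Accepted reads collapsing to the same
(chromosome, TA position, transposon orientation) are summed into insertion
sites with their percent-of-library-reads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .formats_io import AlignmentRecord, Genome
from .demux_trim import TrimmedRead

MIN_PERCENT_IDENTITY = 90.0
MIN_MARGIN = 5.0
MAX_MISMATCHES = 2

REJECT_IDENTITY = "identity_below_90"
REJECT_NO_TA = "no_TA_at_alignment_start"
REJECT_MARGIN = "margin_below_5"
REJECT_MISMATCHES = "more_than_2_mismatches"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class InsertionSite:
    """A mapped TA-dinucleotide integration aggregated over reads."""

    tumor_id: str
    chrom: str
    ta_position: int  # 0-based position of the T on the forward strand
    orientation: str  # transposon orientation relative to the forward strand
    library: tuple[str, str]  # (enzyme, ir_end)
    read_count: int
    percent_of_reads: float

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.ta_position, self.orientation)


@dataclass
class LibraryProfile:
    """All insertion sites observed in one (tumor, enzyme, IR-end) library."""

    tumor_id: str
    library: tuple[str, str]
    sites: list[InsertionSite]
    total_mapped_reads: int

    def recompute_percentages(self) -> None:
        total = self.total_mapped_reads
        self.sites = [
            replace(s, percent_of_reads=(s.read_count / total * 100.0 if total else 0.0))
            for s in self.sites
        ]


def filter_alignments(
    best: AlignmentRecord,
    second: AlignmentRecord | None = None,
    min_identity: float = MIN_PERCENT_IDENTITY,
    min_margin: float = MIN_MARGIN,
    max_mismatches: int = MAX_MISMATCHES,
) -> tuple[bool, str | None]:
    """Apply the four retention rules to the top-two placements of a read.

    Returns ``(accepted, reason)`` where ``reason`` names the first failed
    criterion (identity, TA, margin, mismatch cap) or is None on acceptance.
    The margin rule is vacuously satisfied when no second hit exists.
    """
    if best.percent_identity < min_identity:
        return False, REJECT_IDENTITY
    if not best.starts_with_TA:
        return False, REJECT_NO_TA
    if second is not None and best.percent_identity - second.percent_identity < min_margin:
        return False, REJECT_MARGIN
    if best.mismatches > max_mismatches:
        return False, REJECT_MISMATCHES
    return True, None


def toy_align(
    segment: str,
    genome: Genome,
    read_id: str = "read",
    max_mismatches: int = 3,
) -> tuple[AlignmentRecord | None, AlignmentRecord | None]:
    """Exhaustive end-to-end alignment of a segment against a small genome.

    Scans every placement on both strands of every chromosome, counting
    substitutions (no gaps), and returns the two lowest-mismatch placements
    with at most ``max_mismatches`` mismatches — emulating an aligner asked
    for its top two hits.  Ties break deterministically by
    (mismatches, chrom, position, strand).  Intended for test-scale genomes.
    """
    L = len(segment)
    seg_arr = np.frombuffer(segment.encode(), dtype=np.uint8)
    candidates: list[tuple[int, str, int, str]] = []
    for chrom in sorted(genome.sequences):
        seq = genome.sequences[chrom]
        if len(seq) < L:
            continue
        ref = np.frombuffer(seq.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(ref, L)
        for strand, probe in (("+", seg_arr),
                              ("-", np.frombuffer(revcomp(segment).encode(), dtype=np.uint8))):
            mism = (windows != probe).sum(axis=1)
            for pos in np.nonzero(mism <= max_mismatches)[0]:
                candidates.append((int(mism[pos]), chrom, int(pos), strand))
    candidates.sort()
    records = []
    for mismatches, chrom, pos, strand in candidates[:2]:
        if strand == "+":
            ta = genome.has_ta(chrom, pos)
        else:
            ta = genome.has_ta(chrom, pos + L - 2)
        records.append(
            AlignmentRecord(read_id, chrom, pos, strand, L, mismatches, ta)
        )
    best = records[0] if records else None
    second = records[1] if len(records) > 1 else None
    return best, second


def junction_ta_position(alignment: AlignmentRecord) -> int:
    """Genomic position of the T of the junction TA for either strand.

    The read begins with the TA, so on the forward strand the TA is at the
    alignment start; on the reverse strand it is the last two reference
    bases (TA is its own reverse complement), giving both strands one
    canonical address.
    """
    if alignment.strand == "+":
        return alignment.position
    return alignment.position + alignment.aligned_length - 2


def transposon_orientation(strand: str, ir_end: str) -> str:
    """Transposon orientation on the forward strand from read strand and end.

    An IRR junction read extends in the transposon's own 5'->3' direction,
    so a forward-strand IRR read (or a reverse-strand IRL read) implies a
    plus-orientation transposon.
    """
    if ir_end == "IRR":
        return strand
    return "-" if strand == "+" else "+"


@dataclass(frozen=True)
class AcceptedRead:
    """A read that survived the alignment filter, reduced to its site."""

    read_id: str
    tumor_id: str
    library: tuple[str, str]
    chrom: str
    ta_position: int
    orientation: str


def filter_read(
    trimmed: TrimmedRead,
    best: AlignmentRecord | None,
    second: AlignmentRecord | None,
    **filter_kwargs,
) -> AcceptedRead | None:
    if best is None:
        return None
    accepted, _reason = filter_alignments(best, second, **filter_kwargs)
    if not accepted:
        return None
    return AcceptedRead(
        read_id=trimmed.read_id,
        tumor_id=trimmed.tumor_id,
        library=(trimmed.enzyme, trimmed.ir_end),
        chrom=best.chrom,
        ta_position=junction_ta_position(best),
        orientation=transposon_orientation(best.strand, trimmed.ir_end),
    )


def aggregate_sites(
    accepted: Iterable[AcceptedRead],
    genome: Genome,
    tumor_id: str,
    library: tuple[str, str],
) -> LibraryProfile:
    """Collapse accepted reads into unique insertion sites for one library.

    Reads sharing (chrom, ta_position, orientation) sum into one site;
    percent_of_reads is relative to the library's total mapped reads.  A
    site whose computed position is not a TA in the reference indicates a
    coordinate bug or reference mismatch and is dropped with a warning.
    """
    counts: dict[tuple[str, int, str], int] = {}
    for read in accepted:
        counts[(read.chrom, read.ta_position, read.orientation)] = (
            counts.get((read.chrom, read.ta_position, read.orientation), 0) + 1
        )
    total = sum(counts.values())
    sites: list[InsertionSite] = []
    for (chrom, pos, orient), n in sorted(counts.items()):
        if not genome.has_ta(chrom, pos):
            warnings.warn(
                f"site {chrom}:{pos} has no TA in the reference; dropped",
                stacklevel=2,
            )
            total -= n
            continue
        sites.append(
            InsertionSite(tumor_id, chrom, pos, orient, library, n, 0.0)
        )
    profile = LibraryProfile(tumor_id, library, sites, total)
    profile.recompute_percentages()
    return profile


SITE_TABLE_COLUMNS = [
    "tumor_id", "enzyme", "ir_end", "chrom", "address",
    "orientation", "read_count", "percent_of_reads",
]


def profiles_to_table(profiles: Sequence[LibraryProfile]):
    """Flatten library profiles into the sites table (address is 1-based)."""
    import pandas as pd

    rows = [
        {
            "tumor_id": p.tumor_id,
            "enzyme": p.library[0],
            "ir_end": p.library[1],
            "chrom": s.chrom,
            "address": s.ta_position + 1,
            "orientation": s.orientation,
            "read_count": s.read_count,
            "percent_of_reads": s.percent_of_reads,
        }
        for p in profiles
        for s in p.sites
    ]
    return pd.DataFrame(rows, columns=SITE_TABLE_COLUMNS)


def table_to_profiles(df) -> list[LibraryProfile]:
    """Rebuild library profiles from a sites table."""
    profiles: list[LibraryProfile] = []
    for (tumor, enzyme, ir_end), group in df.groupby(
        ["tumor_id", "enzyme", "ir_end"], sort=True
    ):
        sites = [
            InsertionSite(
                tumor_id=str(tumor),
                chrom=str(r.chrom),
                ta_position=int(r.address) - 1,
                orientation=str(r.orientation),
                library=(str(enzyme), str(ir_end)),
                read_count=int(r.read_count),
                percent_of_reads=float(r.percent_of_reads),
            )
            for r in group.itertuples()
        ]
        profiles.append(
            LibraryProfile(str(tumor), (str(enzyme), str(ir_end)), sites,
                           sum(s.read_count for s in sites))
        )
    for p in profiles:
        p.recompute_percentages()
    return profiles
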