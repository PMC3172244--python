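"""Barcode demultiplexing, transposon-flank trimming and TA verification.

Each LM-PCR amplicon read is structured as::

    [6-base barcode][transposon end (flank) sequence][TA + genomic junction]

Demultiplexing matches the first six bases exactly against the barcode
table.  The flank is then located by exact-position comparison with a
substitution budget (default 2 mismatches, no indels) — the amplicon
structure is fixed, so full local alignment is unnecessary.  Everything
3' of the flank is the genomic segment; it must begin with the TA
dinucleotide that Sleeping Beauty requires at its integration site and be
long enough to map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .formats_io import BarcodeSpec, SequenceRead

BARCODE_LENGTH = 6
DEFAULT_MAX_FLANK_MISMATCHES = 2
DEFAULT_MIN_SEGMENT_LENGTH = 20

REJECT_FLANK_NOT_FOUND = "flank_not_found"
REJECT_NO_TA = "no_ta_junction"
REJECT_TOO_SHORT = "segment_too_short"


@dataclass(frozen=True)
class TrimmedRead:
    """A demultiplexed read reduced to its genomic junction segment."""

    read_id: str
    tumor_id: str
    ir_end: str
    enzyme: str
    genomic_segment: str


@dataclass(frozen=True)
class RejectedRead:
    read_id: str
    reason: str


def demultiplex(
    reads: Iterable[SequenceRead], barcode_specs: Sequence[BarcodeSpec]
) -> tuple[dict[BarcodeSpec, list[SequenceRead]], list[SequenceRead]]:
    """Assign each read to the barcode its first 6 bases exactly match.

    Returns (assignments, unassigned).  Every input read appears exactly
    once across the outputs.  The barcode prefix is retained on the read;
    trimming happens in :func:`find_and_trim_flank`.
    """
    by_barcode = {spec.barcode: spec for spec in barcode_specs}
    if len(by_barcode) != len(barcode_specs):
        raise ValueError("duplicate barcodes in specs")
    assigned: dict[BarcodeSpec, list[SequenceRead]] = {s: [] for s in barcode_specs}
    unassigned: list[SequenceRead] = []
    for read in reads:
        spec = by_barcode.get(read.sequence[:BARCODE_LENGTH])
        if spec is None:
            unassigned.append(read)
        else:
            assigned[spec].append(read)
    return assigned, unassigned


def _hamming_within(a: str, b: str, budget: int) -> int | None:
    """Mismatch count between equal-length strings, or None if > budget."""
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > budget:
                return None
    return mism


def find_and_trim_flank(
    read: SequenceRead,
    spec: BarcodeSpec,
    max_mismatches: int = DEFAULT_MAX_FLANK_MISMATCHES,
    min_segment_length: int = DEFAULT_MIN_SEGMENT_LENGTH,
    offset_window: int = 0,
) -> TrimmedRead | RejectedRead:
    """Locate the expected flank just after the barcode and trim it off.

    The flank must begin within ``offset_window`` bases of the position
    immediately after the barcode (default: exactly there) with at most
    ``max_mismatches`` substitutions.  On success the remainder of the read
    is returned as the genomic segment; the TA junction check is applied
    separately by :func:`verify_ta`.
    """
    flank = spec.expected_flank
    seq = read.sequence
    start0 = BARCODE_LENGTH
    for offset in range(offset_window + 1):
        start = start0 + offset
        window = seq[start : start + len(flank)]
        if len(window) < len(flank):
            break
        if _hamming_within(window, flank, max_mismatches) is not None:
            segment = seq[start + len(flank) :]
            if len(segment) < min_segment_length:
                return RejectedRead(read.read_id, REJECT_TOO_SHORT)
            return TrimmedRead(read.read_id, spec.tumor_id, spec.ir_end,
                               spec.enzyme, segment)
    return RejectedRead(read.read_id, REJECT_FLANK_NOT_FOUND)


def verify_ta(trimmed: TrimmedRead) -> bool:
    """Sleeping Beauty integrates only at TA: the junction must start with TA."""
    return trimmed.genomic_segment[:2] == "TA"


def process_library(
    reads: Iterable[SequenceRead],
    spec: BarcodeSpec,
    max_mismatches: int = DEFAULT_MAX_FLANK_MISMATCHES,
    min_segment_length: int = DEFAULT_MIN_SEGMENT_LENGTH,
) -> tuple[list[TrimmedRead], list[RejectedRead]]:
    """Trim and TA-verify all reads already assigned to one barcode."""
    kept: list[TrimmedRead] = []
    rejected: list[RejectedRead] = []
    for read in reads:
        result = find_and_trim_flank(read, spec, max_mismatches, min_segment_length)
        if isinstance(result, RejectedRead):
            rejected.append(result)
        elif not verify_ta(result):
            rejected.append(RejectedRead(read.read_id, REJECT_NO_TA))
        else:
            kept.append(result)
    return kept, rejected
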