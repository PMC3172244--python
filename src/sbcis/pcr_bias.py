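"""Restriction-fragment length analysis of LM-PCR amplification bias.

Each library digests tumor DNA with one enzyme (AluI "AGCT" or NlaIII
"CATG") and amplifies the junction between one transposon end and the
nearest cut site.  Fragment length therefore depends on the distance from
the insertion's TA to the nearest recognition site on the side that the
(orientation, IR-end) combination reads into: a plus-orientation transposon
reads leftward (decreasing coordinates) from IRL and rightward from IRR;
a minus-orientation transposon swaps the sides.  Fragments shorter than
~20 b or longer than ~250-500 b amplify poorly, biasing which insertions
each of the four libraries can see.

Both recognition motifs are reverse-complement palindromes, so a
forward-strand scan finds every cut site.  Lengths count genomic bases from
the motif edge proximal to the TA through the TA inclusive; a
strict-cut-site mode applies the exact cut offsets instead (AluI blunt
AG^CT, NlaIII CATG^).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .clonality import TumorProfile
from .formats_io import ENZYME_MOTIFS, Genome

MIN_AMPLIFIABLE = 20
MAX_AMPLIFIABLE_SHORT = 250  # exclusive: library amplifies iff 20 <= len < 250
MAX_FRAGMENT = 500

#: Cut offset from motif start on the forward strand (strict mode).
CUT_OFFSETS = {"AluI": 2, "NlaIII": 4}

LIBRARIES = [
    ("AluI", "IRL"), ("AluI", "IRR"), ("NlaIII", "IRL"), ("NlaIII", "IRR"),
]


def motif_positions(sequence: str, motif: str) -> np.ndarray:
    """Sorted start positions of ``motif`` on the forward strand."""
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    m = np.frombuffer(motif.encode(), dtype=np.uint8)
    if len(arr) < len(m):
        return np.empty(0, dtype=np.int64)
    hits = np.ones(len(arr) - len(m) + 1, dtype=bool)
    for i, b in enumerate(m):
        hits &= arr[i : i + len(hits)] == b
    return np.nonzero(hits)[0].astype(np.int64)


class MotifIndex:
    """Per-chromosome sorted motif positions for both enzymes."""

    def __init__(self, genome: Genome):
        self.positions = {
            enzyme: {c: motif_positions(s, motif) for c, s in genome.sequences.items()}
            for enzyme, motif in ENZYME_MOTIFS.items()
        }


def junction_side(orientation: str, ir_end: str) -> str:
    """'left' (decreasing coordinates) or 'right' side read by a library."""
    if orientation == "+":
        return "left" if ir_end == "IRL" else "right"
    return "right" if ir_end == "IRL" else "left"


def fragment_length(
    genome: Genome,
    chrom: str,
    ta_position: int,
    orientation: str,
    enzyme: str,
    ir_end: str,
    motif_index: MotifIndex | None = None,
    strict_cut_site: bool = False,
) -> int | None:
    """Genomic junction-fragment length for one site in one library.

    Length runs from the TA boundary (TA included) to the proximal edge of
    the nearest recognition site on the read-into side; None when that side
    has no recognition site.  ``strict_cut_site`` measures to the enzyme's
    actual cut position instead of the motif edge.
    """
    if not genome.has_ta(chrom, ta_position):
        raise ValueError(f"{chrom}:{ta_position} is not a TA in the reference")
    if motif_index is None:
        motif_index = MotifIndex(genome)
    pos = motif_index.positions[enzyme][chrom]
    motif_len = len(ENZYME_MOTIFS[enzyme])
    side = junction_side(orientation, ir_end)
    t = ta_position
    if side == "right":
        i = int(np.searchsorted(pos, t, side="left"))
        if i == len(pos):
            return None
        start = int(pos[i])
        if strict_cut_site:
            return start + CUT_OFFSETS[enzyme] - t
        return start - t
    # left side: nearest motif whose end is at or left of the A of the TA
    i = int(np.searchsorted(pos, t + 2 - motif_len, side="right")) - 1
    if i < 0:
        return None
    end = int(pos[i]) + motif_len
    if strict_cut_site:
        return (t + 2) - (int(pos[i]) + CUT_OFFSETS[enzyme])
    return (t + 2) - end


@dataclass(frozen=True)
class FragmentReport:
    tumor_id: str
    chrom: str
    ta_position: int
    orientation: str
    lengths: Mapping[tuple[str, str], int | None]
    n_libraries_clonal: int

    def amplifiable_short(self, library: tuple[str, str]) -> bool:
        length = self.lengths.get(library)
        return length is not None and MIN_AMPLIFIABLE <= length < MAX_AMPLIFIABLE_SHORT


def fragment_report(
    profiles: Sequence[TumorProfile],
    genome: Genome,
    motif_index: MotifIndex | None = None,
    strict_cut_site: bool = False,
) -> list[FragmentReport]:
    """Per clonal site: the four library fragment lengths + clonal library count."""
    if motif_index is None:
        motif_index = MotifIndex(genome)
    reports = []
    for tp in profiles:
        for s in tp.clonal_sites:
            lengths = {
                (enzyme, ir_end): fragment_length(
                    genome, s.chrom, s.ta_position, s.orientation, enzyme,
                    ir_end, motif_index, strict_cut_site,
                )
                for enzyme, ir_end in LIBRARIES
            }
            reports.append(
                FragmentReport(tp.tumor_id, s.chrom, s.ta_position,
                               s.orientation, lengths, len(s.libraries))
            )
    return reports


def fragment_size_distribution(
    reports: Iterable[FragmentReport],
    min_len: int = MIN_AMPLIFIABLE,
    max_len: int = MAX_FRAGMENT,
) -> dict[tuple[str, str], dict[int, float]]:
    """Per-library percentage histogram of fragment lengths within [min, max].

    Percentages within each library sum to 100 over the included lengths.
    """
    counts: dict[tuple[str, str], dict[int, int]] = {lib: {} for lib in LIBRARIES}
    for rep in reports:
        for lib, length in rep.lengths.items():
            if length is not None and min_len <= length <= max_len:
                counts[lib][length] = counts[lib].get(length, 0) + 1
    out: dict[tuple[str, str], dict[int, float]] = {}
    for lib, hist in counts.items():
        total = sum(hist.values())
        out[lib] = {
            length: n / total * 100.0 for length, n in sorted(hist.items())
        } if total else {}
    return out


def unamplifiable_ta_fraction(
    genome: Genome,
    max_short: int = MAX_AMPLIFIABLE_SHORT,
    min_len: int = MIN_AMPLIFIABLE,
    exclude_chroms: Sequence[str] = (),
) -> float:
    """Percentage of genomic TA sites no library can amplify at < 250 b.

    For every TA the four fragment lengths (enzyme x side) are computed; a
    site counts as unamplifiable when none falls in [min_len, max_short).
    """
    from .gcis import ta_positions

    motif_index = MotifIndex(genome)
    total = 0
    unamp = 0
    for chrom, seq in genome.sequences.items():
        if chrom in exclude_chroms:
            continue
        tas = ta_positions(seq)
        if len(tas) == 0:
            continue
        total += len(tas)
        ok = np.zeros(len(tas), dtype=bool)
        for enzyme in ENZYME_MOTIFS:
            pos = motif_index.positions[enzyme][chrom]
            motif_len = len(ENZYME_MOTIFS[enzyme])
            if len(pos) == 0:
                continue
            # right side: nearest motif start at or beyond the T
            i = np.searchsorted(pos, tas, side="left")
            has = i < len(pos)
            right = np.full(len(tas), np.iinfo(np.int64).max, dtype=np.int64)
            right[has] = pos[np.minimum(i, len(pos) - 1)][has] - tas[has]
            ok |= (right >= min_len) & (right < max_short)
            # left side: nearest motif end at or left of the A
            j = np.searchsorted(pos, tas + 2 - motif_len, side="right") - 1
            has = j >= 0
            left = np.full(len(tas), np.iinfo(np.int64).max, dtype=np.int64)
            left[has] = (tas[has] + 2) - (pos[np.maximum(j, 0)][has] + motif_len)
            ok |= (left >= min_len) & (left < max_short)
        unamp += int((~ok).sum())
    if total == 0:
        raise ValueError("genome contains no TA sites")
    return unamp / total * 100.0


def library_concordance(profiles: Sequence[TumorProfile], min_libraries: int = 3) -> float:
    """Percentage of merged clonal sites called clonal in >= 3 of 4 libraries."""
    sites = [s for tp in profiles for s in tp.clonal_sites]
    if not sites:
        return 0.0
    hits = sum(1 for s in sites if len(s.libraries) >= min_libraries)
    return hits / len(sites) * 100.0
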