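"""Gene-centric common insertion site (gCIS) statistics and annotation.

Sleeping Beauty integrates only at TA dinucleotides, so under the null
hypothesis insertions fall on genes in proportion to their TA content.  For
each gene the *gene-associated region* is the union of all its transcripts
extended by a 10 kb promoter upstream of the 5'-most transcription start.
With N total clonal insertions across the cohort, T_g TA sites in the gene
region and T_genome TA sites genome-wide, the expected burden is
E_g = N * T_g / T_genome and the observed burden O_g is tested with a
two-cell goodness-of-fit chi-square (in-gene vs not-in-gene, 1 df).

A gene is called a gCIS when its p-value passes the Bonferroni threshold
alpha / G (G = genes tested), it is hit in at least three distinct tumors,
and the burden exceeds expectation (one-sided enrichment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .align_filter import InsertionSite
from .clonality import MergedSite, TumorProfile
from .formats_io import GeneTranscript, Genome

PROMOTER_BP = 10_000
DEFAULT_ALPHA = 0.05
MIN_TUMORS = 3


@dataclass(frozen=True)
class GeneRegion:
    """A gene's testable footprint: transcript union + 10 kb promoter."""

    gene_name: str
    chrom: str
    strand: str
    intervals: tuple[tuple[int, int], ...]  # disjoint, sorted, half-open
    ta_count: int

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]

    def contains(self, position: int) -> bool:
        """Whether a TA at ``position`` lies fully inside the region."""
        for a, b in self.intervals:
            if a <= position <= b - 2:
                return True
        return False


@dataclass(frozen=True)
class GCISRecord:
    gene_name: str
    chrom: str
    region_start: int
    region_end: int
    ta_count: int
    observed: int
    expected: float
    chi_square: float
    p_value: float
    n_tumors: int
    tumor_ids: tuple[str, ...]
    significant: bool


def _union_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    merged: list[list[int]] = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return tuple((a, b) for a, b in merged)


def ta_positions(sequence: str) -> np.ndarray:
    """Sorted 0-based positions p with sequence[p:p+2] == 'TA'."""
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    if len(arr) < 2:
        return np.empty(0, dtype=np.int64)
    return np.nonzero((arr[:-1] == ord("T")) & (arr[1:] == ord("A")))[0].astype(np.int64)


class TAIndex:
    """Per-chromosome sorted TA positions for fast interval counting."""

    def __init__(self, genome: Genome):
        self.positions = {c: ta_positions(s) for c, s in genome.sequences.items()}

    def count_in(self, chrom: str, intervals: Iterable[tuple[int, int]]) -> int:
        pos = self.positions[chrom]
        total = 0
        for a, b in intervals:
            # TA fully inside: a <= p and p + 2 <= b
            total += int(np.searchsorted(pos, b - 2, side="right")
                         - np.searchsorted(pos, a, side="left"))
        return total

    def genome_total(self, exclude_chroms: Iterable[str] = ()) -> int:
        excluded = set(exclude_chroms)
        return sum(len(p) for c, p in self.positions.items() if c not in excluded)


def count_ta_sites(genome: Genome, chrom: str | None = None,
                   intervals: Iterable[tuple[int, int]] | None = None) -> int:
    """Count TA dinucleotides genome-wide or within intervals of one chromosome."""
    index = TAIndex(genome)
    if chrom is None:
        return index.genome_total()
    if intervals is None:
        return len(index.positions[chrom])
    return index.count_in(chrom, intervals)


def build_gene_regions(
    transcripts: Sequence[GeneTranscript],
    chrom_lengths: dict[str, int],
    ta_index: TAIndex | None = None,
    promoter_bp: int = PROMOTER_BP,
) -> list[GeneRegion]:
    """Union each gene's transcripts and add the strand-aware promoter.

    Plus-strand genes extend ``promoter_bp`` left of the smallest txStart,
    minus-strand genes right of the largest txEnd; extensions are clipped at
    the chromosome bounds.  Genes whose transcripts span several chromosomes
    or strands are skipped with a warning.
    """
    by_gene: dict[str, list[GeneTranscript]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_name, []).append(t)
    regions: list[GeneRegion] = []
    for gene_name in sorted(by_gene):
        txs = by_gene[gene_name]
        chroms = {t.chrom for t in txs}
        strands = {t.strand for t in txs}
        if len(chroms) > 1 or len(strands) > 1:
            warnings.warn(
                f"gene {gene_name}: transcripts on multiple chromosomes/strands; skipped",
                stacklevel=2,
            )
            continue
        chrom, strand = txs[0].chrom, txs[0].strand
        chrom_len = chrom_lengths[chrom]
        spans = [(t.tx_start, t.tx_end) for t in txs]
        if strand == "+":
            tss = min(s for s, _ in spans)
            spans.append((max(0, tss - promoter_bp), tss))
        else:
            tss = max(e for _, e in spans)
            spans.append((tss, min(chrom_len, tss + promoter_bp)))
        intervals = _union_intervals(
            (max(0, a), min(chrom_len, b)) for a, b in spans if a < b
        )
        ta_count = ta_index.count_in(chrom, intervals) if ta_index is not None else 0
        regions.append(GeneRegion(gene_name, chrom, strand, intervals, ta_count))
    return regions


def gcis_chi_square(observed: int, expected: float, n_total: int) -> float:
    """Two-cell goodness-of-fit statistic (in-gene vs rest), 1 df."""
    in_gene = (observed - expected) ** 2 / expected
    out_gene = ((n_total - observed) - (n_total - expected)) ** 2 / (n_total - expected)
    return in_gene + out_gene


def gcis_test(
    tumor_profiles: Sequence[TumorProfile],
    gene_regions: Sequence[GeneRegion],
    genome: Genome,
    alpha: float = DEFAULT_ALPHA,
    min_tumors: int = MIN_TUMORS,
    exclude_chroms: Sequence[str] = (),
    ta_index: TAIndex | None = None,
) -> list[GCISRecord]:
    """Per-gene chi-square enrichment over the pooled clonal insertions.

    Every clonal site counts once per gene it falls in (a site inside two
    overlapping gene regions contributes to both); recurrence is counted in
    distinct tumors.  ``exclude_chroms`` (normally the donor chromosome) is
    removed from the genome-wide TA total for consistency with profile
    filtering.  Genes with no TA sites have zero expectation and are
    excluded from testing and from the Bonferroni divisor.
    """
    if ta_index is None:
        ta_index = TAIndex(genome)
    t_genome = ta_index.genome_total(exclude_chroms)
    if t_genome == 0:
        raise ValueError("genome contains no TA sites")
    sites: list[MergedSite] = [
        s for tp in tumor_profiles for s in tp.clonal_sites
    ]
    n_total = len(sites)
    testable = [
        g for g in gene_regions
        if (g.ta_count if g.ta_count else ta_index.count_in(g.chrom, g.intervals)) > 0
        and g.chrom not in exclude_chroms
    ]
    n_genes = len(testable)
    # sites grouped per chromosome for fast membership checks
    by_chrom: dict[str, list[MergedSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    records: list[GCISRecord] = []
    bonferroni = alpha / n_genes if n_genes else np.nan
    for g in testable:
        t_g = g.ta_count or ta_index.count_in(g.chrom, g.intervals)
        expected = n_total * t_g / t_genome
        hits = [s for s in by_chrom.get(g.chrom, []) if g.contains(s.ta_position)]
        observed = len(hits)
        tumors = tuple(sorted({s.tumor_id for s in hits}))
        if n_total == 0 or expected == 0 or expected >= n_total:
            chi = 0.0
            p = 1.0
        else:
            chi = gcis_chi_square(observed, expected, n_total)
            p = float(stats.chi2.sf(chi, df=1))
        significant = (
            p <= bonferroni and len(tumors) >= min_tumors and observed > expected
        )
        records.append(
            GCISRecord(
                gene_name=g.gene_name, chrom=g.chrom,
                region_start=g.start, region_end=g.end, ta_count=t_g,
                observed=observed, expected=expected, chi_square=chi,
                p_value=max(p, np.finfo(float).tiny), n_tumors=len(tumors),
                tumor_ids=tumors, significant=bool(significant),
            )
        )
    return records


def significant_genes(records: Iterable[GCISRecord]) -> set[str]:
    return {r.gene_name for r in records if r.significant}


# ---------------------------------------------------------------------------
# Per-insertion annotation


def _gene_body(txs: Sequence[GeneTranscript]) -> tuple[int, int]:
    return min(t.tx_start for t in txs), max(t.tx_end for t in txs)


def annotate_insertion(
    site: InsertionSite | MergedSite,
    transcripts: Sequence[GeneTranscript],
    promoter_bp: int = PROMOTER_BP,
) -> dict:
    """Annotate one insertion with its nearest gene and predicted effect.

    Region hit is exon, intron, promoter (within 10 kb upstream of the TSS)
    or intergenic; distance is 0 inside the gene body, otherwise base pairs
    to the nearest gene boundary.  Orientation is reported relative to the
    gene strand (sense/antisense).  The predicted-effect rule is heuristic:
    sense insertions in the promoter or first intron are "activating",
    intergenic insertions "none", everything else "disrupting".
    """
    by_gene: dict[str, list[GeneTranscript]] = {}
    for t in transcripts:
        if t.chrom == site.chrom:
            by_gene.setdefault(t.gene_name, []).append(t)
    if not by_gene:
        return {
            "gene_name": "NA", "gene_region_hit": "intergenic",
            "predicted_effect": "none", "distance_from_gene": -1,
            "orientation_vs_gene": "NA",
        }
    pos = site.ta_position

    def distance(gene: str) -> int:
        a, b = _gene_body(by_gene[gene])
        if a <= pos < b:
            return 0
        return a - pos if pos < a else pos - (b - 1)

    nearest = min(sorted(by_gene), key=distance)
    txs = by_gene[nearest]
    strand = txs[0].strand
    a, b = _gene_body(txs)
    dist = distance(nearest)
    sense = site.orientation == strand
    region_hit = "intergenic"
    effect = "none"
    if dist == 0:
        in_exon = any(
            s <= pos < e for t in txs for s, e in zip(t.exon_starts, t.exon_ends)
        )
        region_hit = "exon" if in_exon else "intron"
        first_intron = False
        if region_hit == "intron":
            for t in txs:
                if strand == "+" and len(t.exon_ends) > 1:
                    first_intron |= t.exon_ends[0] <= pos < t.exon_starts[1]
                elif strand == "-" and len(t.exon_ends) > 1:
                    first_intron |= t.exon_ends[-2] <= pos < t.exon_starts[-1]
        effect = "activating" if (sense and first_intron) else "disrupting"
    else:
        upstream = (strand == "+" and pos < a) or (strand == "-" and pos >= b)
        if upstream and dist <= promoter_bp:
            region_hit = "promoter"
            effect = "activating" if sense else "disrupting"
    return {
        "gene_name": nearest,
        "gene_region_hit": region_hit,
        "predicted_effect": effect,
        "distance_from_gene": dist,
        "orientation_vs_gene": "sense" if sense else "antisense",
    }


GCIS_TABLE_COLUMNS = [
    "gene", "chrom", "region_start", "region_end", "ta_count", "observed",
    "expected", "chi_square", "p_value", "bonferroni_threshold", "n_tumors",
    "tumor_ids", "significant",
]


def gcis_to_table(records: Sequence[GCISRecord], alpha: float = DEFAULT_ALPHA):
    import pandas as pd

    n_genes = len(records)
    bonf = alpha / n_genes if n_genes else np.nan
    rows = [
        {
            "gene": r.gene_name, "chrom": r.chrom,
            "region_start": r.region_start, "region_end": r.region_end,
            "ta_count": r.ta_count, "observed": r.observed,
            "expected": r.expected, "chi_square": r.chi_square,
            "p_value": r.p_value, "bonferroni_threshold": bonf,
            "n_tumors": r.n_tumors, "tumor_ids": ",".join(r.tumor_ids),
            "significant": r.significant,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=GCIS_TABLE_COLUMNS)
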