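"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive and shares no code path with the
package: plain loops, math.lgamma pmfs, character-by-character scans.
"""

from __future__ import annotations

import math

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def brute_force_align(segment: str, sequences: dict[str, str], max_mismatches: int = 3):
    """All (mismatches, chrom, pos, strand) placements, best-first."""
    hits = []
    for chrom in sorted(sequences):
        seq = sequences[chrom]
        for probe, strand in ((segment, "+"), (revcomp(segment), "-")):
            for pos in range(len(seq) - len(segment) + 1):
                mism = sum(1 for a, b in zip(probe, seq[pos : pos + len(segment)])
                           if a != b)
                if mism <= max_mismatches:
                    hits.append((mism, chrom, pos, strand))
    hits.sort()
    return hits


def nb_pmf(k: int, size: float, prob: float) -> float:
    """Negative binomial pmf via log-gamma (independent of scipy)."""
    log_p = (
        math.lgamma(k + size) - math.lgamma(size) - math.lgamma(k + 1)
        + size * math.log(prob) + k * math.log1p(-prob)
    )
    return math.exp(log_p)


def nb_grid_argmin(props, size_grid, prob_grid):
    """Exhaustive SSE minimization; first (smallest size, prob) wins ties."""
    best = None
    for size in size_grid:
        for prob in prob_grid:
            sse = sum((nb_pmf(k, size, prob) - props[k]) ** 2 for k in range(len(props)))
            if best is None or sse < best[0]:
                best = (sse, size, prob)
    return best[1], best[2], best[0]


def nb_quantile(size: float, prob: float, q: float) -> int:
    """Smallest k with CDF(k) >= q, by direct summation."""
    total = 0.0
    k = 0
    while True:
        total += nb_pmf(k, size, prob)
        if total >= q:
            return k
        k += 1


def count_ta(seq: str, start: int = 0, end: int | None = None) -> int:
    """Naive scan for TA dinucleotides fully inside [start, end)."""
    if end is None:
        end = len(seq)
    return sum(1 for p in range(start, end - 1) if seq[p : p + 2] == "TA")


def nearest_motif_fragment(seq: str, t: int, side: str, motif: str) -> int | None:
    """Naive fragment length from the TA at t to the nearest motif on a side."""
    if side == "right":
        for pos in range(t, len(seq) - len(motif) + 1):
            if seq[pos : pos + len(motif)] == motif:
                return pos - t
        return None
    best = None
    for pos in range(0, len(seq) - len(motif) + 1):
        if pos + len(motif) <= t + 2 and seq[pos : pos + len(motif)] == motif:
            best = pos
    if best is None:
        return None
    return (t + 2) - (best + len(motif))


def two_cell_chi_square(observed: int, expected: float, n_total: int):
    """Goodness-of-fit chi-square on the (in-gene, out-of-gene) table via scipy."""
    from scipy.stats import chisquare

    stat, p = chisquare(
        [observed, n_total - observed], [expected, n_total - expected]
    )
    return float(stat), float(p)
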