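"""Clonal insertion-site identification by dynamic three-method filtering.

Tumor libraries mix a few clonally expanded insertions (high read counts)
with many background insertions present in only a few cells (low counts).
Three per-library read-count cutoffs are computed independently:

1. **Negative binomial (NB)**: sites with 1-3 reads are taken as certain
   background; their zero-shifted counts are fit with an NB distribution by
   least-squares over a (size, prob) grid with steps 0.01 and 0.001, and the
   cutoff is the count below which 95% of the fitted background lies.
2. **Top-site**: 1% of the read count of the most abundant site.
3. **Total-reads**: 0.1% of the library's total mapped reads.

The applied cutoff is the maximum of the three (the *dynamic cutoff*);
sites must strictly exceed it to be called clonal.  Donor-chromosome sites
are removed before any cutoff is computed (local-hopping bias), and the
four libraries of each tumor are merged into a non-redundant clonal site
list keeping, per site, the largest percent-of-reads across libraries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .align_filter import InsertionSite, LibraryProfile

MIN_BACKGROUND_SITES = 50
BACKGROUND_MAX_COUNT = 3  # sites with 1..3 reads model the background
NB_QUANTILE = 0.95

DEFAULT_GRID = {
    "size_min": 0.01, "size_max": 10.0, "size_step": 0.01,
    "prob_min": 0.001, "prob_max": 0.999, "prob_step": 0.001,
}


@dataclass(frozen=True)
class NBFit:
    """A grid-fit negative binomial background model for one library."""

    size: float
    prob: float
    sse: float
    threshold: int  # unshifted read-count cutoff

    def __post_init__(self):
        if not self.size > 0:
            raise ValueError("size must be positive")
        if not 0 < self.prob < 1:
            raise ValueError("prob must be in (0,1)")
        if self.threshold < 1:
            raise ValueError("threshold must be >= 1")


@dataclass(frozen=True)
class CutoffResult:
    nb_cutoff: float
    topsite_cutoff: float
    totalreads_cutoff: float
    applied_cutoff: float
    method_applied: str
    nb_fit: NBFit | None = None

    def __post_init__(self):
        expected = max(self.nb_cutoff, self.topsite_cutoff, self.totalreads_cutoff)
        if self.applied_cutoff != expected:
            raise ValueError("applied_cutoff must be the maximum of the three")


@dataclass(frozen=True)
class MergedSite:
    """A clonal site merged across a tumor's four LM-PCR libraries."""

    tumor_id: str
    chrom: str
    ta_position: int
    orientation: str
    libraries: frozenset  # contributing (enzyme, ir_end) pairs
    percent_of_reads: float  # max over contributing libraries
    read_count: int  # max over contributing libraries

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.ta_position, self.orientation)


@dataclass
class TumorProfile:
    """Non-redundant clonal insertion sites for one tumor."""

    tumor_id: str
    clonal_sites: list[MergedSite] = field(default_factory=list)


def remove_donor_chromosome(profile: LibraryProfile, donor_chrom: str) -> LibraryProfile:
    """Discard all sites on the transposon donor chromosome.

    Local hopping concentrates re-insertions near the donor concatemer, so
    the entire donor chromosome is excluded before cutoffs are computed.
    Total mapped reads and percentages are recomputed from the remainder.
    """
    kept = [s for s in profile.sites if s.chrom != donor_chrom]
    out = LibraryProfile(profile.tumor_id, profile.library, kept,
                         sum(s.read_count for s in kept))
    out.recompute_percentages()
    return out


_PMF_GRID_CACHE: dict[tuple, tuple] = {}


def _pmf_grid(grid: dict) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(sizes, probs, pmf[k, i_size, i_prob] for k in 0..2), cached per bounds."""
    key = tuple(sorted(grid.items()))
    if key not in _PMF_GRID_CACHE:
        sizes = np.round(
            np.arange(grid["size_min"], grid["size_max"] + grid["size_step"] / 2,
                      grid["size_step"]), 10)
        probs = np.round(
            np.arange(grid["prob_min"], grid["prob_max"] + grid["prob_step"] / 2,
                      grid["prob_step"]), 10)
        k = np.arange(BACKGROUND_MAX_COUNT).reshape(-1, 1, 1)
        pmf = stats.nbinom.pmf(k, sizes.reshape(1, -1, 1), probs.reshape(1, 1, -1))
        _PMF_GRID_CACHE[key] = (sizes, probs, pmf)
    return _PMF_GRID_CACHE[key]


def fit_nb_background(
    site_read_counts: Sequence[int],
    grid: dict | None = None,
    min_background_sites: int = MIN_BACKGROUND_SITES,
) -> NBFit | None:
    """Fit the NB background model to a library's site read counts.

    ``site_read_counts`` are the per-site read counts of *all* sites in the
    library.  Only sites with 1-3 reads inform the fit: their zero-shifted
    counts (k = reads - 1) give empirical proportions over all sites, which
    are matched against the untruncated NB pmf at k = 0, 1, 2 by least
    squares over the (size, prob) grid.  Ties break toward the smallest
    (size, prob) lexicographically.  Returns None when fewer than
    ``min_background_sites`` background sites are available.
    """
    if grid is None:
        grid = DEFAULT_GRID
    counts = np.asarray(site_read_counts)
    n_total = len(counts)
    if n_total == 0:
        return None
    background = counts[(counts >= 1) & (counts <= BACKGROUND_MAX_COUNT)]
    if len(background) < min_background_sites:
        return None
    props = np.array(
        [(background == k + 1).sum() / n_total for k in range(BACKGROUND_MAX_COUNT)]
    )
    sizes, probs, pmf = _pmf_grid(grid)
    sse = ((pmf - props.reshape(-1, 1, 1)) ** 2).sum(axis=0)
    # row-major argmin = first (smallest size, then prob) on ties
    flat = int(np.argmin(sse))
    i, j = divmod(flat, sse.shape[1])
    size, prob = float(sizes[i]), float(probs[j])
    threshold = nb_threshold_from_params(size, prob)
    return NBFit(size=size, prob=prob, sse=float(sse[i, j]), threshold=threshold)


def nb_threshold_from_params(size: float, prob: float, quantile: float = NB_QUANTILE) -> int:
    """Unshifted read-count cutoff: smallest c with fitted CDF(c) >= quantile, plus 1."""
    c = int(stats.nbinom.ppf(quantile, size, prob))
    return c + 1


def nb_threshold(fit: NBFit | None) -> float:
    """The NB cutoff, or 0 when the NB method is unavailable."""
    return float(fit.threshold) if fit is not None else 0.0


def topsite_cutoff(profile: LibraryProfile) -> float:
    """1% of the read count of the most abundant site."""
    if not profile.sites:
        return 0.0
    return 0.01 * max(s.read_count for s in profile.sites)


def totalreads_cutoff(profile: LibraryProfile) -> float:
    """0.1% of the library's total mapped reads."""
    return 0.001 * profile.total_mapped_reads


def dynamic_cutoff(
    profile: LibraryProfile,
    grid: dict | None = None,
    min_background_sites: int = MIN_BACKGROUND_SITES,
) -> CutoffResult:
    """Compute all three cutoffs and apply the maximum."""
    if not profile.sites:
        warnings.warn(
            f"{profile.tumor_id} {profile.library}: empty profile, cutoffs skipped",
            stacklevel=2,
        )
        return CutoffResult(0.0, 0.0, 0.0, 0.0, "none", None)
    fit = fit_nb_background(
        [s.read_count for s in profile.sites], grid, min_background_sites
    )
    nb = nb_threshold(fit)
    top = topsite_cutoff(profile)
    total = totalreads_cutoff(profile)
    applied = max(nb, top, total)
    # on exact ties prefer naming NB, then topsite
    if applied == nb:
        method = "NB"
    elif applied == top:
        method = "topsite"
    else:
        method = "totalreads"
    return CutoffResult(nb, top, total, applied, method, fit)


def call_clonal(profile: LibraryProfile, cutoff: CutoffResult | float) -> list[InsertionSite]:
    """Sites strictly exceeding the applied cutoff are clonal."""
    value = cutoff.applied_cutoff if isinstance(cutoff, CutoffResult) else float(cutoff)
    return [s for s in profile.sites if s.read_count > value]


def merge_libraries(
    tumor_id: str, clonal_lists: Sequence[Sequence[InsertionSite]]
) -> TumorProfile:
    """Union the clonal calls of a tumor's libraries into one profile.

    Sites are keyed by (chrom, ta_position, orientation); a site clonal in
    several libraries keeps the largest percent-of-reads and records every
    contributing library.
    """
    merged: dict[tuple, MergedSite] = {}
    for sites in clonal_lists:
        for s in sites:
            if s.tumor_id != tumor_id:
                raise ValueError(f"site from tumor {s.tumor_id!r} in merge of {tumor_id!r}")
            prev = merged.get(s.key)
            if prev is None:
                merged[s.key] = MergedSite(
                    tumor_id, s.chrom, s.ta_position, s.orientation,
                    frozenset([s.library]), s.percent_of_reads, s.read_count,
                )
            else:
                merged[s.key] = replace(
                    prev,
                    libraries=prev.libraries | {s.library},
                    percent_of_reads=max(prev.percent_of_reads, s.percent_of_reads),
                    read_count=max(prev.read_count, s.read_count),
                )
    return TumorProfile(tumor_id, [merged[k] for k in sorted(merged)])


def clonal_profiles_for_tumor(
    profiles: Sequence[LibraryProfile],
    donor_chrom: str | None = None,
    grid: dict | None = None,
    min_background_sites: int = MIN_BACKGROUND_SITES,
) -> tuple[TumorProfile, list[CutoffResult]]:
    """Full per-tumor clonality stage: donor removal, cutoffs, call, merge."""
    tumor_ids = {p.tumor_id for p in profiles}
    if len(tumor_ids) != 1:
        raise ValueError(f"profiles span multiple tumors: {tumor_ids}")
    (tumor_id,) = tumor_ids
    cutoffs: list[CutoffResult] = []
    clonal_lists: list[list[InsertionSite]] = []
    for profile in profiles:
        if donor_chrom is not None:
            profile = remove_donor_chromosome(profile, donor_chrom)
        cutoff = dynamic_cutoff(profile, grid, min_background_sites)
        cutoffs.append(cutoff)
        clonal_lists.append(call_clonal(profile, cutoff))
    return merge_libraries(tumor_id, clonal_lists), cutoffs
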