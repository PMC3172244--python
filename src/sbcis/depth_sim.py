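"""Read-depth saturation analysis by resampling mapped reads.

Mapped reads from all libraries are pooled (each entry keeps its tumor and
library labels and map location).  For a ladder of target depths, reads are
drawn with replacement from the pool, library profiles rebuilt, and the
full clonality stage re-run; repeating this over many iterations yields
the mean clonal-site yield and the consistency of site identification
(fraction of the union of called sites found in >=80/90/100% of
iterations).  When gene models are supplied, the gCIS test also runs per
iteration and is scored for accuracy and sensitivity against the reference
gene set obtained from the full, unsubsampled data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .align_filter import InsertionSite, LibraryProfile
from .clonality import (
    MIN_BACKGROUND_SITES, MergedSite, TumorProfile, clonal_profiles_for_tumor,
    fit_nb_background, nb_threshold,
)
from .gcis import GeneRegion, TAIndex, gcis_test, significant_genes
from .formats_io import Genome

POOL_COLUMNS = ["tumor_id", "enzyme", "ir_end", "chrom", "ta_position",
                "orientation", "read_count"]

DEFAULT_DEPTHS = np.unique(
    np.round(np.logspace(np.log10(1_000), np.log10(150_000), 19)).astype(int)
)


@dataclass(frozen=True)
class DepthSimResult:
    depth: int
    iterations: int
    mean_clonal_sites: float
    consistency_80: float
    consistency_90: float
    consistency_100: float
    gcis_accuracy: float | None = None
    gcis_sensitivity: float | None = None
    #: mean % of the full-data clonal sites recovered per iteration
    site_sensitivity: float | None = None


def pool_from_profiles(profiles: Sequence[LibraryProfile]) -> pd.DataFrame:
    """One row per unique mapped-read location with its read count."""
    rows = [
        {
            "tumor_id": p.tumor_id, "enzyme": p.library[0], "ir_end": p.library[1],
            "chrom": s.chrom, "ta_position": s.ta_position,
            "orientation": s.orientation, "read_count": s.read_count,
        }
        for p in profiles
        for s in p.sites
    ]
    return pd.DataFrame(rows, columns=POOL_COLUMNS)


def subsample(pool: pd.DataFrame, depth_per_sample: int, n_samples: int,
              rng: np.random.Generator) -> pd.DataFrame:
    """Draw depth_per_sample * n_samples reads with replacement from the pool.

    Sampling is global (each read keeps its tumor label), so achieved
    per-tumor depth varies around the target.  Returns a pool-shaped frame
    with resampled counts (zero-count rows dropped).
    """
    if pool.empty:
        raise ValueError("cannot subsample an empty read pool")
    draws = int(depth_per_sample) * int(n_samples)
    counts = pool["read_count"].to_numpy()
    total = counts.sum()
    if draws == 0:
        return pool.iloc[0:0].copy()
    sampled = rng.multinomial(draws, counts / total)
    out = pool.copy()
    out["read_count"] = sampled
    return out[out["read_count"] > 0].reset_index(drop=True)


def subsample_stratified(pool: pd.DataFrame, depth_per_sample: int,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Alternative mode: draw exactly depth_per_sample reads per tumor."""
    parts = []
    for _tumor, group in pool.groupby("tumor_id", sort=True):
        parts.append(subsample(group, depth_per_sample, 1, rng))
    return pd.concat(parts, ignore_index=True) if parts else pool.iloc[0:0].copy()


def profiles_from_pool(pool: pd.DataFrame) -> list[LibraryProfile]:
    profiles: list[LibraryProfile] = []
    for (tumor, enzyme, ir_end), group in pool.groupby(
        ["tumor_id", "enzyme", "ir_end"], sort=True
    ):
        sites = [
            InsertionSite(str(tumor), str(r.chrom), int(r.ta_position),
                          str(r.orientation), (str(enzyme), str(ir_end)),
                          int(r.read_count), 0.0)
            for r in group.itertuples()
        ]
        prof = LibraryProfile(str(tumor), (str(enzyme), str(ir_end)), sites,
                              sum(s.read_count for s in sites))
        prof.recompute_percentages()
        profiles.append(prof)
    return profiles


def run_clonality(profiles: Sequence[LibraryProfile], donor_chrom: str | None,
                  **clonality_kwargs) -> list[TumorProfile]:
    by_tumor: dict[str, list[LibraryProfile]] = {}
    for p in profiles:
        by_tumor.setdefault(p.tumor_id, []).append(p)
    return [
        clonal_profiles_for_tumor(by_tumor[t], donor_chrom, **clonality_kwargs)[0]
        for t in sorted(by_tumor)
    ]


def clonal_calls_from_pool(
    pool: pd.DataFrame,
    donor_chrom: str | None = None,
    grid: dict | None = None,
    min_background_sites: int = MIN_BACKGROUND_SITES,
) -> list[TumorProfile]:
    """Vectorized clonality stage on a pool-shaped frame.

    Applies the same donor removal, dynamic cutoff (via the shared NB fit
    and cutoff formulas) and strict clonal call as the object-level stage,
    operating on count arrays per library; merged tumor profiles keep the
    contributing-library sets and max percent-of-reads, identically to
    :func:`sbcis.clonality.clonal_profiles_for_tumor`.
    """
    if donor_chrom is not None:
        pool = pool[pool["chrom"] != donor_chrom]
    merged: dict[str, dict[tuple, MergedSite]] = {}
    for (tumor, enzyme, ir_end), group in pool.groupby(
        ["tumor_id", "enzyme", "ir_end"], sort=True
    ):
        counts = group["read_count"].to_numpy()
        if len(counts) == 0:
            continue
        total = int(counts.sum())
        fit = fit_nb_background(counts, grid, min_background_sites)
        cutoff = max(nb_threshold(fit), 0.01 * counts.max(), 0.001 * total)
        clonal = group[counts > cutoff]
        sites = merged.setdefault(str(tumor), {})
        for r in clonal.itertuples():
            key = (str(r.chrom), int(r.ta_position), str(r.orientation))
            pct = int(r.read_count) / total * 100.0
            prev = sites.get(key)
            if prev is None:
                sites[key] = MergedSite(str(tumor), *key,
                                        frozenset([(str(enzyme), str(ir_end))]),
                                        pct, int(r.read_count))
            else:
                sites[key] = MergedSite(
                    str(tumor), *key,
                    prev.libraries | {(str(enzyme), str(ir_end))},
                    max(prev.percent_of_reads, pct),
                    max(prev.read_count, int(r.read_count)),
                )
    return [
        TumorProfile(t, [sites[k] for k in sorted(sites)])
        for t, sites in sorted(merged.items())
    ]


def consistency_analysis(iteration_site_sets: Sequence[set]) -> tuple[float, float, float]:
    """Percent of union-of-iterations sites found in >=80/90/100% of iterations."""
    if not iteration_site_sets:
        raise ValueError("need at least one iteration")
    union: set = set().union(*iteration_site_sets)
    if not union:
        warnings.warn("no sites called in any iteration; consistency undefined",
                      stacklevel=2)
        return (0.0, 0.0, 0.0)
    n_iter = len(iteration_site_sets)
    freq = {site: sum(site in s for s in iteration_site_sets) / n_iter
            for site in union}
    def pct(level: float) -> float:
        return sum(1 for f in freq.values() if f >= level) / len(union) * 100.0
    return (pct(0.8), pct(0.9), pct(1.0))


def gcis_depth_accuracy(found_sets: Sequence[set], reference: set) -> tuple[float, float]:
    """Mean accuracy and sensitivity of per-iteration gCIS calls vs reference."""
    accs, sens = [], []
    for found in found_sets:
        if not found:
            warnings.warn("empty gCIS set in an iteration; accuracy counted as 0",
                          stacklevel=2)
            accs.append(0.0)
        else:
            accs.append(len(found & reference) / len(found) * 100.0)
        sens.append(len(found & reference) / len(reference) * 100.0 if reference else 0.0)
    return float(np.mean(accs)), float(np.mean(sens))


def depth_curve(
    pool: pd.DataFrame,
    depths: Sequence[int],
    iterations: int = 20,
    seed: int = 0,
    donor_chrom: str | None = None,
    stratified: bool = False,
    genome: Genome | None = None,
    gene_regions: Sequence[GeneRegion] | None = None,
    reference_genes: set | None = None,
    reference_sites: set | None = None,
    gcis_kwargs: dict | None = None,
    clonality_kwargs: dict | None = None,
) -> list[DepthSimResult]:
    """Run the full depth simulation over a ladder of target depths.

    Reproducible end-to-end for a given seed.  gCIS accuracy/sensitivity is
    computed only when genome + gene regions + reference set are supplied.
    """
    rng = np.random.default_rng(seed)
    n_samples = pool["tumor_id"].nunique()
    clonality_kwargs = clonality_kwargs or {}
    gcis_kwargs = gcis_kwargs or {}
    ta_index = TAIndex(genome) if genome is not None else None
    results: list[DepthSimResult] = []
    for depth in depths:
        site_sets: list[set] = []
        found_sets: list[set] = []
        n_clonal: list[int] = []
        for _ in range(iterations):
            if stratified:
                sub = subsample_stratified(pool, depth, rng)
            else:
                sub = subsample(pool, depth, n_samples, rng)
            tumor_profiles = clonal_calls_from_pool(sub, donor_chrom,
                                                    **clonality_kwargs)
            keys = {
                (tp.tumor_id, *s.key) for tp in tumor_profiles for s in tp.clonal_sites
            }
            site_sets.append(keys)
            n_clonal.append(len(keys))
            if gene_regions is not None and genome is not None:
                recs = gcis_test(tumor_profiles, gene_regions, genome,
                                 ta_index=ta_index, **gcis_kwargs)
                found_sets.append(significant_genes(recs))
        c80, c90, c100 = consistency_analysis(site_sets)
        acc = sen = site_sen = None
        if found_sets and reference_genes is not None:
            acc, sen = gcis_depth_accuracy(found_sets, reference_genes)
        if reference_sites:
            site_sen = float(np.mean(
                [len(s & reference_sites) / len(reference_sites) * 100.0
                 for s in site_sets]
            ))
        results.append(
            DepthSimResult(int(depth), iterations, float(np.mean(n_clonal)),
                           c80, c90, c100, acc, sen, site_sen)
        )
    return results


def results_to_table(results: Sequence[DepthSimResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "depth": r.depth, "iterations": r.iterations,
                "mean_clonal_sites": r.mean_clonal_sites,
                "consistency_80": r.consistency_80,
                "consistency_90": r.consistency_90,
                "consistency_100": r.consistency_100,
                "gcis_accuracy": r.gcis_accuracy,
                "gcis_sensitivity": r.gcis_sensitivity,
                "site_sensitivity": r.site_sensitivity,
            }
            for r in results
        ]
    )
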