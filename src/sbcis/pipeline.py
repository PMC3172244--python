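"""End-to-end pipeline: reads -> clonal sites -> gCIS, with run reporting.

Stage order is fixed: demultiplex -> flank trim + TA verify -> align
(imported SAM or the built-in exhaustive aligner) -> filter -> aggregate
per-library sites -> donor-chromosome removal -> dynamic cutoffs -> clonal
calls -> per-tumor library merge -> gCIS.  Every intermediate table is
written to the output directory, and a JSON run report records per-stage
record counts, the seed and a config hash, so a same-seed rerun is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .align_filter import (
    AcceptedRead, aggregate_sites, filter_read, profiles_to_table, toy_align,
)
from .clonality import CutoffResult, clonal_profiles_for_tumor, TumorProfile, MergedSite
from .demux_trim import demultiplex, process_library
from .formats_io import Genome, parse_barcode_table, parse_refflat, read_sequences
from .gcis import TAIndex, build_gene_regions, gcis_test, gcis_to_table


@dataclass
class RunConfig:
    reads: str
    barcodes: str
    genome: str
    out_dir: str
    refflat: str | None = None
    donor_chrom: str | None = None
    aligner_sam: str | None = None  # None -> built-in exhaustive aligner
    alpha: float = 0.05
    min_tumors: int = 3
    flank_mismatches: int = 2
    min_segment: int = 20
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def merged_to_table(profiles: Sequence[TumorProfile]) -> pd.DataFrame:
    rows = [
        {
            "tumor_id": tp.tumor_id, "chrom": s.chrom, "address": s.ta_position + 1,
            "orientation": s.orientation,
            "libraries": "|".join(sorted(f"{e}:{i}" for e, i in s.libraries)),
            "read_count": s.read_count, "percent_of_reads": s.percent_of_reads,
        }
        for tp in profiles
        for s in tp.clonal_sites
    ]
    return pd.DataFrame(rows, columns=["tumor_id", "chrom", "address", "orientation",
                                       "libraries", "read_count", "percent_of_reads"])


def table_to_merged(df: pd.DataFrame) -> list[TumorProfile]:
    profiles: dict[str, TumorProfile] = {}
    for r in df.itertuples():
        tp = profiles.setdefault(str(r.tumor_id), TumorProfile(str(r.tumor_id), []))
        libs = frozenset(tuple(x.split(":")) for x in str(r.libraries).split("|"))
        tp.clonal_sites.append(
            MergedSite(str(r.tumor_id), str(r.chrom), int(r.address) - 1,
                       str(r.orientation), libs, float(r.percent_of_reads),
                       int(r.read_count))
        )
    return [profiles[t] for t in sorted(profiles)]


def cutoffs_to_table(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=[
        "tumor_id", "enzyme", "ir_end", "nb_size", "nb_prob", "nb_sse",
        "nb_cutoff", "topsite_cutoff", "totalreads_cutoff", "applied_cutoff",
        "method_applied",
    ])


class _CachingAligner:
    """Aligns each distinct segment once (reads from one site share sequences)."""

    def __init__(self, genome: Genome):
        self.genome = genome
        self.cache: dict[str, tuple] = {}

    def __call__(self, segment: str):
        if segment not in self.cache:
            self.cache[segment] = toy_align(segment, self.genome)
        return self.cache[segment]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the machine-readable run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__, "seed": config.seed,
        "config_hash": config.config_hash(), "stages": {},
    }
    for path_attr in ("reads", "barcodes", "genome"):
        if not Path(getattr(config, path_attr)).exists():
            raise FileNotFoundError(f"{path_attr} file not found: "
                                    f"{getattr(config, path_attr)}")

    genome = Genome.from_fasta(config.genome)
    specs = parse_barcode_table(config.barcodes)
    reads = list(read_sequences(config.reads))
    report["stages"]["input_reads"] = len(reads)

    assigned, unassigned = demultiplex(reads, specs)
    report["stages"]["demux_assigned"] = sum(len(v) for v in assigned.values())
    report["stages"]["demux_unassigned"] = len(unassigned)

    sam_hits = None
    if config.aligner_sam:
        from .formats_io import read_sam_alignments
        sam_hits = read_sam_alignments(config.aligner_sam, genome)
    aligner = _CachingAligner(genome)

    profiles = []
    n_trimmed = n_rejected = n_accepted = 0
    reject_rows = []
    for spec in specs:
        trimmed, rejected = process_library(
            assigned[spec], spec, config.flank_mismatches, config.min_segment
        )
        n_trimmed += len(trimmed)
        n_rejected += len(rejected)
        reject_rows.extend({"read_id": r.read_id, "reason": r.reason} for r in rejected)
        accepted: list[AcceptedRead] = []
        for tr in trimmed:
            if sam_hits is not None:
                hits = sam_hits.get(tr.read_id, [])
                best = hits[0] if hits else None
                second = hits[1] if len(hits) > 1 else None
            else:
                best, second = aligner(tr.genomic_segment)
            acc = filter_read(tr, best, second)
            if acc is not None:
                accepted.append(acc)
        n_accepted += len(accepted)
        profiles.append(aggregate_sites(accepted, genome, spec.tumor_id, spec.library))
    report["stages"]["trimmed_reads"] = n_trimmed
    report["stages"]["rejected_reads"] = n_rejected
    report["stages"]["aligned_accepted_reads"] = n_accepted
    pd.DataFrame(reject_rows, columns=["read_id", "reason"]).to_csv(
        out / "rejects.tsv", sep="\t", index=False)
    sites_df = profiles_to_table(profiles)
    sites_df.to_csv(out / "sites.tsv", sep="\t", index=False)
    report["stages"]["library_sites"] = len(sites_df)

    by_tumor: dict[str, list] = {}
    for p in profiles:
        by_tumor.setdefault(p.tumor_id, []).append(p)
    tumor_profiles: list[TumorProfile] = []
    cutoff_rows = []
    for tumor in sorted(by_tumor):
        tp, cutoffs = clonal_profiles_for_tumor(by_tumor[tumor], config.donor_chrom)
        tumor_profiles.append(tp)
        for prof, c in zip(by_tumor[tumor], cutoffs):
            cutoff_rows.append({
                "tumor_id": tumor, "enzyme": prof.library[0], "ir_end": prof.library[1],
                "nb_size": c.nb_fit.size if c.nb_fit else None,
                "nb_prob": c.nb_fit.prob if c.nb_fit else None,
                "nb_sse": c.nb_fit.sse if c.nb_fit else None,
                "nb_cutoff": c.nb_cutoff, "topsite_cutoff": c.topsite_cutoff,
                "totalreads_cutoff": c.totalreads_cutoff,
                "applied_cutoff": c.applied_cutoff, "method_applied": c.method_applied,
            })
    cutoffs_to_table(cutoff_rows).to_csv(out / "cutoffs.tsv", sep="\t", index=False)
    merged_df = merged_to_table(tumor_profiles)
    merged_df.to_csv(out / "clonal.tsv", sep="\t", index=False)
    report["stages"]["clonal_sites"] = len(merged_df)

    if config.refflat:
        transcripts = parse_refflat(config.refflat)
        ta_index = TAIndex(genome)
        regions = build_gene_regions(transcripts, genome.chrom_lengths, ta_index)
        exclude = (config.donor_chrom,) if config.donor_chrom else ()
        records = gcis_test(tumor_profiles, regions, genome, alpha=config.alpha,
                            min_tumors=config.min_tumors, exclude_chroms=exclude,
                            ta_index=ta_index)
        gcis_to_table(records, config.alpha).to_csv(out / "gcis.tsv", sep="\t",
                                                    index=False)
        report["stages"]["gcis_genes_tested"] = len(records)
        report["stages"]["gcis_significant"] = sum(r.significant for r in records)

        from .formats_io import AnnotatedSite, write_annotation_table
        from .gcis import annotate_insertion

        annotated = [
            AnnotatedSite(
                tumor_id=tp.tumor_id,
                chromosome=s.chrom, ta_position=s.ta_position,
                percent_of_reads=s.percent_of_reads,
                **annotate_insertion(s, transcripts),
            )
            for tp in tumor_profiles
            for s in tp.clonal_sites
        ]
        write_annotation_table(annotated, out / "annotations.tsv")
        report["stages"]["annotated_sites"] = len(annotated)

    (out / "run_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
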