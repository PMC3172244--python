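"""Truth-labeled synthetic data: genome, gene models, cohorts and raw reads.

Emulates the statistical structure of a Sleeping Beauty tumor cohort so the
whole pipeline is testable without downloads: a small random genome with
controllable TA and restriction-motif densities; refFlat gene models; per
tumor a handful of clonally expanded insertions (some recurrently planted
in designated CIS genes across several tumors, some on the donor
chromosome as local-hopping decoys) over many low-count background
insertions whose read counts follow a shifted negative binomial; and raw
LM-PCR amplicon reads (barcode + transposon flank + TA-starting genomic
junction of 40-45 bases) honouring per-library restriction-fragment
feasibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .align_filter import revcomp
from .formats_io import (
    BarcodeSpec, GeneTranscript, Genome, SequenceRead,
    write_barcode_table, write_refflat,
)
from .gcis import TAIndex, build_gene_regions
from .pcr_bias import MotifIndex, fragment_length

DEFAULT_FLANKS = {"IRL": "TGTATGTAAACTTCCGACTTCAACTG", "IRR": "GGATTAAATGTCAGGAATTGTGAAAA"}
DEFAULT_JUNCTION_RANGE = (40, 45)
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedSite:
    """One truth insertion: where it is and how abundant it should look."""

    tumor_id: str
    chrom: str
    ta_position: int
    orientation: str
    fraction: float  # intended fraction of library reads (clonal) or 0 (background)
    is_clonal: bool
    cis_gene: str | None = None


@dataclass
class SyntheticTruth:
    """Complete generative record of one synthetic cohort."""

    genome: Genome
    transcripts: list[GeneTranscript]
    barcode_specs: list[BarcodeSpec]
    donor_chrom: str
    nb_size: float
    nb_prob: float
    seed: int
    clonal_sites: dict[str, list[PlantedSite]] = field(default_factory=dict)
    background_sites: dict[str, list[PlantedSite]] = field(default_factory=dict)
    cis_genes: dict[str, list[str]] = field(default_factory=dict)

    @property
    def tumor_ids(self) -> list[str]:
        return sorted(self.clonal_sites)

    def planted_clonal_keys(self, tumor_id: str, exclude_donor: bool = True) -> set:
        """(chrom, ta_position, orientation) of planted clonal sites."""
        return {
            (s.chrom, s.ta_position, s.orientation)
            for s in self.clonal_sites[tumor_id]
            if not (exclude_donor and s.chrom == self.donor_chrom)
        }

    def to_json(self, path: str | Path) -> None:
        def site_dict(s: PlantedSite) -> dict:
            return {
                "tumor_id": s.tumor_id, "chrom": s.chrom,
                "ta_position": s.ta_position, "orientation": s.orientation,
                "fraction": s.fraction, "is_clonal": s.is_clonal,
                "cis_gene": s.cis_gene,
            }

        payload = {
            "donor_chrom": self.donor_chrom, "nb_size": self.nb_size,
            "nb_prob": self.nb_prob, "seed": self.seed,
            "cis_genes": self.cis_genes,
            "clonal_sites": {t: [site_dict(s) for s in v]
                             for t, v in self.clonal_sites.items()},
            "background_sites": {t: [site_dict(s) for s in v]
                                 for t, v in self.background_sites.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @staticmethod
    def sites_from_json(path: str | Path) -> dict:
        return json.loads(Path(path).read_text())


def make_genome(
    n_chroms: int = 3,
    chrom_length: int = 30_000,
    ta_density_bias: float = 1.0,
    motif_spacing: int | None = 60,
    seed: int = 0,
    donor_chrom_index: int = 0,
) -> tuple[Genome, str]:
    """Random genome with tunable TA and restriction-motif densities.

    Bases are drawn i.i.d. uniformly (natural TA density ~1/16 per
    position); ``ta_density_bias`` > 1 plants extra TA dinucleotides to
    multiply that density.  When ``motif_spacing`` is given, AGCT and CATG
    recognition sites are planted with geometric gaps of that mean, so
    restriction fragments are short enough to amplify.  One chromosome is
    designated the transposon donor.  Deterministic per seed.
    """
    if ta_density_bias <= 0:
        raise ValueError("ta_density_bias must be positive")
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    for i in range(n_chroms):
        arr = BASES[rng.integers(0, 4, size=chrom_length)]
        if ta_density_bias > 1:
            extra = (ta_density_bias - 1) / 16.0
            n_extra = rng.binomial(chrom_length - 1, extra)
            for p in rng.integers(0, chrom_length - 1, size=n_extra):
                arr[p] = ord("T")
                arr[p + 1] = ord("A")
        if motif_spacing is not None:
            for motif in (b"AGCT", b"CATG"):
                p = int(rng.integers(0, motif_spacing))
                while p + 4 <= chrom_length:
                    arr[p : p + 4] = np.frombuffer(motif, dtype=np.uint8)
                    p += 4 + int(rng.geometric(1.0 / motif_spacing))
        seqs[f"chr{i + 1}"] = arr.tobytes().decode()
    genome = Genome(seqs)
    donor = f"chr{donor_chrom_index + 1}"
    return genome, donor


def make_gene_models(
    genome: Genome,
    genes_per_chrom: int = 2,
    gene_length: int = 3_000,
    n_exons: int = 3,
    seed: int = 0,
) -> list[GeneTranscript]:
    """Evenly spaced single-transcript gene models on every chromosome."""
    rng = np.random.default_rng(seed)
    transcripts: list[GeneTranscript] = []
    idx = 0
    for chrom in sorted(genome.sequences):
        length = len(genome.sequences[chrom])
        slot = length // genes_per_chrom
        if slot < gene_length + 11_000:  # gene body + room for the 10 kb promoter
            raise ValueError("chromosome too short for requested gene layout")
        for g in range(genes_per_chrom):
            start = g * slot + 11_000  # leave room for the 10 kb promoter
            end = start + gene_length
            strand = "+" if rng.random() < 0.5 else "-"
            exon_len = gene_length // (2 * n_exons)
            starts, ends = [], []
            for e in range(n_exons):
                s = start + e * (gene_length // n_exons)
                starts.append(s)
                ends.append(min(s + exon_len, end))
            idx += 1
            transcripts.append(
                GeneTranscript(f"Gene{idx}", f"NM_{idx:06d}", chrom, strand,
                               start, end, tuple(starts), tuple(ends))
            )
    return transcripts


def default_barcode_specs(tumor_ids: Sequence[str]) -> list[BarcodeSpec]:
    """One 6-base barcode per (tumor, enzyme, IR-end) library."""
    alphabet = "ACGT"
    specs: list[BarcodeSpec] = []
    i = 0
    for tumor in tumor_ids:
        for enzyme in ("AluI", "NlaIII"):
            for ir_end in ("IRL", "IRR"):
                # base-4 encoding of the library index guarantees uniqueness
                barcode = "".join(alphabet[(i // 4**k) % 4] for k in range(6))
                specs.append(
                    BarcodeSpec(barcode, tumor, ir_end, enzyme, DEFAULT_FLANKS[ir_end])
                )
                i += 1
    return specs


def _sample_ta(rng, ta_pool: list[tuple[str, int]], used: set) -> tuple[str, int]:
    while True:
        chrom, pos = ta_pool[int(rng.integers(0, len(ta_pool)))]
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            return chrom, pos


def make_cohort(
    genome: Genome,
    transcripts: Sequence[GeneTranscript],
    donor_chrom: str,
    n_tumors: int = 12,
    n_cis_genes: int = 4,
    cis_recurrence: int = 6,
    clonal_per_tumor: int = 8,
    background_per_tumor: int = 200,
    donor_decoys_per_tumor: int = 3,
    nb_size: float = 0.5,
    nb_prob: float = 0.3,
    clonal_fraction_total: float = 0.7,
    clonal_spread: float = 20.0,
    seed: int = 0,
) -> SyntheticTruth:
    """Plant a truth cohort over the synthetic genome.

    Each designated CIS gene receives one clonal insertion in
    ``cis_recurrence`` distinct tumors; remaining clonal insertions (plus
    donor-chromosome decoys that exercise local-hopping removal) land on
    TA sites outside all gene regions.  Clonal sites share
    ``clonal_fraction_total`` of each library's reads (the remainder is
    background, count-modelled as 1 + NB(nb_size, nb_prob) at read time).
    Clonal abundances are heterogeneous, as in real tumors: intended
    fractions follow a geometric ladder whose largest/smallest ratio is
    ``clonal_spread``, so shallow sequencing misses the low-abundance tail
    first while the 1%-of-top cutoff still clears every planted site.
    """
    rng = np.random.default_rng(seed)
    tumor_ids = [f"T{i + 1:02d}" for i in range(n_tumors)]
    ta_index = TAIndex(genome)
    regions = build_gene_regions(list(transcripts), genome.chrom_lengths, ta_index)
    candidates = [r for r in regions if r.chrom != donor_chrom and r.ta_count >= 5]
    if len(candidates) < n_cis_genes:
        raise ValueError("not enough candidate genes off the donor chromosome")
    cis_regions = [candidates[i] for i in
                   rng.choice(len(candidates), size=n_cis_genes, replace=False)]

    # TA pools: inside each CIS gene region; intergenic (outside all regions)
    def region_tas(region) -> list[tuple[str, int]]:
        pos = ta_index.positions[region.chrom]
        out = []
        for a, b in region.intervals:
            lo = np.searchsorted(pos, a, side="left")
            hi = np.searchsorted(pos, b - 2, side="right")
            out.extend((region.chrom, int(p)) for p in pos[lo:hi])
        return out

    all_region_tas: set = set()
    for r in regions:
        all_region_tas.update(region_tas(r))
    intergenic = [
        (c, int(p)) for c in sorted(genome.sequences) if c != donor_chrom
        for p in ta_index.positions[c] if (c, int(p)) not in all_region_tas
    ]
    donor_tas = [(donor_chrom, int(p)) for p in ta_index.positions[donor_chrom]]

    truth = SyntheticTruth(
        genome=Genome(genome.sequences), transcripts=list(transcripts),
        barcode_specs=default_barcode_specs(tumor_ids), donor_chrom=donor_chrom,
        nb_size=nb_size, nb_prob=nb_prob, seed=seed,
    )
    used: set = set()
    clonal: dict[str, list[PlantedSite]] = {t: [] for t in tumor_ids}

    for region in cis_regions:
        chosen = rng.choice(n_tumors, size=min(cis_recurrence, n_tumors), replace=False)
        gene_tas = region_tas(region)
        truth.cis_genes[region.gene_name] = sorted(tumor_ids[i] for i in chosen)
        for i in chosen:
            chrom, pos = _sample_ta(rng, gene_tas, used)
            orient = "+" if rng.random() < 0.5 else "-"
            clonal[tumor_ids[i]].append(
                PlantedSite(tumor_ids[i], chrom, pos, orient, 0.0, True,
                            region.gene_name)
            )

    for tumor in tumor_ids:
        while len([s for s in clonal[tumor] if s.chrom != donor_chrom]) < clonal_per_tumor:
            chrom, pos = _sample_ta(rng, intergenic, used)
            orient = "+" if rng.random() < 0.5 else "-"
            clonal[tumor].append(PlantedSite(tumor, chrom, pos, orient, 0.0, True))
        for _ in range(donor_decoys_per_tumor):
            chrom, pos = _sample_ta(rng, donor_tas, used)
            orient = "+" if rng.random() < 0.5 else "-"
            clonal[tumor].append(PlantedSite(tumor, chrom, pos, orient, 0.0, True))
        # geometric ladder of intended fractions summing to clonal_fraction_total
        n = len(clonal[tumor])
        ratio = clonal_spread ** (1.0 / (n - 1)) if n > 1 else 1.0
        weights = np.array([ratio ** i for i in range(n)])
        fracs = clonal_fraction_total * weights / weights.sum()
        order = rng.permutation(n)  # abundance uncorrelated with CIS status
        clonal[tumor] = [
            PlantedSite(s.tumor_id, s.chrom, s.ta_position, s.orientation,
                        float(fracs[order[i]]), True, s.cis_gene)
            for i, s in enumerate(clonal[tumor])
        ]
    truth.clonal_sites = clonal

    # background positions are unique within a tumor but may recur between
    # tumors (ongoing transposition hits TA sites independently per animal);
    # background_per_tumor counts the off-donor sites that survive removal,
    # with an extra 10% planted on the donor chromosome to exercise it
    background: dict[str, list[PlantedSite]] = {t: [] for t in tumor_ids}
    n_donor_bg = background_per_tumor // 10
    if (background_per_tumor > len(intergenic) // 2
            or n_donor_bg > len(donor_tas) // 2):
        raise ValueError("background_per_tumor too large for the genome's TA pool")
    for tumor in tumor_ids:
        tumor_used = set(used)
        for pool, n in ((intergenic, background_per_tumor), (donor_tas, n_donor_bg)):
            for _ in range(n):
                chrom, pos = _sample_ta(rng, pool, tumor_used)
                orient = "+" if rng.random() < 0.5 else "-"
                background[tumor].append(
                    PlantedSite(tumor, chrom, pos, orient, 0.0, False))
    truth.background_sites = background
    return truth


def _read_strand(orientation: str, ir_end: str) -> str:
    """Genomic strand a junction read maps to (inverse of orientation calling)."""
    if ir_end == "IRR":
        return orientation
    return "-" if orientation == "+" else "+"


def _junction_segment(genome: Genome, chrom: str, t: int, strand: str, length: int) -> str | None:
    seq = genome.sequences[chrom]
    if strand == "+":
        seg = seq[t : t + length]
    else:
        seg = revcomp(seq[max(0, t + 2 - length) : t + 2])
    return seg if len(seg) >= 2 else None


def _mutate(seq: str, rate: float, rng) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGT"[(("ACGT".index(out[i]) + 1 + int(rng.integers(0, 3))) % 4)]
    return "".join(out)


def make_reads(
    truth: SyntheticTruth,
    reads_per_library: int = 2_000,
    junction_length_range: tuple[int, int] = DEFAULT_JUNCTION_RANGE,
    flank_error_rate: float = 0.0,
    min_fragment: int = 20,
    max_fragment: int = 500,
    respect_fragments: bool = True,
    seed: int | None = None,
) -> list[SequenceRead]:
    """Emit LM-PCR amplicon reads for every library of the cohort.

    Per library, clonal sites receive round(fraction x reads_per_library)
    reads (rounding residue goes to the most abundant clonal site) and each
    background site 1 + NB(nb_size, nb_prob) reads.  No read is emitted for
    a library whose restriction fragment at the site is missing or outside
    [min_fragment, max_fragment] — the amplifiable range; junction segments
    are clipped to the fragment.  ``respect_fragments=False`` disables the
    constraint (an idealized digest where every junction amplifies).
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    motif_index = MotifIndex(truth.genome) if respect_fragments else None
    lo, hi = junction_length_range
    reads: list[SequenceRead] = []
    for spec in truth.barcode_specs:
        enzyme, ir_end = spec.enzyme, spec.ir_end
        sites = []
        planted = truth.clonal_sites[spec.tumor_id]
        counts = [int(round(s.fraction * reads_per_library)) for s in planted]
        if counts:
            target = int(round(sum(s.fraction for s in planted) * reads_per_library))
            counts[int(np.argmax(counts))] += target - sum(counts)
        for s, n in zip(planted, counts):
            sites.append((s, n))
        for s in truth.background_sites[spec.tumor_id]:
            n = 1 + int(rng.negative_binomial(truth.nb_size, truth.nb_prob))
            sites.append((s, n))
        for site_i, (s, n) in enumerate(sites):
            if n <= 0:
                continue
            if respect_fragments:
                frag = fragment_length(
                    truth.genome, s.chrom, s.ta_position, s.orientation,
                    enzyme, ir_end, motif_index,
                )
                if frag is None or frag < min_fragment or frag > max_fragment:
                    continue  # library cannot amplify this junction
            else:
                frag = hi
            strand = _read_strand(s.orientation, ir_end)
            for k in range(n):
                length = min(int(rng.integers(lo, hi + 1)), frag)
                seg = _junction_segment(truth.genome, s.chrom, s.ta_position,
                                        strand, length)
                if seg is None:
                    continue
                flank = _mutate(spec.expected_flank, flank_error_rate, rng)
                reads.append(
                    SequenceRead(
                        f"{spec.label}_s{site_i}_r{k}",
                        spec.barcode + flank + seg,
                    )
                )
    return reads


def make_library_profiles(
    truth: SyntheticTruth,
    reads_per_library: int = 20_000,
    respect_fragments: bool = False,
    min_fragment: int = 20,
    max_fragment: int = 500,
    seed: int | None = None,
):
    """Build count-level library profiles directly from the truth.

    Skips read synthesis and alignment: each library gets its clonal counts
    (fraction x reads_per_library, residue to the top site) and per-site
    background counts drawn 1 + NB(nb_size, nb_prob).  With
    ``respect_fragments`` a site is dropped from libraries that cannot
    amplify its junction, as in :func:`make_reads`.  Useful for exercising
    the clonality, gCIS and depth-simulation stages at realistic depths.
    """
    from .align_filter import InsertionSite, LibraryProfile

    rng = np.random.default_rng(truth.seed if seed is None else seed)
    motif_index = MotifIndex(truth.genome) if respect_fragments else None
    profiles = []
    for spec in truth.barcode_specs:
        planted = truth.clonal_sites[spec.tumor_id]
        counts = [int(round(s.fraction * reads_per_library)) for s in planted]
        if counts:
            target = int(round(sum(s.fraction for s in planted) * reads_per_library))
            counts[int(np.argmax(counts))] += target - sum(counts)
        pairs = list(zip(planted, counts))
        pairs += [
            (s, 1 + int(rng.negative_binomial(truth.nb_size, truth.nb_prob)))
            for s in truth.background_sites[spec.tumor_id]
        ]
        sites = []
        for s, n in pairs:
            if n <= 0:
                continue
            if respect_fragments:
                frag = fragment_length(
                    truth.genome, s.chrom, s.ta_position, s.orientation,
                    spec.enzyme, spec.ir_end, motif_index,
                )
                if frag is None or frag < min_fragment or frag > max_fragment:
                    continue
            sites.append(
                InsertionSite(spec.tumor_id, s.chrom, s.ta_position,
                              s.orientation, spec.library, n, 0.0)
            )
        profile = LibraryProfile(spec.tumor_id, spec.library, sites,
                                 sum(s.read_count for s in sites))
        profile.recompute_percentages()
        profiles.append(profile)
    return profiles


def write_fastq(reads: Sequence[SequenceRead], path: str | Path) -> None:
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for r in reads:
            qual = r.quality or "I" * len(r.sequence)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def generate_dataset(
    out_dir: str | Path,
    preset: str = "smoke",
    seed: int = 7,
) -> SyntheticTruth:
    """Emit genome.fa, genes.refflat, barcodes.tsv, reads.fastq.gz, truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if preset == "smoke":
        genome, donor = make_genome(n_chroms=3, chrom_length=12_000, seed=seed)
        transcripts = make_gene_models(genome, genes_per_chrom=1, gene_length=800,
                                       seed=seed)
        truth = make_cohort(
            genome, transcripts, donor, n_tumors=4, n_cis_genes=1,
            cis_recurrence=3, clonal_per_tumor=3, background_per_tumor=30,
            donor_decoys_per_tumor=1, seed=seed,
        )
        reads = make_reads(truth, reads_per_library=300, seed=seed)
    elif preset == "cohort":
        genome, donor = make_genome(n_chroms=4, chrom_length=40_000, seed=seed)
        transcripts = make_gene_models(genome, genes_per_chrom=2, seed=seed)
        truth = make_cohort(genome, transcripts, donor, seed=seed)
        reads = make_reads(truth, reads_per_library=2_000, seed=seed)
    else:
        raise ValueError(f"unknown preset {preset!r}")
    truth.genome.to_fasta(out / "genome.fa")
    write_refflat(truth.transcripts, out / "genes.refflat")
    write_barcode_table(truth.barcode_specs, out / "barcodes.tsv")
    write_fastq(reads, out / "reads.fastq.gz")
    truth.to_json(out / "truth.json")
    (out / "donor_chrom.txt").write_text(truth.donor_chrom + "\n")
    return truth
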