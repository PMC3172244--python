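import numpy as np
import pytest

from sbcis.clonality import MergedSite, TumorProfile, clonal_profiles_for_tumor
from sbcis.formats_io import GeneTranscript, Genome
from sbcis.gcis import (
    TAIndex, annotate_insertion, build_gene_regions, count_ta_sites,
    gcis_chi_square, gcis_test, significant_genes, ta_positions,
)
from sbcis.synthetic_data import make_genome, make_library_profiles

from .oracles import count_ta, two_cell_chi_square

LIBS = frozenset([("AluI", "IRL"), ("AluI", "IRR"), ("NlaIII", "IRL")])


def tx(gene, chrom, strand, start, end, exons=None):
    exons = exons or [(start, end)]
    return GeneTranscript(gene, f"{gene}_tx", chrom, strand, start, end,
                          tuple(s for s, _ in exons), tuple(e for _, e in exons))


def merged(tumor, chrom, pos, orient="+"):
    return MergedSite(tumor, chrom, pos, orient, LIBS, 10.0, 500)


class TestGeneRegions:
    LENGTHS = {"chr1": 20_000, "chr2": 2_000_000}

    def test_union_with_promoter_clipped_at_zero(self):
        txs = [tx("G", "chr1", "+", 100, 500), tx("G", "chr1", "+", 300, 900)]
        (region,) = build_gene_regions(txs, self.LENGTHS)
        assert region.intervals == ((0, 900),)

    def test_plus_strand_promoter_extends_left(self):
        (region,) = build_gene_regions([tx("G", "chr1", "+", 20_000, 21_000)],
                                       {"chr1": 30_000})
        assert region.intervals == ((10_000, 21_000),)

    def test_minus_strand_promoter_extends_right(self):
        (region,) = build_gene_regions([tx("G", "chr1", "-", 100, 500)],
                                       {"chr1": 20_000})
        assert region.intervals == ((100, 10_500),)

    def test_multi_chrom_gene_skipped(self):
        txs = [tx("G", "chr1", "+", 100, 500), tx("G", "chr2", "+", 100, 500)]
        with pytest.warns(UserWarning, match="skipped"):
            regions = build_gene_regions(txs, self.LENGTHS)
        assert regions == []


class TestTACounting:
    def test_direct_count(self):
        genome = Genome({"c": "TATAAT"})
        assert count_ta_sites(genome, "c") == 2
        assert list(ta_positions("TATAAT")) == [0, 2]

    def test_no_ta(self):
        assert count_ta_sites(Genome({"c": "GGGGGG"}), "c") == 0

    def test_matches_naive_scan_on_random_genome(self):
        genome, _ = make_genome(n_chroms=1, chrom_length=100_000, seed=3)
        seq = genome.sequences["chr1"]
        assert count_ta_sites(genome, "chr1") == count_ta(seq)
        index = TAIndex(genome)
        for a, b in [(0, 1000), (537, 9_312), (99_000, 100_000)]:
            assert index.count_in("chr1", [(a, b)]) == count_ta(seq, a, b)


class TestChiSquare:
    def test_worked_example(self):
        # O=10, E=2, N=1000: (8^2)/2 + (8^2)/998 = 32 + 64/998
        assert gcis_chi_square(10, 2.0, 1000) == pytest.approx(32 + 64 / 998)

    def test_matches_independent_two_cell_computation(self):
        from scipy.stats import chi2

        for o, e, n in [(10, 2.0, 1000), (3, 7.5, 200), (50, 12.3, 5000)]:
            stat = gcis_chi_square(o, e, n)
            oracle_stat, oracle_p = two_cell_chi_square(o, e, n)
            assert stat == pytest.approx(oracle_stat, rel=1e-9)
            assert float(chi2.sf(stat, 1)) == pytest.approx(oracle_p, rel=1e-9)


@pytest.fixture(scope="module")
def flat_genome():
    # all-TA chromosome: uniform target density, easy expectations
    return Genome({"chr1": "TA" * 50_000})


class TestGCISTest:
    def test_three_tumor_recurrence_floor(self, flat_genome):
        txs = [tx("Hit6", "chr1", "+", 20_000, 22_000),
               tx("Hit2", "chr1", "+", 60_000, 62_000)]
        regions = build_gene_regions(txs, flat_genome.chrom_lengths,
                                     TAIndex(flat_genome))
        profiles = []
        for i in range(12):
            t = f"T{i:02d}"
            sites = []
            if i < 6:  # recurrent gene: 1 insertion in 6 tumors
                sites.append(merged(t, "chr1", 20_500 + 2 * i))
            if i < 2:  # same burden but only 2 tumors: below the floor
                sites.append(merged(t, "chr1", 60_500 + 2 * i))
                sites.append(merged(t, "chr1", 60_600 + 2 * i))
                sites.append(merged(t, "chr1", 60_700 + 2 * i))
            profiles.append(TumorProfile(t, sites))
        records = gcis_test(profiles, regions, flat_genome)
        by_gene = {r.gene_name: r for r in records}
        assert by_gene["Hit6"].significant
        assert by_gene["Hit6"].n_tumors == 6
        assert not by_gene["Hit2"].significant  # recurrence floor despite burden
        assert by_gene["Hit2"].n_tumors == 2

    def test_insertion_in_overlapping_genes_counts_for_both(self, flat_genome):
        txs = [tx("A", "chr1", "+", 30_000, 34_000),
               tx("B", "chr1", "+", 32_000, 36_000)]
        regions = build_gene_regions(txs, flat_genome.chrom_lengths,
                                     TAIndex(flat_genome))
        profiles = [TumorProfile("T1", [merged("T1", "chr1", 32_500)])]
        records = gcis_test(profiles, regions, flat_genome)
        assert [r.observed for r in records] == [1, 1]

    def test_gene_without_ta_excluded(self):
        genome = Genome({"chr1": "TA" * 5_000 + "GC" * 10_000 + "TA" * 5_000})
        txs = [tx("NoTA", "chr1", "+", 22_000, 24_000)]  # inside the GC desert
        regions = build_gene_regions(txs, genome.chrom_lengths, TAIndex(genome))
        records = gcis_test([TumorProfile("T1", [])], regions, genome)
        assert records == []

    def test_family_wise_error_control_under_null(self, gcis_truth):
        """Uniform TA placement: Bonferroni keeps the per-gene hit rate <= alpha."""
        truth = gcis_truth
        genome = truth.genome
        index = TAIndex(genome)
        regions = build_gene_regions(truth.transcripts, genome.chrom_lengths, index)
        tumors = [f"T{i:02d}" for i in range(12)]
        n_hits = 0
        n_tests = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            profiles = {t: TumorProfile(t, []) for t in tumors}
            chroms = sorted(genome.sequences)
            weights = np.array([len(index.positions[c]) for c in chroms], float)
            for i in range(400):
                c = chroms[rng.choice(len(chroms), p=weights / weights.sum())]
                pos = int(index.positions[c][rng.integers(0, len(index.positions[c]))])
                t = tumors[i % len(tumors)]
                profiles[t].clonal_sites.append(merged(t, c, pos))
            records = gcis_test(list(profiles.values()), regions, genome,
                                ta_index=index)
            n_tests += len(records)
            bonf = 0.05 / len(records)
            n_hits += sum(r.p_value <= bonf for r in records)
        assert n_hits / n_tests <= 0.05

    def test_planted_cis_genes_are_exactly_the_significant_set(self, gcis_truth):
        truth = gcis_truth
        profiles = make_library_profiles(truth, reads_per_library=100_000, seed=5)
        by_tumor = {}
        for p in profiles:
            by_tumor.setdefault(p.tumor_id, []).append(p)
        tumor_profiles = [
            clonal_profiles_for_tumor(libs, truth.donor_chrom)[0]
            for libs in by_tumor.values()
        ]
        index = TAIndex(truth.genome)
        regions = build_gene_regions(truth.transcripts,
                                     truth.genome.chrom_lengths, index)
        records = gcis_test(tumor_profiles, regions, truth.genome,
                            exclude_chroms=(truth.donor_chrom,), ta_index=index)
        assert significant_genes(records) == set(truth.cis_genes)
        for r in records:
            if r.significant:
                assert r.observed > r.expected and r.n_tumors >= 3


class TestAnnotateInsertion:
    TXS = [tx("G", "chr1", "+", 50_000, 56_000,
              exons=[(50_000, 51_000), (52_000, 53_000), (55_000, 56_000)])]

    def ann(self, pos, orient="+"):
        return annotate_insertion(merged("T1", "chr1", pos, orient), self.TXS)

    def test_exonic_sense_insertion(self):
        a = self.ann(52_500)
        assert (a["gene_region_hit"], a["orientation_vs_gene"],
                a["distance_from_gene"]) == ("exon", "sense", 0)

    def test_first_intron_sense_is_activating(self):
        a = self.ann(51_500)
        assert a["gene_region_hit"] == "intron"
        assert a["predicted_effect"] == "activating"

    def test_later_intron_is_disrupting(self):
        assert self.ann(54_000)["predicted_effect"] == "disrupting"

    def test_promoter_insertion_with_distance(self):
        a = self.ann(46_000)
        assert a["gene_region_hit"] == "promoter"
        assert a["distance_from_gene"] == 4_000
        assert a["predicted_effect"] == "activating"

    def test_antisense_promoter_not_activating(self):
        assert self.ann(46_000, orient="-")["predicted_effect"] == "disrupting"

    def test_far_insertion_intergenic_with_nearest_gene(self):
        a = self.ann(500_000)
        assert a["gene_region_hit"] == "intergenic"
        assert a["gene_name"] == "G"
        assert a["predicted_effect"] == "none"
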