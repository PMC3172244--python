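import numpy as np
import pytest

from sbcis.formats_io import Genome
from sbcis.synthetic_data import (
    make_cohort, make_gene_models, make_genome, make_library_profiles,
)


@pytest.fixture(scope="session")
def small_genome():
    """Random 3 x 30 kb genome with planted restriction motifs."""
    genome, donor = make_genome(n_chroms=3, chrom_length=30_000, seed=11)
    return genome, donor


@pytest.fixture(scope="session")
def cohort_truth(small_genome):
    """Default 12-tumor cohort on the small genome."""
    genome, donor = small_genome
    transcripts = make_gene_models(genome, seed=11)
    return make_cohort(genome, transcripts, donor, seed=11)


@pytest.fixture(scope="session")
def separated_profiles(cohort_truth):
    """Library profiles at saturating depth: clonal counts dwarf background."""
    return make_library_profiles(cohort_truth, reads_per_library=100_000, seed=11)


@pytest.fixture(scope="session")
def depth_truth():
    """Cohort with paper-like background load: ~95% of sites are background
    carrying ~30% of reads, so depth subsampling behaves like real libraries."""
    genome, donor = make_genome(n_chroms=3, chrom_length=100_000, seed=23)
    transcripts = make_gene_models(genome, seed=23)
    return make_cohort(genome, transcripts, donor, n_tumors=6, n_cis_genes=2,
                       cis_recurrence=3, clonal_per_tumor=8,
                       background_per_tumor=3_000, seed=23)


@pytest.fixture(scope="session")
def depth_profiles(depth_truth):
    return make_library_profiles(depth_truth, reads_per_library=25_000, seed=23)


@pytest.fixture(scope="session")
def gcis_truth():
    """Sparse-gene cohort: each gene region ~1% of the genome, for gCIS power."""
    genome, donor = make_genome(n_chroms=4, chrom_length=500_000,
                                motif_spacing=80, seed=5)
    transcripts = make_gene_models(genome, genes_per_chrom=2, gene_length=2_000,
                                   seed=5)
    return make_cohort(genome, transcripts, donor, n_tumors=12, n_cis_genes=3,
                       cis_recurrence=6, clonal_per_tumor=8,
                       background_per_tumor=100, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def toy_genome():
    """Hand-written two-chromosome genome for exact-coordinate tests."""
    chr1 = ("ACGT" * 10) + "TA" + ("GGCC" * 10) + "AGCT" + ("AT" * 10) + "CATG"
    chr2 = "CCCC" + "TA" + "GGGGGGGG" + "TA" + "AAAA"
    return Genome({"chr1": chr1, "chr2": chr2})
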