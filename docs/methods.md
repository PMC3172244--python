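# Methods

This note documents the models and procedures implemented in `sbcis`, the
choices made where the design was genuinely open, and what the synthetic
data does and does not establish about real screens.

## Amplicon model and read processing

A Sleeping Beauty LM-PCR amplicon is assumed to have fixed structure:
6-base sample barcode at position 0, the transposon inverted-repeat flank
immediately after, then the genomic junction beginning with the TA
dinucleotide that SB duplicates on integration. Because the structure is
fixed, flank location uses exact-position comparison with a substitution
budget instead of local alignment; reads whose flank carries indels are
rejected, which is conservative. Defaults: barcode matching exact (6-base
codes are short enough that tolerating errors risks cross-assignment);
flank budget 2 substitutions; minimum mappable junction 20 bases (the
shortest fragment the bias analysis treats as amplifiable). Base qualities
are carried through but never used — filtering happens on alignment
evidence, not on quality strings.

Alignment import accepts a SAM subset (read id, chromosome, 0-based
position, strand from FLAG 0x10, NM mismatch count), best-first per read;
the package never shells out to an aligner. The built-in exhaustive
aligner scans every end-to-end placement on both strands (substitutions
only, ≤ 3 mismatches, deterministic (mismatch, chrom, position, strand)
tie-break) and is intended for test-scale genomes only.

Percent identity is (aligned_length − mismatches)/aligned_length — the
natural definition for ungapped alignments. The "5% better than
second-best" rule is an absolute difference in identity points. Both
strands of a junction address the same TA: on the forward strand the TA is
at the alignment start, on the reverse strand it is the last two reference
bases (TA is its own reverse complement), so `ta_position` is canonical
and merging across libraries and transposon ends is exact. Transposon
orientation is `+` iff an IRR read maps forward or an IRL read maps
reverse; the synthetic read generator implements the inverse mapping, so
the convention is internally consistent (no external convention exists to
match).

## Dynamic clonality filtering

Background insertions — present in one or a few cells each — are modeled
by a shifted negative binomial over per-site read counts. The fit uses
sites with 1–3 reads: their zero-shifted counts k−1 ∈ {0,1,2} give
empirical proportions *relative to all sites in the library*, matched
against the untruncated NB pmf at k = 0, 1, 2 by least squares over a
(size, prob) grid with steps 0.01 and 0.001 (bounds [0.01, 10] ×
[0.001, 0.999], configurable). Proportions are taken over all sites so
that, on background-dominated libraries, they estimate the pmf itself;
ties break to the smallest (size, prob) lexicographically. The pmf grid is
precomputed once and cached, so repeated fits (depth simulation) cost a
few milliseconds each. With fewer than 50 background sites the NB method
is marked unavailable and contributes a cutoff of 0; the grid-fit argmin is
regression-checked against an independent log-gamma implementation.

Three points constrain two parameters, so the fitted (size, prob) pair has
a flat SSE valley: at 10,000 sites the recovered prob scatters by a few
hundredths around the truth while the derived threshold (the smallest c
with fitted CDF ≥ 0.95, reported unshifted as c + 1) is stable — the
threshold, not the parameters, is the decision quantity.

The applied cutoff is the maximum of the NB threshold, 1% of the top
site's reads, and 0.1% of total reads; sites must strictly exceed it
(sites at the estimated background level should not pass). Donor-
chromosome sites are removed *before* cutoffs are computed, and the four
libraries merge keyed by (chrom, ta_position, orientation), keeping the
maximum percent-of-reads and the contributing-library set (used later for
concordance).

## gCIS

The gene-associated region is the interval union of a gene's transcripts
plus 10 kb upstream of the 5′-most TSS (strand-aware, clipped at
chromosome bounds); genes whose transcripts span chromosomes or strands
are skipped. With N clonal insertions cohort-wide, T_g TA sites in the
region and T_genome genome-wide, E_g = N·T_g/T_genome (equivalently the
sum of per-tumor expectations), and the two-cell goodness-of-fit
chi-square on (in-gene, out-of-gene) honors the single degree of freedom.
Choices: every clonal site counts once per overlapping gene region;
recurrence is counted in distinct tumors; only enrichment (O_g > E_g) can
be significant; the Bonferroni divisor is the number of genes actually
tested (genes with zero TA content are excluded from testing and from G);
T_genome excludes the donor chromosome whenever donor sites were excluded
from the profiles, keeping numerator and denominator consistent. The
annotation rule table (promoter/first-intron sense → "activating",
other intragenic or antisense → "disrupting", intergenic → "none") is a
configurable heuristic; only the region assignment, not the effect label,
feeds the statistics.

## Depth simulation

Reads are pooled cohort-wide (each entry keeps its tumor, library and map
location) and drawn with replacement — achieved per-tumor depth therefore
varies around the target, matching an "average reads per sample" design;
a stratified per-tumor mode is available. Per depth and iteration the full
clonality stage is re-run via a vectorized path that is
regression-checked to equal the object-level stage exactly. Consistency
is the fraction of the union of called sites present in ≥ 80/90/100% of
iterations; gCIS accuracy and sensitivity compare per-iteration
significant sets to the full-data reference; an optional per-site
sensitivity tracks recovery of the full-data clonal site set.

On both real and synthetic data the mean clonal-site count is *not*
monotone in depth: modest depths transiently admit background sites
(their counts exceed the still-small cutoffs) that more data eliminates,
while the low-abundance clonal tail is recovered only as depth grows.
Sensitivity and consistency, by contrast, improve monotonically, and the
mean count saturates at the true clonal count; those are the properties
the tests assert.

## PCR-bias analysis

Both recognition motifs (AluI AGCT, NlaIII CATG) are reverse-complement
palindromes, so a forward-strand scan is complete. The side a library
reads into follows from (orientation, IR-end): a plus-orientation
transposon reads leftward from IRL and rightward from IRR, swapped for
minus orientation. Fragment length counts genomic bases from the TA
boundary (TA included) to the proximal motif edge; a strict-cut-site mode
measures to the enzyme's actual cut position (AluI AG^CT, NlaIII CATG^) —
the ≤ 2-base difference is immaterial to 20–500 b binning. A TA site is
"unamplifiable" when none of the four (enzyme × side) fragments falls in
[20, 250) bases. The distribution and genome-wide scan are cross-checked
against naive nearest-motif oracles.

## Synthetic data: what it emulates and what it does not

The generator produces i.i.d.-uniform genomes (natural TA density 1/16 per
position, optionally biased upward) with restriction motifs planted at
geometric spacings; single-transcript gene models on a regular grid with
room for the 10 kb promoter; and cohorts in which each tumor carries a few
clonal insertions — some planted recurrently in designated CIS genes,
some intergenic, some on the donor chromosome as local-hopping decoys —
over many background insertions with counts 1 + NB(size 0.5, prob 0.3).
Clonal abundances follow a geometric ladder (largest/smallest intended
fraction 20) summing to 70% of library reads, reflecting the observation
that a few percent of sites carry the large majority of reads while
keeping every planted site above the 1%-of-top cutoff at saturating
depth; background positions are unique within a tumor but may recur
between tumors. Reads honor per-library fragment feasibility (no read
emitted when the junction fragment falls outside [20, 500] bases) unless
an idealized digest is requested.

Default study conditions used by the test suite (scaled to desk size as
the package's own choice): cohorts of 4–12 tumors; 100,000 reads per
library for well-separated recovery experiments; a depth-simulation
cohort of 6 tumors × 3,000 off-donor background sites per tumor (≈ 27% of
reads in background, ~95% of sites at ≤ 3 reads) subsampled at 1,000–
60,000 reads per sample over 6–8 iterations; gCIS power cohorts on a
4 × 500 kb genome where each 12 kb gene region is ≈ 1% of the testable
genome.

What passing tests show: the filtering rules implement their definitions
exactly; the NB machinery recovers a generating NB background and bounds
it at the intended 95%; planted clonal sites and planted CIS genes are
recovered exactly under good separation; family-wise error is controlled
under null placement; the depth and bias analyses reproduce the expected
qualitative shapes. What they do not show: performance on real libraries
with sequencing error profiles, chimeric reads, mappability structure,
GC/secondary-structure amplification bias, or background that deviates
from a stationary NB — the generator does not model any of those.

## Numerical and degenerate-input choices

NB grid SSE uses proportions (not raw counts); argmin is taken in
row-major (size, prob) order so exact ties resolve to the smallest pair.
Libraries with no sites produce a zero cutoff with a warning; an
all-singleton background drives the fit toward a point mass and a
threshold of 1. Empty gCIS found-sets score accuracy 0 (with a warning)
so averages stay defined; consistency with an empty union reports 0.
Aggregation drops (with a warning) any site whose computed address is not
a TA in the reference — that indicates a coordinate bug or reference
mismatch, never valid data. All tables carry 1-based addresses; all
in-memory coordinates are 0-based half-open.

## Known limitations

The built-in aligner is quadratic and for tests only; real screens should
import aligner output. The NB fit is a 3-point least-squares, not a
maximum-likelihood fit — deliberate, to keep the background model tied to
the 1–3-read sites, but it identifies parameters only up to an SSE
valley. gCIS treats insertions as exchangeable across tumors given the
recurrence floor; it does not model per-tumor insertion-count
heterogeneity beyond the expectation. Fragment analysis considers length
only; no quantitative de-biasing of read counts is attempted.
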