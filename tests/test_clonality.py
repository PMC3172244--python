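import numpy as np
import pytest
from scipy import stats

from sbcis.align_filter import InsertionSite, LibraryProfile
from sbcis.clonality import (
    CutoffResult, call_clonal, clonal_profiles_for_tumor, dynamic_cutoff,
    fit_nb_background, merge_libraries, nb_threshold, nb_threshold_from_params,
    remove_donor_chromosome, topsite_cutoff, totalreads_cutoff,
)
from sbcis.synthetic_data import make_library_profiles

from .oracles import nb_grid_argmin, nb_quantile


def profile(counts, tumor="T1", library=("AluI", "IRL"), chroms=None):
    sites = [
        InsertionSite(tumor, chroms[i] if chroms else "chr2", 10 + 2 * i, "+",
                      library, c, 0.0)
        for i, c in enumerate(counts)
    ]
    p = LibraryProfile(tumor, library, sites, sum(counts))
    p.recompute_percentages()
    return p


class TestDonorRemoval:
    def test_donor_sites_removed_and_totals_recomputed(self):
        p = profile([5, 5, 5, 5, 5, 5, 5, 5, 5, 5],
                    chroms=["chr1"] * 3 + ["chr2"] * 7)
        out = remove_donor_chromosome(p, "chr1")
        assert len(out.sites) == 7
        assert out.total_mapped_reads == 35
        assert all(s.chrom != "chr1" for s in out.sites)

    def test_absent_donor_is_identity(self):
        p = profile([3, 4])
        out = remove_donor_chromosome(p, "chrX")
        assert [s.read_count for s in out.sites] == [3, 4]

    def test_all_donor_gives_empty_profile(self):
        p = profile([3, 4], chroms=["chr1", "chr1"])
        out = remove_donor_chromosome(p, "chr1")
        assert out.sites == [] and out.total_mapped_reads == 0
        with pytest.warns(UserWarning, match="empty"):
            result = dynamic_cutoff(out)
        assert result.applied_cutoff == 0.0


class TestNBFit:
    def test_parameter_recovery_on_simulated_background(self):
        rng = np.random.default_rng(1)
        counts = 1 + rng.negative_binomial(0.5, 0.3, size=10_000)
        fit = fit_nb_background(counts)
        assert abs(fit.size - 0.5) <= 0.1
        assert abs(fit.prob - 0.3) <= 0.05
        assert fit.threshold == 1 + nb_quantile(fit.size, fit.prob, 0.95)

    def test_grid_argmin_matches_full_precision_oracle(self):
        """Vectorized grid fit = naive lgamma-based exhaustive search, exactly."""
        rng = np.random.default_rng(7)
        counts = 1 + rng.negative_binomial(0.4, 0.25, size=3_000)
        grid = {"size_min": 0.1, "size_max": 2.0, "size_step": 0.01,
                "prob_min": 0.05, "prob_max": 0.6, "prob_step": 0.001}
        fit = fit_nb_background(counts, grid=grid)
        n_total = len(counts)
        props = [np.sum(counts == k + 1) / n_total for k in range(3)]
        sizes = [round(0.1 + 0.01 * i, 10) for i in range(191)]
        probs = [round(0.05 + 0.001 * j, 10) for j in range(551)]
        o_size, o_prob, _ = nb_grid_argmin(props, sizes, probs)
        assert (fit.size, fit.prob) == (pytest.approx(o_size), pytest.approx(o_prob))

    def test_all_singletons_drive_prob_to_one(self):
        fit = fit_nb_background([1] * 200)
        assert fit.prob > 0.9
        assert fit.threshold == 1

    def test_too_few_background_sites_unavailable(self):
        assert fit_nb_background([1] * 49) is None
        assert nb_threshold(None) == 0.0


class TestNBThreshold:
    def test_forced_by_cdf_rule(self):
        # find parameters whose CDF crosses 0.95 between 4 and 5 (zero-shifted)
        size, prob = 1.0, 0.45
        assert stats.nbinom.cdf(4, size, prob) < 0.95 <= stats.nbinom.cdf(5, size, prob)
        assert nb_threshold_from_params(size, prob) == 6

    def test_matches_analytic_quantile(self):
        assert nb_threshold_from_params(0.5, 0.3) == 1 + nb_quantile(0.5, 0.3, 0.95)
        assert nb_threshold_from_params(3.0, 0.8) == 1 + nb_quantile(3.0, 0.8, 0.95)

    def test_point_mass_gives_threshold_one(self):
        assert nb_threshold_from_params(0.01, 0.999) == 1


class TestSimpleCutoffs:
    @pytest.mark.parametrize("counts,expected", [
        ([10_000, 50, 3], 100.0), ([50, 3], 0.5), ([123], 1.23),
    ])
    def test_topsite_is_one_percent_of_max(self, counts, expected):
        assert topsite_cutoff(profile(counts)) == pytest.approx(expected)

    @pytest.mark.parametrize("total,expected", [(200_000, 200.0), (1_000, 1.0)])
    def test_totalreads_is_tenth_percent_of_total(self, total, expected):
        p = profile([total])
        assert totalreads_cutoff(p) == pytest.approx(expected)

    def test_empty_profile_cutoffs_zero(self):
        p = LibraryProfile("T1", ("AluI", "IRL"), [], 0)
        assert topsite_cutoff(p) == 0.0 and totalreads_cutoff(p) == 0.0


class TestDynamicCutoff:
    def test_maximum_wins(self):
        r = CutoffResult(6.0, 100.0, 200.0, 200.0, "totalreads")
        assert r.applied_cutoff == 200.0
        r = CutoffResult(6.0, 0.5, 1.0, 6.0, "NB")
        assert r.applied_cutoff == 6.0
        with pytest.raises(ValueError):
            CutoffResult(6.0, 100.0, 200.0, 100.0, "topsite")

    def test_unavailable_nb_contributes_zero(self):
        p = profile([40, 30, 20])  # < 50 background sites
        result = dynamic_cutoff(p)
        assert result.nb_cutoff == 0.0
        assert result.applied_cutoff == max(result.topsite_cutoff,
                                            result.totalreads_cutoff)

    def test_dominance_over_individual_methods(self, separated_profiles):
        """The dynamic clonal set is a subset of each single-method set."""
        for p in separated_profiles[:8]:
            result = dynamic_cutoff(p)
            dynamic_set = {s.key for s in call_clonal(p, result)}
            for single in (result.nb_cutoff, result.topsite_cutoff,
                           result.totalreads_cutoff):
                assert dynamic_set <= {s.key for s in call_clonal(p, single)}


class TestCallClonal:
    def test_strictly_above_cutoff(self):
        p = profile([300, 150, 100, 3, 1])
        assert len(call_clonal(p, 100.0)) == 2  # 100 itself excluded

    def test_zero_cutoff_keeps_all(self):
        p = profile([5, 1])
        assert len(call_clonal(p, 0.0)) == 2


class TestMergeLibraries:
    def site(self, lib, pct, pos=10, count=100):
        return InsertionSite("T1", "chr2", pos, "+", lib, count, pct)

    def test_max_percent_across_libraries(self):
        merged = merge_libraries("T1", [
            [self.site(("AluI", "IRL"), 2.3)], [self.site(("NlaIII", "IRR"), 4.1)],
        ])
        (s,) = merged.clonal_sites
        assert s.percent_of_reads == 4.1
        assert s.libraries == {("AluI", "IRL"), ("NlaIII", "IRR")}

    def test_single_library_site_carried_through(self):
        merged = merge_libraries("T1", [[self.site(("AluI", "IRL"), 2.3)], []])
        assert len(merged.clonal_sites) == 1

    def test_disjoint_sites_sum(self):
        lists = [[self.site(("AluI", "IRL"), 1.0, pos=10)],
                 [self.site(("AluI", "IRR"), 1.0, pos=20)],
                 [self.site(("NlaIII", "IRL"), 1.0, pos=30)],
                 [self.site(("NlaIII", "IRR"), 1.0, pos=40)]]
        assert len(merge_libraries("T1", lists).clonal_sites) == 4


class TestBackgroundControl:
    def test_nb_cutoff_retains_at_most_about_five_percent(self):
        """<=~5% of pure-background sites survive the fitted NB threshold."""
        survived = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            counts = 1 + rng.negative_binomial(0.5, 0.3, size=10_000)
            fit = fit_nb_background(counts)
            survived.append(np.mean(counts > fit.threshold))
        assert np.mean(survived) <= 0.05 + 0.01

    def test_planted_clonal_recovery_across_seeds(self, cohort_truth):
        """Exact recovery of planted clonal sites at saturating depth, 20 seeds."""
        truth = cohort_truth
        for seed in range(20):
            profiles = make_library_profiles(truth, reads_per_library=100_000,
                                             seed=seed)
            by_tumor = {}
            for p in profiles:
                by_tumor.setdefault(p.tumor_id, []).append(p)
            for tumor, libs in by_tumor.items():
                tp, _ = clonal_profiles_for_tumor(libs, truth.donor_chrom)
                recovered = {s.key for s in tp.clonal_sites}
                planted = truth.planted_clonal_keys(tumor)
                assert recovered == planted
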