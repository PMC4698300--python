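"""Overlap summaries, interval shuffling and the permutation test."""

import numpy as np
import pytest
from scipy import stats

from cnvrecur.errors import DegenerateInputError, ValidationError
from cnvrecur.genome import CNVRecord, GenomeBuild
from cnvrecur.intervals import OverlapRegion, coverage_segments
from cnvrecur.randomization import (
    normality_check,
    randomization_test,
    sample_placements,
    shuffle_intervals,
    summarize_overlaps,
)
from cnvrecur.synthetic import SyntheticSpec, generate_all, generate_null_cohort


class TestSummarizeOverlaps:
    def test_published_style_depth_table_mean(self):
        # per-depth counts 198,73,37,20,8,4,3,1 for depths 1..8:
        # weighted mean = 628/344 (hand arithmetic)
        counts = {1: 198, 2: 73, 3: 37, 4: 20, 5: 8, 6: 4, 7: 3, 8: 1}
        regions, pos = [], 0
        for d, n in counts.items():
            for _ in range(n):
                regions.append(OverlapRegion("c", pos, pos + 10, d))
                pos += 20
        s = summarize_overlaps(regions)
        assert s.mean_overlap == pytest.approx(628 / 344)
        assert s.n_shared == 344 - 198
        assert s.count_by_depth == counts

    def test_disjoint_intervals_all_depth_one(self):
        cnvs = [CNVRecord("c", 100 * i, 100 * i + 50, f"P{i}", "deletion") for i in range(5)]
        s = summarize_overlaps(coverage_segments(cnvs))
        assert s.n_shared == 0 and s.mean_overlap == 1.0

    def test_empty_list_reports_absent_mean(self):
        s = summarize_overlaps([])
        assert s.n_regions == 0 and s.mean_overlap is None


class TestShuffle:
    def test_support_of_single_interval(self):
        g = GenomeBuild("g", (("c", 1000),))
        rng = np.random.default_rng(0)
        for _ in range(50):
            (r,) = shuffle_intervals([CNVRecord("c", 0, 100, "P", "deletion")], g, rng)
            assert r.length == 100 and 0 <= r.start <= 900

    def test_forced_unique_placement(self):
        g = GenomeBuild("g", (("c", 1000),), (("c", 0, 900),))
        (r,) = shuffle_intervals([CNVRecord("c", 0, 100, "P", "deletion")], g, 0)
        assert (r.start, r.end) == (900, 1000)

    def test_unplaceable_interval_is_an_error(self):
        g = GenomeBuild("g", (("c", 1000),), (("c", 400, 600),))
        with pytest.raises(ValidationError, match="length 500"):
            shuffle_intervals([CNVRecord("c", 0, 500, "P", "deletion")], g, 0)

    def test_length_multiset_preserved(self):
        g = GenomeBuild("g", (("c1", 100_000), ("c2", 50_000)))
        rng = np.random.default_rng(1)
        cnvs = [
            CNVRecord("c1", 10 * i, 10 * i + 7 + i, f"P{i}", "deletion") for i in range(30)
        ]
        shuffled = shuffle_intervals(cnvs, g, rng)
        assert sorted(r.length for r in shuffled) == sorted(r.length for r in cnvs)

    def test_start_distribution_uniform_chi2(self):
        """200 intervals x 1000 shuffles: uniform over legal starts (alpha=0.01)."""
        g = GenomeBuild("g", (("c", 10_000),))
        rng = np.random.default_rng(12345)
        L = 100  # legal starts 0..9900
        cnvs = [CNVRecord("c", 0, L, f"P{i}", "deletion") for i in range(200)]
        starts = []
        for _ in range(100):
            starts.extend(r.start for r in shuffle_intervals(cnvs, g, rng))
        hist, _ = np.histogram(starts, bins=20, range=(0, 10_000 - L + 1))
        p = stats.chisquare(hist).pvalue
        assert p > 0.01

    def test_cross_chromosome_relocation_proportional_to_space(self):
        g = GenomeBuild("g", (("c1", 90_000), ("c2", 10_000)))
        rng = np.random.default_rng(7)
        cnvs = [CNVRecord("c1", 0, 10, f"P{i}", "deletion") for i in range(2000)]
        shuffled = shuffle_intervals(cnvs, g, rng)
        frac_c1 = np.mean([r.chrom == "c1" for r in shuffled])
        assert frac_c1 == pytest.approx(0.9, abs=0.03)


@pytest.fixture(scope="module")
def planted_result(bundle):
    dels = [r for r in bundle.records if r.cnv_type == "deletion"]
    return randomization_test(dels, bundle.genome, R=200, seed=11)


class TestRandomizationTest:
    def test_permutation_scores_standardize(self, planted_result):
        z = planted_result.z
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=1) - 1) < 1e-9

    def test_z_real_matches_independent_recomputation(self, bundle, planted_result):
        dels = [r for r in bundle.records if r.cnv_type == "deletion"]
        obs = summarize_overlaps(coverage_segments(dels)).mean_overlap
        expected = (obs - planted_result.mu_bar) / planted_result.sigma
        assert planted_result.z_real == pytest.approx(expected)

    def test_planted_cohort_detected(self, planted_result):
        assert planted_result.z_real > 3
        assert planted_result.empirical_p <= 1 / planted_result.R + 1e-12

    def test_empirical_p_monotone_in_z_real(self, planted_result):
        z = planted_result.z
        R = planted_result.R
        ps = [max(int(np.sum(z >= zr)), 1) / R for zr in np.linspace(-3, 3, 13)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_planted_beats_null_across_seeds(self, bundle):
        """Planted recurrence must out-score a matched uniform-null cohort."""
        dels = [r for r in bundle.records if r.cnv_type == "deletion"]
        wins = 0
        n_rep = 20
        for seed in range(n_rep):
            null, _ = generate_null_cohort(
                bundle.genome, len(dels), (np.log(30_000), 0.8), seed
            )
            z_pl = randomization_test(dels, bundle.genome, R=60, seed=seed).z_real
            z_nu = randomization_test(null, bundle.genome, R=60, seed=seed).z_real
            wins += z_pl > z_nu
        assert wins >= int(0.95 * n_rep)

    def test_degenerate_null_is_an_error(self):
        # one interval as long as the only chromosome: every shuffle identical
        g = GenomeBuild("g", (("c", 1000),))
        cnvs = [CNVRecord("c", 0, 1000, "P", "deletion")]
        with pytest.raises(DegenerateInputError):
            randomization_test(cnvs, g, R=10, seed=0)

    def test_r_below_two_rejected(self, toy_genome):
        with pytest.raises(ValidationError):
            randomization_test([CNVRecord("chrT", 0, 10, "P", "deletion")], toy_genome, R=1)


class TestNormalityCheck:
    def test_normal_draws_not_rejected(self):
        rng = np.random.default_rng(42)
        assert normality_check(rng.normal(size=1000)) > 0.05

    def test_skewed_mixture_rejected(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(size=900), rng.normal(15, 0.1, size=100)])
        assert normality_check(x) < 0.05

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            normality_check(np.ones(100))

    def test_out_of_range_n_rejected(self):
        with pytest.raises(ValidationError):
            normality_check([1.0, 2.0])
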