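import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from top2track.core_io import (
    GenomicInterval,
    IntervalSet,
    MethylationTable,
    ReadLibrary,
)
from top2track.region_ops import LabeledRegions, random_regions
from top2track.sequence_encoding import synthetic_shape_table
from top2track.signal_scoring import (
    FeatureSpec,
    build_feature_matrix,
    count_reads,
    score_chip,
    score_coverage,
    score_methylation,
    signal_profile,
)

W = GenomicInterval("chr1", 1000, 1300)


def _lib(read_tuples, size=None):
    return ReadLibrary(
        IntervalSet(GenomicInterval(c, s, e) for c, s, e in read_tuples),
        library_size=size,
    )


class TestCountReads:
    def test_empty_library(self):
        assert count_reads(_lib([]), W) == 0

    def test_half_open_boundaries(self):
        # abutting the window end (start == end of window) -> not counted;
        # abutting the start (read end == window start) -> not counted;
        # 1 bp of overlap on either side -> counted
        lib = _lib(
            [
                ("chr1", 1300, 1350),  # starts at window end
                ("chr1", 950, 1000),  # ends at window start
                ("chr1", 1299, 1349),  # 1 bp in
                ("chr1", 951, 1001),  # 1 bp in
            ]
        )
        assert count_reads(lib, W) == 2

    def test_inside_plus_straddling(self):
        inside = [("chr1", 1000 + 10 * i, 1050 + 10 * i) for i in range(5)]
        straddle = [("chr1", 970, 1020)]
        assert count_reads(_lib(inside + straddle), W) == 6


class TestScoreChip:
    def test_self_ratio_is_zero(self):
        lib = _lib([("chr1", 1000, 1050)] * 1 + [("chr1", 2000, 2050)], size=100)
        assert score_chip(lib, lib, W) == 0.0

    def test_equal_sizes_formula(self):
        test = _lib([("chr1", 1010, 1060)] * 3, size=100)
        inp = _lib([("chr1", 1010, 1060)] * 1, size=100)
        # counts 3 vs 1, equal sizes: log2((3+1)/(1+1)) = 1.0
        assert score_chip(test, inp, W) == pytest.approx(1.0)

    def test_scaling_to_smaller_library(self):
        test = _lib([("chr1", 1010, 1060)] * 9, size=1000)
        inp = _lib([("chr1", 1010, 1060)] * 4, size=500)
        # m=500: test 9*0.5=4.5, input 4*1; log2(5.5/5) ~ 0.1375
        assert score_chip(test, inp, W) == pytest.approx(
            np.log2(5.5 / 5.0), abs=1e-9
        )
        assert score_chip(test, inp, W) == pytest.approx(0.1375, abs=5e-4)

    def test_antisymmetric_under_swap(self):
        test = _lib([("chr1", 1010, 1060)] * 7, size=300)
        inp = _lib([("chr1", 1010, 1060)] * 2, size=200)
        assert score_chip(test, inp, W) == pytest.approx(-score_chip(inp, test, W))

    def test_zero_library_size_errors(self):
        good = _lib([("chr1", 1010, 1060)], size=10)
        bad = ReadLibrary(IntervalSet(), library_size=None)
        bad.library_size = 0
        with pytest.raises(ValueError):
            score_chip(good, bad, W)


class TestScoreCoverage:
    def test_zero_reads(self):
        lib = ReadLibrary(IntervalSet(), library_size=1000)
        assert score_coverage(lib, W) == 0.0

    def test_division(self):
        lib = _lib([("chr1", 1010, 1060)] * 50, size=1_000_000)
        assert score_coverage(lib, W) == pytest.approx(5e-5)

    def test_scale_invariance(self):
        a = _lib([("chr1", 1010, 1060)] * 10, size=1000)
        b = _lib([("chr1", 1010, 1060)] * 20, size=2000)
        assert score_coverage(a, W) == pytest.approx(score_coverage(b, W))


class TestScoreMethylation:
    def test_mean_and_missing(self):
        t = MethylationTable(
            [("chr1", 1010, 100.0), ("chr1", 1020, 100.0), ("chr1", 1030, 0.0), ("chr1", 1040, 100.0)]
        )
        assert score_methylation(t, W) == pytest.approx(75.0)
        assert np.isnan(score_methylation(t, GenomicInterval("chr1", 5000, 5300)))

    def test_all_fully_methylated(self):
        t = MethylationTable([("chr1", 1010, 100.0), ("chr1", 1020, 100.0)])
        assert score_methylation(t, W) == 100.0


class TestSignalProfile:
    def test_uniform_reads_flat(self):
        rng = np.random.default_rng(0)
        reads = [("chr1", int(s), int(s) + 50) for s in rng.integers(0, 99_000, 100_000)]
        lib = _lib(reads)
        centers = IntervalSet(
            [GenomicInterval("chr1", 20_000 + 5000 * i, 20_300 + 5000 * i) for i in range(10)]
        )
        profile = signal_profile(lib, centers, flank_bp=2000, bin_bp=200)
        assert profile.max() / profile.min() <= 1.1

    def test_central_peak(self):
        centers = IntervalSet([GenomicInterval("chr1", 10_000, 10_300)])
        mid = 10_150
        reads = [("chr1", mid - 150 + 3 * i, mid - 100 + 3 * i) for i in range(80)]
        lib = _lib(reads)
        profile = signal_profile(lib, centers, flank_bp=2000, bin_bp=100)
        assert np.argmax(profile) in (19, 20)
        assert profile[0] == 0 and profile[-1] == 0

    def test_profile_length(self):
        lib = _lib([("chr1", 0, 50)])
        centers = IntervalSet([GenomicInterval("chr1", 5000, 5300)])
        profile = signal_profile(lib, centers, flank_bp=4000, bin_bp=50)
        assert len(profile) == 2 * 4000 // 50

    def test_empty_centers_error(self):
        with pytest.raises(ValueError):
            signal_profile(_lib([("chr1", 0, 50)]), IntervalSet(), 1000)


def _labeled(regions):
    return LabeledRegions(
        regions=IntervalSet.from_ordered(regions),
        labels=np.zeros(len(regions), dtype=int),
        provenance="observed",
    )


class TestBuildFeatureMatrix:
    def test_small_matrix_shape(self):
        regions = _labeled(
            [GenomicInterval("chr1", 1000 * i, 1000 * i + 300) for i in range(1, 4)]
        )
        test = _lib([("chr1", 1010, 1060)], size=100)
        inp = _lib([("chr1", 1010, 1060)], size=100)
        specs = [
            FeatureSpec(name="chip1", kind="chip", test=test, input_=inp),
            FeatureSpec(name="cov1", kind="coverage", lib=test),
        ]
        m = build_feature_matrix(regions, specs)
        assert m.values.shape == (3, 2)
        assert m.feature_names == ["chip1", "cov1"]

    def test_kmer_column_counts_for_300bp(self, toy_genome):
        regions = _labeled([GenomicInterval("chr1", 100, 400)])
        specs = [FeatureSpec(name=f"k{k}", kind="kmer", k=k) for k in (1, 2, 3)]
        m = build_feature_matrix(regions, specs, genome=toy_genome)
        # 1,200 + 4,784 + 19,072 positional k-mer parameters at L = 300
        assert m.values.shape[1] == 1200 + 4784 + 19072

    def test_full_parametrization_with_signal_features(self, toy_genome):
        # 15 signal features + k-mers, as in the full training parametrization
        regions = _labeled([GenomicInterval("chr1", 100, 400), GenomicInterval("chr1", 600, 900)])
        lib = _lib([("chr1", 110, 160)], size=50)
        specs = [
            FeatureSpec(name=f"sig{i}", kind="coverage", lib=lib) for i in range(15)
        ] + [FeatureSpec(name=f"k{k}", kind="kmer", k=k) for k in (1, 2, 3)]
        m = build_feature_matrix(regions, specs, genome=toy_genome)
        assert m.values.shape == (2, 15 + 1200 + 4784 + 19072)

    def test_methylation_imputation_flagged(self):
        regions = _labeled(
            [GenomicInterval("chr1", 1000, 1300), GenomicInterval("chr1", 5000, 5300)]
        )
        table = MethylationTable([("chr1", 1010, 80.0)])
        m = build_feature_matrix(
            regions, [FeatureSpec(name="meth", kind="methylation", methylation=table)]
        )
        assert m.metadata["imputed_columns"] == ["meth"]
        assert m.values[1, 0] == pytest.approx(80.0)  # column mean

    def test_row_permutation_only_permutes_rows(self, toy_genome):
        ivs = [GenomicInterval("chr1", 1000 * i, 1000 * i + 300) for i in range(1, 4)]
        lib = _lib([("chr1", 1010, 1060), ("chr1", 2020, 2070)], size=50)
        specs = [FeatureSpec(name="cov", kind="coverage", lib=lib),
                 FeatureSpec(name="k1", kind="kmer", k=1)]
        m1 = build_feature_matrix(_labeled(ivs), specs, genome=toy_genome)
        m2 = build_feature_matrix(_labeled(ivs[::-1]), specs, genome=toy_genome)
        assert np.array_equal(m1.values, m2.values[::-1])

    def test_region_outside_genome_errors(self, toy_genome):
        regions = _labeled([GenomicInterval("chr1", 4900, 5200)])
        with pytest.raises(ValueError):
            build_feature_matrix(
                regions, [FeatureSpec(name="k1", kind="kmer", k=1)], genome=toy_genome
            )


class TestSiteEnrichmentSeparation:
    def test_chip_score_separates_sites_from_background(self, fixture_world):
        genome, truth, libs, _ = fixture_world
        test, inp = libs["ctcf"]
        bg = random_regions(
            truth.top2b_sites, genome, IntervalSet(), IntervalSet(), seed=11
        )
        site_scores = [score_chip(test, inp, iv) for iv in truth.top2b_sites]
        bg_scores = [score_chip(test, inp, iv) for iv in bg]
        assert np.mean(site_scores) > np.mean(bg_scores)
        p = mannwhitneyu(site_scores, bg_scores, alternative="greater").pvalue
        assert p < 1e-6
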