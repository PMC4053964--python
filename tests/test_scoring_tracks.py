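import numpy as np
import pytest

from xlinkscape import (
    AlignedRead,
    GeneIndex,
    GenomicInterval,
    ScoreTrack,
    capture_overlap,
    compute_cls,
    coverage_tracks,
    metagene_profile,
    random_control_bins,
    ranked_overlap_bins,
    site_density,
)
from xlinkscape.scoring_tracks import (
    block_fully_covered,
    block_overlap,
    paired_scores,
)


def read(start, end, tc=(), strand="+", chrom="chrT"):
    return AlignedRead(GenomicInterval(chrom, start, end, strand), "lib",
                       n_mismatches=len(tc), tc_positions=tc)


class TestComputeCLS:
    def test_formula_and_rpkm_removal(self, two_gene_annotation):
        index = GeneIndex(two_gene_annotation)
        # 2 conversion reads at position 510 (geneA 3' UTR) of 1000 total
        reads = [read(500, 530, tc=(510,)) for _ in range(2)]
        reads += [read(850, 880, tc=(860,), strand="-") for _ in range(3)]
        reads += [read(2000, 2030) for _ in range(995)]
        track = compute_cls(reads, index, {"geneA": 4.0, "geneB": 0.0})
        # conversion RPM 2000 over RPKM 4 -> CLS 5e5; scaled example:
        # RPM 2 / RPKM 4 * 1000 = 500
        assert track.get("chrT", 510, "+") == pytest.approx(
            (2 * 1e6 / 1000) / 4.0 * 1000)
        assert track.regions[("chrT", 510, "+")] == "three_utr"
        # geneB has no mRNA-seq coverage: removed
        assert track.get("chrT", 860, "-") is None

    def test_cls_equals_thousand_when_rpm_equals_rpkm(self,
                                                      two_gene_annotation):
        index = GeneIndex(two_gene_annotation)
        reads = [read(500, 530, tc=(510,))]  # RPM = 1e6
        track = compute_cls(reads, index, {"geneA": 1e6}, total_mapped_reads=1)
        assert track.get("chrT", 510, "+") == pytest.approx(1000.0)


class TestRankedOverlapBins:
    def test_six_positions_bin_size_four_stride_two(self):
        cls = np.array([5.0, 1.0, 3.0, 2.0, 4.0, 6.0])
        ext = cls.copy()  # external equals the ranking score
        series = ranked_overlap_bins(cls, ext, bin_size=4)
        assert series.bin_size == 4 and series.stride == 2
        assert series.start_ranks.tolist() == [0, 2]
        # ranks 1-4 hold values 1,2,3,4; ranks 3-6 hold 3,4,5,6
        assert series.means.tolist() == [2.5, 4.5]

    def test_constant_external_gives_constant_bins(self, rng):
        cls = rng.random(200)
        series = ranked_overlap_bins(cls, np.full(200, 7.5), n_bins=20)
        assert np.allclose(series.means, 7.5)

    def test_external_equal_to_rank_is_strictly_increasing(self, rng):
        cls = rng.permutation(300).astype(float)
        series = ranked_overlap_bins(cls, cls, n_bins=30)
        assert np.all(np.diff(series.means) > 0)

    def test_fewer_positions_than_bin_rejected(self):
        with pytest.raises(ValueError):
            ranked_overlap_bins(np.arange(3.0), np.arange(3.0), bin_size=4)

    def test_interior_positions_fall_in_two_bins_at_half_overlap(self):
        n, size = 100, 10
        series = ranked_overlap_bins(np.arange(float(n)), np.arange(float(n)),
                                     bin_size=size)
        counts = np.zeros(n, int)
        for s in series.start_ranks:
            counts[s:s + size] += 1
        assert np.all(counts[size // 2: -(size // 2)] == 2)
        assert counts[0] == 1 and counts[-1] == 1


class TestRandomControlBins:
    def test_same_seed_is_deterministic(self, rng):
        ext = np.arange(100.0)
        a = random_control_bins(ext, n_bins=10, seed=3)
        b = random_control_bins(ext, n_bins=10, seed=3)
        assert np.array_equal(a.rep_means, b.rep_means)
        assert a.rep_means.shape[0] == 10  # ten replicates by default

    def test_constant_external_gives_constant_controls(self):
        out = random_control_bins(np.full(80, 2.5), n_bins=8, seed=0)
        assert np.allclose(out.rep_means, 2.5)

    def test_controls_are_unbiased_around_global_mean(self, rng):
        ext = rng.exponential(1.0, size=400)
        out = random_control_bins(ext, n_bins=10, reps=200, seed=9)
        # grand mean over many randomized replicates ~ global mean
        assert abs(out.rep_means.mean() - ext.mean()) < 4 * ext.std() / np.sqrt(
            out.rep_means.shape[0] * out.bin_size)

    def test_paired_scores_drops_positions_without_external(self):
        from xlinkscape.scoring_tracks import CLSTrack

        track = CLSTrack()
        track.set("chrI", 5, "+", 1.0)
        track.set("chrI", 6, "+", 2.0)
        ext = ScoreTrack()
        ext.set("chrI", 5, 0.9)
        cls_v, ext_v, dropped = paired_scores(track, ext)
        assert cls_v.tolist() == [1.0] and ext_v.tolist() == [0.9]
        assert dropped == 1


class TestMetagene:
    def test_no_coverage_gives_zero_profile(self, two_gene_annotation):
        tracks = {("chrT", "+"): np.zeros(2000), ("chrT", "-"): np.zeros(2000)}
        prof = metagene_profile(tracks, two_gene_annotation, "polya",
                                window=(-50, 10))
        assert np.all(prof.values == 0)
        assert prof.n_features == 2

    def test_single_read_at_anchor_reproduces_footprint(self,
                                                        two_gene_annotation):
        genome = {"chrT": "A" * 2000}
        # geneA poly(A) junction at 599 (+ strand); read covering [570, 600)
        tracks = coverage_tracks([read(570, 600)], genome, what="depth")
        single = {"geneA": two_gene_annotation["geneA"]}
        prof = metagene_profile(tracks, single, "polya", window=(-40, 5))
        covered = prof.offsets[prof.values > 0]
        assert covered.min() == -29 and covered.max() == 0

    def test_minus_strand_offsets_are_strand_oriented(self,
                                                      two_gene_annotation):
        genome = {"chrT": "A" * 2000}
        # geneB (minus) poly(A) junction at position 700; 5' of it = higher
        # coordinates. a read at [705, 720) sits upstream of the junction
        tracks = coverage_tracks([read(705, 720, strand="-")], genome)
        single = {"geneB": two_gene_annotation["geneB"]}
        prof = metagene_profile(tracks, single, "polya", window=(-30, 5))
        covered = prof.offsets[prof.values > 0]
        assert covered.max() <= -5 and covered.min() >= -20

    def test_branch_point_anchor_requires_mapping(self, two_gene_annotation):
        tracks = {("chrT", "+"): np.zeros(2000), ("chrT", "-"): np.zeros(2000)}
        prof = metagene_profile(tracks, two_gene_annotation, "branch_point",
                                window=(-20, 5), bp_anchors={"geneA": 340})
        assert prof.n_features == 1

    def test_truncation_counts_contributing_features(self,
                                                     two_gene_annotation):
        tracks = {("chrT", "+"): np.ones(2000), ("chrT", "-"): np.ones(2000)}
        prof = metagene_profile(tracks, two_gene_annotation, "polya",
                                window=(-150, 0))
        # geneA 3' UTR is 100 nt, geneB's is 100 nt: offsets beyond -100
        # have no contributors
        assert prof.n_contributing[prof.offsets < -100].max() == 0
        assert prof.n_contributing[prof.offsets == -50] == 2


def iv(start, end, strand="+", chrom="chrI"):
    return GenomicInterval(chrom, start, end, strand)


class TestBlockOverlap:
    def test_single_site_full_coverage_rule(self):
        block = iv(10, 20)
        assert block_fully_covered(block, [iv(5, 25)], mode="single")
        # split across two adjacent sites fails the single-site rule ...
        assert not block_fully_covered(block, [iv(5, 15), iv(15, 25)],
                                       mode="single")
        # ... but passes the union rule
        assert block_fully_covered(block, [iv(5, 15), iv(15, 25)],
                                   mode="union")

    def test_chi_square_matches_textbook_formula(self, rng):
        # engineered outcome: 40/100 observed vs ~10/100 control
        regions = [iv(0, 5000)]
        blocks = [iv(100 + i * 50, 100 + i * 50 + 10) for i in range(100)]
        sites = [iv(98 + i * 50, 112 + i * 50) for i in range(40)]
        result = block_overlap(blocks, sites, regions, seed=11)
        a, b = result.observed_overlapped, 100 - result.observed_overlapped
        c, d = result.control_overlapped, 100 - result.control_overlapped
        n = a + b + c + d
        expected_chi2 = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d))
        assert result.chi2 == pytest.approx(expected_chi2)
        assert result.observed_overlapped == 40

    def test_control_blocks_match_sizes(self, rng):
        regions = [iv(0, 400)]
        blocks = [iv(10, 25), iv(50, 90)]
        from xlinkscape.scoring_tracks import random_control_blocks

        controls = random_control_blocks(blocks, regions,
                                         np.random.default_rng(0))
        assert [len(c) for c in controls] == [15, 40]
        for c in controls:
            assert 0 <= c.start and c.end <= 400

    def test_region_too_small_rejected(self):
        from xlinkscape.scoring_tracks import random_control_blocks

        with pytest.raises(ValueError):
            random_control_blocks([iv(0, 50)], [iv(0, 10)],
                                  np.random.default_rng(0))


class TestCaptureOverlap:
    def test_half_overlap_boundary(self):
        ref = [iv(0, 110)]
        assert capture_overlap([iv(100, 120)], ref) == [True]    # 10 of 20
        assert capture_overlap([iv(101, 121)], ref) == [False]   # 9 of 20
        assert capture_overlap([iv(50, 60)], ref) == [True]      # nested

    def test_union_of_adjacent_references_counts(self):
        ref = [iv(0, 10), iv(10, 20)]
        assert capture_overlap([iv(5, 15)], ref, min_frac=1.0) == [True]

    def test_monotone_in_min_frac(self, rng):
        ref = [iv(int(s), int(s) + 20) for s in rng.integers(0, 900, 40)]
        queries = [iv(int(s), int(s) + int(n))
                   for s, n in zip(rng.integers(0, 950, 60),
                                   rng.integers(5, 40, 60))]
        prev = None
        for frac in (0.9, 0.5, 0.1):
            got = capture_overlap(queries, ref, min_frac=frac)
            if prev is not None:
                assert all(b or not a for a, b in zip(prev, got))
            prev = got


class TestSiteDensity:
    def test_density_formula(self):
        assert site_density(0.5, 100, 25) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            site_density(0.5, 100, 0)
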