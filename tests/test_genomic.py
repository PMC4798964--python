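import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiconcord.genomic import (
    GenomeSpec,
    GenomicInterval,
    RegionSet,
    ShuffleParams,
    TssAnnotation,
    intersect_fraction,
    jaccard,
    read_bed,
    region_fpkm,
    shuffle_matched,
    tss_distance_classify,
    write_bed,
)
from oracle_utils import brute_intersect_fraction, brute_jaccard, random_regionset


class TestGenomicInterval:
    def test_invariants(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)

    def test_len_and_midpoint(self):
        iv = GenomicInterval("chr1", 10, 30)
        assert len(iv) == 20
        assert iv.midpoint == 20


class TestRegionSet:
    def test_sorted_on_construction(self):
        rs = RegionSet.from_tuples([("chr2", 5, 10), ("chr1", 50, 60), ("chr1", 5, 10)])
        assert [(iv.chrom, iv.start) for iv in rs] == [
            ("chr1", 5), ("chr1", 50), ("chr2", 5)
        ]

    def test_merge_book_ended(self):
        rs = RegionSet.from_tuples([("chr1", 0, 10), ("chr1", 10, 20), ("chr1", 30, 40)])
        merged = rs.merged()
        assert [(iv.start, iv.end) for iv in merged] == [(0, 20), (30, 40)]

    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 50)), min_size=1, max_size=30
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_merge_idempotent(self, raw):
        rs = RegionSet.from_tuples([("chr1", s, s + l) for s, l in raw])
        once = rs.merged()
        assert once.merged() == once


class TestIntersectFraction:
    def test_one_of_two(self):
        a = RegionSet.from_tuples([("chr1", 0, 100), ("chr1", 200, 300)])
        b = RegionSet.from_tuples([("chr1", 50, 150)])
        res = intersect_fraction(a, b)
        assert res.fraction == 0.5
        assert res.n_overlapping == 1

    def test_identity(self):
        a = random_regionset(np.random.default_rng(0), 20)
        assert intersect_fraction(a, a).fraction == 1.0

    def test_min_bp(self):
        a = RegionSet.from_tuples([("chr1", 0, 100)])
        b = RegionSet.from_tuples([("chr1", 95, 200)])
        assert intersect_fraction(a, b, min_bp=5).fraction == 1.0
        assert intersect_fraction(a, b, min_bp=6).fraction == 0.0

    def test_matches_bruteforce_on_random_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            a = random_regionset(rng, 200)
            b = random_regionset(rng, 200)
            assert intersect_fraction(a, b).fraction == pytest.approx(
                brute_intersect_fraction(a, b), abs=0
            )

    def test_mismatched_namespace_error(self):
        a = RegionSet.from_tuples([("chr1", 0, 10)])
        b = RegionSet.from_tuples([("scaffold_9", 0, 10)])
        with pytest.raises(ValueError, match="namespace"):
            intersect_fraction(a, b)


class TestJaccard:
    def test_identical(self):
        a = random_regionset(np.random.default_rng(1), 30)
        assert jaccard(a, a) == 1.0

    def test_disjoint(self):
        a = RegionSet.from_tuples([("chr1", 0, 100)])
        b = RegionSet.from_tuples([("chr1", 200, 300)])
        assert jaccard(a, b) == 0.0

    def test_hand_computed(self):
        a = RegionSet.from_tuples([("chr1", 0, 100)])
        b = RegionSet.from_tuples([("chr1", 50, 150)])
        assert jaccard(a, b) == pytest.approx(50 / 150)

    def test_both_empty(self):
        assert jaccard(RegionSet([]), RegionSet([])) == 0.0

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            a = random_regionset(rng, 150)
            b = random_regionset(rng, 150)
            assert jaccard(a, b) == pytest.approx(brute_jaccard(a, b), abs=1e-12)


class TestShuffleMatched:
    genome = GenomeSpec(
        chrom_lengths={"chr1": 50_000, "chr2": 50_000},
        gaps=RegionSet.from_tuples([("chr1", 10_000, 12_000)]),
    )

    def _input(self):
        rng = np.random.default_rng(3)
        return RegionSet.from_tuples(
            [("chr1", int(s), int(s) + int(l)) for s, l in
             zip(rng.integers(0, 40_000, 25), rng.integers(50, 400, 25))]
        )

    def test_length_multiset_conserved(self):
        a = self._input()
        for rep in shuffle_matched(a, self.genome, ShuffleParams(n_repeats=3, seed=1)):
            assert sorted(len(iv) for iv in rep) == sorted(len(iv) for iv in a)

    def test_avoids_gaps_and_overlap(self):
        a = self._input()
        for rep in shuffle_matched(a, self.genome, ShuffleParams(n_repeats=5, seed=2)):
            assert intersect_fraction(rep, self.genome.gaps).n_overlapping == 0
            merged = rep.merged(book_ended=False)
            assert sum(len(iv) for iv in merged) == sum(len(iv) for iv in rep)

    def test_deterministic_byte_identical(self, tmp_path):
        a = self._input()
        paths = []
        for run in (0, 1):
            rs = shuffle_matched(a, self.genome, ShuffleParams(n_repeats=2, seed=7))[0]
            p = tmp_path / f"run{run}.bed"
            write_bed(rs, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_occupancy_matches_expectation(self):
        # uniform gapless genome: mean per-bp occupancy ~ placed_bp / genome_bp
        genome = GenomeSpec(chrom_lengths={"chr1": 100_000})
        a = RegionSet.from_tuples([("chr1", i * 200, i * 200 + 100) for i in range(20)])
        total = np.zeros(100_000)
        n_runs = 100
        for seed in range(n_runs):
            reps = shuffle_matched(a, genome, ShuffleParams(n_repeats=10, seed=seed))
            for rep in reps:
                for iv in rep:
                    total[iv.start: iv.end] += 1
        expected = n_runs * 10 * (20 * 100) / 100_000
        assert abs(total.mean() - expected) / expected < 0.05

    def test_impossible_placement_errors(self):
        genome = GenomeSpec(chrom_lengths={"chr1": 1000})
        a = RegionSet.from_tuples([("chr1", 0, 600), ("chr1", 600, 1000)])
        big = RegionSet.from_tuples([("chr1", 0, 600)] )
        with pytest.raises(RuntimeError, match="repeat 0"):
            shuffle_matched(
                RegionSet(list(a) + list(big)), genome, ShuffleParams(n_repeats=1, seed=0)
            )


class TestRegionFpkm:
    def test_derived_example(self):
        region = RegionSet.from_tuples([("chr1", 0, 1000)])
        frags = [GenomicInterval("chr1", 100 + i, 150 + i) for i in range(10)]
        vals = region_fpkm(frags, region, library_size=10**6)
        assert vals[0] == pytest.approx(10.0)

    def test_zero_fragments(self):
        region = RegionSet.from_tuples([("chr1", 0, 1000)])
        assert region_fpkm([], region, 10**6)[0] == 0.0

    def test_library_scaling(self):
        region = RegionSet.from_tuples([("chr1", 0, 1000)])
        frags = [GenomicInterval("chr1", 10, 60)] * 4
        v1 = region_fpkm(frags, region, 1000)
        v2 = region_fpkm(frags, region, 2000)
        assert np.allclose(v1, 2 * v2)

    def test_fragment_order_invariance(self):
        rng = np.random.default_rng(5)
        frags = [
            GenomicInterval("chr1", int(s), int(s) + 50)
            for s in rng.integers(0, 5000, 100)
        ]
        regions = random_regionset(rng, 30, chroms=("chr1",), max_pos=5000)
        v1 = region_fpkm(frags, regions, 10**5)
        rng.shuffle(frags)
        v2 = region_fpkm(frags, regions, 10**5)
        assert np.array_equal(v1, v2)


class TestTssDistance:
    tss = [TssAnnotation("g1", "chr1", 10_000, "+")]

    def test_derived_example(self):
        regions = RegionSet.from_tuples([("chr1", 10_500, 11_000)])
        rec = tss_distance_classify(regions, self.tss)[0]
        assert rec.distance == 750
        assert rec.bucket == "<10kb"

    @pytest.mark.parametrize(
        "mid,expected", [(35_000, "10-100kb"), (160_000, ">100kb"), (15_000, "<10kb")]
    )
    def test_buckets(self, mid, expected):
        regions = RegionSet.from_tuples([("chr1", mid - 50, mid + 50)])
        assert tss_distance_classify(regions, self.tss)[0].bucket == expected

    def test_boundary_10kb_goes_mid(self):
        regions = RegionSet.from_tuples([("chr1", 19_950, 20_050)])  # midpoint 20000
        rec = tss_distance_classify(regions, self.tss)[0]
        assert rec.distance == 10_000
        assert rec.bucket == "10-100kb"

    def test_no_tss_chrom_flagged(self):
        regions = RegionSet.from_tuples([("chrX", 0, 100)])
        rec = tss_distance_classify(regions, self.tss)[0]
        assert rec.flagged and rec.distance is None


class TestBedIO:
    def test_round_trip(self, tmp_path):
        rs = RegionSet(
            [
                GenomicInterval("chr1", 5, 50, name="a", score=1.5, strand="+"),
                GenomicInterval("chr2", 0, 10, name="b", score=2.0, strand="-"),
            ]
        )
        p = tmp_path / "x.bed"
        write_bed(rs, p)
        back = read_bed(p)
        assert [(iv.chrom, iv.start, iv.end, iv.name) for iv in back] == [
            ("chr1", 5, 50, "a"), ("chr2", 0, 10, "b")
        ]

    def test_writer_emits_sorted(self, tmp_path):
        rs = RegionSet.from_tuples([("chr2", 0, 5), ("chr1", 3, 9)])
        p = tmp_path / "y.bed"
        write_bed(rs, p)
        lines = p.read_text().splitlines()
        assert lines[0].startswith("chr1")
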