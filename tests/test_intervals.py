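"""Interval algebra: bedtools-semantics checks against per-base oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from rddmloci.intervals import (
    Genome,
    GenomicInterval,
    IntervalSet,
    intersect_segments,
    merge_within,
    partition_by_overlap,
    read_bed,
    shuffle_intervals,
    write_bed,
)

from conftest import COORD_MAX, coverage_mask, oracle_overlaps, random_interval_set


class TestGenomicInterval:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)  # degenerate span
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 10)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 10, score=-1.0)

    def test_genome_bounds_checked(self):
        g = Genome({"chr1": 100})
        with pytest.raises(ValueError):
            IntervalSet([GenomicInterval("chr1", 0, 200)], genome=g)
        with pytest.raises(ValueError):
            IntervalSet([GenomicInterval("chrX", 0, 10)], genome=g)

    def test_canonical_sort_order(self):
        a = GenomicInterval("chr2", 0, 10)
        b = GenomicInterval("chr1", 50, 60)
        c = GenomicInterval("chr1", 5, 10)
        assert IntervalSet([a, b, c]).intervals == (c, b, a)


class TestIntersectSegments:
    def test_empty_annihilates(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 100)])
        assert len(intersect_segments(a, IntervalSet())) == 0
        assert len(intersect_segments(IntervalSet(), a)) == 0

    def test_basic_overlap(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 100)])
        b = IntervalSet([GenomicInterval("chr1", 50, 150)])
        out = intersect_segments(a, b)
        assert out.intervals == (GenomicInterval("chr1", 50, 100),)

    def test_self_intersection_preserves_coverage(self, rng):
        s = random_interval_set(rng)
        if len(s):
            out = intersect_segments(s, s)
            assert out.coverage_length() == s.coverage_length()

    def test_disjoint_chromosome_namespaces_error(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 10)])
        b = IntervalSet([GenomicInterval("scaffold_7", 0, 10)])
        with pytest.raises(ValueError, match="chr1|scaffold_7"):
            intersect_segments(a, b)

    def test_matches_per_base_oracle(self, rng):
        for _ in range(50):
            a = random_interval_set(rng, n_max=50)
            b = random_interval_set(rng, n_max=50)
            if len(a) == 0 or len(b) == 0 or a.chroms.isdisjoint(b.chroms):
                continue
            out = intersect_segments(a, b)
            am, bm = coverage_mask(a), coverage_mask(b)
            om = coverage_mask(out)
            for chrom in am:
                np.testing.assert_array_equal(om[chrom], am[chrom] & bm[chrom])


class TestPartitionByOverlap:
    def test_single_bp_overlap_is_a_hit(self):
        q = IntervalSet([GenomicInterval("chr1", 0, 10)])
        r = IntervalSet([GenomicInterval("chr1", 9, 20)])
        hits, misses = partition_by_overlap(q, r)
        assert hits == q and len(misses) == 0

    def test_abutting_does_not_overlap(self):
        q = IntervalSet([GenomicInterval("chr1", 0, 10)])
        r = IntervalSet([GenomicInterval("chr1", 10, 20)])
        hits, misses = partition_by_overlap(q, r)
        assert misses == q and len(hits) == 0

    def test_identity_reference(self, rng):
        q = random_interval_set(rng, n_max=30)
        hits, misses = partition_by_overlap(q, q)
        assert hits == q and len(misses) == 0 or len(q) == 0

    def test_empty_reference_all_misses(self):
        q = IntervalSet([GenomicInterval("chr1", 5, 15)])
        hits, misses = partition_by_overlap(q, IntervalSet())
        assert len(hits) == 0 and misses == q

    def test_partition_exhausts_query(self, rng):
        for _ in range(20):
            q = random_interval_set(rng, n_max=100)
            r = random_interval_set(rng, n_max=100)
            hits, misses = partition_by_overlap(q, r)
            assert len(hits) + len(misses) == len(q)

    def test_matches_per_base_oracle(self, rng):
        for _ in range(50):
            q = random_interval_set(rng, n_max=50)
            r = random_interval_set(rng, n_max=50)
            hits, _ = partition_by_overlap(q, r)
            hit_set = set(hits.intervals)
            for iv in q:
                assert (iv in hit_set) == oracle_overlaps(iv, r)


class TestMergeWithin:
    def test_gap_at_boundary_merges(self):
        s = IntervalSet([GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 1000, 1100)])
        out = merge_within(s, 1000)  # gap 900 <= 1000
        assert out.intervals == (GenomicInterval("chr1", 0, 1100),)
        out = merge_within(
            IntervalSet([GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 1100, 1200)]),
            1000,
        )  # gap exactly 1000: boundary inclusive
        assert out.intervals == (GenomicInterval("chr1", 0, 1200),)

    def test_gap_beyond_boundary_does_not_merge(self):
        s = IntervalSet([GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 1101, 1200)])
        out = merge_within(s, 1000)  # gap 1001
        assert len(out) == 2

    def test_singleton_unchanged(self):
        s = IntervalSet([GenomicInterval("chr1", 7, 70)])
        assert merge_within(s, 12345) == s

    @given(st.lists(st.tuples(st.integers(0, 400), st.integers(1, 80)), max_size=30),
           st.integers(0, 100))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_idempotent_and_transitive_closure(self, spans, gap):
        s = IntervalSet(GenomicInterval("chr1", a, a + w) for a, w in spans)
        if len(s) == 0:
            return
        once = merge_within(s, gap)
        assert merge_within(once, gap) == once
        # output disjoint with pairwise gaps > gap
        ivs = once.intervals
        for x, y in zip(ivs, ivs[1:]):
            assert y.start - x.end > gap
        # coverage never shrinks
        assert once.coverage_length() >= s.coverage_length()


class TestShuffle:
    def test_preserves_length_multiset(self, rng, toy_genome):
        s = random_interval_set(rng, n_max=60)
        out = shuffle_intervals(s, toy_genome, seed=5)
        assert sorted(out.lengths()) == sorted(s.lengths())

    def test_fixed_seed_is_deterministic(self, toy_genome, rng):
        s = random_interval_set(rng, n_max=40)
        a = shuffle_intervals(s, toy_genome, seed=99)
        b = shuffle_intervals(s, toy_genome, seed=99)
        assert a == b

    def test_interval_longer_than_any_chromosome_errors(self):
        g = Genome({"chr1": 50})
        s = IntervalSet([GenomicInterval("chr1", 0, 40)])
        with pytest.raises(ValueError):
            shuffle_intervals(IntervalSet([GenomicInterval("chr1", 0, 50)]),
                              Genome({"chr1": 10}))
        # sanity: fitting interval works
        assert len(shuffle_intervals(s, g, seed=0)) == 1

    def test_placement_uniform_over_offsets(self):
        # one 1000-bp chromosome, one 100-bp interval: starts uniform on [0, 900]
        g = Genome({"chr1": 1000})
        s = IntervalSet([GenomicInterval("chr1", 0, 100)])
        starts = [
            shuffle_intervals(s, g, seed=seed)[0].start for seed in range(10_000)
        ]
        counts, _ = np.histogram(starts, bins=np.arange(0, 902, 53))
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        p = sps.chi2.sf(chi2, len(counts) - 1)
        assert p > 0.01
        assert min(starts) >= 0 and max(starts) <= 900


class TestBedIO:
    def test_read_basic(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("track name=x\nchr1\t0\t100\n# comment\nchr2\t5\t10\tpk\t3.5\t+\n")
        s = read_bed(p)
        assert s.intervals == (
            GenomicInterval("chr1", 0, 100),
            GenomicInterval("chr2", 5, 10, "+", "pk", 3.5),
        )

    @pytest.mark.parametrize("line", ["chr1\t100\t100", "chr1\t-5\t10", "chr1\t10"])
    def test_malformed_line_cites_line_number(self, tmp_path, line):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t50\n" + line + "\n")
        with pytest.raises(ValueError, match=":2"):
            read_bed(p)

    def test_round_trip_random_sets(self, tmp_path, rng):
        s = random_interval_set(rng, n_max=1000)
        p = tmp_path / "rt.bed"
        write_bed(s, p)
        assert read_bed(p) == s

    def test_round_trip_annotated(self, tmp_path):
        s = IntervalSet([GenomicInterval("chr1", 1, 9, "-", "peak1", 2.5)])
        p = tmp_path / "rt6.bed"
        write_bed(s, p)
        assert read_bed(p) == s
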