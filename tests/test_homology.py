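"""Shared segments, coverage, unique regions, copy grouping, annotation."""
import pytest

from mitodiff.homology import (
    annotate_regions,
    coverage_stats,
    find_shared_segments,
    group_region_copies,
    unique_regions,
    unique_total,
)
from mitodiff.model import CircularGenome, revcomp

from conftest import random_dna


@pytest.fixture(scope="module")
def genome_a():
    return CircularGenome("A", random_dna(41, 20_000))


class TestSharedSegments:
    def test_self_comparison_full_coverage(self, genome_a):
        segs = find_shared_segments(genome_a, genome_a)
        bp, p = coverage_stats(segs, genome_a, "query")
        assert bp == genome_a.length and p == 100.0
        assert all(s.identity == 100.0 for s in segs)
        assert unique_regions(genome_a, segs) == []

    def test_reverse_complement_full_segment(self, genome_a):
        rc = CircularGenome("R", revcomp(genome_a.sequence))
        segs = find_shared_segments(genome_a, rc)
        bp, p = coverage_stats(segs, genome_a, "query")
        assert bp == genome_a.length
        assert any(s.subject_iv.strand == "-" for s in segs)

    def test_insertion_splits_coverage(self, genome_a):
        ins = random_dna(42, 5000)
        b = CircularGenome("B", genome_a.sequence[:8000] + ins + genome_a.sequence[8000:])
        segs = find_shared_segments(b, genome_a)
        bp, _ = coverage_stats(segs, b, "query")
        assert b.length - 5000 <= bp <= b.length - 5000 + 62
        (region,) = unique_regions(b, segs)
        assert abs(region.iv.lo - 8001) <= 31
        assert abs(region.length - 5000) <= 62

    def test_min_identity_validated(self, genome_a):
        with pytest.raises(ValueError):
            find_shared_segments(genome_a, genome_a, min_identity=120.0)

    def test_symmetry_of_coverage(self, genome_a):
        ins = random_dna(43, 2000)
        b = CircularGenome("B", genome_a.sequence[:5000] + ins + genome_a.sequence[5000:])
        ab = find_shared_segments(genome_a, b)
        ba = find_shared_segments(b, genome_a)
        cov_a_query, _ = coverage_stats(ab, genome_a, "query")
        cov_a_subject, _ = coverage_stats(ba, genome_a, "subject")
        assert abs(cov_a_query - cov_a_subject) <= 62


class TestCoverageStats:
    def test_no_segments(self, genome_a):
        assert coverage_stats([], genome_a) == (0, 0.0)

    def test_bad_side(self, genome_a):
        with pytest.raises(ValueError):
            coverage_stats([], genome_a, side="middle")


class TestUniqueRegions:
    def test_planted_insertions_recovered(self, genome_a):
        i1, i2, i3 = random_dna(44, 200), random_dna(45, 500), random_dna(46, 6371)
        seq = (
            genome_a.sequence[:2000] + i1 + genome_a.sequence[2000:9000] + i2
            + genome_a.sequence[9000:15000] + i3 + genome_a.sequence[15000:]
        )
        c = CircularGenome("C", seq)
        regions = unique_regions(c, find_shared_segments(c, genome_a))
        assert [r.id for r in regions] == ["U1", "U2", "U3"]
        expected = [(2001, 200), (9201, 500), (15701, 6371)]
        for r, (start, length) in zip(regions, expected):
            assert abs(r.iv.lo - start) <= 31
            assert abs(r.length - length) <= 62

    def test_short_insertion_below_threshold_excluded(self, genome_a):
        short = random_dna(47, 80)
        c = CircularGenome("C", genome_a.sequence[:4000] + short + genome_a.sequence[4000:])
        regions = unique_regions(c, find_shared_segments(c, genome_a), min_len=100)
        assert regions == []

    def test_conservation_with_filter_disabled(self, genome_a):
        ins = random_dna(48, 1500)
        c = CircularGenome("C", genome_a.sequence[:6000] + ins + genome_a.sequence[6000:])
        segs = find_shared_segments(c, genome_a)
        covered, _ = coverage_stats(segs, c, "query")
        regions = unique_regions(c, segs, min_len=0)
        assert covered + sum(r.length for r in regions) == c.length

    def test_unique_total_counts_every_copy(self, genome_a):
        ins = random_dna(49, 400)
        seq = genome_a.sequence
        c = CircularGenome("C", seq[:3000] + ins + seq[3000:9000] + ins + seq[9000:])
        regions = unique_regions(c, find_shared_segments(c, genome_a))
        total, p = unique_total(regions, c.length)
        assert abs(total - 800) <= 4
        assert p == pytest.approx(100 * total / c.length, abs=0.01)


class TestGroupRegionCopies:
    def test_identical_insertions_form_one_group(self, genome_a):
        ins = random_dna(51, 400)
        seq = genome_a.sequence
        c = CircularGenome(
            "C",
            seq[:1000] + ins + seq[1000:5000] + ins + seq[5000:9000] + ins
            + seq[9000:13000] + ins + seq[13000:],
        )
        regions = unique_regions(c, find_shared_segments(c, genome_a))
        groups = group_region_copies(regions, c)
        assert len(regions) == 4
        assert sorted(len(v) for v in groups.values()) == [4]
        assert all(r.group_size == 4 for r in regions)

    def test_distinct_insertions_stay_single(self, genome_a):
        seq = genome_a.sequence
        c = CircularGenome(
            "C", seq[:1000] + random_dna(52, 400) + seq[1000:5000] + random_dna(53, 400) + seq[5000:]
        )
        regions = unique_regions(c, find_shared_segments(c, genome_a))
        group_region_copies(regions, c)
        assert all(r.group_size == 1 for r in regions)

    def test_diverged_copies_split_at_threshold(self, genome_a):
        ins = list(random_dna(54, 400))
        div = ins.copy()
        step = 20  # 5% divergence: 20 substitutions in 400 bp
        for p in range(0, 400, step):
            div[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[div[p]]
        seq = genome_a.sequence
        c = CircularGenome(
            "C", seq[:1000] + "".join(ins) + seq[1000:5000] + "".join(div) + seq[5000:]
        )
        regions = unique_regions(c, find_shared_segments(c, genome_a))
        assert len(regions) == 2
        group_region_copies(regions, c, min_group_identity=97.0)
        assert all(r.group_size == 1 for r in regions)
        group_region_copies(regions, c, min_group_identity=90.0)
        assert all(r.group_size == 2 for r in regions)


@pytest.fixture(scope="module")
def ct():
    return CircularGenome("ct", random_dna(55, 10_000))


class TestAnnotateRegions:
    def _regions_for(self, genome_a, insert):
        c = CircularGenome("C", genome_a.sequence[:4000] + insert + genome_a.sequence[4000:])
        regions = unique_regions(c, find_shared_segments(c, genome_a))
        return c, regions

    def test_ct_derived(self, genome_a, ct):
        c, regions = self._regions_for(genome_a, ct.sequence[2000:2800])
        annotate_regions(regions, c, {"ct_genome": ct})
        assert [r.source_class for r in regions] == ["ct-derived"]

    def test_novel(self, genome_a, ct):
        c, regions = self._regions_for(genome_a, random_dna(56, 800))
        annotate_regions(regions, c, {"ct_genome": ct})
        assert [r.source_class for r in regions] == ["novel"]

    def test_mixed_with_sub_intervals(self, genome_a, ct):
        c, regions = self._regions_for(genome_a, ct.sequence[500:1100] + random_dna(57, 600))
        annotate_regions(regions, c, {"ct_genome": ct})
        (r,) = regions
        assert r.source_class == "mixed"
        assert len(r.hits) >= 1
        cls, s, e, _ = r.hits[0]
        assert cls == "ct-derived" and e - s + 1 >= 500

    def test_empty_reference_warns_all_novel(self, genome_a, ct):
        c, regions = self._regions_for(genome_a, random_dna(58, 500))
        with pytest.warns(UserWarning):
            annotate_regions(regions, c, {})
        assert [r.source_class for r in regions] == ["novel"]
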