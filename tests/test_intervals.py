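import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import intersect_filter_oracle, merge_oracle
from snpenrich.intervals import (
    GenomicInterval,
    IntervalSet,
    build_compendium,
    filter_by_length,
    intersect_clip,
    intersect_filter,
    merge_within_gap,
    read_bed,
    write_bed,
)

GI = GenomicInterval


def iset(*triples, name=""):
    return IntervalSet([GI(*t) for t in triples], name=name)


class TestGenomicInterval:
    @pytest.mark.parametrize(
        "chrom,start,end", [("chr1", -1, 5), ("chr1", 10, 10), ("chr1", 10, 5), ("", 0, 5)]
    )
    def test_invalid_rejected(self, chrom, start, end):
        with pytest.raises(ValueError):
            GI(chrom, start, end)

    def test_length_and_overlap(self):
        a, b = GI("chr1", 0, 5000), GI("chr1", 4999, 5200)
        assert a.length == 5000
        assert a.overlaps(b)
        assert not a.overlaps(GI("chr1", 5000, 5200))  # abutting shares no base
        assert not a.overlaps(GI("chr2", 0, 5000))


class TestBedIO:
    def test_read_sorts_and_skips_headers(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("track name=x\n# comment\nchr1\t100\t200\nchr1\t50\t80\n\n")
        s = read_bed(p)
        assert [(i.chrom, i.start, i.end) for i in s] == [("chr1", 50, 80), ("chr1", 100, 200)]

    def test_reversed_coordinates_error_names_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t200\nchr1\t200\t100\n")
        with pytest.raises(ValueError, match="bad.bed:2"):
            read_bed(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.bed"
        p.write_text("")
        assert len(read_bed(p)) == 0

    def test_round_trip_with_name_column(self, tmp_path):
        s = iset(("chr2", 5, 9), ("chr1", 0, 10), name="enh")
        path = tmp_path / "rt.bed"
        write_bed(s, path)
        assert "\tenh" in path.read_text()
        assert read_bed(path) == s


class TestMergeWithinGap:
    def test_gap_strictly_less_merges(self):
        assert merge_within_gap(iset(("chr1", 100, 200), ("chr1", 250, 400)), 100) == iset(
            ("chr1", 100, 400)
        )

    def test_gap_equal_does_not_merge(self):
        s = iset(("chr1", 100, 200), ("chr1", 300, 400))
        assert merge_within_gap(s, 100) == s

    def test_cross_chromosome_never_merges(self):
        s = iset(("chr1", 100, 200), ("chr2", 100, 200))
        assert merge_within_gap(s, 10**9) == s

    def test_abutting_and_overlapping_always_merge(self):
        s = iset(("chr1", 0, 100), ("chr1", 100, 200), ("chr1", 150, 300))
        assert merge_within_gap(s, 0) == iset(("chr1", 0, 300))

    @given(
        st.lists(
            st.tuples(st.integers(0, 9_900), st.integers(1, 100)).map(
                lambda t: ("chr1", t[0], t[0] + t[1])
            ),
            min_size=0,
            max_size=50,
        ),
        st.integers(0, 300),
    )
    @settings(max_examples=60, deadline=None)
    def test_idempotent_and_coverage_monotone(self, triples, gap):
        s = iset(*triples)
        once = merge_within_gap(s, gap)
        assert merge_within_gap(once, gap) == once
        assert once.total_bases() >= s.normalize().total_bases()
        assert once.is_normalized()


class TestFilterByLength:
    def test_strict_lower_bound(self):
        assert len(filter_by_length(iset(("chr1", 0, 2000)), 2000)) == 0
        assert len(filter_by_length(iset(("chr1", 0, 2001)), 2000)) == 1

    def test_upper_bound_inclusive(self):
        assert len(filter_by_length(iset(("chr1", 0, 300_000)), 3000, 200_000)) == 0
        assert len(filter_by_length(iset(("chr1", 0, 200_000)), 3000, 200_000)) == 1

    def test_never_increases_count(self, rng):
        ivs = [("chr1", int(s), int(s) + int(l)) for s, l in
               zip(rng.integers(0, 10**6, 30), rng.integers(1, 5000, 30))]
        s = iset(*ivs)
        assert len(filter_by_length(s, 1000)) <= len(s)


class TestIntersectFilter:
    def test_single_base_overlap_keeps_whole_stretch(self):
        out = intersect_filter(iset(("chr1", 0, 5000)), iset(("chr1", 4999, 5200)))
        assert out == iset(("chr1", 0, 5000))

    def test_abutting_mark_does_not_count(self):
        assert len(intersect_filter(iset(("chr1", 0, 5000)), iset(("chr1", 5000, 5200)))) == 0

    def test_marks_on_other_chromosome(self):
        assert len(intersect_filter(iset(("chr1", 0, 5000)), iset(("chr2", 0, 5000)))) == 0

    def test_subset_of_input(self, rng):
        stretches = iset(*[("chr1", int(s), int(s) + 100) for s in rng.integers(0, 9000, 20)])
        marks = iset(*[("chr1", int(s), int(s) + 50) for s in rng.integers(0, 9000, 10)])
        out = intersect_filter(stretches, marks)
        assert set(out.intervals) <= set(stretches.intervals)

    def test_clip_mode_cuts_to_shared_bases(self):
        out = intersect_clip(iset(("chr1", 0, 5000)), iset(("chr1", 4000, 6000)))
        assert out == iset(("chr1", 4000, 5000))


def random_instance(rng, n=12, size=10_000):
    starts = rng.integers(0, size - 200, n)
    lengths = rng.integers(1, 200, n)
    return [(int(s), int(s + l)) for s, l in zip(starts, lengths)]


def test_merge_and_intersect_match_bitmap_oracle(rng):
    """Interval algebra agrees with a per-base bitmap on a 10 kb toy chromosome."""
    size = 10_000
    for _ in range(300):
        ivs = random_instance(rng)
        gap = int(rng.integers(0, 400))
        got = merge_within_gap(iset(*[("chr1", s, e) for s, e in ivs]), gap)
        assert [(i.start, i.end) for i in got] == merge_oracle(ivs, gap, size)

        stretches = merge_oracle(ivs, 0, size)
        marks = random_instance(rng, n=6)
        min_ov = int(rng.integers(1, 50))
        got2 = intersect_filter(
            iset(*[("chr1", s, e) for s, e in stretches]),
            iset(*[("chr1", s, e) for s, e in marks]),
            min_overlap=min_ov,
        )
        assert [(i.start, i.end) for i in got2] == intersect_filter_oracle(
            stretches, marks, min_ov, size
        )


class TestBuildCompendium:
    def test_hnisz_merges_then_length_filters(self):
        marks = {"H3K27Ac": iset(("chr1", 0, 900), ("chr1", 950, 2200))}
        comp = build_compendium("HNISZ_generic", marks)
        assert comp.intervals == iset(("chr1", 0, 2200))

    def test_hnisz_short_cluster_dropped(self):
        comp = build_compendium("HNISZ_generic", {"H3K27Ac": iset(("chr1", 0, 1500))})
        assert len(comp) == 0

    def test_pc_consensus_requires_both_vcap_features(self):
        lncap = iset(("chr1", 0, 10_000))
        marks = {
            "LNCaP_H3K27Ac": lncap,
            "LNCaP_MED12": iset(("chr1", 100, 200)),
            "VCaP_H3K27Ac": iset(("chr1", 0, 5000)),
            "VCaP_BRD4": iset(("chr2", 0, 500)),  # wrong chromosome
        }
        assert len(build_compendium("PC_consensus", marks)) == 0
        marks["VCaP_BRD4"] = iset(("chr1", 400, 700))
        assert build_compendium("PC_consensus", marks).intervals == lncap

    def test_missing_mark_names_it(self):
        with pytest.raises(KeyError, match="VCaP_BRD4"):
            build_compendium("VCaP_BRD4", {})

    def test_recipe_provenance_recorded(self):
        comp = build_compendium(
            "HNISZ_generic",
            {"H3K27Ac": iset(("chr1", 0, 3000)), "BRD4": iset(("chr1", 10, 20))},
            binding_marks=["BRD4"],
        )
        assert comp.recipe["recipe_id"] == "HNISZ_generic"
        assert comp.recipe["binding_marks"] == ["BRD4"]
        assert comp.source_marks == ["H3K27Ac", "BRD4"]

    def test_deterministic_bed_output(self, tmp_path, rng):
        ivs = [("chr1", int(s), int(s) + int(l)) for s, l in
               zip(rng.integers(0, 10**6, 40), rng.integers(100, 3000, 40))]
        marks = {"H3K27Ac": iset(*ivs)}
        p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
        write_bed(build_compendium("HNISZ_generic", marks).intervals, p1)
        write_bed(build_compendium("HNISZ_generic", marks).intervals, p2)
        assert p1.read_bytes() == p2.read_bytes()
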