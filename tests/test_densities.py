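"""Pileup, track serialization, profile extraction and read counting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pol3scan.annotations import GeneAnnotation, extend_gene
from pol3scan.densities import (
    READ_COLUMNS,
    ReadRecord,
    StrandedTrack,
    count_reads,
    extract_profile,
    pileup,
    pileup_ends,
    read_bed6,
    read_track,
    reads_from_records,
    write_bed6,
    write_track,
)

SIZES = {"chrT": 200}


def make_reads(rows):
    """rows: (start, end, strand[, n_hits]) on chrT."""
    recs = [ReadRecord("chrT", r[0], r[1], r[2], r[3] if len(r) > 3 else 1) for r in rows]
    return reads_from_records(recs)


class TestPileup:
    def test_no_reads_all_zero(self):
        track = pileup(pd.DataFrame(columns=READ_COLUMNS), SIZES)
        assert track.total() == 0

    def test_two_overlapping_reads_brute_force(self):
        reads = make_reads([(0, 10, "+"), (5, 15, "+")])
        track = pileup(reads, SIZES)
        values = track.values("chrT", "+")
        expected = np.zeros(200)
        for s, e in [(0, 10), (5, 15)]:
            expected[s:e] += 1
        assert np.array_equal(values, expected)
        assert np.array_equal(values[5:10], np.full(5, 2.0))

    def test_unique_only_drops_multimappers(self):
        reads = make_reads([(0, 10, "+", 2)])
        assert pileup(reads, SIZES, unique_only=True).total() == 0
        assert pileup(reads, SIZES, unique_only=False).total() == 10

    def test_strands_kept_separate(self):
        reads = make_reads([(0, 10, "+"), (0, 10, "-")])
        track = pileup(reads, SIZES)
        assert track.values("chrT", "+")[:10].sum() == 10
        assert track.values("chrT", "-")[:10].sum() == 10

    def test_unknown_chromosome_is_error(self):
        reads = reads_from_records([ReadRecord("chrX", 0, 5, "+")])
        with pytest.raises(KeyError):
            pileup(reads, SIZES)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 180), st.integers(1, 20), st.sampled_from("+-")),
            min_size=0,
            max_size=25,
        )
    )
    def test_mass_conservation(self, raw):
        reads = make_reads([(s, s + w, strand) for s, w, strand in raw])
        track = pileup(reads, SIZES)
        expected = sum(w for _, w, _ in raw)
        assert track.total() == expected

    def test_end_pileup_puts_single_base_marks(self):
        reads = make_reads([(10, 40, "+"), (10, 40, "-")])
        track = pileup_ends(reads, SIZES)
        plus = track.values("chrT", "+")
        minus = track.values("chrT", "-")
        assert plus[39] == 1 and plus.sum() == 1  # plus-strand 3' end = end-1
        assert minus[10] == 1 and minus.sum() == 1  # minus-strand 3' end = start


class TestTrackIO:
    def base_track(self):
        track = StrandedTrack(SIZES)
        track.values("chrT", "+")[7] = 3.0
        return track

    def test_zero_track_empty_file(self, tmp_path):
        path = tmp_path / "t.sgr"
        write_track(StrandedTrack(SIZES), path, "sgr")
        assert path.read_text() == ""

    def test_sgr_positions_are_one_based(self, tmp_path):
        path = tmp_path / "t.sgr"
        write_track(self.base_track(), path, "sgr")
        chrom, pos, value = path.read_text().split()
        assert (chrom, pos, value) == ("chrT", "8", "3")

    def test_sgrs_round_trip_exact(self, tmp_path):
        track = self.base_track()
        track.values("chrT", "-")[100] = 2.5
        path = tmp_path / "t.sgrs"
        write_track(track, path, "sgrs")
        back = read_track(path, "sgrs", SIZES)
        for key, arr in track.items():
            assert np.array_equal(back.values(*key), arr)

    def test_bedgraph_round_trip_of_step_function(self, tmp_path):
        track = StrandedTrack(SIZES)
        track.values("chrT", "+")[10:20] = 1.0
        track.values("chrT", "+")[20:35] = 4.0
        path = tmp_path / "t.bedgraph"
        write_track(track, path, "bedgraph")
        back = read_track(path, "bedgraph", SIZES)
        assert np.array_equal(back.values("chrT", "+"), track.values("chrT", "+"))

    def test_sgr_rejects_two_stranded_track(self, tmp_path):
        track = self.base_track()
        track.values("chrT", "-")[3] = 1.0
        with pytest.raises(ValueError, match="single-strand"):
            write_track(track, tmp_path / "t.sgr", "sgr")

    def test_bed6_round_trip(self, tmp_path):
        reads = make_reads([(0, 10, "+", 2), (5, 15, "-")])
        path = tmp_path / "r.bed"
        write_bed6(reads, path)
        back = read_bed6(path)
        pd.testing.assert_frame_equal(back, reads)


class TestExtractProfile:
    def gene(self, strand):
        return GeneAnnotation("g", "chrT", 60, 120, strand, biotype="tRNA")

    def test_mirror_symmetry_between_strands(self):
        track = StrandedTrack(SIZES)
        sig = np.arange(200, dtype=float)
        track.values("chrT", "+")[:] = sig
        track.values("chrT", "-")[:] = sig
        # equal flanks so both extended windows cover the same genomic span
        plus = extract_profile(track, extend_gene(self.gene("+"), 25, 25, 200))
        minus = extract_profile(track, extend_gene(self.gene("-"), 25, 25, 200))
        assert np.array_equal(minus.values, plus.values[::-1])

    def test_sum_conservation_and_anchors(self):
        track = StrandedTrack(SIZES)
        track.values("chrT", "+")[:] = np.random.default_rng(0).random(200)
        ext = extend_gene(self.gene("+"), 20, 30, 200)
        gv = extract_profile(track, ext)
        assert np.isclose(gv.values.sum(), track.values("chrT", "+")[40:150].sum())
        assert gv.anchors["mature5"] == 20
        assert gv.anchors["mature3"] == 20 + 60 - 1

    def test_minus_strand_anchors_point_at_mature_ends(self):
        track = StrandedTrack(SIZES)
        track.values("chrT", "-")[119] = 5.0  # genomic base of the minus-strand 5' end
        gv = extract_profile(track, extend_gene(self.gene("-"), 20, 30, 200))
        assert gv.values[gv.anchors["mature5"]] == 5.0

    def test_double_reversal_is_identity(self):
        track = StrandedTrack(SIZES)
        track.values("chrT", "-")[:] = np.random.default_rng(1).random(200)
        ext = extend_gene(self.gene("-"), 20, 30, 200)
        gv = extract_profile(track, ext)
        assert np.array_equal(gv.values[::-1], track.values("chrT", "-")[ext.ext_start : ext.ext_end])


class TestCountReads:
    def test_three_prime_end_convention_plus(self):
        reads = make_reads([(10, 40, "+")])
        assert count_reads(reads, "chrT", 35, 60, "+", "three_prime_end") == 1
        assert count_reads(reads, "chrT", 0, 20, "+", "three_prime_end") == 0
        assert count_reads(reads, "chrT", 0, 20, "+", "any_overlap") == 1

    def test_three_prime_end_convention_minus(self):
        reads = make_reads([(10, 40, "-")])
        assert count_reads(reads, "chrT", 10, 11, "-", "three_prime_end") == 1
        assert count_reads(reads, "chrT", 35, 60, "-", "three_prime_end") == 0

    def test_opposite_strand_never_counts(self):
        reads = make_reads([(10, 40, "+")])
        for mode in ("three_prime_end", "any_overlap", "midpoint"):
            assert count_reads(reads, "chrT", 0, 200, "-", mode) == 0

    def test_midpoint_mode(self):
        reads = make_reads([(10, 40, "+")])
        assert count_reads(reads, "chrT", 25, 26, "+", "midpoint") == 1
        assert count_reads(reads, "chrT", 26, 200, "+", "midpoint") == 0

    def test_end_counting_is_partition_exclusive_but_overlap_is_not(self):
        rng = np.random.default_rng(5)
        rows = [(int(s), int(s) + int(w), "+") for s, w in zip(rng.integers(0, 150, 40), rng.integers(5, 30, 40))]
        reads = make_reads([(s, min(e, 200), st) for s, e, st in rows])
        whole = (0, 180)
        parts = [(0, 60), (60, 120), (120, 180)]
        end_sum = sum(count_reads(reads, "chrT", a, b, "+", "three_prime_end") for a, b in parts)
        assert end_sum == count_reads(reads, "chrT", *whole, "+", "three_prime_end")
        overlap_sum = sum(count_reads(reads, "chrT", a, b, "+", "any_overlap") for a, b in parts)
        assert overlap_sum > count_reads(reads, "chrT", *whole, "+", "any_overlap")
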