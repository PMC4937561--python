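"""Coverage thresholding, BEDTools-style merging and novel-unit discovery."""

import numpy as np
import pytest

from pol3scan.annotations import extend_gene
from pol3scan.densities import StrandedTrack, pileup
from pol3scan.discovery import CandidateFeature, discover_novel, merge_intervals, threshold_runs
from pol3scan.synthetic_data import simulate_dataset


def track_with(segments, size=300):
    """segments: (start, end, height, strand)."""
    track = StrandedTrack({"chrT": size})
    for s, e, h, strand in segments:
        track.values("chrT", strand)[s:e] = h
    return track


def feat(start, end, strand="+", max_h=60.0, mean_h=60.0):
    return CandidateFeature("chrT", strand, start, end, max_h, mean_h)


class TestThresholdRuns:
    def test_zero_track_empty(self):
        assert threshold_runs(track_with([])) == []

    def test_tall_wide_plateau_found(self):
        (f,) = threshold_runs(track_with([(40, 52, 60, "+")]))
        assert (f.start, f.end, f.max_height, f.mean_height) == (40, 52, 60.0, 60.0)

    def test_short_plateau_filtered_by_length(self):
        assert threshold_runs(track_with([(40, 49, 60, "+")])) == []

    def test_low_plateau_filtered_by_height(self):
        assert threshold_runs(track_with([(40, 60, 49.5, "+")])) == []

    def test_strands_independent(self):
        track = track_with([(10, 25, 60, "+"), (100, 140, 80, "-")])
        found = threshold_runs(track)
        assert [(f.strand, f.start, f.end) for f in found] == [("+", 10, 25), ("-", 100, 140)]

    def test_matches_brute_force_on_random_tracks(self):
        rng = np.random.default_rng(31)
        for _ in range(200):
            values = rng.choice([0, 30, 60, 80], size=120).astype(float)
            track = StrandedTrack({"chrT": 120})
            track.values("chrT", "+")[:] = values
            got = {(f.start, f.end) for f in threshold_runs(track, 50, 5)}
            # brute force: scan maximal qualifying runs
            expected = set()
            i = 0
            while i < 120:
                if values[i] >= 50:
                    j = i
                    while j < 120 and values[j] >= 50:
                        j += 1
                    if j - i >= 5:
                        expected.add((i, j))
                    i = j
                else:
                    i += 1
            assert got == expected


class TestMergeIntervals:
    def test_gap_within_d_merges(self):
        merged = merge_intervals([feat(0, 10), feat(14, 20)], d=5)
        assert [(f.start, f.end) for f in merged] == [(0, 20)]

    def test_gap_beyond_d_stays_separate(self):
        merged = merge_intervals([feat(0, 10), feat(16, 20)], d=5)
        assert [(f.start, f.end) for f in merged] == [(0, 10), (16, 20)]

    def test_merge_is_idempotent(self):
        rng = np.random.default_rng(32)
        feats = [feat(int(s), int(s) + int(w)) for s, w in zip(rng.integers(0, 250, 15), rng.integers(1, 20, 15))]
        once = merge_intervals(feats, d=7)
        twice = merge_intervals(once, d=7)
        assert [(f.start, f.end) for f in twice] == [(f.start, f.end) for f in once]

    def test_output_disjoint_with_gaps_beyond_d(self):
        rng = np.random.default_rng(33)
        feats = [feat(int(s), int(s) + int(w)) for s, w in zip(rng.integers(0, 400, 30), rng.integers(1, 25, 30))]
        merged = merge_intervals(feats, d=10)
        for a, b in zip(merged, merged[1:]):
            assert b.start - a.end > 10

    def test_heights_aggregate(self):
        merged = merge_intervals(
            [feat(0, 10, max_h=50, mean_h=50), feat(12, 17, max_h=90, mean_h=80)], d=5
        )
        (f,) = merged
        assert f.max_height == 90
        assert f.mean_height == pytest.approx((50 * 10 + 80 * 5) / 15)

    def test_different_strands_never_merge(self):
        merged = merge_intervals([feat(0, 10, "+"), feat(11, 20, "-")], d=5)
        assert len(merged) == 2

    def test_matches_bedtools_semantics_oracle(self):
        # independent set-based oracle: pad every interval by d on the right,
        # union, then trim -- equivalent to gap <= d merging
        rng = np.random.default_rng(34)
        for _ in range(300):
            n = rng.integers(1, 10)
            feats = [
                feat(int(s), int(s) + int(w))
                for s, w in zip(rng.integers(0, 120, n), rng.integers(1, 15, n))
            ]
            d = int(rng.integers(0, 12))
            got = [(f.start, f.end) for f in merge_intervals(feats, d)]
            covered = np.zeros(200, dtype=bool)
            for f in feats:
                covered[f.start : f.end + d] = True
            expected = []
            i = 0
            while i < 200:
                if covered[i]:
                    j = i
                    while j < 200 and covered[j]:
                        j += 1
                    hi = max(f.end for f in feats if f.start >= i and f.end <= j)
                    expected.append((i, hi))
                    i = j
                else:
                    i += 1
            assert got == expected


class TestMergeAgainstBedtools:
    def test_matches_bedtools_binary(self, tmp_path):
        import shutil
        import subprocess

        if shutil.which("bedtools") is None:
            pytest.skip("bedtools binary not available")
        rng = np.random.default_rng(55)
        for d in (0, 5, 200):
            n = 25
            starts = np.sort(rng.integers(0, 5000, n))
            widths = rng.integers(1, 60, n)
            feats = [feat(int(s), int(s + w)) for s, w in zip(starts, widths)]
            bed = tmp_path / f"in_{d}.bed"
            bed.write_text("".join(f"chrT\t{f.start}\t{f.end}\n" for f in feats))
            res = subprocess.run(
                ["bedtools", "merge", "-d", str(d), "-i", str(bed)],
                capture_output=True,
                text=True,
                check=True,
            )
            expected = [
                (int(a), int(b))
                for _, a, b in (line.split("\t") for line in res.stdout.strip().splitlines())
            ]
            got = [(f.start, f.end) for f in merge_intervals(feats, d)]
            assert got == expected


class TestDiscoverNovel:
    def test_signal_only_inside_annotation_yields_nothing(self, sim_small):
        cfg, genome, genes, truth, reads = sim_small
        # drop the planted novel units' reads: keep only gene-derived reads
        gene_reads = reads[~reads["name"].str.startswith("novel")]
        track = pileup(gene_reads, genome.chrom_sizes)
        exts = [extend_gene(g, 50, 250, genome.chrom_length(g.chrom)) for g in genes]
        assert discover_novel(track, exts) == []

    def test_planted_units_recovered_exactly(self, sim_small):
        cfg, genome, genes, truth, reads = sim_small
        track = pileup(reads, genome.chrom_sizes)
        exts = [extend_gene(g, 50, 250, genome.chrom_length(g.chrom)) for g in genes]
        found = {(c.start, c.end, c.strand) for c in discover_novel(track, exts)}
        planted = {(u.start, u.end, u.strand) for u in truth.novel}
        assert found == planted

    def test_nearby_units_merge_at_wide_distance(self):
        track = track_with([(10, 40, 80, "+"), (190, 230, 80, "+")], size=500)
        found = discover_novel(track, [], merge_novel=200)
        assert [(f.start, f.end) for f in found] == [(10, 230)]
        found = discover_novel(track, [], merge_novel=100)
        assert len(found) == 2

    def test_monotone_in_min_height(self):
        rng = np.random.default_rng(35)
        track = StrandedTrack({"chrT": 400})
        track.values("chrT", "+")[:] = rng.choice([0, 40, 60, 90], size=400)
        low = discover_novel(track, [], min_height=50)
        high = discover_novel(track, [], min_height=70)
        low_cover = np.zeros(400, dtype=bool)
        for f in low:
            low_cover[f.start : f.end] = True
        for f in high:
            # every high-threshold candidate lies within low-threshold cover
            assert low_cover[f.start : f.end].all()

    def test_strand_aware_subtraction_flag(self):
        track = track_with([(100, 160, 80, "+")], size=500)
        annotation = [("chrT", "-", 90, 170)]
        assert discover_novel(track, annotation, strand_aware=True) != []
        assert discover_novel(track, annotation, strand_aware=False) == []
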