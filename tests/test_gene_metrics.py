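"""Expression windows, 5':3' ratios, RT levels and condition comparisons."""

import numpy as np
import pandas as pd
import pytest

from pol3scan.annotations import GeneAnnotation
from pol3scan.densities import READ_COLUMNS, ReadRecord, reads_from_records
from pol3scan.gene_metrics import (
    compare_conditions,
    expression_level,
    hpm_normalize,
    peak_ratio_5to3,
    pre_trna_window,
    rt_level,
    surveillance_rt_frequency,
)

PLUS = GeneAnnotation("gp", "chrT", 100, 180, "+", biotype="tRNA")
MINUS = GeneAnnotation("gm", "chrT", 100, 180, "-", biotype="tRNA")


def reads_ending_at(positions, strand="+", chrom="chrT"):
    """One read per 3'-end position (length 20)."""
    recs = []
    for p in positions:
        if strand == "+":
            recs.append(ReadRecord(chrom, p - 19, p + 1, "+"))
        else:
            recs.append(ReadRecord(chrom, p, p + 20, "-"))
    return reads_from_records(recs)


class TestExpression:
    def test_no_reads_zero(self):
        assert expression_level(reads_from_records([]), PLUS) == 0

    def test_counts_only_ends_inside_window(self):
        # window for PLUS is [85, 180)
        inside = list(range(90, 100))
        outside = [80, 84, 180, 200, 220]
        reads = reads_ending_at(inside + outside)
        assert expression_level(reads, PLUS) == len(inside)

    def test_minus_strand_window_extends_toward_larger_coords(self):
        assert pre_trna_window(MINUS) == (100, 195)
        reads = reads_ending_at([185, 194, 195], strand="-")
        assert expression_level(reads, MINUS) == 2


class TestPeakRatio:
    def test_ratio_three_gives_group_one(self):
        # PLUS window [85,180), split at 85+48=133 (length 95, 5' half 48)
        reads = reads_ending_at(list(range(90, 133)) + list(range(140, 154)))
        n5 = 43
        n3 = 14
        ratio, group = peak_ratio_5to3(reads, PLUS)
        assert ratio == pytest.approx(n5 / n3)
        assert group == 1

    def test_balanced_counts_group_two(self):
        reads = reads_ending_at(list(range(90, 100)) + list(range(140, 150)))
        ratio, group = peak_ratio_5to3(reads, PLUS)
        assert ratio == 1.0
        assert group == 2

    def test_zero_three_prime_half_is_missing(self):
        reads = reads_ending_at(list(range(90, 95)))
        assert peak_ratio_5to3(reads, PLUS) == (None, None)

    def test_odd_length_extra_base_goes_to_five_prime_half(self):
        # window length 95 is odd: 5' half covers [85, 133), 3' half [133, 180)
        reads = reads_ending_at([132, 133])
        ratio, _ = peak_ratio_5to3(reads, PLUS)
        assert ratio == 1.0  # one end on each side of the split


class TestRtLevel:
    def test_all_ends_in_mature_body_zero(self):
        reads = reads_ending_at(list(range(120, 140)))
        assert rt_level(reads, PLUS) == 0.0

    def test_thirty_percent(self):
        # numerator window [195, 430); denominator [85, 430)
        extension = list(range(200, 230))  # 30 reads
        body = list(range(90, 160))  # 70 reads
        reads = reads_ending_at(extension + body)
        assert rt_level(reads, PLUS) == pytest.approx(0.30)

    def test_no_reads_missing(self):
        assert rt_level(reads_from_records([]), PLUS) is None

    def test_partition_identity_with_end_counting(self):
        # expression + gap reads + extension reads = RT denominator
        rng = np.random.default_rng(3)
        reads = reads_ending_at(sorted(rng.integers(85, 430, size=300)))
        from pol3scan.densities import count_reads
        from pol3scan.gene_metrics import rt_denominator_window, rt_numerator_window

        expr = expression_level(reads, PLUS)
        gap = count_reads(reads, "chrT", 180, 195, "+")
        num = count_reads(reads, "chrT", *rt_numerator_window(PLUS), "+")
        den = count_reads(reads, "chrT", *rt_denominator_window(PLUS), "+")
        assert expr + gap + num == den

    def test_minus_strand_mirror(self):
        # numerator window for MINUS is [-150, 85) clipped ... use genomic coords
        reads = reads_ending_at([84, 70, 60], strand="-")  # inside [−70, 85)
        body = reads_ending_at(list(range(110, 117)), strand="-")
        all_reads = pd.concat([reads, body], ignore_index=True)
        assert rt_level(all_reads, MINUS) == pytest.approx(3 / 10)


class TestHpmAndComparison:
    def test_hpm_definition_and_scale_invariance(self):
        assert hpm_normalize({"g": 5}, 1_000_000)["g"] == 5.0
        a = hpm_normalize({"g": 7}, 2_000_000)
        b = hpm_normalize({"g": 70}, 20_000_000)
        assert a["g"] == b["g"]
        with pytest.raises(ValueError):
            hpm_normalize({"g": 1}, 0)

    def test_identical_tables_identity_fit(self):
        table = {f"g{i}": float(i + 1) for i in range(10)}
        res = compare_conditions(table, table)
        assert np.allclose(res.table["ratio"], 1.0)
        assert res.slope == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_doubling_identity_transform_closed_form(self):
        a = {f"g{i}": float(i + 1) for i in range(8)}
        b = {k: 2 * v for k, v in a.items()}
        res = compare_conditions(a, b, transform="identity")
        assert np.allclose(res.table["ratio"], 2.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0)

    def test_antisymmetry_of_ratios(self):
        rng = np.random.default_rng(0)
        a = {f"g{i}": float(v) for i, v in enumerate(rng.uniform(1, 100, 12))}
        b = {f"g{i}": float(v) for i, v in enumerate(rng.uniform(1, 100, 12))}
        fwd = compare_conditions(a, b).table.set_index("gene_id")["ratio"]
        rev = compare_conditions(b, a).table.set_index("gene_id")["ratio"]
        assert np.allclose(fwd * rev, 1.0)

    def test_too_few_shared_genes_is_error(self):
        with pytest.raises(ValueError, match="shared genes"):
            compare_conditions({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})

    def test_missing_genes_dropped_and_reported(self):
        a = {f"g{i}": float(i + 1) for i in range(5)}
        b = {f"g{i}": float(2 * i) for i in range(1, 6)}
        res = compare_conditions(a, b)
        assert res.dropped_genes == ["g0", "g5"]


class TestSurveillance:
    def test_pure_body_binding_zero(self):
        reads = reads_ending_at(list(range(110, 150)))
        assert surveillance_rt_frequency(reads, [PLUS]) == 0.0

    def test_pure_extension_binding_one(self):
        reads = reads_ending_at(list(range(200, 240)))
        assert surveillance_rt_frequency(reads, [PLUS]) == 1.0

    def test_planted_fraction_recovered(self):
        rng = np.random.default_rng(11)
        n_ext, n_gene = 200, 800  # 20% in extensions
        ext_pos = rng.integers(195, 430, size=n_ext)
        gene_pos = rng.integers(85, 180, size=n_gene)
        reads = reads_ending_at(np.concatenate([ext_pos, gene_pos]))
        freq = surveillance_rt_frequency(reads, [PLUS])
        assert freq == pytest.approx(0.20, abs=1e-12)

    def test_no_signal_missing(self):
        assert surveillance_rt_frequency(reads_from_records([]), [PLUS]) is None
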