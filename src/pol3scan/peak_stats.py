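"""Peaks and troughs in read-through regions, and U-richness statistics.

Density minima within 3'-extended regions coincide with U-rich sequence:
a polymerase that releases its transcript at an oligo(U) stretch carries
no RNA and disappears from a nascent-transcript library.  The analysis
detects alternating peak/trough pairs on a lightly smoothed profile and
compares transcript-sense U content in windows around paired peaks and
troughs with a paired signed-rank (default), paired t, or rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .annotations import ExtendedGene, GenomeSequence
from .densities import GeneVector

__all__ = [
    "Extremum",
    "UTestResult",
    "find_extrema",
    "peak_trough_pairs",
    "u_content_window",
    "urichness_test",
    "collect_pair_windows",
    "MIN_MEAN_READS",
    "HALF_WIDTH",
    "SMOOTH_WINDOW",
]

SMOOTH_WINDOW = 3  #: moving-average width (nt) before extremum calling
MIN_MEAN_READS = 300  #: peak filter: mean raw density over +-10 nt of the apex
HALF_WIDTH = 10  #: U-content window half-width (20 nt total, center excluded)


@dataclass
class Extremum:
    index: int  # position within the profile array
    kind: str  # "peak" or "trough"
    height: float  # smoothed density at the extremum
    mean_reads: float  # mean raw density over +-HALF_WIDTH nt


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    if window % 2 != 1:
        raise ValueError("smoothing window must be odd")
    if window == 1:
        return values.astype(float)
    pad = window // 2
    padded = np.pad(values.astype(float), pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def _raw_extrema(smoothed: np.ndarray) -> list[tuple[int, str, float]]:
    """Strict interior extrema; plateaus collapse to their center index."""
    # compress to runs of constant value
    change = np.flatnonzero(np.diff(smoothed) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [len(smoothed)]))
    out = []
    for k in range(1, len(starts) - 1):
        v = smoothed[starts[k]]
        prev_v = smoothed[starts[k - 1]]
        next_v = smoothed[starts[k + 1]]
        center = (starts[k] + ends[k] - 1) // 2
        if v > prev_v and v > next_v:
            out.append((int(center), "peak", float(v)))
        elif v < prev_v and v < next_v:
            out.append((int(center), "trough", float(v)))
    return out


def _enforce_alternation(extrema: list[tuple[int, str, float]]) -> list[tuple[int, str, float]]:
    """Drop the lesser of two adjacent same-kind extrema until alternating."""
    out: list[tuple[int, str, float]] = []
    for ext in extrema:
        if out and out[-1][1] == ext[1]:
            prev = out[-1]
            if ext[1] == "peak":
                keep = ext if ext[2] > prev[2] else prev
            else:
                keep = ext if ext[2] < prev[2] else prev
            out[-1] = keep
        else:
            out.append(ext)
    return out


def find_extrema(
    profile: GeneVector | np.ndarray,
    region: tuple[int, int] | None = None,
    smooth_window: int = SMOOTH_WINDOW,
    min_mean_reads: float = MIN_MEAN_READS,
    half_width: int = HALF_WIDTH,
) -> list[Extremum]:
    """Alternating peaks and troughs within ``region`` of a profile.

    The signal is moving-average smoothed; strict local extrema (plateau
    centers) are found, alternation is enforced, and peaks whose mean raw
    density over +-``half_width`` nt falls below ``min_mean_reads`` are
    filtered out.  Troughs are retained only when an adjacent peak passes
    the filter.  Returned indices are relative to the full profile.
    """
    raw = profile.values if isinstance(profile, GeneVector) else np.asarray(profile, dtype=float)
    a, b = (0, len(raw)) if region is None else region
    if b - a < smooth_window:
        raise ValueError("region shorter than the smoothing window")
    segment = raw[a:b]
    smoothed = _moving_average(segment, smooth_window)
    extrema = _enforce_alternation(_raw_extrema(smoothed))

    def mean_raw(i: int) -> float:
        lo, hi = max(0, a + i - half_width), min(len(raw), a + i + half_width + 1)
        return float(raw[lo:hi].mean())

    annotated = [
        Extremum(index=a + i, kind=kind, height=h, mean_reads=mean_raw(i))
        for i, kind, h in extrema
    ]
    passing_peaks = {
        j for j, e in enumerate(annotated) if e.kind == "peak" and e.mean_reads >= min_mean_reads
    }
    kept = []
    for j, e in enumerate(annotated):
        if e.kind == "peak":
            if j in passing_peaks:
                kept.append(e)
        else:
            neighbors = {j - 1, j + 1}
            if neighbors & passing_peaks:
                kept.append(e)
    return kept


def peak_trough_pairs(extrema: list[Extremum]) -> list[tuple[Extremum, Extremum]]:
    """Each peak paired with the nearest following trough."""
    pairs = []
    for j, e in enumerate(extrema):
        if e.kind != "peak":
            continue
        following = next((t for t in extrema[j + 1 :] if t.kind == "trough"), None)
        if following is not None:
            pairs.append((e, following))
    return pairs


def u_content_window(
    genome: GenomeSequence,
    chrom: str,
    position: int,
    strand: str,
    half_width: int = HALF_WIDTH,
) -> float:
    """Transcript-sense U fraction in the 2*half_width nt around a position.

    The window comprises ``half_width`` nt on each side of the position
    with the central base excluded, so the default is exactly 20 nt.
    """
    seq = genome.fetch(chrom, position - half_width, position + half_width + 1)
    window = seq[:half_width] + seq[half_width + 1 :]
    u_base = "T" if strand == "+" else "A"  # genomic base read as U in the transcript
    return window.upper().count(u_base) / len(window)


@dataclass
class UTestResult:
    n_pairs: int
    u_fraction_peaks: list[float]
    u_fraction_troughs: list[float]
    statistic: float
    p_value: float
    method: str
    half_width: int = HALF_WIDTH
    all_zero: bool = False

    @property
    def mean_difference(self) -> float:
        """Mean (trough - peak) U-fraction difference."""
        return float(
            np.mean(np.asarray(self.u_fraction_troughs) - np.asarray(self.u_fraction_peaks))
        )


def urichness_test(
    u_peaks,
    u_troughs,
    method: str = "wilcoxon_paired",
    half_width: int = HALF_WIDTH,
) -> UTestResult:
    """Two-sided test of U-content difference between paired peaks and troughs.

    ``wilcoxon_paired`` is a signed-rank test on (trough - peak)
    differences with zero differences dropped; ``t_paired`` is a paired
    t-test; ``mannwhitney`` an unpaired rank-sum.  If every difference is
    zero the result is flagged with p = 1.
    """
    u_peaks = [float(x) for x in u_peaks]
    u_troughs = [float(x) for x in u_troughs]
    if len(u_peaks) != len(u_troughs) or not u_peaks:
        raise ValueError("need equal, nonempty peak and trough lists")
    diffs = np.asarray(u_troughs) - np.asarray(u_peaks)
    if method == "wilcoxon_paired":
        nonzero = diffs[diffs != 0]
        if len(nonzero) == 0:
            return UTestResult(len(u_peaks), u_peaks, u_troughs, 0.0, 1.0, method, half_width, True)
        res = stats.wilcoxon(nonzero, alternative="two-sided", zero_method="wilcox")
        stat, p = float(res.statistic), float(res.pvalue)
    elif method == "t_paired":
        if np.all(diffs == diffs[0]) and diffs[0] == 0:
            return UTestResult(len(u_peaks), u_peaks, u_troughs, 0.0, 1.0, method, half_width, True)
        res = stats.ttest_rel(u_troughs, u_peaks)
        stat, p = float(res.statistic), float(res.pvalue)
    elif method == "mannwhitney":
        res = stats.mannwhitneyu(u_troughs, u_peaks, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return UTestResult(len(u_peaks), u_peaks, u_troughs, stat, p, method, half_width)


def collect_pair_windows(
    profile: GeneVector,
    ext: ExtendedGene,
    genome: GenomeSequence,
    rt_region: tuple[int, int],
    t1_offset: int | None = None,
    t1_len: int = 0,
    min_mean_reads: float = MIN_MEAN_READS,
    half_width: int = HALF_WIDTH,
    smooth_window: int = SMOOTH_WINDOW,
    exclude_first_terminator: bool = True,
) -> list[tuple[float, float]]:
    """(peak U-fraction, trough U-fraction) pairs for one gene's RT region.

    ``rt_region`` is a profile-index interval.  When
    ``exclude_first_terminator`` is set, any pair whose U-content window
    overlaps the canonical terminator [mature 3', mature 3' + t1_offset +
    t1_len) (transcript offsets) is removed, so the T1 tract itself
    cannot drive the statistic.
    """
    gene = ext.gene
    extrema = find_extrema(
        profile,
        region=rt_region,
        smooth_window=smooth_window,
        min_mean_reads=min_mean_reads,
        half_width=half_width,
    )
    pairs = peak_trough_pairs(extrema)
    m3 = profile.anchors["mature3"]
    excl_lo, excl_hi = m3 + 1, m3 + 1 + (0 if t1_offset is None else t1_offset + t1_len)
    out = []
    for peak, trough in pairs:
        if exclude_first_terminator:
            windows_touch = any(
                (e.index - half_width) < excl_hi and (e.index + half_width + 1) > excl_lo
                for e in (peak, trough)
            )
            if windows_touch:
                continue
        result = []
        for e in (peak, trough):
            if gene.strand == "+":
                gpos = ext.ext_start + e.index
            else:
                gpos = ext.ext_end - 1 - e.index
            result.append(u_content_window(genome, gene.chrom, gpos, gene.strand, half_width))
        out.append((result[0], result[1]))
    return out
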