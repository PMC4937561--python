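"""Per-gene scalar statistics of polymerase occupancy.

Expression is counted over the pre-tRNA window (15 nt upstream of the
mature 5' end through the mature 3' end).  The 5':3' peak ratio splits
that window at its midpoint; genes with ratio > 1.5 form group 1 (the
predominant initiation-peak pattern), the rest group 2.  Terminator
read-through (RT) is the fraction of pre-tRNA signal falling 15-250 nt
downstream of the mature 3' end.  All counts accept the counting modes of
:mod:`pol3scan.densities`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import GeneAnnotation
from .densities import count_reads

__all__ = [
    "GeneMetrics",
    "ComparisonResult",
    "pre_trna_window",
    "rt_numerator_window",
    "rt_denominator_window",
    "expression_level",
    "peak_ratio_5to3",
    "rt_level",
    "hpm_normalize",
    "compare_conditions",
    "surveillance_rt_frequency",
    "metrics_table",
    "UPSTREAM_PAD",
    "RT_GAP",
    "RT_SPAN",
    "GROUP_THRESHOLD",
]

UPSTREAM_PAD = 15  #: nt upstream of the mature 5' end in the pre-tRNA window
RT_GAP = 15  #: extension region starts this many nt past the mature 3' end
RT_SPAN = 250  #: extension region ends this many nt past the mature 3' end
GROUP_THRESHOLD = 1.5  #: 5':3' ratio above which a gene falls in group 1


@dataclass
class GeneMetrics:
    gene_id: str
    expression_reads: int
    expression_hpm: float | None = None
    ratio_5to3: float | None = None
    group: int | None = None
    rt_level: float | None = None


@dataclass
class ComparisonResult:
    """Cross-condition expression comparison (ratios + trend-line fit)."""

    table: pd.DataFrame  # gene_id, hpm_a, hpm_b, ratio
    slope: float
    intercept: float
    r_squared: float
    transform: str
    dropped_genes: list[str]


def pre_trna_window(gene: GeneAnnotation, pad: int = UPSTREAM_PAD) -> tuple[int, int]:
    """[mature 5' - pad, mature 3') as a genomic half-open interval."""
    if gene.strand == "+":
        return gene.mature_start - pad, gene.mature_end
    return gene.mature_start, gene.mature_end + pad


def rt_numerator_window(gene: GeneAnnotation, gap: int = RT_GAP, span: int = RT_SPAN) -> tuple[int, int]:
    """[mature 3' + gap, mature 3' + span) in transcript direction."""
    if gene.strand == "+":
        return gene.mature_end + gap, gene.mature_end + span
    return gene.mature_start - span, gene.mature_start - gap


def rt_denominator_window(
    gene: GeneAnnotation, pad: int = UPSTREAM_PAD, span: int = RT_SPAN
) -> tuple[int, int]:
    """[mature 5' - pad, mature 3' + span): the whole pre-tRNA + RT region."""
    if gene.strand == "+":
        return gene.mature_start - pad, gene.mature_end + span
    return gene.mature_start - span, gene.mature_end + pad


def expression_level(reads: pd.DataFrame, gene: GeneAnnotation, mode: str = "three_prime_end") -> int:
    """Read count over the pre-tRNA window (relative transcription)."""
    a, b = pre_trna_window(gene)
    return count_reads(reads, gene.chrom, a, b, gene.strand, mode=mode)


def peak_ratio_5to3(
    reads: pd.DataFrame,
    gene: GeneAnnotation,
    threshold: float = GROUP_THRESHOLD,
    mode: str = "three_prime_end",
) -> tuple[float | None, int | None]:
    """5'-half / 3'-half read ratio over the pre-tRNA window, and its group.

    The window is split at its midpoint; for odd lengths the extra base
    goes to the 5' half.  A zero 3'-half count makes both results missing.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    a, b = pre_trna_window(gene)
    half5 = math.ceil((b - a) / 2)
    if gene.strand == "+":
        five = (a, a + half5)
        three = (a + half5, b)
    else:
        five = (b - half5, b)
        three = (a, b - half5)
    n5 = count_reads(reads, gene.chrom, *five, gene.strand, mode=mode)
    n3 = count_reads(reads, gene.chrom, *three, gene.strand, mode=mode)
    if n3 == 0:
        return None, None
    ratio = n5 / n3
    return ratio, (1 if ratio > threshold else 2)


def rt_level(
    reads: pd.DataFrame,
    gene: GeneAnnotation,
    rt_gap: int = RT_GAP,
    rt_span: int = RT_SPAN,
    mode: str = "three_prime_end",
) -> float | None:
    """Fraction of pre-tRNA signal in the downstream extension window."""
    if not rt_gap < rt_span:
        raise ValueError("rt_gap must be < rt_span")
    num = count_reads(reads, gene.chrom, *rt_numerator_window(gene, rt_gap, rt_span), gene.strand, mode=mode)
    den = count_reads(
        reads, gene.chrom, *rt_denominator_window(gene, UPSTREAM_PAD, rt_span), gene.strand, mode=mode
    )
    if den == 0:
        return None
    return num / den


def hpm_normalize(counts: dict[str, float], total_mapped: int) -> dict[str, float]:
    """Hits per million mapped reads."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return {gene: c * 1e6 / total_mapped for gene, c in counts.items()}


def compare_conditions(
    metrics_a: dict[str, float],
    metrics_b: dict[str, float],
    transform: str = "log2_pseudocount",
    pseudocount: float = 1.0,
) -> ComparisonResult:
    """Per-gene b/a expression ratios plus an OLS trend line.

    The fit regresses the transformed condition-b values on the
    transformed condition-a values (log2(x + pseudocount) by default).
    Genes missing in either table are dropped and reported.
    """
    if transform not in ("log2_pseudocount", "identity"):
        raise ValueError(f"unknown transform {transform!r}")
    shared = sorted(set(metrics_a) & set(metrics_b))
    dropped = sorted((set(metrics_a) | set(metrics_b)) - set(shared))
    if len(shared) < 3:
        raise ValueError(f"need >=3 shared genes for the trend line, got {len(shared)}")
    a = np.array([metrics_a[g] for g in shared], dtype=float)
    b = np.array([metrics_b[g] for g in shared], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(a > 0, b / a, np.nan)
    if transform == "log2_pseudocount":
        xa, xb = np.log2(a + pseudocount), np.log2(b + pseudocount)
    else:
        xa, xb = a, b
    fit = stats.linregress(xa, xb)
    table = pd.DataFrame({"gene_id": shared, "hpm_a": a, "hpm_b": b, "ratio": ratio})
    return ComparisonResult(
        table=table,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        transform=transform,
        dropped_genes=dropped,
    )


def surveillance_rt_frequency(
    reads: pd.DataFrame,
    genes: list[GeneAnnotation],
    rt_gap: int = RT_GAP,
    rt_span: int = RT_SPAN,
    mode: str = "three_prime_end",
) -> float | None:
    """Global frequency of factor binding to RT regions.

    Sum of extension-window counts over all genes, divided by the sum of
    (gene + extension) counts; the region definitions match
    :func:`rt_level`.
    """
    num = 0
    den = 0
    for gene in genes:
        num += count_reads(reads, gene.chrom, *rt_numerator_window(gene, rt_gap, rt_span), gene.strand, mode=mode)
        den += count_reads(
            reads, gene.chrom, *rt_denominator_window(gene, UPSTREAM_PAD, rt_span), gene.strand, mode=mode
        )
    if den == 0:
        return None
    return num / den


def metrics_table(
    reads: pd.DataFrame,
    genes: list[GeneAnnotation],
    mode: str = "three_prime_end",
    threshold: float = GROUP_THRESHOLD,
    rt_gap: int = RT_GAP,
    rt_span: int = RT_SPAN,
    total_mapped: int | None = None,
) -> pd.DataFrame:
    """All per-gene metrics as one tidy table (NA encodes missing)."""
    if total_mapped is None:
        total_mapped = int(len(reads))
    rows = []
    for gene in genes:
        expr = expression_level(reads, gene, mode=mode)
        ratio, group = peak_ratio_5to3(reads, gene, threshold=threshold, mode=mode)
        rt = rt_level(reads, gene, rt_gap=rt_gap, rt_span=rt_span, mode=mode)
        rows.append(
            {
                "gene_id": gene.gene_id,
                "expression_reads": expr,
                "expression_hpm": expr * 1e6 / total_mapped if total_mapped else np.nan,
                "ratio_5to3": np.nan if ratio is None else ratio,
                "group": np.nan if group is None else group,
                "rt_level": np.nan if rt is None else rt,
            }
        )
    return pd.DataFrame(rows)
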