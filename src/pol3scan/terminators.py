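"""Terminator-strength analysis from downstream sequence.

The canonical RNAPIII terminator is an oligo(U) tract in the nascent
transcript (a T-run on the coding DNA strand).  T1 is the longest U run
within the 50 nt downstream of the mature 3' end; a secondary terminator
T2 is sought in a window after T1 and classified as strong (>= 7 U),
weak (4-6 U) or absent (< 4 U).  Genes are stratified by read-through
level to relate terminator strength to termination efficiency.

Boundary choices: the strong/weak split leaves exactly-6 on the weak
side (strong means more than 6 U); the weak floor of 4 U is the shortest
tract reported to terminate in any organism.  All three boundaries are
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TerminatorCall",
    "RtStratification",
    "longest_u_stretch",
    "classify_secondary_terminator",
    "call_terminators",
    "terminator_strength_by_rt",
    "DEFAULT_RT_BINS",
    "T1_WINDOW",
    "T2_WINDOW",
    "WEAK_MIN",
    "STRONG_MIN",
]

T1_WINDOW = 50  #: nt downstream of the mature 3' end searched for T1
T2_WINDOW = 40  #: nt after the end of T1 searched for T2
WEAK_MIN = 4  #: shortest U run counted as a weak terminator
STRONG_MIN = 7  #: shortest U run counted as a strong terminator

#: Overlapping RT-level bins used for terminator-strength stratification.
DEFAULT_RT_BINS = (
    ("<5%", 0.0, 0.05),
    ("<15%", 0.0, 0.15),
    ("<25%", 0.0, 0.25),
    (">15%", 0.15, 1.0 + 1e-9),
    (">25%", 0.25, 1.0 + 1e-9),
    (">35%", 0.35, 1.0 + 1e-9),
)


@dataclass
class TerminatorCall:
    gene_id: str
    t1_offset: int | None  # nt downstream of the mature 3' end
    t1_len: int
    t2_class: str | None = None  # strong / weak / absent
    t2_len: int | None = None


def _u_runs(seq: str):
    """(start, length) of maximal U/T runs; N and any other letter break runs."""
    run_start = None
    for i, base in enumerate(seq.upper() + "$"):  # sentinel flushes the last run
        if base in ("T", "U"):
            if run_start is None:
                run_start = i
        elif run_start is not None:
            yield run_start, i - run_start
            run_start = None


def longest_u_stretch(downstream_seq: str, window: int = T1_WINDOW) -> tuple[int, int | None]:
    """Length and start offset of the longest U/T run in the first ``window`` nt.

    The sequence must be transcript-sense.  Runs straddling the window
    edge are truncated at it.  Ties resolve to the smallest offset; a
    sequence without any U yields (0, None).
    """
    region = downstream_seq[:window]
    best_len, best_off = 0, None
    for start, length in _u_runs(region):
        if length > best_len:
            best_len, best_off = length, start
    return best_len, best_off


def classify_secondary_terminator(
    downstream_seq: str,
    t1_offset: int,
    t1_len: int,
    t2_window: int = T2_WINDOW,
    weak_min: int = WEAK_MIN,
    strong_min: int = STRONG_MIN,
) -> tuple[str, int]:
    """Class and length of the longest U run in the window after T1 ends.

    The search covers the ``t2_window`` nt immediately 3' of the final T1
    base.  An empty remainder is ``absent`` with length 0.
    """
    if t1_offset is None:
        raise ValueError("T1 must be found before classifying T2")
    start = t1_offset + t1_len
    region = downstream_seq[start : start + t2_window]
    t2_len, _ = longest_u_stretch(region, window=t2_window)
    if t2_len >= strong_min:
        return "strong", t2_len
    if t2_len >= weak_min:
        return "weak", t2_len
    return "absent", t2_len


def call_terminators(
    downstream_seqs: dict[str, str],
    t1_window: int = T1_WINDOW,
    t2_window: int = T2_WINDOW,
    weak_min: int = WEAK_MIN,
    strong_min: int = STRONG_MIN,
) -> list[TerminatorCall]:
    """T1 + T2 calls for each gene's transcript-sense downstream sequence."""
    calls = []
    for gene_id, seq in downstream_seqs.items():
        t1_len, t1_off = longest_u_stretch(seq, window=t1_window)
        call = TerminatorCall(gene_id=gene_id, t1_offset=t1_off, t1_len=t1_len)
        if t1_off is not None:
            call.t2_class, call.t2_len = classify_secondary_terminator(
                seq, t1_off, t1_len, t2_window=t2_window, weak_min=weak_min, strong_min=strong_min
            )
        calls.append(call)
    return calls


@dataclass
class RtStratification:
    """Per-RT-bin distributions of canonical terminator length."""

    table: pd.DataFrame  # bin, t1_len, n_genes, fraction, cumulative_fraction
    bin_counts: dict[str, int]
    empty_bins: list[str]


def terminator_strength_by_rt(
    calls: list[TerminatorCall],
    rt_levels: dict[str, float],
    bins=DEFAULT_RT_BINS,
) -> RtStratification:
    """Stratify T1 lengths by RT level (bins may overlap, as in <5%/ >25%).

    For each bin the empirical cumulative distribution of t1_len is
    reported along with the fraction of genes at each exact length.
    Genes without an RT level are ignored; empty bins are flagged.
    """
    shared = [c for c in calls if c.gene_id in rt_levels and rt_levels[c.gene_id] is not None]
    rows = []
    bin_counts: dict[str, int] = {}
    empty = []
    for label, lo, hi in bins:
        members = [c for c in shared if lo <= rt_levels[c.gene_id] < hi]
        bin_counts[label] = len(members)
        if not members:
            empty.append(label)
            continue
        lens = np.array([c.t1_len for c in members])
        for length in range(int(lens.max()) + 1):
            frac = float((lens == length).mean())
            cum = float((lens <= length).mean())
            rows.append(
                {
                    "bin": label,
                    "t1_len": length,
                    "n_genes": len(members),
                    "fraction": frac,
                    "cumulative_fraction": cum,
                }
            )
    return RtStratification(table=pd.DataFrame(rows), bin_counts=bin_counts, empty_bins=empty)
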