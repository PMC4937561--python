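"""Novel transcription-unit discovery from stranded coverage tracks.

Candidate features are maximal runs of coverage at least ``min_height``
deep and ``min_len`` long.  The discovery pipeline merges nearby runs
(gap <= 5 nt), removes anything overlapping an annotated feature or an
extended tRNA transcription unit, and merges the survivors with a wider
gap (<= 200 nt) into candidate units.  Merge semantics follow the
BEDTools convention: two intervals combine when the gap between them is
at most ``d`` nt.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from intervaltree import IntervalTree

from .annotations import ExtendedGene
from .densities import StrandedTrack

__all__ = [
    "CandidateFeature",
    "threshold_runs",
    "merge_intervals",
    "discover_novel",
    "MIN_HEIGHT",
    "MIN_LEN",
    "MERGE_ANNOTATED",
    "MERGE_NOVEL",
]

MIN_HEIGHT = 50.0  #: minimum per-base coverage of a candidate run
MIN_LEN = 10  #: minimum run length (nt)
MERGE_ANNOTATED = 5  #: gap (nt) for the first merge pass
MERGE_NOVEL = 200  #: gap (nt) for the final merge of unannotated features


@dataclass(frozen=True)
class CandidateFeature:
    chrom: str
    strand: str
    start: int
    end: int
    max_height: float
    mean_height: float
    stage: str = "raw"

    @property
    def length(self) -> int:
        return self.end - self.start


def threshold_runs(
    track: StrandedTrack, min_height: float = MIN_HEIGHT, min_len: int = MIN_LEN
) -> list[CandidateFeature]:
    """Maximal per-strand runs of coverage >= min_height, length >= min_len."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    features = []
    for (chrom, strand), values in sorted(track.items()):
        mask = values >= min_height
        if not mask.any():
            continue
        padded = np.concatenate(([False], mask, [False]))
        d = np.diff(padded.astype(np.int8))
        run_starts = np.flatnonzero(d == 1)
        run_ends = np.flatnonzero(d == -1)
        for s, e in zip(run_starts, run_ends):
            if e - s >= min_len:
                seg = values[s:e]
                features.append(
                    CandidateFeature(
                        chrom=chrom,
                        strand=strand,
                        start=int(s),
                        end=int(e),
                        max_height=float(seg.max()),
                        mean_height=float(seg.mean()),
                        stage="raw",
                    )
                )
    return features


def merge_intervals(features: list[CandidateFeature], d: int, stage: str | None = None) -> list[CandidateFeature]:
    """Union same-strand same-chromosome intervals with gaps <= d.

    Heights aggregate as max of max and length-weighted mean of mean
    (gaps contribute nothing).  Output is sorted and pairwise separated
    by gaps > d; merging twice with the same d is a no-op.
    """
    if d < 0:
        raise ValueError("merge distance must be non-negative")
    grouped: dict[tuple[str, str], list[CandidateFeature]] = {}
    for f in features:
        grouped.setdefault((f.chrom, f.strand), []).append(f)
    out: list[CandidateFeature] = []
    for key in sorted(grouped):
        run: list[CandidateFeature] = []
        run_end = None  # max end seen in the current run (containment-safe)
        for f in sorted(grouped[key], key=lambda x: (x.start, x.end)):
            if run and f.start - run_end <= d:
                run.append(f)
                run_end = max(run_end, f.end)
            else:
                if run:
                    out.append(_combine(run, stage))
                run = [f]
                run_end = f.end
        if run:
            out.append(_combine(run, stage))
    out.sort(key=lambda f: (f.chrom, f.strand, f.start))
    return out


def _combine(run: list[CandidateFeature], stage: str | None) -> CandidateFeature:
    start = min(f.start for f in run)
    end = max(f.end for f in run)
    lengths = np.array([f.length for f in run], dtype=float)
    means = np.array([f.mean_height for f in run])
    return CandidateFeature(
        chrom=run[0].chrom,
        strand=run[0].strand,
        start=start,
        end=end,
        max_height=max(f.max_height for f in run),
        mean_height=float((means * lengths).sum() / lengths.sum()),
        stage=stage or run[0].stage,
    )


def discover_novel(
    track: StrandedTrack,
    annotation: list[ExtendedGene | tuple],
    min_height: float = MIN_HEIGHT,
    min_len: int = MIN_LEN,
    merge_annotated: int = MERGE_ANNOTATED,
    merge_novel: int = MERGE_NOVEL,
    strand_aware: bool = True,
) -> list[CandidateFeature]:
    """Candidate novel transcription units.

    ``annotation`` entries are :class:`ExtendedGene` (the extended
    interval is masked, covering tRNA 3' extensions) or raw
    ``(chrom, strand, start, end)`` tuples for other features.  A
    candidate overlapping any annotated interval by >= 1 base (same
    strand, or either strand with ``strand_aware=False``) is dropped.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for entry in annotation:
        if isinstance(entry, ExtendedGene):
            chrom, strand, start, end = entry.gene.chrom, entry.gene.strand, entry.ext_start, entry.ext_end
        else:
            chrom, strand, start, end = entry
        strands = (strand,) if strand_aware else ("+", "-")
        for s in strands:
            trees.setdefault((chrom, s), IntervalTree()).addi(start, end)

    raw = threshold_runs(track, min_height=min_height, min_len=min_len)
    merged = merge_intervals(raw, merge_annotated, stage="merged5")
    unannotated = []
    for f in merged:
        tree = trees.get((f.chrom, f.strand))
        if tree is not None and tree.overlap(f.start, f.end):
            continue
        unannotated.append(replace(f, stage="unannotated"))
    return merge_intervals(unannotated, merge_novel, stage="merged200")


def candidates_to_gtf(features: list[CandidateFeature], path, prefix: str = "TLT") -> None:
    """Write candidates as GTF exon lines named prefix1..N."""
    with open(path, "w") as fh:
        for i, f in enumerate(sorted(features, key=lambda x: (x.chrom, x.start)), start=1):
            attrs = (
                f'gene_id "{prefix}{i}"; gene_biotype "putative_pol3"; '
                f'max_height "{f.max_height:g}"; mean_height "{f.mean_height:.2f}";'
            )
            fh.write(
                "\t".join(
                    [f.chrom, "pol3scan", "exon", str(f.start + 1), str(f.end), ".", f.strand, ".", attrs]
                )
                + "\n"
            )
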