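#!/usr/bin/env python
"""Terminator strength versus read-through.

Scans the 50 nt downstream of each mature 3' end for the longest
oligo(U) tract (T1), classifies the secondary terminator (T2) in the
40 nt after T1, and stratifies T1 length by measured RT level.  The
expected signature is monotone: genes with long U tracts terminate
efficiently (low RT), genes with 4-6 U read through frequently.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pol3scan.annotations import GenomeSequence, load_annotation, transcript_sequence
from pol3scan.densities import read_bed6
from pol3scan.gene_metrics import rt_level
from pol3scan.terminators import call_terminators, terminator_strength_by_rt

DATA = Path("results/dataset")
OUT = Path("results/terminators")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = GenomeSequence.from_fasta(DATA / "genome.fa")
    genes = load_annotation(DATA / "annotation.gtf", biotype_filter="tRNA")
    reads = read_bed6(DATA / "reads.bed")

    downstream = {}
    for g in genes:
        n = genome.chrom_length(g.chrom)
        if g.strand == "+":
            downstream[g.gene_id] = transcript_sequence(genome, g.chrom, g.mature_end, min(g.mature_end + 250, n), "+")
        else:
            downstream[g.gene_id] = transcript_sequence(genome, g.chrom, max(g.mature_start - 250, 0), g.mature_start, "-")
    calls = call_terminators(downstream)
    pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "t1_offset": c.t1_offset,
                "t1_len": c.t1_len,
                "t2_class": c.t2_class,
                "t2_len": c.t2_len,
            }
            for c in calls
        ]
    ).to_csv(OUT / "terminator_calls.tsv", sep="\t", index=False, na_rep="NA")

    rt = {g.gene_id: rt_level(reads, g) for g in genes}
    strat = terminator_strength_by_rt(calls, rt)
    strat.table.to_csv(OUT / "t1_by_rt_bin.tsv", sep="\t", index=False)

    frame = pd.DataFrame(
        {"gene_id": [c.gene_id for c in calls], "t1_len": [c.t1_len for c in calls]}
    ).assign(rt=lambda d: d["gene_id"].map(rt))
    by_len = frame.groupby("t1_len")["rt"].agg(["mean", "count"])
    print("mean RT by canonical terminator length:")
    for t1_len, row in by_len.iterrows():
        print(f"  {t1_len}U: {100 * row['mean']:5.1f}%  (n={int(row['count'])})")
    deltas = np.diff(by_len["mean"].to_numpy())
    print(f"monotone nonincreasing in T1 length: {bool((deltas <= 0).all())}")
    t2 = pd.Series([c.t2_class for c in calls]).value_counts()
    print("secondary terminator classes:", dict(t2))


if __name__ == "__main__":
    main()
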