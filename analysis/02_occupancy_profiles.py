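#!/usr/bin/env python
"""Polymerase occupancy profiles: metagenes, heatmaps, clustering.

Reads the dataset from results/dataset/, locates the internal promoter
boxes, and asks where polymerase density concentrates: the expectation
for RNAPIII-style data is a dominant 5' peak at the A box and a weaker
3' peak at the B box, visible in box-anchored metagenes.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pol3scan.annotations import GenomeSequence, extend_gene, load_annotation
from pol3scan.densities import extract_profile, read_bed6, read_track
from pol3scan.motif_scan import locate_boxes
from pol3scan.profiles import cluster_rows, heatmap_matrix, metagene

DATA = Path("results/dataset")
OUT = Path("results/profiles")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = GenomeSequence.from_fasta(DATA / "genome.fa")
    genes = load_annotation(DATA / "annotation.gtf", biotype_filter="tRNA")
    end_track = read_track(DATA / "ends.sgrs", "sgrs", genome.chrom_sizes)

    hits = locate_boxes(genes, genome)
    pd.DataFrame(
        [{"gene_id": h.gene_id, "box": h.box, "offset": h.offset, "score": h.score} for h in hits]
    ).to_csv(OUT / "boxes.tsv", sep="\t", index=False)
    offsets = {(h.gene_id, h.box): h.offset for h in hits}
    a_offsets = [off for (g, box), off in offsets.items() if box == "A"]
    print(f"A box: median offset +{np.median(a_offsets):.0f} from the mature 5' end")

    vectors = []
    for gene in genes:
        ext = extend_gene(gene, 50, 250, genome.chrom_length(gene.chrom))
        gv = extract_profile(end_track, ext)
        for box, anchor in (("A", "boxA"), ("B", "boxB")):
            if (gene.gene_id, box) in offsets:
                gv.anchors[anchor] = gv.anchors["mature5"] + offsets[(gene.gene_id, box)]
        vectors.append(gv)

    for anchor in ("mature5", "mature3", "boxA", "boxB"):
        mg = metagene(vectors, anchor, (200, 250))
        mg.to_frame().to_csv(OUT / f"metagene_{anchor}.tsv", sep="\t", index=False)
        peak = int(np.argmax(mg.values)) - 200
        print(f"metagene anchored on {anchor:8s}: maximum at {peak:+d} nt ({mg.n_genes} genes)")

    for norm in ("row_max", "log2_global"):
        hm = heatmap_matrix(vectors, 50, 250, normalization=norm)
        order, _, flagged = cluster_rows(hm)
        hm.matrix = hm.matrix[order]
        hm.gene_ids = [hm.gene_ids[i] for i in order]
        hm.to_frame().to_csv(OUT / f"heatmap_{norm}.tsv", sep="\t", index=False)
        print(f"heatmap ({norm}): {hm.matrix.shape[0]} genes x {hm.matrix.shape[1]} columns, "
              f"clustered with 1-Pearson distance ({len(flagged)} flat rows)")


if __name__ == "__main__":
    main()
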