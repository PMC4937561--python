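#!/usr/bin/env python
"""U-richness of density peaks versus troughs inside read-through regions.

Calls alternating peaks and troughs on the polymerase-position track
within each gene's 15-250 nt downstream window (canonical terminator
excluded), measures transcript-sense U content in 20-nt windows around
each site, and tests the paired difference with the Wilcoxon signed-rank
statistic.  A 50-nt window serves as the dilution control: a genuinely
local sequence signal should weaken when the window grows.

This analysis regenerates the dataset at higher depth (50,000
reads/gene) because single-base peak calling needs more signal than the
interval statistics of steps 02-04.
"""

from pathlib import Path

import pandas as pd

from pol3scan.annotations import extend_gene
from pol3scan.densities import pileup_ends, extract_profile
from pol3scan.peak_stats import collect_pair_windows, urichness_test
from pol3scan.synthetic_data import SimConfig, simulate_dataset

OUT = Path("results/urichness")
SEED = 1
DEPTH_CONFIG = dict(n_genes=30, depth=50_000)
MIN_MEAN = 25.0  # peak cutoff scaled to this depth


def pooled(cfg, half_width):
    genome, genes, truth, reads = simulate_dataset(cfg)
    track = pileup_ends(reads, genome.chrom_sizes)
    tmap = {t.gene_id: t for t in truth.genes}
    peaks, troughs = [], []
    for gene in genes:
        ext = extend_gene(gene, 50, 250, genome.chrom_length(gene.chrom))
        gv = extract_profile(track, ext)
        t = tmap[gene.gene_id]
        m3 = gv.anchors["mature3"]
        region = (m3 + 1 + 15, min(len(gv.values), m3 + 1 + 250))
        for p, tr in collect_pair_windows(
            gv, ext, genome, rt_region=region,
            t1_offset=t.t1_offset, t1_len=t.t1_len,
            min_mean_reads=MIN_MEAN, half_width=half_width,
        ):
            peaks.append(p)
            troughs.append(tr)
    return urichness_test(peaks, troughs, half_width=half_width)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for label, u_dropout, half_width in [
        ("dropout_20nt", 0.05, 10),
        ("dropout_50nt_control", 0.05, 25),
        ("no_dropout_20nt", 0.0, 10),
    ]:
        cfg = SimConfig(seed=SEED, u_dropout=u_dropout, **DEPTH_CONFIG)
        res = pooled(cfg, half_width)
        rows.append(
            {
                "analysis": label,
                "n_pairs": res.n_pairs,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "mean_trough_minus_peak": res.mean_difference,
            }
        )
        print(
            f"{label:22s}: n={res.n_pairs:4d}  p={res.p_value:.2e}  "
            f"mean U(trough)-U(peak) = {res.mean_difference:+.4f}"
        )
    pd.DataFrame(rows).to_csv(OUT / "urichness_tests.tsv", sep="\t", index=False)
    print("troughs are U-richer than peaks when dropout is active; the 50-nt")
    print("window dilutes the contrast and the no-dropout control is null.")


if __name__ == "__main__":
    main()
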