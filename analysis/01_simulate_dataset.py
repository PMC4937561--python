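#!/usr/bin/env python
"""Generate the reference synthetic dataset for the downstream analyses.

Emulated design: tRNA-sized transcription units on both strands with
internal A/B promoter boxes, planted oligo(U) terminators of varying
length, terminator-length-dependent read-through, U-dependent signal
dropout in read-through regions, and two intergenic plateau units.

Writes FASTA / GTF / BED6 / sgrs / ground-truth TSV under
results/dataset/ so later steps (02-07) run from files, exactly as a
real analysis would.
"""

from pathlib import Path

from pol3scan.annotations import write_annotation
from pol3scan.densities import pileup, pileup_ends, write_bed6, write_track
from pol3scan.synthetic_data import SimConfig, simulate_dataset

OUT = Path("results/dataset")
SEED = 1

# study conditions: 30 genes at 20,000 reads/gene keeps every stage
# (including per-base peak calling) well above shot noise at desk scale
CONFIG = SimConfig(seed=SEED, n_genes=30, depth=20_000)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome, genes, truth, reads = simulate_dataset(CONFIG)
    genome.to_fasta(OUT / "genome.fa")
    write_annotation(genes, OUT / "annotation.gtf")
    write_bed6(reads, OUT / "reads.bed")
    truth.gene_frame().to_csv(OUT / "truth_genes.tsv", sep="\t", index=False)
    with open(OUT / "truth_novel.tsv", "w") as fh:
        fh.write("chrom\tstrand\tstart\tend\theight\n")
        for u in truth.novel:
            fh.write(f"{u.chrom}\t{u.strand}\t{u.start}\t{u.end}\t{u.height}\n")
    write_track(pileup(reads, genome.chrom_sizes), OUT / "coverage.sgrs", "sgrs")
    write_track(pileup_ends(reads, genome.chrom_sizes), OUT / "ends.sgrs", "sgrs")

    n_plus = (reads["strand"] == "+").sum()
    print(f"dataset: {len(genes)} genes, {len(truth.novel)} novel units, {len(reads)} reads")
    print(f"         {n_plus} plus-strand reads / {len(reads) - n_plus} minus-strand reads")
    print(f"         written to {OUT}/")


if __name__ == "__main__":
    main()
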