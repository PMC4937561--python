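# pol3scan

Quantitative analysis of transcriptionally engaged RNA polymerase III from
nascent-transcript sequencing data (CRAC / NET-seq style), for researchers
studying tRNA gene transcription, termination and surveillance in yeast-like
genomes.

In such experiments the sequenced read is the RNA still held by the
polymerase, so the read's 3′-terminal base marks the polymerase position.
From stranded aligned-read intervals (BED6), a genome (FASTA) and a gene
annotation (Ensembl-dialect GTF), the package computes:

- **Occupancy profiles** — stranded base-resolution coverage and
  polymerase-position tracks (sgr/sgrs/bedGraph), per-gene profiles over
  transcription units extended 50 nt upstream / 250 nt downstream, metagene
  profiles anchored on the mature 5′/3′ ends or on the internal A/B promoter
  boxes (located by PWM scan), and heatmap matrices (per-row maximum or
  global log2 scaling) clustered with the 1 − Pearson distance.
- **Per-gene metrics** — expression over the pre-tRNA window
  `[mature 5′ − 15, mature 3′)`, the 5′:3′ peak ratio with its group call
  (ratio > 1.5 → group 1, the dominant initiation-peak pattern), and the
  terminator **read-through (RT) level**

  &nbsp;&nbsp;RT = reads in `[3′ + 15, 3′ + 250)` / reads in `[5′ − 15, 3′ + 250)`,

  plus hits-per-million normalization and cross-condition comparison with a
  log2 trend line.
- **Terminator statistics** — longest oligo(U) tract (T1) in the 50 nt
  downstream of each gene, secondary-terminator (T2) classification
  (strong ≥ 7 U, weak 4–6 U, absent < 4 U) in the 40 nt after T1, and the
  distribution of T1 length across RT-level bins.
- **U-richness of peaks and troughs** — alternating density extrema inside
  RT regions, transcript-sense U content in 20-nt windows around each site,
  and a paired Wilcoxon signed-rank test of the trough − peak difference
  (exact for small n).
- **Novel transcription units** — coverage runs ≥ 50 reads deep and ≥ 10 nt
  long, merged at gap ≤ 5, filtered against the extended annotation, merged
  at gap ≤ 200 (BEDTools `merge -d` semantics).
- **R-loop propensity** — nearest-neighbor ΔG°37 of the DNA:DNA duplex
  versus the nascent-RNA:DNA hybrid over the 20 nt downstream of each gene
  (ΔΔG = ΔG_hybrid − ΔG_duplex; negative favors the R-loop).
- **A synthetic-data generator** with full ground truth — planted promoter
  boxes, terminators of configurable length, a 5′-peak/3′-peak/body density
  mixture, logistic terminator-length → read-through coupling
  θ(L) = 1/(1+e^(−k(L−L0))), U-dependent signal dropout in RT regions and
  intergenic plateau units — so every stage is verifiable without any
  external dataset.

## Worked example

The analysis is organized as numbered drivers under `analysis/`, run from
the repository root; `01` writes a seed-determined dataset
(30 genes, ~600k reads) under `results/dataset/` and the later steps read it:

```sh
python analysis/01_simulate_dataset.py
python analysis/02_occupancy_profiles.py
python analysis/04_terminator_strength.py
python analysis/05_urichness.py
```

which prints, among other things:

```
A box: median offset +8 from the mature 5' end
metagene anchored on boxA    : maximum at +0 nt (30 genes)
metagene anchored on boxB    : maximum at +0 nt (30 genes)

mean RT by canonical terminator length:
  4U:  97.1%  (n=2)
  5U:  88.0%  (n=3)
  6U:  50.0%  (n=9)
  7U:  11.8%  (n=10)
  8U:   1.8%  (n=6)
monotone nonincreasing in T1 length: True

dropout_20nt          : n= 736  p=7.53e-04  mean U(trough)-U(peak) = +0.0088
dropout_50nt_control  : n= 664  p=8.62e-01  mean U(trough)-U(peak) = +0.0002
no_dropout_20nt       : n=1081  p=6.43e-01  mean U(trough)-U(peak) = +0.0009
```

Reading these numbers: the 5′ polymerase peak sits exactly at the A-box
start and the 3′ peak at the B-box start (the metagene maxima at offset 0);
read-through falls monotonically from ~97% for 4-U terminators to ~2% for
8-U terminators, the logistic planted by the generator; and density troughs
inside RT regions are significantly U-richer than their paired upstream
peaks only when U-dependent dropout is active, with the effect disappearing
in 50-nt windows — a localized sequence signal.

The same stages are available as a library (`pol3scan.*` modules), as one
orchestrated run (`pol3scan.pipeline.run_pipeline`, which writes every
table plus a reproducibility manifest), and as a CLI:

```sh
pol3scan run --simulate --seed 7 --out-dir pol3scan_out
pol3scan metrics --reads reads.bed --genes annotation.gtf --out metrics.tsv
```

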