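# Methods

## Signal model and coordinate conventions

All internal coordinates are 0-based half-open on the genomic forward
strand; GTF (1-based inclusive) and sgr/sgrs (1-based positions) are
converted only at file boundaries. A gene's *mature span* is the genomic
span of the primary transcript body with introns included; intron intervals
are carried separately. Transcription units are extended 50 nt upstream of
the mature 5′ end and 250 nt downstream of the mature 3′ end (strand-aware,
clamped to the chromosome); overlapping extensions of neighboring genes are
left as-is, since every statistic is per-gene.

In nascent-transcript data the sequenced fragment is the RNA attached to
the polymerase, so the read's strand-aware 3′-terminal base estimates the
polymerase position. The package therefore distinguishes two tracks:

- **coverage** (`pileup`): each read adds 1 to every base it covers.
  Used where plateau heights matter (novel-unit discovery).
- **polymerase position** (`pileup_ends`): each read adds 1 at its
  3′-terminal base. Used for profile shape — metagenes, heatmaps and
  peak/trough calling — because full-read coverage convolves the position
  signal with the 20–40 nt read length, smearing box-anchored peaks and
  displacing extrema by about half a read length.

Read counting in windows defaults to `three_prime_end` (count a read where
its 3′ end falls), which makes the expression / gap / extension windows an
exact partition of the pre-tRNA region; `any_overlap` and `midpoint` modes
are provided for compatibility with overlap-based counters.

## Per-gene statistics

- **Expression**: reads in `[mature 5′ − 15, mature 3′)`.
- **5′:3′ peak ratio**: the same window split at its midpoint, the extra
  base of odd windows assigned to the 5′ half (a deterministic choice, as
  the convention is otherwise arbitrary); ratio > 1.5 → group 1. A zero
  3′-half count yields a missing ratio rather than infinity.
- **RT level**: extension reads `[3′+15, 3′+250)` over pre-tRNA + extension
  reads `[5′−15, 3′+250)`. The 250-nt end is overridable per gene to
  support experimentally annotated longer read-through products.
- **HPM**: counts × 10⁶ / total mapped reads. Cross-condition comparison
  fits ordinary least squares on log2(HPM + 1) by default (the pseudocount
  of 1 HPM handles silent genes; an identity transform is selectable) and
  reports slope, intercept and R² with per-gene b/a ratios.
- **Surveillance RT-binding frequency**: Σ extension counts / Σ (gene +
  extension) counts over all genes, same windows as RT.

## Promoter boxes

A-box and B-box anchors come from a log-odds PWM scan (bits, uniform
background). Default PWMs derive from the consensus words TGGCNNAGTGG
(A box) and GTTCGANNC (B box) with degenerate letters expanded to equal
probability mixtures and pseudocount 0.01; user matrices in MEME minimal
text format are accepted. The A box is searched in the 5′ half of the gene
body, the B box 3′ of the A-box hit, which accommodates intron-containing
genes where the A–B spacing varies. No score threshold is applied: anchors
need only be positionally accurate, and the canonical +8 A-box offset acts
as a sanity prior in the tests. Ties resolve to the smallest offset, with a
1e-9-bit tolerance so that summation order cannot flip exact ties.

## Profiles, heatmaps, clustering

Metagenes sum per-gene polymerase-position densities at anchor + offset;
positions outside a gene's extended interval contribute zero. Heatmap rows
span fixed flanks around the variable-length body; the body is rescaled to
the median body length by linear interpolation (exact on linear ramps),
which keeps the 5′ and 3′ peaks at the body edges. `row_max` divides each
row by its maximum (all-zero rows are flagged, not rescaled);
`log2_global` applies log2(x+1). Rows are clustered agglomeratively
(average linkage by default, complete selectable) on d = 1 − Pearson;
zero-variance rows get distance 1 to everything and are flagged.

## Terminator analysis

T1 is the longest U/T run within the 50 nt downstream of the mature 3′ end
(transcript sense; N breaks runs; ties → smallest offset; runs straddling
the window edge are truncated at it). T2 is the longest run in the 40 nt
immediately after T1's final base, classified strong ≥ 7 U / weak 4–6 U /
absent < 4 U. The boundaries are parameters: "more than 6 U" fixes the
strong threshold at 7, and 4 U — the shortest tract reported to terminate
in any organism — is the weak floor. The RT stratification reports, per
(possibly overlapping) RT bin, the exact and cumulative distribution of T1
length.

## Peaks, troughs and U richness

Within each gene's RT region the polymerase-position profile is smoothed
with a centered moving average (default width 3), strict local extrema are
taken with plateaus collapsed to their centers, alternation is enforced by
dropping the lesser of adjacent same-kind extrema, and peaks are filtered
by mean raw density over ±10 nt of the apex (a windowed mean is robust to
single-base spikes; the cutoff is a parameter and should scale with
sequencing depth). Each surviving peak is paired with the following trough.
U content is the transcript-sense U/T fraction in the 10 nt before plus
10 nt after a site, center base excluded (exactly 20 nt). Pairs whose
windows touch the canonical terminator `[3′, 3′ + t1_offset + t1_len)` are
excluded so T1 itself cannot drive the statistic. The pooled paired test is
Wilcoxon signed-rank (two-sided, zero differences dropped; exact for small
n, matching full sign-flip enumeration), with paired t and Mann-Whitney
alternatives.

## Novel-unit discovery

Maximal runs of coverage ≥ 50 over ≥ 10 nt per strand, merged at gap ≤ 5
nt, subtracted against annotated features *including* the 250-nt tRNA
extensions (≥ 1 base overlap, strand-aware by default), then merged at
gap ≤ 200 nt. Merging follows BEDTools `merge -d` semantics — gap measured
against the running maximum end, so contained intervals cannot split a
run — and is validated against the `bedtools` binary in the tests.
Survivors are reported with max and length-weighted mean heights; no
manual curation is attempted.

## R-loop thermodynamics

ΔG°37 of a window is an initiation term plus the sum of dinucleotide step
energies. The DNA:DNA table is the unified duplex parameter set
(SantaLucia 1998); the RNA:DNA table is the hybrid set (Sugimoto et al.
1995); both ship as plain-text data files with citations. Terminal
corrections beyond a single initiation constant are omitted because
fixed-length window comparisons cancel constant terms in
ΔΔG = ΔG_hybrid − ΔG_duplex. Steps containing N are skipped. Note that the
downstream window contains the terminator U tract and rU:dA steps are far
weaker than dT:dA steps, so terminator length couples ΔΔG to read-through
in any model where U tracts terminate: a negative ΔΔG–RT rank correlation
is the expected signature, and independence only holds when RT is assigned
independently of sequence (the null test does exactly that).

## Generative model (synthetic data)

One chromosome (default 60 kb, uniform background) carries `n_genes`
(default 30) non-overlapping transcription units on random strands, mature
spans 72–133 nt, ~25% with an intron of 14–60 nt inserted between the
boxes. The A-box word is planted at +8, the B-box word 25 nt from the
mature 3′ end of the genomic span. A T-run of length L drawn from
{4..9} (weights 0.05/0.10/0.20/0.30/0.25/0.10, the 7–8 U mode typical of
strong terminators) is planted 10 nt downstream of the mature 3′ end;
background runs in the downstream 250 nt are capped below L so T1 is
unambiguous. Downstream U frequency is per-gene uniform in [0.2, 0.4].

Each gene receives N ~ Poisson(depth × activity) polymerases (default
depth 2000/gene; deeper where per-base statistics demand it — 20,000 in
the profile analyses, 50,000 in the U-richness analysis with the peak
cutoff scaled to 25, and 100,000 in the read-through recovery, whose
tolerance of ±0.02 presumes that depth). With probability
p_rt = 1 − θ(L), θ(L) = 1/(1+e^(−k(L−L0))) (defaults k=2, L0=6), a
polymerase reads through; otherwise its position is drawn from
w5·N(boxA, σ5) + w3·N(boxB, σ3) + w_body·U(body) (defaults 0.5/0.25/0.25,
σ5=3, σ3=4), truncated to the unit. A read-through polymerase's detected
position is drawn over the RT region with probability proportional to
S(q)·v(q): S(q) is the survival of a per-base release walk from the end of
T1 (release probability `u_dropout`, default 0.05, at each U base), and
v(q) = (1−u_dropout)^(#U within ±10 nt) is a local visibility factor — a
polymerase traversing U-rich sequence holds its transcript poorly and a
transcript-free polymerase is invisible to crosslinking. The survival term
makes density decay downstream while remaining detectable 100–150 nt out;
the visibility term places density minima *at* U patches with recovery in
U-poor stretches, which is what makes trough windows U-rich. With
u_dropout = 0 the RT occupancy is exactly uniform, giving the calibrated
null. Each polymerase emits a read of length U(20, 40) ending at its
position, truncated at the TSS (10 nt upstream of the mature 5′ end).
Planted novel units emit `height` identical full-length reads, an exact
coverage plateau. All outputs are deterministic functions of the seed.

The analytic RT expectation used for parameter recovery is p_rt times the
mass of the normalized occupancy law at offsets ≥ 15 nt; it is computed by
direct summation over the planted downstream sequence, independent of the
read-counting estimator it validates.

### What the generator does not emulate

Sequencing error, adapter artifacts, PCR duplicates, multimapping reads
(n_hits is always 1), chromatin or replication effects on polymerase
progression, RNase footprint biases, and cross-gene sequence homology
(every simulated gene body is random apart from the planted boxes). Tests
passing on this generator therefore demonstrate correctness of the
measurement pipeline under the stated model — not robustness of the
biology to mapping artifacts or to features the model omits.

## Numerical choices and degenerate inputs

Missing values (zero denominators: RT, ratios, comparison tables) are NA,
never ±inf. PWM columns must sum to 1 within 1e-9; scan ties and merge
outputs are deterministic. Signed-rank p-values follow
p = min(1, 2·min(P(W⁺≤w), P(W⁺≥w))); all-zero difference sets return p = 1
with a flag. Heatmap body interpolation is recorded in the output metadata
(`body_columns`) for comparability. The pipeline manifest records the
package version, seed, every parameter and SHA-256 of every output, and a
rerun from the same configuration reproduces identical bytes.

## Known limitations

Annotated 3′ extensions from external evidence are supported only through
the per-gene RT span override (no separate extension-GTF reader). The
discovery stage reports all surviving candidates without classification.
FIMO-style p/q-values for box hits are not computed (scores only). The
thermodynamic tables carry no salt or temperature corrections; ΔΔG is
meaningful for ranking windows of equal length only.
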