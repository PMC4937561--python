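"""Synthetic genomes, annotations and read sets with known ground truth.

The generator emulates the salient features of nascent-transcript
(CRAC-style) RNAPIII data so that every analysis stage has a recoverable
target:

* tRNA-sized genes on both strands, with A-box and B-box consensus words
  planted at canonical offsets (A box at +8; B box a fixed distance from
  the mature 3' end, shifted by an intron when present);
* a T-run terminator (T1) of configurable length planted 10 nt
  downstream of each mature 3' end, with background U runs capped below
  the planted length so T1 is unambiguous;
* polymerase density as a mixture of a 5' peak at the A box, a 3' peak
  at the B box and a uniform body component; each polymerase emits a
  read whose 3' end is the polymerase position;
* terminator-length-dependent read-through: a polymerase escapes T1 with
  probability p_rt = 1 - theta(t1_len), theta(L) = 1/(1+exp(-k(L-L0)));
* U-frequency-dependent signal dropout in read-through regions: an
  escaped polymerase releases its transcript at downstream U bases with
  per-U probability ``u_dropout``; a released polymerase is invisible to
  a nascent-transcript library, so occupancy is proportional to the
  survival function of the release walk;
* intergenic plateau units standing in for novel transcription units.

All outputs are deterministic functions of ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotations import GeneAnnotation, GenomeSequence, reverse_complement
from .densities import READ_COLUMNS
from .motif_scan import A_BOX_CONSENSUS, B_BOX_CONSENSUS

__all__ = [
    "SimConfig",
    "GeneTruth",
    "NovelTruth",
    "SimTruth",
    "termination_probability",
    "simulate_genome",
    "simulate_reads",
    "simulate_dataset",
    "rt_occupancy_weights",
    "expected_rt_level",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_NON_T = np.frombuffer(b"ACG", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset (defaults = desk scale)."""

    seed: int = 0
    n_genes: int = 30
    chrom_len: int = 60_000
    chrom_name: str = "chrSim"
    mature_len_range: tuple[int, int] = (72, 133)  # genomic span, intron included
    intron_prob: float = 0.25
    intron_len_range: tuple[int, int] = (14, 60)
    boxA_offset: int = 8
    boxB_from_3prime: int = 25
    t1_len_probs: dict[int, float] = field(
        default_factory=lambda: {4: 0.05, 5: 0.10, 6: 0.20, 7: 0.30, 8: 0.25, 9: 0.10}
    )
    t1_len_values: tuple[int, ...] | None = None  # explicit per-gene override
    t1_gap: int = 10  # T1 starts this many nt downstream of the mature 3' end
    u_freq_range: tuple[float, float] = (0.2, 0.4)  # per-gene downstream U frequency
    depth: float = 2000.0  # mean reads per gene
    activity: tuple[float, ...] | None = None  # per-gene depth multipliers
    w5: float = 0.5
    w3: float = 0.25
    w_body: float = 0.25
    sigma5: float = 3.0
    sigma3: float = 4.0
    k: float = 2.0  # steepness of the terminator-strength logistic
    L0: float = 6.0  # U-tract length at which termination probability is 0.5
    u_dropout: float = 0.05  # per-U transcript-release probability in RT regions
    u_dropout_halfwidth: int = 10  # local context (nt) for the visibility penalty
    read_len_range: tuple[int, int] = (20, 40)
    tss_offset: int = 10  # transcription start site, nt upstream of the mature 5' end
    rt_span: int = 250
    n_novel: int = 2
    novel_height: int = 80
    novel_width: int = 60
    strand_prob: float = 0.5  # probability of the plus strand

    def validate(self) -> None:
        if abs(self.w5 + self.w3 + self.w_body - 1.0) > 1e-9:
            raise ValueError("peak weights w5 + w3 + w_body must sum to 1")
        for name in ("intron_prob", "u_dropout", "strand_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.t1_len_values is None:
            if abs(sum(self.t1_len_probs.values()) - 1.0) > 1e-9:
                raise ValueError("t1_len_probs must sum to 1")
            support = set(self.t1_len_probs)
        else:
            support = set(self.t1_len_values)
        if not support <= set(range(1, 16)):
            raise ValueError("t1 lengths must lie within {1..15}")
        if self.activity is not None and len(self.activity) != self.n_genes:
            raise ValueError("activity must have one entry per gene")
        if self.t1_len_values is not None and len(self.t1_len_values) != self.n_genes:
            raise ValueError("t1_len_values must have one entry per gene")


def termination_probability(t1_len: float, k: float = 2.0, L0: float = 6.0) -> float:
    """theta(L) = 1/(1+exp(-k(L-L0))): canonical termination probability."""
    return 1.0 / (1.0 + np.exp(-k * (t1_len - L0)))


@dataclass
class GeneTruth:
    gene_id: str
    strand: str
    mature_start: int
    mature_end: int
    boxA_offset: int  # transcript offset from the mature 5' end
    boxB_offset: int
    intron: tuple[int, int] | None  # transcript-offset interval, or None
    t1_len: int
    t1_offset: int
    u_freq: float
    p_rt: float
    activity: float
    downstream_seq: str  # transcript-sense, rt_span nt past the mature 3' end


@dataclass
class NovelTruth:
    chrom: str
    strand: str
    start: int
    end: int
    height: int


@dataclass
class SimTruth:
    config: SimConfig
    genes: list[GeneTruth]
    novel: list[NovelTruth]

    def gene_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.genes:
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "strand": g.strand,
                    "mature_start": g.mature_start,
                    "mature_end": g.mature_end,
                    "boxA_offset": g.boxA_offset,
                    "boxB_offset": g.boxB_offset,
                    "t1_len": g.t1_len,
                    "u_freq": g.u_freq,
                    "p_rt": g.p_rt,
                    "activity": g.activity,
                }
            )
        return pd.DataFrame(rows)


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _cap_t_runs(arr: np.ndarray, rng: np.random.Generator, max_run: int) -> None:
    """Break every T run longer than ``max_run`` in place."""
    count = 0
    for i in range(len(arr)):
        if arr[i] == ord("T"):
            count += 1
            if count > max_run:
                arr[i] = _NON_T[rng.integers(0, 3)]
                count = 0
        else:
            count = 0


def _fill_consensus(word: str, rng: np.random.Generator) -> np.ndarray:
    out = np.empty(len(word), dtype=np.uint8)
    for i, letter in enumerate(word):
        out[i] = _BASES[rng.integers(0, 4)] if letter == "N" else ord(letter)
    return out


def simulate_genome(config: SimConfig) -> tuple[GenomeSequence, list[GeneAnnotation], SimTruth]:
    """Random genome with planted genes, terminators and novel units."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    genome = _random_bases(rng, config.chrom_len)

    slot_margin = config.rt_span  # reserve the full extension on both sides
    min_gap, max_gap = 200, 400
    cursor = slot_margin + 150
    gene_slots: list[tuple[int, int]] = []  # mature spans, in placement order
    t1_choices = list(config.t1_len_probs)
    t1_weights = np.array([config.t1_len_probs[c] for c in t1_choices], dtype=float)

    genes: list[GeneAnnotation] = []
    truths: list[GeneTruth] = []
    for i in range(config.n_genes):
        span = int(rng.integers(config.mature_len_range[0], config.mature_len_range[1] + 1))
        # intron between the boxes, when the span leaves room for it
        intron = None
        max_intron = span - (38 + config.boxB_from_3prime)
        if max_intron >= config.intron_len_range[0] and rng.random() < config.intron_prob:
            ilen = int(rng.integers(config.intron_len_range[0], min(config.intron_len_range[1], max_intron) + 1))
            intron = (38, 38 + ilen)
        m5 = cursor
        m3 = m5 + span
        if m3 + slot_margin + 150 > config.chrom_len:
            raise ValueError(
                f"cannot place {config.n_genes} genes without overlap in {config.chrom_len} nt; "
                "increase chrom_len"
            )
        strand = "+" if rng.random() < config.strand_prob else "-"
        if config.t1_len_values is not None:
            t1_len = int(config.t1_len_values[i])
        else:
            t1_len = int(t1_choices[rng.choice(len(t1_choices), p=t1_weights)])
        u_freq = float(rng.uniform(*config.u_freq_range))

        # transcript-sense body with planted promoter boxes
        body = _random_bases(rng, span)
        box_a = _fill_consensus(A_BOX_CONSENSUS, rng)
        body[config.boxA_offset : config.boxA_offset + len(box_a)] = box_a
        box_b = _fill_consensus(B_BOX_CONSENSUS, rng)
        b_off = span - config.boxB_from_3prime
        body[b_off : b_off + len(box_b)] = box_b

        # transcript-sense downstream region with planted, unambiguous T1
        down = np.where(
            rng.random(config.rt_span) < u_freq,
            np.uint8(ord("T")),
            _NON_T[rng.integers(0, 3, size=config.rt_span)],
        ).astype(np.uint8)
        _cap_t_runs(down, rng, max_run=t1_len - 1)
        t1_start = config.t1_gap
        down[t1_start : t1_start + t1_len] = ord("T")
        down[t1_start - 1] = _NON_T[rng.integers(0, 3)]
        if t1_start + t1_len < len(down):
            down[t1_start + t1_len] = _NON_T[rng.integers(0, 3)]

        if strand == "+":
            genome[m5:m3] = body
            genome[m3 : m3 + config.rt_span] = down
            intron_genomic = (m5 + intron[0], m5 + intron[1]) if intron else None
        else:
            genome[m5:m3] = np.frombuffer(
                reverse_complement(body.tobytes().decode()).encode(), dtype=np.uint8
            )
            genome[m5 - config.rt_span : m5] = np.frombuffer(
                reverse_complement(down.tobytes().decode()).encode(), dtype=np.uint8
            )
            intron_genomic = (m3 - intron[1], m3 - intron[0]) if intron else None

        gene_id = f"tSim{i:03d}"
        genes.append(
            GeneAnnotation(
                gene_id=gene_id,
                chrom=config.chrom_name,
                mature_start=m5,
                mature_end=m3,
                strand=strand,
                biotype="tRNA",
                intron_intervals=(intron_genomic,) if intron_genomic else (),
                is_nuclear=True,
            )
        )
        activity = 1.0 if config.activity is None else float(config.activity[i])
        truths.append(
            GeneTruth(
                gene_id=gene_id,
                strand=strand,
                mature_start=m5,
                mature_end=m3,
                boxA_offset=config.boxA_offset,
                boxB_offset=b_off,
                intron=intron,
                t1_len=t1_len,
                t1_offset=config.t1_gap,
                u_freq=u_freq,
                p_rt=float(1.0 - termination_probability(t1_len, config.k, config.L0)),
                activity=activity,
                downstream_seq=down.tobytes().decode(),
            )
        )
        gene_slots.append((m5, m3))
        cursor = m3 + 2 * slot_margin + int(rng.integers(min_gap, max_gap))

    # novel units in the free space between consecutive extended slots
    novel: list[NovelTruth] = []
    if config.n_novel > 0 and len(gene_slots) >= 2:
        gaps = []
        for j in range(len(gene_slots) - 1):
            lo = gene_slots[j][1] + slot_margin + 20
            hi = gene_slots[j + 1][0] - slot_margin - 20
            if hi - lo >= config.novel_width:
                gaps.append((lo, hi))
        chosen = rng.choice(len(gaps), size=min(config.n_novel, len(gaps)), replace=False)
        for j in sorted(chosen):
            lo, hi = gaps[j]
            start = (lo + hi - config.novel_width) // 2
            strand = "+" if rng.random() < 0.5 else "-"
            novel.append(
                NovelTruth(
                    chrom=config.chrom_name,
                    strand=strand,
                    start=int(start),
                    end=int(start + config.novel_width),
                    height=config.novel_height,
                )
            )

    seq = GenomeSequence({config.chrom_name: genome.tobytes().decode()})
    return seq, genes, SimTruth(config=config, genes=truths, novel=novel)


def rt_occupancy_weights(truth: GeneTruth, config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """(offsets, weights) of detected read-through polymerase positions.

    Offsets are transcript-sense nt past the mature 3' end (offset 0 =
    first downstream base).  Detected occupancy at offset q combines two
    U-dependent factors, both scaled by ``u_dropout``:

    * cumulative release: walking from the first base after T1, the
      transcript is released (noncanonical termination) with probability
      ``u_dropout`` at every U base, so the surviving polymerase flux is
      S(q) = prod_{j<q} (1 - u_dropout * [seq_j is U]);
    * local visibility: a polymerase traversing U-rich sequence holds
      its transcript poorly (rU:dA hybrids are unstable) and a
      transcript-free polymerase is invisible to crosslinking, so the
      detection probability carries a factor (1 - u_dropout) per U base
      within ``u_dropout_halfwidth`` nt of q.

    The local factor recovers in U-poor sequence, which places density
    minima at, not merely after, oligo(U) patches.  With u_dropout = 0
    the occupancy is uniform.
    """
    q0 = truth.t1_offset + truth.t1_len
    seq = truth.downstream_seq
    offsets = np.arange(q0, config.rt_span)
    is_u_all = np.frombuffer(seq.encode(), dtype=np.uint8) == ord("T")
    release = np.where(is_u_all[q0:], config.u_dropout, 0.0)
    survival = np.concatenate(([1.0], np.cumprod(1.0 - release[:-1])))
    half = config.u_dropout_halfwidth
    kernel = np.ones(2 * half + 1)
    local_u = np.convolve(is_u_all.astype(float), kernel, mode="same")[q0:]
    visibility = (1.0 - config.u_dropout) ** local_u
    weights = survival * visibility
    return offsets, weights / weights.sum()


def expected_rt_level(truth: GeneTruth, config: SimConfig, rt_gap: int = 15) -> float:
    """Analytic expectation of the measured RT level for one gene.

    All simulated reads fall inside the RT denominator window, so the
    expectation is p_rt times the occupancy mass at offsets >= rt_gap.
    """
    offsets, weights = rt_occupancy_weights(truth, config)
    return truth.p_rt * float(weights[offsets >= rt_gap].sum())


def simulate_reads(
    config: SimConfig, truth: SimTruth, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Reads (BED6-semantics DataFrame) from the generative model."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    chunks = []
    weights = np.array([config.w5, config.w3, config.w_body])
    lmin, lmax = config.read_len_range
    for g in truth.genes:
        n = int(rng.poisson(config.depth * g.activity))
        if n == 0:
            continue
        span = g.mature_end - g.mature_start
        n_rt = int(rng.binomial(n, g.p_rt))
        n_body = n - n_rt
        comp = rng.choice(3, size=n_body, p=weights)
        t = np.empty(n_body, dtype=float)
        t[comp == 0] = rng.normal(g.boxA_offset, config.sigma5, size=(comp == 0).sum())
        t[comp == 1] = rng.normal(g.boxB_offset, config.sigma3, size=(comp == 1).sum())
        t[comp == 2] = rng.uniform(0, span, size=(comp == 2).sum())
        t = np.clip(np.rint(t).astype(int), -config.tss_offset, span + g.t1_offset - 1)
        if n_rt > 0:
            offs, w = rt_occupancy_weights(g, config)
            q = rng.choice(offs, size=n_rt, p=w)
            t = np.concatenate([t, span + q])
        lengths = rng.integers(lmin, lmax + 1, size=len(t))
        if g.strand == "+":
            pos = g.mature_start + t
            start = np.maximum(pos - lengths + 1, g.mature_start - config.tss_offset)
            end = pos + 1
        else:
            pos = (g.mature_end - 1) - t
            start = pos
            end = np.minimum(pos + lengths, g.mature_end + config.tss_offset)
        chunks.append(
            pd.DataFrame(
                {
                    "chrom": config.chrom_name,
                    "start": start,
                    "end": end,
                    "name": [f"{g.gene_id}_r{i}" for i in range(len(t))],
                    "n_hits": 1,
                    "strand": g.strand,
                }
            )
        )
    for j, unit in enumerate(truth.novel):
        chunks.append(
            pd.DataFrame(
                {
                    "chrom": unit.chrom,
                    "start": unit.start,
                    "end": unit.end,
                    "name": [f"novel{j}_r{i}" for i in range(unit.height)],
                    "n_hits": 1,
                    "strand": unit.strand,
                }
            )
        )
    if not chunks:
        return pd.DataFrame(columns=READ_COLUMNS)
    return pd.concat(chunks, ignore_index=True).loc[:, READ_COLUMNS]


def simulate_dataset(config: SimConfig):
    """(genome, genes, truth, reads) for one seed-determined dataset."""
    genome, genes, truth = simulate_genome(config)
    reads = simulate_reads(config, truth)
    return genome, genes, truth, reads
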