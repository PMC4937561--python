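"""Nearest-neighbor free-energy comparison: DNA duplex vs RNA:DNA hybrid.

R-loop propensity downstream of a terminator is scored by comparing the
predicted ΔG°37 of the genomic DNA/DNA duplex with that of the hybrid
between the nascent RNA and the template DNA strand over the same
window (default: the 20 nt downstream of the mature 3' end).  ΔΔG =
ΔG(hybrid) - ΔG(duplex); more negative values favor the hybrid and hence
R-loop formation.

Parameter sets are the standard published nearest-neighbor tables
(DNA/DNA unified parameters; RNA/DNA hybrid parameters), shipped as
plain-text data files with citations in their headers.  Terminal
corrections beyond one initiation term are omitted: fixed-length window
comparisons cancel constant terms in ΔΔG.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .annotations import GeneAnnotation, GenomeSequence, transcript_sequence

__all__ = ["NnTable", "DuplexThermo", "load_nn_table", "duplex_delta_g", "rloop_score", "RLOOP_WINDOW"]

RLOOP_WINDOW = 20  #: nt downstream of the mature 3' end


@dataclass(frozen=True)
class NnTable:
    steps: dict[str, float]  # dinucleotide -> kcal/mol
    initiation: float
    duplex_kind: str  # "dna_dna" or "rna_dna"

    def __post_init__(self) -> None:
        if len(self.steps) != 16:
            raise ValueError(f"expected 16 dinucleotide steps, got {len(self.steps)}")


def load_nn_table(kind: str) -> NnTable:
    """Load a packaged table: ``dna_dna`` or ``rna_dna``."""
    if kind not in ("dna_dna", "rna_dna"):
        raise ValueError(f"unknown table kind {kind!r}")
    text = resources.files("pol3scan.data").joinpath(f"nn_{kind}.tsv").read_text()
    steps: dict[str, float] = {}
    initiation = 0.0
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#initiation"):
            initiation = float(line.split("\t")[1])
            continue
        if line.startswith("#"):
            continue
        step, value = line.split("\t")
        steps[step] = float(value)
    return NnTable(steps=steps, initiation=initiation, duplex_kind=kind)


_DEFAULT_TABLES: dict[str, NnTable] = {}


def default_table(kind: str) -> NnTable:
    if kind not in _DEFAULT_TABLES:
        _DEFAULT_TABLES[kind] = load_nn_table(kind)
    return _DEFAULT_TABLES[kind]


def duplex_delta_g(seq: str, table: NnTable) -> float:
    """ΔG°37 = initiation + sum of dinucleotide step values.

    ``seq`` is transcript-sense; it is transliterated to the table's
    alphabet (T<->U).  Steps containing letters outside the alphabet
    (e.g. N) are skipped.
    """
    if len(seq) < 2:
        raise ValueError("need at least 2 nt to evaluate a duplex")
    seq = seq.upper()
    seq = seq.replace("T", "U") if table.duplex_kind == "rna_dna" else seq.replace("U", "T")
    total = table.initiation
    for i in range(len(seq) - 1):
        step = seq[i : i + 2]
        value = table.steps.get(step)
        if value is not None:
            total += value
    return total


@dataclass
class DuplexThermo:
    gene_id: str
    window: int
    dG_dna: float
    dG_hybrid: float
    truncated: bool = False

    @property
    def ddG(self) -> float:
        """ΔG(hybrid) - ΔG(duplex); negative favors the R-loop."""
        return self.dG_hybrid - self.dG_dna


def rloop_score(
    gene: GeneAnnotation,
    genome: GenomeSequence,
    window: int = RLOOP_WINDOW,
    dna_table: NnTable | None = None,
    hybrid_table: NnTable | None = None,
) -> DuplexThermo:
    """R-loop propensity over the window downstream of the mature 3' end.

    The DNA duplex and the nascent-RNA:template hybrid are evaluated over
    the same transcript-sense sequence (the hybrid table keys on the RNA
    strand, which equals the transcript-sense sequence with U for T).  A
    window truncated by the chromosome end is computed on the available
    length and flagged.
    """
    dna_table = dna_table or default_table("dna_dna")
    hybrid_table = hybrid_table or default_table("rna_dna")
    chrom_len = genome.chrom_length(gene.chrom)
    if gene.strand == "+":
        start, end = gene.mature_end, gene.mature_end + window
        truncated = end > chrom_len
        end = min(end, chrom_len)
    else:
        start, end = gene.mature_start - window, gene.mature_start
        truncated = start < 0
        start = max(start, 0)
    seq = transcript_sequence(genome, gene.chrom, start, end, gene.strand)
    return DuplexThermo(
        gene_id=gene.gene_id,
        window=end - start,
        dG_dna=duplex_delta_g(seq, dna_table),
        dG_hybrid=duplex_delta_g(seq, hybrid_table),
        truncated=truncated,
    )
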