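"""Genome sequences, gene annotations and flank-extended transcription units.

All internal coordinates are 0-based half-open on the genomic forward
strand; conversions to and from 1-based inclusive conventions happen only
at file boundaries (GTF, sgr).  The mature span of a gene is the genomic
span of the primary transcript body, introns included; intron intervals
are recorded separately so exon shading and splicing-aware analyses remain
possible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GeneAnnotation",
    "ExtendedGene",
    "GenomeSequence",
    "GtfParseError",
    "load_annotation",
    "write_annotation",
    "extend_gene",
    "transcript_sequence",
    "reverse_complement",
    "DEFAULT_MITO_NAMES",
    "DEFAULT_UP_FLANK",
    "DEFAULT_DOWN_FLANK",
]

#: Flank extensions applied to every transcription unit: 50 nt upstream of
#: the mature 5' end and 250 nt downstream of the mature 3' end, the window
#: within which terminator read-through products are quantified.
DEFAULT_UP_FLANK = 50
DEFAULT_DOWN_FLANK = 250

#: Chromosome names treated as mitochondrial (genes there are non-nuclear).
DEFAULT_MITO_NAMES = frozenset({"Mito", "chrM", "MT"})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GtfParseError(ValueError):
    """Malformed GTF input; the message names the offending line number."""


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated transcription unit.

    ``mature_start``/``mature_end`` delimit the genomic span of the mature
    RNA body (0-based half-open, introns included); ``intron_intervals``
    are half-open genomic intervals strictly inside the mature span.
    """

    gene_id: str
    chrom: str
    mature_start: int
    mature_end: int
    strand: str
    biotype: str = "other"
    intron_intervals: tuple[tuple[int, int], ...] = ()
    is_nuclear: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand symbol {self.strand!r}")
        if not self.mature_start < self.mature_end:
            raise ValueError(
                f"{self.gene_id}: mature_start must be < mature_end "
                f"({self.mature_start} >= {self.mature_end})"
            )
        for s, e in self.intron_intervals:
            if not (self.mature_start < s < e < self.mature_end):
                raise ValueError(
                    f"{self.gene_id}: intron [{s},{e}) not strictly inside "
                    f"mature span [{self.mature_start},{self.mature_end})"
                )

    @property
    def mature_length(self) -> int:
        return self.mature_end - self.mature_start

    def exon_intervals(self) -> list[tuple[int, int]]:
        """Exonic sub-intervals of the mature span, 5'->3' in genome order."""
        exons = []
        pos = self.mature_start
        for s, e in sorted(self.intron_intervals):
            exons.append((pos, s))
            pos = e
        exons.append((pos, self.mature_end))
        return exons


@dataclass(frozen=True)
class ExtendedGene:
    """A gene with strand-aware flank extensions, clamped to the chromosome."""

    gene: GeneAnnotation
    ext_start: int
    ext_end: int
    up_flank: int = DEFAULT_UP_FLANK
    down_flank: int = DEFAULT_DOWN_FLANK

    def __post_init__(self) -> None:
        if self.ext_start > self.gene.mature_start or self.ext_end < self.gene.mature_end:
            raise ValueError("extended interval must contain the mature span")

    @property
    def length(self) -> int:
        return self.ext_end - self.ext_start


class GenomeSequence:
    """Mapping chromosome -> uppercase nucleotide text over {A,C,G,T,N}."""

    def __init__(self, sequences: dict[str, str]):
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}

    @classmethod
    def from_fasta(cls, path) -> "GenomeSequence":
        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    def to_fasta(self, path) -> None:
        from Bio.SeqRecord import SeqRecord

        records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in self._seqs.items()]
        SeqIO.write(records, str(path), "fasta")

    def chrom_length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Forward-strand subsequence; out-of-bounds lookups are errors."""
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        n = len(self._seqs[chrom])
        if not (0 <= start <= end <= n):
            raise IndexError(f"interval [{start},{end}) outside {chrom} [0,{n})")
        return self._seqs[chrom][start:end]


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def load_annotation(
    gtf_path,
    biotype_filter: str | None = None,
    mito_names: frozenset[str] = DEFAULT_MITO_NAMES,
) -> list[GeneAnnotation]:
    """Read an Ensembl-dialect GTF into :class:`GeneAnnotation` records.

    Exon lines of one gene are merged into a single mature span with the
    inter-exon gaps recorded as introns.  GTF coordinates (1-based,
    inclusive) are converted to 0-based half-open.  ``biotype_filter``
    keeps only genes whose ``gene_biotype`` attribute matches.
    """
    by_gene: dict[str, dict] = {}
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            if strand not in ("+", "-"):
                raise GtfParseError(f"line {lineno}: unknown strand symbol {strand!r}")
            try:
                start0 = int(start) - 1
                end0 = int(end)
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinate") from exc
            if start0 < 0 or start0 >= end0:
                raise GtfParseError(f"line {lineno}: invalid interval {start}..{end}")
            attr = _parse_attributes(attrs)
            gene_id = attr.get("gene_id")
            if gene_id is None:
                raise GtfParseError(f"line {lineno}: missing gene_id attribute")
            rec = by_gene.setdefault(
                gene_id,
                {
                    "chrom": chrom,
                    "strand": strand,
                    "biotype": attr.get("gene_biotype", "other"),
                    "exons": [],
                    "lineno": lineno,
                },
            )
            if rec["chrom"] != chrom or rec["strand"] != strand:
                raise GtfParseError(
                    f"line {lineno}: gene {gene_id} spans multiple chromosomes/strands"
                )
            rec["exons"].append((start0, end0))

    genes = []
    for gene_id, rec in by_gene.items():
        exons = sorted(rec["exons"])
        introns = tuple(
            (exons[i][1], exons[i + 1][0])
            for i in range(len(exons) - 1)
            if exons[i + 1][0] > exons[i][1]
        )
        gene = GeneAnnotation(
            gene_id=gene_id,
            chrom=rec["chrom"],
            mature_start=exons[0][0],
            mature_end=exons[-1][1],
            strand=rec["strand"],
            biotype=rec["biotype"],
            intron_intervals=introns,
            is_nuclear=rec["chrom"] not in mito_names,
        )
        if biotype_filter is None or gene.biotype == biotype_filter:
            genes.append(gene)
    genes.sort(key=lambda g: (g.chrom, g.mature_start, g.gene_id))
    return genes


def write_annotation(genes: list[GeneAnnotation], path, source: str = "pol3scan") -> None:
    """Write genes back to Ensembl-dialect GTF (one exon line per exon)."""
    with open(path, "w") as fh:
        for gene in genes:
            for s, e in gene.exon_intervals():
                attrs = f'gene_id "{gene.gene_id}"; gene_biotype "{gene.biotype}";'
                fh.write(
                    "\t".join(
                        [
                            gene.chrom,
                            source,
                            "exon",
                            str(s + 1),
                            str(e),
                            ".",
                            gene.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def extend_gene(
    gene: GeneAnnotation,
    up: int = DEFAULT_UP_FLANK,
    down: int = DEFAULT_DOWN_FLANK,
    chrom_len: int | None = None,
) -> ExtendedGene:
    """Extend a gene by ``up`` nt at the 5' end and ``down`` nt at the 3' end.

    On the minus strand the 5' flank extends toward larger genomic
    coordinates.  The extended interval is clamped to [0, chrom_len).
    """
    if up < 0 or down < 0:
        raise ValueError("flank extensions must be non-negative")
    if chrom_len is not None and chrom_len < gene.mature_end:
        raise ValueError(
            f"{gene.gene_id}: chromosome length {chrom_len} < mature_end {gene.mature_end}"
        )
    if gene.strand == "+":
        start, end = gene.mature_start - up, gene.mature_end + down
    else:
        start, end = gene.mature_start - down, gene.mature_end + up
    start = max(0, start)
    if chrom_len is not None:
        end = min(end, chrom_len)
    return ExtendedGene(gene=gene, ext_start=start, ext_end=end, up_flank=up, down_flank=down)


def transcript_sequence(genome: GenomeSequence, chrom: str, start: int, end: int, strand: str) -> str:
    """Sequence of [start, end) in transcript (5'->3') orientation."""
    if strand not in ("+", "-"):
        raise ValueError(f"unknown strand symbol {strand!r}")
    seq = genome.fetch(chrom, start, end)
    return seq if strand == "+" else reverse_complement(seq)


def gene_to_gtf_and_back(gene: GeneAnnotation, tmp_path) -> GeneAnnotation:
    """Round-trip a single gene through GTF (used by invariant tests)."""
    write_annotation([gene], tmp_path)
    (reloaded,) = load_annotation(tmp_path)
    return replace(reloaded, is_nuclear=gene.is_nuclear)
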