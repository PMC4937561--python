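"""Position-weight-matrix localization of A-box and B-box promoter elements.

RNAPIII type-2 genes carry their promoter inside the transcribed region:
the A box (D-arm) starting near position +8 of the mature tRNA and the B
box (T-arm) further 3', at a variable distance when an intron intervenes.
A simple log-odds scan against consensus-derived PWMs is sufficient to
anchor metagene profiles; no score threshold is applied (the best hit is
always reported).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

from .annotations import GeneAnnotation, GenomeSequence, transcript_sequence

__all__ = [
    "Pwm",
    "BoxHit",
    "scan_best_hit",
    "locate_boxes",
    "read_meme_motifs",
    "A_BOX_CONSENSUS",
    "B_BOX_CONSENSUS",
]

ALPHABET = "ACGT"
_INDEX = {c: i for i, c in enumerate(ALPHABET)}

#: Consensus words for the internal promoter boxes (IUPAC degenerate).
A_BOX_CONSENSUS = "TGGCNNAGTGG"
B_BOX_CONSENSUS = "GTTCGANNC"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class BoxHit:
    gene_id: str
    box: str  # "A" or "B"
    offset: int  # nt from the mature 5' end, transcript orientation
    score: float  # log-odds, bits


class Pwm:
    """Probability matrix over {A,C,G,T} with background and pseudocount."""

    def __init__(self, matrix: np.ndarray, background: np.ndarray | None = None):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (width, 4)")
        if not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        if (matrix <= 0).any():
            raise ValueError("PWM entries must be positive (apply a pseudocount)")
        self.matrix = matrix
        self.background = (
            np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
        )
        # log-odds in bits; rows indexed by position, columns by base
        self.log_odds = np.log2(self.matrix / self.background)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_consensus(cls, consensus: str, pseudocount: float = 0.01) -> "Pwm":
        """Degenerate consensus -> equal-probability mixture, then pseudocount."""
        rows = []
        for letter in consensus.upper():
            allowed = IUPAC.get(letter)
            if allowed is None:
                raise ValueError(f"unknown consensus letter {letter!r}")
            col = np.zeros(4)
            for base in allowed:
                col[_INDEX[base]] = 1.0 / len(allowed)
            col = (col + pseudocount) / (1.0 + 4 * pseudocount)
            rows.append(col)
        return cls(np.array(rows))

    @classmethod
    def from_counts(cls, counts: np.ndarray, pseudocount: float = 0.01) -> "Pwm":
        counts = np.asarray(counts, dtype=float) + pseudocount
        return cls(counts / counts.sum(axis=1, keepdims=True))


def _encode(sequence: str) -> np.ndarray:
    """Base indices, with -1 for non-ACGT letters (scored as background)."""
    arr = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    out = np.full(len(arr), -1, dtype=np.int64)
    for base, idx in _INDEX.items():
        out[arr == ord(base)] = idx
    return out


def scan_best_hit(sequence: str, pwm: Pwm) -> tuple[int, float]:
    """Best-scoring window of ``pwm`` along ``sequence``.

    score(w) = sum_i log2(p_i(w_i) / bg(w_i)); ties resolve to the
    smallest offset.  Non-ACGT letters contribute zero log-odds.
    """
    n, w = len(sequence), pwm.width
    if n < w:
        raise ValueError(f"sequence length {n} < motif width {w}")
    enc = _encode(sequence)
    n_win = n - w + 1
    scores = np.zeros(n_win)
    for i in range(w):
        col = enc[i : i + n_win]
        valid = col >= 0
        scores[valid] += pwm.log_odds[i, col[valid]]
    # ties resolve to the smallest offset; tolerate summation-order noise
    best = scores.max()
    offset = int(np.flatnonzero(scores >= best - 1e-9)[0])
    return offset, float(scores[offset])


def locate_boxes(
    genes: list[GeneAnnotation],
    genome: GenomeSequence,
    pwm_a: Pwm | None = None,
    pwm_b: Pwm | None = None,
) -> list[BoxHit]:
    """Per-gene best A-box and B-box hits, in transcript orientation.

    The A box is searched in the 5' half of the gene body; the B box in
    the region 3' of the A-box hit, which accommodates intron-containing
    genes where the A-B spacing is variable.  Genes too short for a motif
    yield no hit for that motif.
    """
    pwm_a = pwm_a or Pwm.from_consensus(A_BOX_CONSENSUS)
    pwm_b = pwm_b or Pwm.from_consensus(B_BOX_CONSENSUS)
    hits: list[BoxHit] = []
    for gene in genes:
        seq = transcript_sequence(genome, gene.chrom, gene.mature_start, gene.mature_end, gene.strand)
        half = math.ceil(len(seq) / 2)
        # windows starting in the 5' half (allow the motif to cross the midline)
        region_a = seq[: min(len(seq), half + pwm_a.width - 1)]
        if len(region_a) < pwm_a.width:
            continue
        a_off, a_score = scan_best_hit(region_a, pwm_a)
        hits.append(BoxHit(gene.gene_id, "A", a_off, a_score))
        region_b = seq[a_off + pwm_a.width :]
        if len(region_b) < pwm_b.width:
            continue
        b_rel, b_score = scan_best_hit(region_b, pwm_b)
        hits.append(BoxHit(gene.gene_id, "B", a_off + pwm_a.width + b_rel, b_score))
    return hits


_MEME_MOTIF_RE = re.compile(r"^MOTIF\s+(\S+)")


def read_meme_motifs(path, pseudocount: float = 0.01) -> dict[str, Pwm]:
    """Read PWMs from MEME minimal motif text format."""
    motifs: dict[str, Pwm] = {}
    name = None
    rows: list[list[float]] = []
    expecting = False

    def flush():
        nonlocal rows, name
        if name is not None and rows:
            mat = np.asarray(rows, dtype=float)
            mat = (mat + pseudocount) / (1.0 + 4 * pseudocount)
            motifs[name] = Pwm(mat / mat.sum(axis=1, keepdims=True))
        rows = []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            m = _MEME_MOTIF_RE.match(line)
            if m:
                flush()
                name = m.group(1)
                expecting = False
                continue
            if line.startswith("letter-probability matrix"):
                expecting = True
                continue
            if expecting:
                parts = line.split()
                try:
                    values = [float(x) for x in parts[:4]]
                except ValueError:
                    expecting = False
                    continue
                if len(values) == 4:
                    rows.append(values)
                else:
                    expecting = False
    flush()
    return motifs
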