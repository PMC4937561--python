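"""Metagene profiles, heatmap matrices and correlation-distance clustering.

A metagene sums per-gene densities after aligning every gene at a common
anchor (mature 5'/3' end or A/B box).  Heatmap rows span fixed 5'/3'
flanks around a variable-length gene body; bodies are rescaled to the
median body length by linear interpolation so that the 5' and 3' peak
positions stay at the body edges.  Rows are clustered with the
1 - Pearson correlation distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .densities import GeneVector

__all__ = ["Metagene", "HeatmapMatrix", "metagene", "heatmap_matrix", "cluster_rows"]

ANCHORS = ("mature5", "mature3", "boxA", "boxB")


@dataclass
class Metagene:
    anchor: str
    window: tuple[int, int]  # (upstream nt, downstream nt)
    values: np.ndarray  # length = up + down + 1
    n_genes: int
    n_skipped: int = 0

    def offsets(self) -> np.ndarray:
        return np.arange(-self.window[0], self.window[1] + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets(), "value": self.values, "n_genes": self.n_genes})


@dataclass
class HeatmapMatrix:
    matrix: np.ndarray  # rows = genes, columns = anchored positions
    gene_ids: list[str]
    normalization: str
    body_columns: int
    up_flank: int
    down_flank: int
    zero_rows: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"c{i}" for i in range(self.matrix.shape[1])]
        df = pd.DataFrame(self.matrix, columns=cols)
        df.insert(0, "gene_id", self.gene_ids)
        return df


def metagene(gene_vectors: list[GeneVector], anchor: str, window: tuple[int, int]) -> Metagene:
    """Per-position sum of densities at anchor + offset over all genes.

    Positions falling outside a gene's extended interval contribute 0;
    genes lacking the anchor are skipped and counted.
    """
    if anchor not in ANCHORS:
        raise ValueError(f"unknown anchor {anchor!r}")
    up, down = window
    values = np.zeros(up + down + 1)
    n_used = n_skipped = 0
    for gv in gene_vectors:
        if anchor not in gv.anchors:
            n_skipped += 1
            continue
        a = gv.anchors[anchor]
        lo, hi = a - up, a + down + 1  # profile index range wanted
        src_lo, src_hi = max(lo, 0), min(hi, len(gv.values))
        if src_lo < src_hi:
            values[src_lo - lo : src_hi - lo] += gv.values[src_lo:src_hi]
        n_used += 1
    if n_used == 0:
        raise ValueError(f"no gene carries anchor {anchor!r}")
    return Metagene(anchor=anchor, window=window, values=values, n_genes=n_used, n_skipped=n_skipped)


def _resample(values: np.ndarray, n_out: int) -> np.ndarray:
    """Linear interpolation onto ``n_out`` evenly spaced points (exact on ramps)."""
    if len(values) == n_out:
        return values.copy()
    if len(values) == 1:
        return np.full(n_out, values[0])
    x_old = np.linspace(0.0, 1.0, len(values))
    x_new = np.linspace(0.0, 1.0, n_out)
    return np.interp(x_new, x_old, values)


def heatmap_matrix(
    gene_vectors: list[GeneVector],
    up_flank: int,
    down_flank: int,
    normalization: str = "row_max",
    body_columns: int | None = None,
) -> HeatmapMatrix:
    """Gene x position matrix over [mature5 - up_flank, mature3 + down_flank].

    The variable-length body (mature5..mature3 inclusive) is rescaled to a
    common column count (median body length by default).  ``row_max``
    divides each row by its maximum (all-zero rows are left as zeros and
    flagged); ``log2_global`` applies log2(x + 1) to the raw values.
    """
    if normalization not in ("row_max", "log2_global"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if not gene_vectors:
        raise ValueError("no gene vectors supplied")
    body_lens = [gv.anchors["mature3"] - gv.anchors["mature5"] + 1 for gv in gene_vectors]
    if body_columns is None:
        body_columns = int(np.median(body_lens))
    rows, ids, zero_rows = [], [], []
    for gv in gene_vectors:
        m5, m3 = gv.anchors["mature5"], gv.anchors["mature3"]
        if m5 - up_flank < 0 or m3 + 1 + down_flank > len(gv.values):
            raise ValueError(
                f"{gv.gene_id}: requested flanks exceed the extended interval"
            )
        up = gv.values[m5 - up_flank : m5]
        body = _resample(gv.values[m5 : m3 + 1], body_columns)
        down = gv.values[m3 + 1 : m3 + 1 + down_flank]
        row = np.concatenate([up, body, down])
        if normalization == "row_max":
            peak = row.max()
            if peak > 0:
                row = row / peak
            else:
                zero_rows.append(gv.gene_id)
        else:
            row = np.log2(row + 1.0)
        rows.append(row)
        ids.append(gv.gene_id)
    return HeatmapMatrix(
        matrix=np.vstack(rows),
        gene_ids=ids,
        normalization=normalization,
        body_columns=body_columns,
        up_flank=up_flank,
        down_flank=down_flank,
        zero_rows=zero_rows,
    )


def correlation_distance_matrix(rows: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Pairwise d = 1 - Pearson(r_i, r_j); zero-variance rows get d = 1."""
    n = rows.shape[0]
    sd = rows.std(axis=1)
    flagged = [i for i in range(n) if sd[i] == 0]
    dist = np.ones((n, n))
    np.fill_diagonal(dist, 0.0)
    ok = np.flatnonzero(sd > 0)
    if len(ok) >= 2:
        corr = np.corrcoef(rows[ok])
        sub = 1.0 - corr
        dist[np.ix_(ok, ok)] = sub
        np.fill_diagonal(dist, 0.0)
    return dist, flagged


def cluster_rows(matrix: HeatmapMatrix, linkage_method: str = "average"):
    """Agglomerative clustering on 1 - Pearson distance.

    Returns (row order as indices, scipy linkage matrix, flagged
    zero-variance row indices).
    """
    if linkage_method not in ("average", "complete"):
        raise ValueError(f"unknown linkage {linkage_method!r}")
    rows = matrix.matrix
    if rows.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    dist, flagged = correlation_distance_matrix(rows)
    # numerical noise can leave the matrix asymmetric at ~1e-16
    dist = (dist + dist.T) / 2.0
    z = linkage(squareform(dist, checks=False), method=linkage_method)
    order = list(leaves_list(z))
    return order, z, flagged
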