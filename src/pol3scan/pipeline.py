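"""End-to-end orchestration: simulate or load, then run every analysis stage.

``run_pipeline`` takes a :class:`RunConfig`, executes pileup -> per-gene
metrics -> box localization -> metagenes/heatmaps -> terminator calls ->
U-richness statistics -> novel-unit discovery -> R-loop scores, and
writes plain-text tables plus a manifest recording the seed and every
parameter, so that a rerun from the same manifest reproduces identical
outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotations import (
    DEFAULT_DOWN_FLANK,
    DEFAULT_UP_FLANK,
    GenomeSequence,
    extend_gene,
    load_annotation,
    transcript_sequence,
)
from .densities import extract_profile, pileup, pileup_ends, read_bed6, write_bed6, write_track
from .discovery import MERGE_ANNOTATED, MERGE_NOVEL, MIN_HEIGHT, MIN_LEN, candidates_to_gtf, discover_novel
from .gene_metrics import GROUP_THRESHOLD, RT_GAP, RT_SPAN, metrics_table
from .motif_scan import locate_boxes
from .peak_stats import HALF_WIDTH, MIN_MEAN_READS, SMOOTH_WINDOW, collect_pair_windows, urichness_test
from .profiles import cluster_rows, heatmap_matrix, metagene
from .rloop_thermo import RLOOP_WINDOW, rloop_score
from .synthetic_data import SimConfig, simulate_dataset
from .terminators import T1_WINDOW, T2_WINDOW, call_terminators, terminator_strength_by_rt

logger = logging.getLogger("pol3scan")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All pipeline parameters; defaults follow the standard analysis.

    Either ``simulate`` is set (synthetic run) or ``reads_bed``,
    ``genome_fasta`` and ``annotation_gtf`` point at input files.
    """

    out_dir: str = "pol3scan_out"
    seed: int = 0
    simulate: SimConfig | None = None
    reads_bed: str | None = None
    genome_fasta: str | None = None
    annotation_gtf: str | None = None
    biotype_filter: str | None = "tRNA"
    counting_mode: str = "three_prime_end"
    unique_only: bool = False
    up_flank: int = DEFAULT_UP_FLANK
    down_flank: int = DEFAULT_DOWN_FLANK
    ratio_threshold: float = GROUP_THRESHOLD
    rt_gap: int = RT_GAP
    rt_span: int = RT_SPAN
    t1_window: int = T1_WINDOW
    t2_window: int = T2_WINDOW
    min_mean_reads: float = MIN_MEAN_READS
    half_width: int = HALF_WIDTH
    smooth_window: int = SMOOTH_WINDOW
    urichness_method: str = "wilcoxon_paired"
    discovery_enabled: bool = True
    min_height: float = MIN_HEIGHT
    min_len: int = MIN_LEN
    merge_annotated: int = MERGE_ANNOTATED
    merge_novel: int = MERGE_NOVEL
    rloop_window: int = RLOOP_WINDOW
    metagene_window: tuple[int, int] = (200, 250)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = SimConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()})
        return cfg

    def to_manifest_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns a manifest dict (also written to disk)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "inputs"
    try:
        if config.simulate is not None:
            sim = dataclasses.replace(config.simulate, seed=config.seed)
            genome, genes, truth, reads = simulate_dataset(sim)
            genome.to_fasta(out / "genome.fa")
            from .annotations import write_annotation

            write_annotation(genes, out / "annotation.gtf")
            write_bed6(reads, out / "reads.bed")
            truth.gene_frame().to_csv(out / "sim_truth.tsv", sep="\t", index=False)
        else:
            if not (config.reads_bed and config.genome_fasta and config.annotation_gtf):
                raise ValueError("provide either a simulation config or input file paths")
            genome = GenomeSequence.from_fasta(config.genome_fasta)
            genes = load_annotation(config.annotation_gtf, biotype_filter=config.biotype_filter)
            reads = read_bed6(config.reads_bed)
        genes = [g for g in genes if g.is_nuclear]
        chrom_sizes = genome.chrom_sizes

        stage = "pileup"
        track = pileup(reads, chrom_sizes, unique_only=config.unique_only)
        write_track(track, out / "coverage.sgrs", "sgrs")
        # polymerase-position track: read 3' ends at single-base resolution;
        # profile-shape stages (metagenes, heatmaps, peak/trough calling)
        # use it so peak positions are not smeared by the read length
        end_track = pileup_ends(reads, chrom_sizes, unique_only=config.unique_only)
        write_track(end_track, out / "ends.sgrs", "sgrs")

        stage = "metrics"
        metrics = metrics_table(
            reads,
            genes,
            mode=config.counting_mode,
            threshold=config.ratio_threshold,
            rt_gap=config.rt_gap,
            rt_span=config.rt_span,
        )
        metrics.to_csv(out / "gene_metrics.tsv", sep="\t", index=False, na_rep="NA")

        stage = "boxes"
        box_hits = locate_boxes(genes, genome)
        box_df = pd.DataFrame(
            [{"gene_id": h.gene_id, "box": h.box, "offset": h.offset, "score": h.score} for h in box_hits]
        )
        box_df.to_csv(out / "boxes.tsv", sep="\t", index=False)

        stage = "profiles"
        exts = [extend_gene(g, config.up_flank, config.down_flank, chrom_sizes[g.chrom]) for g in genes]
        vectors = []
        box_lookup = {(h.gene_id, h.box): h.offset for h in box_hits}
        for ext in exts:
            gv = extract_profile(end_track, ext)
            for box, anchor in (("A", "boxA"), ("B", "boxB")):
                off = box_lookup.get((ext.gene.gene_id, box))
                if off is not None:
                    gv.anchors[anchor] = gv.anchors["mature5"] + off
            vectors.append(gv)
        for anchor in ("mature5", "mature3", "boxA", "boxB"):
            mg = metagene(vectors, anchor, config.metagene_window)
            mg.to_frame().to_csv(out / f"metagene_{anchor}.tsv", sep="\t", index=False)
        for norm in ("row_max", "log2_global"):
            hm = heatmap_matrix(vectors, min(50, config.up_flank), config.down_flank, normalization=norm)
            if len(hm.gene_ids) >= 2:
                order, _, _ = cluster_rows(hm)
                hm.matrix = hm.matrix[order]
                hm.gene_ids = [hm.gene_ids[i] for i in order]
            hm.to_frame().to_csv(out / f"heatmap_{norm}.tsv", sep="\t", index=False)

        stage = "terminators"
        downstream = {
            g.gene_id: (
                transcript_sequence(genome, g.chrom, g.mature_end, min(g.mature_end + config.rt_span, chrom_sizes[g.chrom]), "+")
                if g.strand == "+"
                else transcript_sequence(genome, g.chrom, max(g.mature_start - config.rt_span, 0), g.mature_start, "-")
            )
            for g in genes
        }
        calls = call_terminators(downstream, t1_window=config.t1_window, t2_window=config.t2_window)
        pd.DataFrame(
            [
                {
                    "gene_id": c.gene_id,
                    "t1_offset": "NA" if c.t1_offset is None else c.t1_offset,
                    "t1_len": c.t1_len,
                    "t2_class": c.t2_class or "NA",
                    "t2_len": "NA" if c.t2_len is None else c.t2_len,
                }
                for c in calls
            ]
        ).to_csv(out / "terminators.tsv", sep="\t", index=False)
        rt_map = {
            r.gene_id: r.rt_level for r in metrics.itertuples() if not np.isnan(r.rt_level)
        }
        strat = terminator_strength_by_rt(calls, rt_map)
        strat.table.to_csv(out / "terminator_by_rt.tsv", sep="\t", index=False)

        stage = "urichness"
        call_map = {c.gene_id: c for c in calls}
        peaks, troughs = [], []
        for ext, gv in zip(exts, vectors):
            c = call_map.get(ext.gene.gene_id)
            m3 = gv.anchors["mature3"]
            region = (m3 + 1 + config.rt_gap, min(len(gv.values), m3 + 1 + config.rt_span))
            if region[1] - region[0] < config.smooth_window:
                continue
            pairs = collect_pair_windows(
                gv,
                ext,
                genome,
                rt_region=region,
                t1_offset=None if c is None else c.t1_offset,
                t1_len=0 if c is None else c.t1_len,
                min_mean_reads=config.min_mean_reads,
                half_width=config.half_width,
                smooth_window=config.smooth_window,
            )
            for p, t in pairs:
                peaks.append(p)
                troughs.append(t)
        if peaks:
            res = urichness_test(peaks, troughs, method=config.urichness_method, half_width=config.half_width)
            urow = {
                "method": res.method,
                "n_pairs": res.n_pairs,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "mean_difference": res.mean_difference,
            }
        else:
            urow = {"method": config.urichness_method, "n_pairs": 0, "statistic": "NA", "p_value": "NA", "mean_difference": "NA"}
        pd.DataFrame([urow]).to_csv(out / "urichness.tsv", sep="\t", index=False)

        stage = "discovery"
        if config.discovery_enabled:
            candidates = discover_novel(
                track,
                exts,
                min_height=config.min_height,
                min_len=config.min_len,
                merge_annotated=config.merge_annotated,
                merge_novel=config.merge_novel,
            )
            candidates_to_gtf(candidates, out / "discovery.gtf")

        stage = "rloop"
        thermo = [rloop_score(g, genome, window=config.rloop_window) for g in genes]
        pd.DataFrame(
            [
                {"gene_id": t.gene_id, "dG_dna": t.dG_dna, "dG_hybrid": t.dG_hybrid, "ddG": t.ddG}
                for t in thermo
            ]
        ).to_csv(out / "rloop.tsv", sep="\t", index=False)
    except Exception:
        logger.error("pipeline failed at stage %r", stage)
        raise

    stage = "manifest"
    outputs = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": config.to_manifest_dict(),
        "outputs": {name: _sha256(out / name) for name in outputs},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
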