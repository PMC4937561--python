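"""Shared fixtures: tiny hand-built genomes and a session-scoped simulation."""

import numpy as np
import pytest

from pol3scan.annotations import GeneAnnotation, GenomeSequence
from pol3scan.synthetic_data import SimConfig, simulate_dataset


@pytest.fixture
def toy_genome():
    # 600 nt, fixed content: long enough for the 100..180 toy genes + flanks
    rng = np.random.default_rng(99)
    seq = "".join(rng.choice(list("ACGT"), size=600))
    return GenomeSequence({"chrT": seq})


@pytest.fixture
def plus_gene():
    return GeneAnnotation(
        gene_id="tPlus", chrom="chrT", mature_start=100, mature_end=180, strand="+", biotype="tRNA"
    )


@pytest.fixture
def minus_gene():
    return GeneAnnotation(
        gene_id="tMinus", chrom="chrT", mature_start=100, mature_end=180, strand="-", biotype="tRNA"
    )


@pytest.fixture(scope="session")
def sim_small():
    """Deterministic 12-gene dataset shared by read-level tests."""
    cfg = SimConfig(seed=7, n_genes=12, chrom_len=30_000, depth=2000)
    genome, genes, truth, reads = simulate_dataset(cfg)
    return cfg, genome, genes, truth, reads
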