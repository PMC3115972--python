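"""Shared fixtures: a session-scoped synthetic study plus small hand-built
genomes and gene models."""

import numpy as np
import pytest

from snvfunnel.gene_models import GeneModel, ReferenceGenome
from snvfunnel.synthetic_data import SimulationConfig
from snvfunnel.workflow import run_synthetic_study

STUDY_SEED = 1


@pytest.fixture(scope="session")
def config():
    return SimulationConfig(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study(config):
    """One full synthetic end-to-end run shared by the suite."""
    return run_synthetic_study(config)


@pytest.fixture
def flat_genome():
    """10 kb single-chromosome genome of repeating ACGT."""
    genome = ReferenceGenome()
    genome["chr1"] = "ACGT" * 2500
    return genome


def make_gene(gene_id="G1", chrom="chr1", strand="+", tx_start=2000,
              tx_end=3200, exons=None, cds_start=2300, cds_end=3000):
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                     tx_start=tx_start, tx_end=tx_end,
                     exons=exons if exons is not None else [(tx_start, tx_end)],
                     cds_start=cds_start, cds_end=cds_end)


@pytest.fixture
def single_exon_gene():
    """Plus-strand single-exon gene: tx [2000,3200), CDS [2300,3000)."""
    return make_gene()


@pytest.fixture
def rng():
    return np.random.default_rng(STUDY_SEED)
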