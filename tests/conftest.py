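"""Shared fixtures: a handcrafted toy locus and a session-scoped cohort.

The toy chromosome carries two small two-exon genes with known codon
content, one on each strand, so consequence classifications can be checked
by hand and against a brute-force translation oracle.
"""

from __future__ import annotations

import numpy as np
import pytest

from balscan.genome_model import GeneModel, Genome, reverse_complement
from balscan.pipeline import simulate_cohort
from balscan.strain_simulator import (
    SimulationParams,
    simulate_parental,
    simulate_reference,
)

# 20 codons, 60 coding bp; codon 3 is CAA (Q) -> TAA via C>T, codon 2 is TGG (W)
TOY_CODONS = [
    "ATG", "GGC", "TGG", "CAA", "GAG", "TTC", "CTG", "AAA", "CGT", "TAT",
    "GCA", "CAT", "ATC", "GAA", "AGC", "GTT", "CCA", "ACG", "TGC", "TAA",
]
TOY_CODING = "".join(TOY_CODONS)
TOY_INTRON = "GT" + "ACCTGACTTCAGTCCA" + "AG"  # 20 bp, canonical ends

CHROM = "chrT"


def _filler(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def build_toy_locus() -> tuple[Genome, list[GeneModel]]:
    """500 bp chromosome with a plus-strand gene at [100, 180) and its
    minus-strand twin at [300, 380); both split 30+30 coding bp around a
    20 bp intron."""
    rng = np.random.default_rng(2024)
    plus_region = TOY_CODING[:30] + TOY_INTRON + TOY_CODING[30:]
    minus_region = reverse_complement(plus_region)
    seq = (
        _filler(rng, 100)
        + plus_region
        + _filler(rng, 120)
        + minus_region
        + _filler(rng, 120)
    )
    genome = Genome({CHROM: seq})
    gene_plus = GeneModel("toy_plus", CHROM, "+", ((100, 130), (150, 180)))
    gene_minus = GeneModel("toy_minus", CHROM, "-", ((300, 330), (350, 380)))
    return genome, [gene_plus, gene_minus]


@pytest.fixture(scope="session")
def toy_locus():
    return build_toy_locus()


@pytest.fixture(scope="session")
def toy_genome(toy_locus):
    return toy_locus[0]


@pytest.fixture(scope="session")
def toy_genes(toy_locus):
    return toy_locus[1]


# ---------------------------------------------------------------------------
# simulated study


@pytest.fixture(scope="session")
def default_params():
    return SimulationParams(seed=7)


@pytest.fixture(scope="session")
def reference(default_params):
    return simulate_reference(default_params)


@pytest.fixture(scope="session")
def parental(reference, default_params):
    return simulate_parental(reference.genome, default_params)


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """On-disk cohort: 50 balanced strains plus 10 duplication-loss strains."""
    root = tmp_path_factory.mktemp("cohort")
    simulate_cohort(SimulationParams(seed=7), n_strains=50, outdir=root, n_unbalanced=10)
    return root
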