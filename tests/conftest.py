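"""Shared fixtures: hand-built two-exon toy transcripts on both strands and
the seeded synthetic benchmark dataset (session-scoped — it backs the
learning/evaluation/acceptance tests)."""

import numpy as np
import pandas as pd
import pytest

from synpred import SimConfig, assemble, simulate_dataset
from synpred.genomic_io import GenomeSequence, Transcript, Variant

# Toy CDS used on both strands: ATG GAA CTG | GAG TCC GGA (no stops)
TOY_CDS = "ATGGAACTGGAGTCCGGA"


def _pad(n, base="T"):
    return base * n


@pytest.fixture(scope="session")
def toy_genome():
    # c1: plus-strand gene, exon1 [10,19) exon2 [29,38), intron GT..AG
    c1 = _pad(10) + TOY_CDS[:9] + "GT" + "ACACAC" + "AG" + TOY_CDS[9:] + _pad(10)
    # c2: minus-strand gene with the same coding sequence; genomic sequence
    # is the reverse complement laid out with ascending exons
    from synpred.genomic_io import reverse_complement

    rc = reverse_complement(TOY_CDS)
    c2 = _pad(10) + rc[:9] + "CT" + "ACACAC" + "AC" + rc[9:] + _pad(10)
    return GenomeSequence({"c1": c1, "c2": c2})


@pytest.fixture(scope="session")
def toy_plus(toy_genome):
    return Transcript(
        id="txp", gene="gp", contig="c1", strand="+",
        exons=[(10, 19), (29, 38)], cds_start=10, cds_end=38,
    )


@pytest.fixture(scope="session")
def toy_minus(toy_genome):
    return Transcript(
        id="txm", gene="gm", contig="c2", strand="-",
        exons=[(10, 19), (29, 38)], cds_start=10, cds_end=38,
    )


@pytest.fixture(scope="session")
def sim_data():
    """Default synthetic benchmark (seed 1, 300+300 variants)."""
    return simulate_dataset(SimConfig(seed=1))


@pytest.fixture(scope="session")
def sim_matrix(sim_data):
    return assemble(
        sim_data.variants,
        sim_data.reference.transcripts,
        sim_data.reference.genome,
        sim_data.extractor_config(),
    )


@pytest.fixture(scope="session")
def gaussian_xy():
    """Small separable two-class Gaussian problem for fast model tests."""
    rng = np.random.default_rng(7)
    n = 60
    X = pd.DataFrame(
        {
            "f1": np.concatenate([rng.normal(1.5, 1, n), rng.normal(0, 1, n)]),
            "f2": np.concatenate([rng.normal(-1.5, 1, n), rng.normal(0, 1, n)]),
            "noise": rng.normal(0, 1, 2 * n),
        },
        index=[f"v{i}" for i in range(2 * n)],
    )
    y = pd.Series(np.r_[np.ones(n, dtype=int), np.zeros(n, dtype=int)], index=X.index)
    return X, y
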