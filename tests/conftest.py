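import numpy as np
import pytest

from regulomics.genome_io import GeneModel, GeneSet, Peak, PeakSet
from regulomics.synthetic_data import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def default_sim():
    """The default seeded fixture bundle (seed 42), shared across tests."""
    return simulate_all(SimulationConfig(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_genes():
    """Ten genes on one chromosome, mixed strands and biotypes."""
    rows = [
        ("gA", 100_000, 110_000, "+", "protein_coding"),
        ("gB", 150_000, 180_000, "-", "protein_coding"),
        ("gC", 220_000, 225_000, "+", "lincRNA"),
        ("gD", 300_000, 340_000, "-", "pseudogene"),
        ("gE", 400_000, 401_000, "+", "protein_coding"),
        ("gF", 480_000, 530_000, "+", "other_noncoding"),
        ("gG", 600_000, 640_000, "-", "protein_coding"),
        ("gH", 700_000, 705_000, "+", "lincRNA"),
        ("gI", 800_000, 860_000, "-", "protein_coding"),
        ("gJ", 900_000, 960_000, "+", "protein_coding"),
    ]
    return GeneSet(
        GeneModel(gid, "chr1", s, e, strand, bt) for gid, s, e, strand, bt in rows
    )


def random_peaks(rng, n, chrom="chr1", span=1_000_000, width=200):
    starts = rng.integers(0, span - width, size=n)
    return PeakSet(
        Peak(chrom, int(s), int(s) + width, int(s) + width // 2, float(sig))
        for s, sig in zip(starts, rng.uniform(0.5, 5.0, size=n))
    )
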