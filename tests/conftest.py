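import numpy as np
import pandas as pd
import pytest

from h1scape.genome import GeneSet, Genome, ReadSet, RegionSet, SignalTrack
from h1scape.synth import generate_genome


@pytest.fixture
def small_genome() -> Genome:
    return Genome(("chrA", "chrB"), (10_000, 8_000))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_track(genome: Genome, bin_size: int, rng: np.random.Generator,
                 libsize: int | None = None) -> SignalTrack:
    vals = {c: rng.normal(size=genome.n_bins(c, bin_size))
            for c in genome.chrom_names}
    return SignalTrack(bin_size=bin_size, values=vals, libsize=libsize)


def make_genes(rows) -> GeneSet:
    df = pd.DataFrame(rows, columns=["id", "chrom", "start", "end", "strand",
                                     "expression"])
    return GeneSet(df)


def make_reads(rows) -> ReadSet:
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand"])
    return ReadSet(df)


@pytest.fixture(scope="session")
def toy_truth():
    """Small synthetic genome reused by read-level tests (2 x 500 kb)."""
    return generate_genome(n_chrom=2, chrom_length=500_000, n_genes=60,
                           n_lads=4, seed=11, lad_length=40_000)
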