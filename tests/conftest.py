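import numpy as np
import pandas as pd
import pytest

from polledcheck import (
    LocusParams,
    ShortReadParams,
    SimulationConfig,
    TrioParams,
)
from polledcheck import synthetic_data as sd
from polledcheck.trio_mendel import GenotypeMatrix


def random_locus(rng: np.random.Generator, n: int) -> str:
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n).tobytes().decode()


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """A compact error-free genome for locus/read-level tests."""
    return SimulationConfig(
        seed=42,
        locus=LocusParams(genome_length=60_000, locus_start=30_000, decoy_length=20_000),
        short=ShortReadParams(error=0.0),
    )


@pytest.fixture(scope="session")
def small_world(small_cfg):
    """Reference + one Pc-heterozygous animal + truth, shared across tests."""
    reference, genomes, truth = sd.make_genomes(small_cfg, {"animal": "Pcp"})
    return reference, genomes, truth


def matrix_from_array(genotypes: np.ndarray, samples=None) -> GenotypeMatrix:
    n_sites, n_samples = genotypes.shape
    samples = samples or [f"s{i}" for i in range(n_samples)]
    sites = pd.DataFrame(
        {
            "contig": "chr1",
            "pos": np.arange(n_sites) * 100,
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix(
        sites=sites, samples=list(samples), genotypes=genotypes.astype(np.int8)
    )
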