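import numpy as np
import pytest

from dispkit.core import Genome, GenomicInterval
from dispkit.coverage import CoverageTrack
from dispkit.simulate import SimulationConfig, simulate_disp_dataset, simulate_proteome


@pytest.fixture(scope="session")
def small_genome() -> Genome:
    return Genome({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture
def flat_track(small_genome) -> CoverageTrack:
    """Constant depth 3.0 everywhere at 10-bp resolution."""
    values = {c: np.full(small_genome.n_bins(c, 10), 3.0) for c in small_genome}
    return CoverageTrack(genome=small_genome, values=values, resolution=10)


@pytest.fixture(scope="session")
def disp_sim():
    """One full two-condition simulated dataset shared across test modules."""
    return simulate_disp_dataset(SimulationConfig(), seed=11)


@pytest.fixture(scope="session")
def proteome_sim():
    return simulate_proteome(SimulationConfig(), seed=11, with_sequences=False)


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_start=50_000, max_len=2_000):
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, max_start))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out
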