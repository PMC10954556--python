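import numpy as np
import pytest

from holoco.simulate import (
    MeiosisModel,
    ObservationModel,
    SimulatedGenome,
    observe_gamete,
    simulate_meiosis,
    simulate_reference,
)


def bare_genome(chrom_lengths: dict[str, int]) -> SimulatedGenome:
    """Genome with a single dummy marker per chromosome (meiosis-only tests)."""
    markers = {
        c: {
            "pos": np.array([1], dtype=np.int64),
            "hap1": np.array(["A"], dtype=object),
            "hap2": np.array(["C"], dtype=object),
        }
        for c in chrom_lengths
    }
    return SimulatedGenome(chromosomes=list(chrom_lengths.items()), markers=markers)


@pytest.fixture(scope="session")
def small_genome() -> SimulatedGenome:
    """5 x 2 Mb reference at the study's marker density."""
    return simulate_reference([2_000_000] * 5, seed=101)


@pytest.fixture(scope="session")
def dense_genome() -> SimulatedGenome:
    """5 x 10 Mb reference with 1,000 markers per chromosome."""
    return simulate_reference([10_000_000] * 5, marker_spacing=10_000, seed=102)


@pytest.fixture(scope="session")
def meiosis_300cM(dense_genome) -> MeiosisModel:
    return MeiosisModel(
        genetic_length_cM={c: 60.0 for c, _ in dense_genome.chromosomes}, nu=5.0
    )


@pytest.fixture(scope="session")
def noiseless_cells(dense_genome, meiosis_300cM):
    """50 fully observed error-free gametes with their truths."""
    truths = simulate_meiosis(dense_genome, meiosis_300cM, 50, seed=103)
    obs = ObservationModel(markers_per_cell={"kind": "all"}, error_rate=0.0)
    cells = [
        observe_gamete(t, dense_genome, obs, seed=9_000 + i)
        for i, t in enumerate(truths)
    ]
    return cells, truths
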