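import numpy as np
import pytest

from paleomito import (
    DamageModel,
    ReadBatch,
    SimulationConfig,
    generate_genome,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_truth():
    """A 4 kb circular truth genome."""
    return generate_genome(4000, 0.4, seed=11)


@pytest.fixture(scope="session")
def noisefree_cfg():
    return SimulationConfig(
        genome_length=4000,
        n_references=1,
        divergences=[0.05],
        indel_rate=0.0,
        target_depth=30,
        contaminant_fraction=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def noisefree_reads(small_truth, noisefree_cfg):
    """Deep noise-free reads from the small truth genome."""
    return simulate_reads(small_truth, None, noisefree_cfg, DamageModel.none())


@pytest.fixture(scope="session")
def noisefree_batch(noisefree_reads):
    return ReadBatch(noisefree_reads)


def binomial_3se(p: float, n: int) -> float:
    """Three binomial standard errors for a proportion estimated from n trials."""
    return 3.0 * np.sqrt(p * (1.0 - p) / n)
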