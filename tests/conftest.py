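from __future__ import annotations

import numpy as np
import pytest

from gsize import simgenome as sim


def random_dna(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return sim.decode(rng.integers(0, 4, size=length).astype(np.int8))


@pytest.fixture(scope="session")
def repeat_free_genome() -> sim.SimulatedGenome:
    """50 kb genome with no repeat families."""
    return sim.simulate_genome(sim.GenomeSpec(unique_length=50_000, seed=11))


@pytest.fixture(scope="session")
def repeat_genome() -> sim.SimulatedGenome:
    """100 kb genome: 90 kb unique + one 10x1 kb zero-divergence dispersed family."""
    spec = sim.GenomeSpec(
        unique_length=90_000,
        families=(sim.RepeatFamilySpec("rep1", "dispersed", 1000, 10, 0.0),),
        seed=7,
    )
    return sim.simulate_genome(spec)
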