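import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).resolve().parent))

from amfpipe import (
    SimulationConfig,
    simulate_reads,
    simulate_reference_db,
)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def mutate_seq(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = []
    for base in seq:
        if rng.random() < rate:
            out.append(rng.choice([b for b in "ACGT" if b != base]))
        else:
            out.append(base)
    return "".join(out)


@pytest.fixture(scope="session")
def tiny_survey():
    """A small but complete mock survey shared across tests."""
    config = SimulationConfig(
        seed=7,
        n_ref_taxa=6,
        ref_length=(300, 400),
        read_length_mean=350.0,
        read_length_sd=20.0,
        reads_per_replicate=(30, 60),
    )
    known, labeled = simulate_reference_db(config)
    reads_by_sample, truth = simulate_reads(config, labeled)
    return config, known, labeled, reads_by_sample, truth
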