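import numpy as np
import pytest

from vanscape.simulate import (SimulationConfig, simulate_chip, simulate_genome,
                               simulate_methylomes)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=11, genome_length=80_000, n_te_families=2,
                            copies_per_family=3)


@pytest.fixture(scope="session")
def study(small_config):
    """One simulated study shared by recovery tests: genome, annotation,
    truth, WT/treated methylomes and ChIP tracks."""
    genome, annotation, truth = simulate_genome(small_config)
    wt, tr = simulate_methylomes(genome, annotation, truth, small_config)
    ip, inp, summits = simulate_chip(genome, annotation, truth, small_config)
    return {"config": small_config, "genome": genome, "annotation": annotation,
            "truth": truth, "wt": wt, "treated": tr, "ip": ip, "input": inp,
            "summits": summits}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
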