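import numpy as np
import pandas as pd
import pytest

from utrpause import (
    SimulationConfig,
    simulate_netseq,
    simulate_polya,
)


@pytest.fixture(scope="session")
def small_sim():
    """One modest synthetic strain shared across read-only tests."""
    cfg = SimulationConfig(seed=11, n_units=20)
    genome, units, coverage, truth = simulate_netseq(cfg)
    return cfg, genome, units, coverage, truth


@pytest.fixture(scope="session")
def coupled_polya(small_sim):
    cfg, genome, units, coverage, truth = small_sim
    profile, truth_sites = simulate_polya(units, truth, cfg, genome=genome)
    return profile, truth_sites
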