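import numpy as np
import pandas as pd
import pytest

from rhythmecon import SimulationConfig, simulate_timeseries


@pytest.fixture
def small_config() -> SimulationConfig:
    """Small but fully structured simulation used across stage tests."""
    return SimulationConfig(n_genes=300, n_cells=150, seed=42)


@pytest.fixture
def small_sim(small_config):
    ts, truth = simulate_timeseries(small_config)
    return ts, truth


@pytest.fixture
def truth_classes(small_sim):
    """Rhythm class labels taken directly from ground truth (no detection)."""
    _, truth = small_sim
    rna = truth["is_rhythmic_rna"].map({True: "rhythmic", False: "non_rhythmic"})
    prot = truth["is_rhythmic_protein"].map({True: "rhythmic", False: "non_rhythmic"})
    return rna, prot
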