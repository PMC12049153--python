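import numpy as np
import pandas as pd
import pytest

from mpeco.synthetic import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A compact multi-sample dataset shared by read-only tests."""
    cfg = SimulationConfig(
        n_samples=3,
        cells_per_sample=150,
        n_genes=800,
        n_shared_programs=2,
        n_private_programs_per_sample=1,
        program_gene_size=60,
        seed=42,
    )
    em, annot, truth = generate_dataset(cfg)
    return cfg, em, annot, truth


@pytest.fixture(scope="session")
def default_dataset():
    """One dataset at the default study conditions (8 x 300 x 2000)."""
    cfg = SimulationConfig(seed=7)
    em, annot, truth = generate_dataset(cfg)
    return cfg, em, annot, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
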