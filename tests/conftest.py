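import warnings

import numpy as np
import pandas as pd
import pytest

from osteoscreen import SimulationConfig, combat_adjust, simulate_timecourse

# the generator emits expected drop/degenerate warnings in several tests;
# keep test output clean without hiding unexpected ones globally
warnings.filterwarnings("ignore", message=".*dropped.*")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced-size simulation used by most unit tests."""
    return SimulationConfig(
        n_genes=300,
        n_pathway_modules=5,
        module_size=12,
        samples_per_batch_per_stage=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_timecourse(small_config)


@pytest.fixture(scope="session")
def small_merged(small_config, small_dataset):
    expr, meta, coll, edges, truth = small_dataset
    return combat_adjust(expr, meta), meta, coll, edges, truth


@pytest.fixture()
def toy_expr() -> pd.DataFrame:
    rng = np.random.default_rng(5)
    genes = [f"T{i:02d}" for i in range(10)]
    samples = [f"S{j}" for j in range(8)]
    return pd.DataFrame(
        rng.normal(8.0, 1.0, size=(10, 8)), index=genes, columns=samples
    )
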