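import numpy as np
import pandas as pd
import pytest

from methrisk import SimulationConfig, simulate_cohort

SEED = 12345


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured cohort shared across test modules."""
    cfg = SimulationConfig(n_samples=300, n_cpgs=400, n_variants=200,
                           n_cell_types=4, causal_cpgs_per_outcome=10,
                           causal_variants_per_outcome=5, seed=SEED,
                           panel_spec=[("panel_a", ["lab_1"])])
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture()
def toy_covariates(rng):
    n = 120
    return pd.DataFrame({
        "age": rng.uniform(18, 90, n),
        "sex": rng.integers(0, 2, n).astype(float),
        "smoking": rng.choice(["never", "former", "current"], n),
    }, index=[f"s{i}" for i in range(n)])
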