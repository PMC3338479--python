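import numpy as np
import pandas as pd
import pytest

from coexnet import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    """A fast study: 1200 genes, two planted modules, modest DE set."""
    return SimulationConfig(
        n_genes=1200,
        module_sizes=(50, 40),
        module_trait_loadings=(0.85, -0.85),
        n_de_genes=200,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_dataset(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def four_group_design():
    """28-sample design: 7 per group, trait 1 for exercise/fluoxetine."""
    rows = []
    for g in ("control", "enrichment", "exercise", "fluoxetine"):
        for i in range(7):
            rows.append((f"{g[:3]}_{i+1}", g))
    df = pd.DataFrame(rows, columns=["sample_id", "group"])
    df["trait"] = df["group"].isin(["exercise", "fluoxetine"]).astype(int)
    return df
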