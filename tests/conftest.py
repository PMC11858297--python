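import numpy as np
import pandas as pd
import pytest

from rhizonet import synthetic


@pytest.fixture(scope="session")
def demo_bundle():
    """One generated community under the default study conditions."""
    config = synthetic.demo_scenario(seed=11)
    table, taxonomy, truth = synthetic.generate_modular_abundances(config)
    return config, table, taxonomy, truth


@pytest.fixture(scope="session")
def demo_features():
    config = synthetic.demo_scenario(seed=11)
    features, truth = synthetic.generate_soil_plant_table(config, 30)
    return features, truth


@pytest.fixture()
def small_table():
    """Tiny hand-written abundance table (3 taxa x 4 samples)."""
    return pd.DataFrame(
        {
            "S1": [10, 5, 0],
            "S2": [8, 4, 1],
            "S3": [6, 3, 2],
            "S4": [4, 2, 3],
        },
        index=["t1", "t2", "t3"],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
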