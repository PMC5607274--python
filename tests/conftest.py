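import pandas as pd
import pytest

from vscontest import SimulationConfig, gen_library


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=7, n_library=1000, n_clusters=3)


@pytest.fixture(scope="session")
def small_library(small_config):
    return gen_library(small_config)


@pytest.fixture()
def toy_annotations():
    rows = [
        ("c1", "Yes", "IC50", 5.0, "uM"),
        ("c2", "Yes", "inhibition", 30.0, "%"),
        ("c3", "Src", "IC50", 10.0, "uM"),
        ("c4", "Lck", "Ki", 0.5, "uM"),
        ("c5", "Yes", "Kd", 9.99, "uM"),
        ("c6", "Yes", "IC50", 500.0, "nM"),
    ]
    return pd.DataFrame(rows, columns=["compound_id", "target_id", "measure",
                                       "value", "unit"])
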