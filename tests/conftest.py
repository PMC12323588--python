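import numpy as np
import pandas as pd
import pytest

from lordist import LongitudinalTable, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_table() -> LongitudinalTable:
    """1 subject, 2 features, 2 times (parsing-level fixture)."""
    df = pd.DataFrame(
        {
            "subject": ["S1", "S1", "S1", "S1"],
            "time": [0.0, 1.0, 0.0, 1.0],
            "feature": ["F1", "F1", "F2", "F2"],
            "value": [1.0, 2.0, 3.0, 4.0],
        }
    )
    return LongitudinalTable.from_frame(df)


@pytest.fixture(scope="session")
def small_sim():
    """Small but non-trivial simulated dataset for pipeline-level tests:
    12 subjects (6+6), 8 features, 6 aligned times."""
    cfg = SimulationConfig(
        n_case=6, n_control=6, n_timepoints=6, n_features=8, seed=7
    )
    table, groups = simulate_dataset(cfg)
    return table, groups


@pytest.fixture(scope="session")
def default_sim():
    """One full-size study replicate (100 subjects, 200 features)."""
    table, groups = simulate_dataset(SimulationConfig(seed=11))
    return table, groups
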