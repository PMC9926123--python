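import numpy as np
import pandas as pd
import pytest

from vbsphenotyper.sim import SimConfig, simulate_colony


@pytest.fixture(scope="session")
def small_study():
    """Two groups per genotype, enough to exercise every stage."""
    cfg = SimConfig(n_groups_per_genotype={"wildtype": 2, "knockout": 2})
    return simulate_colony(cfg, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_events():
    """Hand-written event log: 3 behaviors, one group of 3 animals."""
    return pd.DataFrame(
        {
            "group_id": ["g1"] * 3,
            "day": [1, 1, 2],
            "phase": ["dark", "dark", "light"],
            "time_s": [10.0, 20.0, 30.0],
            "actor": ["a", "b", "a"],
            "receiver": ["b", "a", None],
            "behavior": ["attack", "huddle", "eating"],
            "duration_s": [2.0, 5.0, 30.0],
            "zone": [0, 1, 2],
        }
    )
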