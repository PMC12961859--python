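import numpy as np
import pytest

from rosali.data import ResponseData
from rosali.simulate import SimulationScenario, simulate_dataset


@pytest.fixture(scope="session")
def small_cs_data():
    """Moderate two-group cross-sectional dataset with known truth."""
    sc = SimulationScenario(
        name="unit-cs",
        n_per_group=(250, 150),
        n_items=3,
        mu={("G1", "T1"): -0.6, ("G0", "T2"): 0.0, ("G1", "T2"): -0.6},
        missing_rate=0.0,
    )
    data, manifest = simulate_dataset(sc, seed=11)
    return data.at_time("T1"), sc


@pytest.fixture(scope="session")
def small_long_data():
    """Moderate longitudinal dataset, no DIF/RS, known latent truth."""
    sc = SimulationScenario(
        name="unit-long",
        n_per_group=(250, 150),
        n_items=4,
        mu={("G1", "T1"): -0.5, ("G0", "T2"): -0.4, ("G1", "T2"): -0.7},
        var={"T1": 1.0, "T2": 1.2},
        cov_t1t2=0.5,
        missing_rate=0.05,
    )
    data, manifest = simulate_dataset(sc, seed=12)
    return data, sc


@pytest.fixture()
def tiny_data():
    """Hand-built 4-person dataset with missingness, both time points."""
    resp = np.array(
        [
            [[2, 1], [0, 0], [3, 2]],
            [[1, -1], [3, 3], [-1, 0]],
            [[0, 1], [1, 2], [2, 2]],
            [[3, 3], [2, 1], [1, -1]],
        ]
    )
    return ResponseData(
        resp, [0, 1, 0, 1], ["a", "b", "c"], [4, 4, 4],
        group_labels=("G0", "G1"), time_labels=("T1", "T2"),
    )
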