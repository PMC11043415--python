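import numpy as np
import pandas as pd
import pytest

from metstab import (
    SimulationConfig,
    ammi_fit,
    cell_means,
    gge_fit,
    load_rice_yield_means,
    simulate_trial,
)
from metstab.io import CellMeans, TrialData


@pytest.fixture(scope="session")
def rice_means():
    return load_rice_yield_means()


@pytest.fixture(scope="session")
def rice_ammi(rice_means):
    return ammi_fit(rice_means)


@pytest.fixture(scope="session")
def rice_gge(rice_means):
    return gge_fit(rice_means)


@pytest.fixture(scope="session")
def sim_trial():
    """One simulated balanced trial at the default (rice-like) conditions."""
    return simulate_trial(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def sim_means(sim_trial):
    return cell_means(sim_trial[0])


def random_means(seed: int, g: int = 5, q: int = 4, scale: float = 10.0) -> CellMeans:
    rng = np.random.default_rng(seed)
    return CellMeans.from_matrix(rng.normal(0, scale, size=(g, q)))


def toy_trial(g=2, q=2, r=2, seed=0) -> TrialData:
    rng = np.random.default_rng(seed)
    rows = []
    for j in range(q):
        for i in range(g):
            for t in range(r):
                rows.append((f"E{j+1}", f"G{i+1}", f"R{t+1}", float(rng.normal(10, 3))))
    return TrialData(pd.DataFrame(rows, columns=["env", "gen", "rep", "value"]))
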