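import numpy as np
import pandas as pd
import pytest

from psmcr import CompetingRisksDataset, SimulationConfig, simulate_dataset


def make_dataset(times, statuses, X, group=None, censoring_time=None):
    """Small helper: build a dataset from plain arrays."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(times):
        X = X.T
    return CompetingRisksDataset(
        ids=np.array([f"s{i}" for i in range(len(times))]),
        times=np.asarray(times, dtype=float),
        statuses=np.asarray(statuses, dtype=int),
        covariates=pd.DataFrame(X, columns=[f"x{j + 1}" for j in range(X.shape[1])]),
        group=group,
        censoring_time=censoring_time,
    )


def random_competing_dataset(rng, n=30, m=2):
    """Continuous-time random competing-risks data (no ties) for oracles."""
    times = rng.exponential(2.0, n) + 1e-3
    statuses = rng.integers(0, 3, n)
    if not (statuses > 0).any():
        statuses[0] = 1
    return make_dataset(times, statuses, rng.normal(size=(n, m)))


@pytest.fixture(scope="session")
def paper_config():
    """The reference simulation design with a fixed session seed."""
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def sim_dataset(paper_config):
    return simulate_dataset(paper_config)


@pytest.fixture(scope="session")
def n50_dataset():
    cfg = SimulationConfig(n=50, seed=3)
    return simulate_dataset(cfg)
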