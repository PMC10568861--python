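import numpy as np
import pandas as pd
import pytest

from mrate.data import Dataset
from mrate.dgp import DGPConfig, generate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """One simulated dataset (n=500) shared across read-only tests."""
    return generate_dataset(DGPConfig(n=500, seed=42))


@pytest.fixture(scope="session")
def big_sim():
    """A large draw for consistency checks; generated once per session."""
    return generate_dataset(DGPConfig(n=100_000, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_dataset(X: np.ndarray, Z, Y, columns=None) -> Dataset:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if columns is None:
        columns = [f"X{i + 1}" for i in range(X.shape[1])]
    return Dataset(X=pd.DataFrame(X, columns=columns), Z=np.asarray(Z), Y=np.asarray(Y))


@pytest.fixture()
def tiny_dataset():
    """Four subjects, two per arm, one covariate."""
    return make_dataset(
        X=[[0.1], [0.2], [0.3], [0.4]], Z=[1, 1, 0, 0], Y=[2.0, 4.0, 1.0, 3.0]
    )
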