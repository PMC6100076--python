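import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from hsvr_qsar import SyntheticSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """Seeded 80-molecule synthetic dataset shared across tests."""
    spec = SyntheticSpec(n_samples=80, noise_sd=0.1, seed=42)
    molecules, descriptors = generate_dataset(spec)
    y = molecules.set_index("id")["log_er"]
    return descriptors, y.loc[descriptors.index]


@pytest.fixture
def toy_table():
    """Tiny named descriptor table with a known linear response."""
    rng = np.random.default_rng(7)
    X = pd.DataFrame(
        {
            "a": rng.normal(size=40),
            "b": rng.normal(size=40),
            "c": rng.normal(size=40),
        },
        index=[f"s{i}" for i in range(40)],
    )
    y = pd.Series(2.0 * X["a"].to_numpy() + 0.05 * rng.normal(size=40), index=X.index)
    return X, y
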