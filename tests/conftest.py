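import numpy as np
import pandas as pd
import pytest

from lodsift.datatypes import PedigreeSet
from lodsift.simulate import (
    SimulationConfig,
    simulate_dataset,
    write_dataset,
)


@pytest.fixture(scope="session")
def nuclear_family() -> PedigreeSet:
    """Two founders, two full-sib offspring."""
    return PedigreeSet(pd.DataFrame({
        "fid": ["A"] * 4,
        "iid": ["fa", "mo", "c1", "c2"],
        "father": ["", "", "fa", "fa"],
        "mother": ["", "", "mo", "mo"],
        "sex": [1, 2, 1, 2],
    }))


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_families=40, n_linkage_markers=30, seed=23)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory, small_dataset):
    out = tmp_path_factory.mktemp("data")
    write_dataset(small_dataset, out)
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
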