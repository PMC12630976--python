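import numpy as np
import pandas as pd
import pytest

from simcalib import (
    TabularDataset,
    forward_sample,
    toy_network,
)

TOY_NAMES = ["chain3", "collider3", "sprinkler4", "hub5"]


@pytest.fixture(scope="session")
def toys():
    return {name: toy_network(name) for name in TOY_NAMES}


@pytest.fixture(scope="session")
def chain_sample_10k():
    return forward_sample(toy_network("chain3"), 10_000, 101)


@pytest.fixture(scope="session")
def collider_sample_10k():
    return forward_sample(toy_network("collider3"), 10_000, 102)


def binary_dataset(columns: dict[str, np.ndarray]) -> TabularDataset:
    """Build a binary TabularDataset from 0/1 integer arrays."""
    frame = pd.DataFrame(
        {k: pd.Series(v.astype(int).astype(str)) for k, v in columns.items()}
    )
    return TabularDataset(frame, {k: ("0", "1") for k in columns})
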