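import numpy as np
import pandas as pd
import pytest

from surgicc import ClusteredDataset


@pytest.fixture
def two_cluster_dataset():
    """Two clusters {0,0} and {1,1}: MSW = 0, MSB = 1, ICC = 1."""
    df = pd.DataFrame(
        {"value": [0.0, 0.0, 1.0, 1.0], "centre": ["a", "a", "b", "b"]}
    )
    return ClusteredDataset("toy", "", "continuous", df)


@pytest.fixture
def nested_dataset():
    """10 participants, 2 centres x 2 surgeons each, two arms."""
    df = pd.DataFrame(
        {
            "participant_id": [f"p{i}" for i in range(10)],
            "value": [1.0, 2.0, 3.0, 2.5, 1.5, 4.0, 3.5, 2.0, 5.0, 4.5],
            "centre": ["C1"] * 5 + ["C2"] * 5,
            "surgeon": ["S1", "S1", "S2", "S2", "S2", "S3", "S3", "S4", "S4", "S4"],
            "arm": ["surgery", "medical"] * 5,
        }
    )
    return ClusteredDataset("recovery score", "3 m", "continuous", df)


@pytest.fixture
def constant_dataset():
    """All values identical across 4 clusters (totally degenerate)."""
    df = pd.DataFrame(
        {"value": [1.0] * 12, "centre": list("aaabbbcccddd")}
    )
    return ClusteredDataset("const", "", "continuous", df)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
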