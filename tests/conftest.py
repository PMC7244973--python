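import numpy as np
import pandas as pd
import pytest

from mtskit import FeatureTable, Group


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    """Complete 5-subject, 3-variable table."""
    frame = pd.DataFrame(
        {
            "A": [1.0, 2.0, 3.0, 4.0, 5.0],
            "B": [2.1, 1.9, 3.2, 4.3, 4.8],
            "C": [10.0, 12.0, 9.0, 11.0, 10.5],
        }
    )
    return FeatureTable(frame, Group.NORMAL)


@pytest.fixture
def random_table(rng):
    """50 x 4 independent-ish Gaussian table."""
    frame = pd.DataFrame(
        rng.standard_normal((50, 4)), columns=["w", "x", "y", "z"]
    )
    return FeatureTable(frame, Group.NORMAL)


def make_table(values, names=None, group=Group.NORMAL):
    values = np.asarray(values, dtype=float)
    names = names or [f"v{i}" for i in range(values.shape[1])]
    return FeatureTable(pd.DataFrame(values, columns=names), group)
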