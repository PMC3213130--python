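import numpy as np
import pandas as pd
import pytest

from pmrwls.sampling import SimConstants
from pmrwls.scenarios import QuantityModel


@pytest.fixture
def rng():
    return np.random.default_rng(2011)


@pytest.fixture
def consts():
    return SimConstants()


@pytest.fixture
def qmodel():
    return QuantityModel()


def make_table(pmr, surrogate, group, ids=None) -> pd.DataFrame:
    """Small helper to build an observation table from raw sequences."""
    frame = pd.DataFrame(
        {
            "id": ids if ids is not None else np.arange(len(pmr)),
            "pmr": np.asarray(pmr, dtype=float),
            "surrogate": np.asarray(surrogate, dtype=float),
            "group": group,
        }
    )
    return frame


@pytest.fixture
def two_group_table(rng):
    """A generic 60-sample two-group dataset with noise, no structure."""
    n = 60
    return make_table(
        pmr=rng.gamma(2.0, 12.0, size=n),
        surrogate=rng.uniform(0.5, 300.0, size=n),
        group=np.repeat([1, 2], n // 2),
    )
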