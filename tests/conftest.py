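import numpy as np
import pandas as pd
import pytest

from metss.preprocess import AbundanceMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def abundance(values, batch=None, sample_ids=None, metabolite_ids=None):
    """Build a small AbundanceMatrix from a 2-D array (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    metabolite_ids = metabolite_ids or [f"m{j}" for j in range(p)]
    df = pd.DataFrame(values, index=sample_ids, columns=metabolite_ids)
    if batch is None:
        batch = ["b0"] * n
    return AbundanceMatrix(df, pd.Series(batch, index=sample_ids))


@pytest.fixture
def toy_matrix():
    return abundance([[2.0, 10.0], [4.0, 20.0], [8.0, 40.0]])
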