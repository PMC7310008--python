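import numpy as np
import pandas as pd
import pytest

from ldalink.tables import AbundanceTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_gene_table():
    rng = np.random.default_rng(7)
    data = pd.DataFrame(
        rng.uniform(0, 100, size=(6, 4)),
        index=[f"P{i}" for i in range(6)],
        columns=[f"G{i}" for i in range(4)],
    )
    return AbundanceTable(data, kind="gene")


@pytest.fixture
def small_microbe_table():
    rng = np.random.default_rng(8)
    data = pd.DataFrame(
        rng.uniform(0, 50, size=(6, 3)),
        index=[f"P{i}" for i in range(6)],
        columns=[f"m{i}" for i in range(3)],
    )
    return AbundanceTable(data, kind="microbe")
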