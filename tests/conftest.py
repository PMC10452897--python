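import numpy as np
import pandas as pd
import pytest

from bcprs.io import RateTable, WeightTable
from bcprs.simulate import synthetic_rates


@pytest.fixture(scope="session")
def norwegian_like_rates():
    """Default registry-shaped incidence/mortality stand-in pair."""
    return synthetic_rates()


@pytest.fixture()
def small_weights():
    return WeightTable(pd.DataFrame({
        "variant_id": ["rs1", "rs2", "rs3"],
        "chromosome": ["1", "2", "3"],
        "position": [100, 200, 300],
        "effect_allele": ["A", "C", "G"],
        "other_allele": ["G", "T", "A"],
        "beta": [0.1, -0.2, 0.05]}))


@pytest.fixture()
def constant_incidence():
    return RateTable("incidence", [0], [100], [0.01])


@pytest.fixture()
def constant_mortality():
    return RateTable("mortality", [0], [100], [0.01])
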