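import numpy as np
import pandas as pd
import pytest

from autoborutarf import FeatureMatrix, ResponseTable, SyntheticConfig
from autoborutarf import synthetic_data


@pytest.fixture
def tiny_expression():
    df = pd.DataFrame(
        [[0.0, 1.0, 2.0], [1.0, 0.0, 2.0], [2.0, 2.0, 2.0], [0.0, 0.0, 0.0]],
        index=["c1", "c2", "c3", "c4"], columns=["g1", "g2", "g3"])
    return FeatureMatrix(df, "expression")


@pytest.fixture
def small_dataset():
    """Complete (no-missingness) small synthetic bundle for fast tests."""
    cfg = SyntheticConfig(n_cells=80, n_expression=40, n_cna=30, n_snv=10,
                          n_informative=3, missing_rate_ic50=0.0,
                          missing_rate_cna=0.0, missing_rate_snv=0.0, seed=7)
    return synthetic_data.generate(cfg)


@pytest.fixture
def holey_dataset():
    """Small synthetic bundle with missing IC50/CNA/SNV entries."""
    cfg = SyntheticConfig(n_cells=50, n_expression=20, n_cna=15, n_snv=8,
                          n_informative=2, missing_rate_ic50=0.15,
                          missing_rate_cna=0.1, missing_rate_snv=0.1, seed=11)
    return synthetic_data.generate(cfg)
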