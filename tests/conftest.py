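import numpy as np
import pandas as pd
import pytest

from bivmlogit.data_model import AnalysisTable, CategoricalSpec
from bivmlogit.synthetic import SyntheticConfig, simulate


@pytest.fixture
def survey_joint_table():
    """Four weighted pseudo-units reproducing the published weighted joint
    counts of the two outcomes (ANC&facility=1266, ANC&home=422,
    noANC&facility=796, noANC&home=1442; total 3,926)."""
    df = pd.DataFrame({
        "y1": [1, 1, 0, 0],
        "y2": [1, 0, 1, 0],
        "cluster": ["z1", "z1", "z2", "z2"],
        "weight": [1266.0, 422.0, 796.0, 1442.0],
    })
    return AnalysisTable(df, ())


@pytest.fixture
def small_schema():
    return (
        CategoricalSpec("education", ("none", "primary", "higher"), "none"),
        CategoricalSpec("residence", ("urban", "rural"), "urban"),
    )


@pytest.fixture
def small_table(small_schema):
    """12 hand-written units in 3 clusters with two covariates."""
    df = pd.DataFrame({
        "y1": [1, 0, 1, 1, 0, 0, 1, 0, 1, 0, 1, 0],
        "y2": [1, 0, 0, 1, 0, 1, 1, 0, 1, 1, 0, 0],
        "cluster": ["a", "a", "a", "a", "b", "b", "b", "b", "c", "c", "c", "c"],
        "weight": [1.0] * 12,
        "education": ["none", "primary", "higher", "none", "primary", "none",
                      "higher", "none", "primary", "none", "none", "higher"],
        "residence": ["urban", "urban", "rural", "rural", "urban", "rural",
                      "rural", "urban", "urban", "rural", "urban", "rural"],
    })
    return AnalysisTable(df, small_schema)


@pytest.fixture
def sim_table_small():
    """Reduced synthetic survey: 12 clusters of ~20, default truths."""
    cfg = SyntheticConfig(n_clusters=12, cluster_size_mean=20.0)
    return simulate(cfg, seed=42)
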