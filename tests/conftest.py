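import numpy as np
import pandas as pd
import pytest

from kneephen.preprocess import FeatureMetadata
from kneephen.synthetic import default_spec, generate_clinical_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed-type synthetic cohort shared across tests."""
    spec = default_spec(seed=11, n_rows=200, n_cols=30)
    table, truth, metadata = generate_clinical_matrix(spec)
    return {"spec": spec, "table": table, "truth": truth, "metadata": metadata}


@pytest.fixture
def mixed_table():
    """A tiny hand-written raw table with every feature kind."""
    raw = pd.DataFrame(
        {
            "age": [50.0, 60.0, 70.0, 55.0],
            "sex": [0.0, 1.0, 1.0, 0.0],
            "severity": ["none", "mild", "severe", "mild"],
            "race": ["A", "B", "C", "B"],
            "womac_total": [1.0, 2.0, 3.0, 4.0],
        }
    )
    metadata = [
        FeatureMetadata(name="age", kind="continuous"),
        FeatureMetadata(name="sex", kind="binary"),
        FeatureMetadata(name="severity", kind="ordinal", levels=("none", "mild", "severe")),
        FeatureMetadata(name="race", kind="nominal", levels=("A", "B", "C")),
        FeatureMetadata(name="womac_total", kind="continuous", exclude="redundant"),
    ]
    return raw, metadata
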