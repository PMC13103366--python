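import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from majic import AbundanceTable, SampleGroups

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def toy_table() -> AbundanceTable:
    """4 samples × 3 species, per-sample sums of 1."""
    df = pd.DataFrame(
        {
            "spA": [0.5, 0.4, 0.0, 0.25],
            "spB": [0.5, 0.3, 0.6, 0.25],
            "spC": [0.0, 0.3, 0.4, 0.50],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return AbundanceTable(df)


@pytest.fixture
def toy_groups(toy_table) -> SampleGroups:
    return SampleGroups(
        group=pd.Series(
            ["B-02", "B-02", "M", "M"], index=toy_table.sample_ids, name="group"
        )
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
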