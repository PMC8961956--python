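import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from rumenet.synthetic import fixture_small
from rumenet.tables import CountTable, SampleFrame

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_dataset():
    """Deterministic tiny synthetic study shared across tests."""
    return fixture_small()


@pytest.fixture()
def toy_counts():
    """A hand-sized count table with known structure."""
    df = pd.DataFrame(
        [[10, 10, 10, 10], [100, 0, 0, 0], [5, 3, 2, 0], [6, 0, 2, 1]],
        index=["s1", "s2", "s3", "s4"],
        columns=["t1", "t2", "t3", "t4"],
    )
    return CountTable.from_frame(df)


@pytest.fixture()
def toy_frame():
    df = pd.DataFrame(
        {
            "animal_id": ["a1", "a2", "a3", "a4"],
            "group": ["CC", "CC", "DL", "DL"],
            "timepoint": ["T1", "T1", "T1", "T1"],
            "day": [0, 0, 0, 0],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    return SampleFrame.from_frame(df)
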