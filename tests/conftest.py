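import numpy as np
import pandas as pd
import pytest

from mgx.io import OTUTable, SampleMetadata


def make_table(values, otu_ids=None, sample_ids=None, mode="counts"):
    values = np.asarray(values, dtype=float)
    otu_ids = otu_ids or [f"otu{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return OTUTable(pd.DataFrame(values, index=otu_ids, columns=sample_ids), mode=mode)


def split_halves(table):
    """First/second half of a table's sample columns (exchangeable cohorts)."""
    cols = table.sample_ids
    n = len(cols) // 2
    return table.select_samples(cols[:n]), table.select_samples(cols[n:])


@pytest.fixture
def tiny_table():
    return make_table([[5, 0], [3, 2], [0, 7]])


@pytest.fixture
def tiny_metadata():
    records = pd.DataFrame(
        {
            "subject_id": ["a", "b", "c", "d", "e", "f"],
            "group": ["M", "M", "M", "F", "F", "F"],
            "body_site": ["gut"] * 6,
        },
        index=pd.Index([f"s{j}" for j in range(6)], name="sample_id"),
    )
    return SampleMetadata(records)
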