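import os
import tempfile

# keep hypothesis' example/constants cache out of the repository tree
os.environ.setdefault("HYPOTHESIS_STORAGE_DIRECTORY",
                      os.path.join(tempfile.gettempdir(), "hypothesis-cache"))

import numpy as np
import pandas as pd
import pytest

from metabonet import SUVTable, SyntheticSpec, load_atlas, make_null_dataset


@pytest.fixture(scope="session")
def atlas():
    return load_atlas()


@pytest.fixture(scope="session")
def null_table():
    """Full-size null cohort (96 regions, 23/24 subjects, same covariance)."""
    return make_null_dataset(SyntheticSpec(), seed=42)


@pytest.fixture(scope="session")
def small_spec():
    """A 20-region miniature for fast permutation tests."""
    return SyntheticSpec(n_regions=20, community_sizes=(10, 10),
                         n_per_group=(12, 12))


@pytest.fixture(scope="session")
def small_table(small_spec):
    return make_null_dataset(small_spec, seed=7)


def make_table(values, groups, columns=None):
    """Hand-built SUVTable from a 2-D array and per-row group labels."""
    values = np.asarray(values, dtype=float)
    if columns is None:
        columns = [f"R{k+1:03d}" for k in range(values.shape[1])]
    idx = pd.Index([f"s{k:02d}" for k in range(values.shape[0])], name="subject")
    data = pd.DataFrame(values, index=idx, columns=columns)
    return SUVTable(data=data, groups=pd.Series(list(groups), index=idx, name="group"))
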