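import numpy as np
import pandas as pd
import pytest

from scbench.data import SCDataset, get_dataset
from scbench.transforms import default_pipeline


@pytest.fixture
def toy_counts():
    """3 cells x 4 genes integer count dataset."""
    X = np.array([[1.0, 0.0, 2.0, 0.0],
                  [2.0, 0.0, 0.0, 3.0],
                  [0.0, 3.0, 1.0, 1.0]])
    return SCDataset(X=X, cell_ids=["c0", "c1", "c2"],
                     gene_ids=["g0", "g1", "g2", "g3"],
                     layers={"raw": X.copy()})


@pytest.fixture
def labeled_toy():
    X = np.array([[5.0, 1.0, 0.0],
                  [4.0, 2.0, 1.0],
                  [6.0, 1.0, 0.0],
                  [0.0, 1.0, 5.0],
                  [1.0, 2.0, 4.0],
                  [0.0, 1.0, 6.0]])
    cell_ids = [f"c{i}" for i in range(6)]
    table = pd.DataFrame({"cell_type": ["A", "A", "A", "B", "B", "B"]},
                         index=cell_ids)
    return SCDataset(X=X, cell_ids=cell_ids, gene_ids=["g0", "g1", "g2"],
                     layers={"raw": X.copy()}, cell_table=table)


@pytest.fixture(scope="session")
def blobs4():
    return get_dataset("synth_blobs4")


@pytest.fixture(scope="session")
def blobs4_prepped(blobs4):
    return default_pipeline("zinb_dec").apply(blobs4)
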