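import numpy as np
import pandas as pd
import pytest

from dietpulse.core_data import StomachRecord, StomachTable
from dietpulse.dissimilarity import DissimilarityMatrix


def make_table(rows, vocabulary, category_map=None):
    """rows: (specimen_id, species, season, location, items-dict)."""
    if category_map is None:
        category_map = {item: "fish" for item in vocabulary}
    records = [StomachRecord(*r[:4], items=r[4]) for r in rows]
    return StomachTable(records, list(vocabulary), category_map)


@pytest.fixture
def tiny_table():
    """3 records, 2 items, one empty stomach."""
    return make_table(
        [
            ("s1", "spA", "wet", "L1", {"a": 2, "b": 1}),
            ("s2", "spA", "dry", "L1", {"a": 1}),
            ("s3", "spB", "wet", "L1", {}),
        ],
        vocabulary=["a", "b"],
        category_map={"a": "fish", "b": "insects"},
    )


def euclidean_dm(points, labels=None):
    from scipy.spatial.distance import pdist, squareform

    points = np.asarray(points, float)
    n = len(points)
    meta = pd.DataFrame({"specimen_id": [str(i) for i in range(n)]})
    if labels is not None:
        meta["species"] = list(labels)
    return DissimilarityMatrix(squareform(pdist(points)), meta, "euclidean")
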