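import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import furscent as fs
from furscent.dissimilarity import DistanceMatrix


@pytest.fixture(scope="session")
def replication_dataset():
    """Synthetic two-colony mother-pup dataset (50 pairs + one twin trio)."""
    return fs.generate_dataset(fs.study_design_config("replication", seed=1))


@pytest.fixture(scope="session")
def preprocessed(replication_dataset):
    return fs.preprocess_pipeline(replication_dataset)


@pytest.fixture(scope="session")
def bc_distance(preprocessed):
    return fs.bray_curtis(preprocessed.matrix)


@pytest.fixture
def small_matrix():
    return fs.AbundanceMatrix(["s1", "s2"], ["10.1", "12.3", "15.0"],
                              np.array([[1.0, 2.0, 0.0], [0.5, 0.0, 3.0]]), "raw")


def euclidean_dm(points, ids=None):
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    ids = ids or [f"p{i}" for i in range(len(points))]
    return DistanceMatrix(ids, squareform(pdist(points)))


@pytest.fixture
def four_point_line():
    """Two tight groups far apart on a line: SS_total=101, SS_between=100."""
    dm = euclidean_dm([0.0, 1.0, 10.0, 11.0], list("abcd"))
    groups = np.array(["g1", "g1", "g2", "g2"])
    meta = fs.SampleMetadata(pd.DataFrame({"sample_id": list("abcd"),
                                           "colony": groups}))
    return dm, groups, meta
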