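import numpy as np
import pytest

import dysrisk as dr


@pytest.fixture(scope="session")
def small_cohort():
    """60-subject 4-item cohort for which exhaustive search is tractable."""
    return dr.end_to_end_fixture(seed=0)


@pytest.fixture(scope="session")
def default_cohort():
    """Cohort at the default group sizes (167 CD / 52 HC)."""
    return dr.simulate_cohort(seed=7)


@pytest.fixture()
def count_table():
    """Tiny hand-built count table with taxonomy (one unclassified taxon)."""
    counts = np.array([
        [5, 0, 3, 2],
        [1, 1, 2, 0],
        [0, 4, 4, 2],
    ])
    taxonomy = {
        "t1": "k__Bacteria; p__Firmicutes; c__Clostridia",
        "t2": "k__Bacteria; p__Bacteroidetes",
        "t3": "k__Bacteria; p__Firmicutes",
        # t4 deliberately unclassified
    }
    return dr.CountTable(["a", "b", "c"], ["t1", "t2", "t3", "t4"], counts, taxonomy)


def euclidean_dm(points, ids=None):
    pts = np.asarray(points, dtype=float)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    ids = ids or [f"s{i}" for i in range(len(pts))]
    return dr.DistanceMatrix(ids, d)


@pytest.fixture()
def clustered_dm():
    """Two tight, well-separated clusters of 8 samples each (large enough
    that a random label permutation almost never recreates the partition)."""
    rng = np.random.default_rng(11)
    pts = np.vstack([
        rng.normal(0, 0.01, size=(8, 2)),
        rng.normal(10, 0.01, size=(8, 2)),
    ])
    return euclidean_dm(pts), ["A"] * 8 + ["B"] * 8
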