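import numpy as np
import pytest

from rumenmark.data_model import CountTable


@pytest.fixture
def small_table():
    """3 OTUs x 2 samples with taxonomy, for I/O and aggregation tests."""
    taxonomy = {
        "OTU_1": "Bacteria;Firmicutes;Clostridia;Clostridiales;Lachnospiraceae;Blautia",
        "OTU_2": "Bacteria;Firmicutes;Clostridia;Clostridiales;Lachnospiraceae;Blautia",
        "OTU_3": "Bacteria;Firmicutes;Clostridia;Clostridiales;Ruminococcaceae",
    }
    counts = np.array([[3, 4], [1, 2], [5, 6]])
    return CountTable(["OTU_1", "OTU_2", "OTU_3"], ["s1", "s2"], counts, taxonomy, "otu")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_blobs_distance(rng, sizes=(20, 20, 20), spread=0.3, sep=5.0):
    """Euclidean distance matrix of well-separated Gaussian blobs + labels."""
    from scipy.spatial.distance import pdist, squareform

    from rumenmark.diversity import DistanceMatrix

    centers = np.array([[0, 0], [sep, 0], [0, sep]])[: len(sizes)]
    pts = np.vstack(
        [c + spread * rng.standard_normal((s, 2)) for c, s in zip(centers, sizes)]
    )
    labels = np.repeat(np.arange(len(sizes)), sizes)
    d = DistanceMatrix([str(i) for i in range(len(pts))], squareform(pdist(pts)), "other")
    return d, labels, pts
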