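import numpy as np
import pytest

from srtgen import SRTData, make_reference_fixture


@pytest.fixture(scope="session")
def small_ref():
    """A small layered NB reference: 40 genes x 200 grid locations, 4 domains."""
    data, truth = make_reference_fixture(
        n_genes=40, n_locations=200, layout="grid", n_domains=4,
        param_sampler="default", pattern="layered", seed=11)
    return data, truth


@pytest.fixture(scope="session")
def starmap_like_ref():
    """A moderate-count random-layout reference (single-cell-resolution regime)."""
    data, truth = make_reference_fixture(
        n_genes=30, n_locations=400, layout="random", n_domains=4,
        param_sampler="starmap_like", pattern="layered", seed=7)
    return data, truth


@pytest.fixture()
def tiny_data():
    """Hand-written 3 genes x 4 locations dataset with domains."""
    counts = np.array([[0, 2, 4, 0],
                       [1, 1, 1, 1],
                       [0, 0, 0, 9]])
    coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    return SRTData(counts, coords,
                   gene_ids=np.array(["g1", "g2", "g3"]),
                   location_ids=np.array(["s1", "s2", "s3", "s4"]),
                   domains=np.array(["L1", "L1", "L2", "L2"]))
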