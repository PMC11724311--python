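import numpy as np
import pytest
import scipy.sparse as sp

import qclus


@pytest.fixture(scope="session")
def heart_registry():
    return qclus.default_registry("heart")


@pytest.fixture(scope="session")
def small_population():
    """A 1200-droplet heart-like population with planted classes."""
    params = qclus.SyntheticParams(n_droplets=1200)
    matrix, truth, registry = qclus.generate_population(params, seed=7)
    return matrix, truth, registry


@pytest.fixture(scope="session")
def small_feature_table(small_population):
    matrix, _, registry = small_population
    return qclus.build_feature_table(matrix, registry)


@pytest.fixture
def tiny_matrix():
    """3 droplets x 4 genes with hand-checkable counts."""
    counts = sp.csr_matrix(
        np.array(
            [
                [10, 0, 0, 0],
                [5, 5, 0, 0],
                [0, 0, 3, 7],
            ]
        )
    )
    return qclus.DropletMatrix(
        counts=counts,
        barcodes=np.array(["BC1", "BC2", "BC3"], dtype=object),
        genes=np.array(["A", "B", "C", "D"], dtype=object),
    )
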