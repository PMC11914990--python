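import numpy as np
import pytest

import fcora


@pytest.fixture
def small_atlas():
    """Two networks of 3 and 4 ROIs: 21 ROI-pairs, 3 network-pairs."""
    return fcora.make_synthetic_atlas(2, (3, 4))


@pytest.fixture
def small_index(small_atlas):
    return fcora.build_roi_pair_index(small_atlas)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_null_regression(rng, n, r, q_extra=1, k=1):
    """Independent y and design blocks for null-behaviour checks."""
    y = rng.standard_normal((n, r))
    X1 = np.column_stack([np.ones(n)] + [rng.standard_normal(n) for _ in range(q_extra)])
    X2 = rng.standard_normal((n, k))
    return y, X1, X2
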