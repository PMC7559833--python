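import numpy as np
import pytest

from panelval import LikertScale, RatingMatrix, load_fixture


@pytest.fixture(scope="session")
def physicians():
    return load_fixture("physicians")


@pytest.fixture(scope="session")
def nurses():
    return load_fixture("nurses")


@pytest.fixture(scope="session")
def nurses_reconciled():
    return load_fixture("nurses", "table6-reconciled")


def random_matrix(rng, n_experts=None, n_items=None, scale=None, panel_id="random"):
    """Arbitrary valid panel for property tests."""
    scale = scale or LikertScale(1, 5)
    n = n_experts or int(rng.integers(2, 12))
    j = n_items or int(rng.integers(1, 12))
    ratings = rng.integers(scale.lowest, scale.highest + 1, size=(n, j))
    return RatingMatrix(
        panel_id, scale,
        [f"E{i+1}" for i in range(n)], [f"Q{k+1}" for k in range(j)], ratings,
    )
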