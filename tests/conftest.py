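import numpy as np
import pytest

from efasdm import (
    LandscapeConfig,
    PredictorStack,
    RasterGrid,
    compute_efa_stack,
    generate_landscape,
)


@pytest.fixture(scope="session")
def small_bundle():
    """One 24x24 landscape shared by read-only tests."""
    return generate_landscape(LandscapeConfig(nrows=24, ncols=24, seed=11))


@pytest.fixture(scope="session")
def small_efa(small_bundle):
    return compute_efa_stack(small_bundle.satellite)


@pytest.fixture(scope="session")
def small_efa_stack(small_efa):
    stack = PredictorStack()
    stack.update(small_efa, "EFAs")
    return stack


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def grid_of(data, cell_size=1.0):
    return RasterGrid(np.asarray(data, dtype=float), cell_size=cell_size)
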