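import numpy as np
import pytest

import mwstroke as mw
from mwstroke import imaging, pipeline


@pytest.fixture(scope="session")
def array():
    return mw.default_array()


@pytest.fixture(scope="session")
def slice_grid():
    # in-plane imaging grid: single XY slice at the antenna ring
    return mw.make_grid(5.0, None)


@pytest.fixture(scope="session")
def slab_grid():
    # 3-D slab for out-of-plane studies, symmetric about the ring plane
    return mw.make_grid(5.0, (40.0, 160.0))


@pytest.fixture(scope="session")
def slice_operator(array, slice_grid):
    return mw.assemble_operator(array, slice_grid, mw.HEAD)


@pytest.fixture(scope="session")
def slab_operator(array, slab_grid):
    return mw.assemble_operator(array, slab_grid, mw.HEAD)


@pytest.fixture(scope="session")
def slice_model(slice_operator):
    return imaging.TSVDBorn(slice_operator)


@pytest.fixture(scope="session")
def slab_model(slab_operator):
    return imaging.TSVDBorn(slab_operator)


@pytest.fixture(scope="session")
def default_config():
    return pipeline.RunConfig(master_seed=1000)


@pytest.fixture(scope="session")
def m1_m2(default_config, slab_operator):
    return pipeline.simulate(default_config, slab_operator)


@pytest.fixture(scope="session")
def trained(default_config, m1_m2):
    m1, m2 = m1_m2
    return pipeline.train_and_evaluate(default_config, m1, m2)


def forward_for(operator, label, diameter, center):
    """Noiseless differential channel vector for a stroke scenario."""
    sc = mw.StrokeScenario(label, center, diameter)
    return mw.forward_dS(operator, mw.true_contrast(sc, operator.grid))
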