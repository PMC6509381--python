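import numpy as np
import pytest
from hypothesis import settings

import coastniche as cn

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_stack() -> cn.EnvironmentalStack:
    """A 40x80 synthetic coastal stack shared across tests."""
    return cn.make_grid(cn.GridSpec(40, 80), seed=7)


@pytest.fixture(scope="session")
def small_truth(small_stack) -> cn.TrueModel:
    return cn.default_true_model(small_stack)


@pytest.fixture(scope="session")
def small_tables(small_stack, small_truth):
    """(presence, background) layer-value tables from the small landscape."""
    occ = cn.sample_occurrences(small_stack, small_truth, 120, seed=3)
    bg = cn.sample_background(small_stack, 1500, seed=4)
    pres = cn.extract_predictors(occ, small_stack, label=1)
    back = cn.extract_predictors(bg, small_stack, label=0)
    return pres.data, back.data


@pytest.fixture(scope="session")
def fitted_model(small_tables):
    pres, back = small_tables
    cfg = cn.MaxentConfig(rm=1.0, fc="LQ", n_hinge_knots=10)
    return cn.fit(pres, back, cfg, categorical={"Drainage", "Tclass"})


def binary_map(values, nodata=None, cell_size=1.0) -> cn.BinaryHabitatMap:
    """Helper to build a habitat map from a 0/1 array."""
    values = np.asarray(values, dtype=np.uint8)
    grid = cn.GridSpec(*values.shape, cell_size=cell_size)
    if nodata is None:
        nodata = np.zeros(values.shape, dtype=bool)
    return cn.BinaryHabitatMap(grid, values, np.asarray(nodata, dtype=bool))
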