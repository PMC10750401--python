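import numpy as np
import pytest

from pacenet import CellParameters, LRM_PARAMS, HRM_PARAMS


@pytest.fixture(scope="session")
def lrm() -> CellParameters:
    return LRM_PARAMS


@pytest.fixture(scope="session")
def hrm() -> CellParameters:
    return HRM_PARAMS


@pytest.fixture(scope="session")
def lrm_basal_run(lrm):
    """Isolated lower-rate-module cell, basal state, 12 s (shared)."""
    from pacenet import simulate_cell
    t, V, ap = simulate_cell(lrm, duration=12.0, dt=0.005, record_stride=100)
    return t, V, ap


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
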