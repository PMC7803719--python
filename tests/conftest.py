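import numpy as np
import pytest

from lamadd import LaminarModel, RunConfig, make_design
from lamadd.hrf import compact_hrf


@pytest.fixture(scope="session")
def default_design():
    return make_design(seed=11)


@pytest.fixture(scope="session")
def compact_model():
    """Linear laminar model whose HRF fits inside one epoch window."""
    return LaminarModel(hrf=compact_hrf())


@pytest.fixture()
def small_config(tmp_path):
    """Reduced-size session for fast end-to-end tests."""
    return RunConfig(seed=3, n_voxels_per_depth=6, rois=(1, 2))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
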