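import numpy as np
import pytest

from expochain import dispersion
from expochain.region import StudyRegion


@pytest.fixture(scope="session")
def small_region():
    return StudyRegion(origin=(0.0, 0.0), cell_size=2000.0, n_rows=10, n_cols=10)


@pytest.fixture(scope="session")
def metamodel():
    """One modest metamodel shared by the dispersion tests."""
    return dispersion.fit_metamodel({"n_met": 12, "n_receptors": 300}, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
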