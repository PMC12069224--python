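import numpy as np
import pytest

from geosuit.grids import GridSpec
from geosuit.synthland import TrueModel, VarSpec, make_stack, true_suitability


@pytest.fixture(scope="session")
def grid40():
    return GridSpec(n_rows=40, n_cols=40, cell_size=0.05)


@pytest.fixture(scope="session")
def stack40(grid40):
    """Four independent smoothed fields plus one engineered collinear layer."""
    specs = [
        VarSpec("temp", "bioclim", smoothness=3.0),
        VarSpec("slope", "topo", smoothness=2.0),
        VarSpec("ndvi", "vegetation", smoothness=3.0),
        VarSpec("footprint", "human", smoothness=3.0),
        VarSpec("temp_twin", "bioclim", smoothness=3.0, partner="temp", rho=0.96),
    ]
    return make_stack(grid40, specs, seed=11)


@pytest.fixture(scope="session")
def strong_model():
    """Dominant linear driver + stratified driver, low prevalence, mild noise."""
    return TrueModel(
        linear_coefs={"temp": 4.0, "ndvi": 0.5},
        step_var="slope",
        step_breaks=(-0.5, 0.5),
        step_levels=(-1.2, 0.0, 1.2),
        intercept=-6.0,
        noise_sd=0.4,
    )


@pytest.fixture(scope="session")
def p_field(stack40, strong_model):
    return true_suitability(stack40, strong_model, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
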