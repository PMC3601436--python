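import numpy as np
import pytest

from ivtreat import ErrorSpec, StructuralParams, simulate_dataset

RHO = 0.721
SIGMA = 1.5


@pytest.fixture(scope="session")
def params_main() -> StructuralParams:
    """Collapsed design at the study's fitted selection correlation."""
    return StructuralParams.collapsed(rho=RHO, sigma_y=SIGMA)


@pytest.fixture(scope="session")
def data_main(params_main):
    """One mid-sized dataset with strong unmeasured selection."""
    return simulate_dataset(
        params_main, ErrorSpec("normal", rho=RHO, sigma_y=SIGMA), 4000, seed=101
    )


@pytest.fixture(scope="session")
def params_exo() -> StructuralParams:
    return StructuralParams.collapsed(rho=0.0, sigma_y=1.2)


@pytest.fixture(scope="session")
def data_exo(params_exo):
    """Exogenous-treatment dataset (rho = 0)."""
    return simulate_dataset(
        params_exo, ErrorSpec("normal", rho=0.0, sigma_y=1.2), 4000, seed=202
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
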