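import numpy as np
import pytest

from phenomate import SimulationConfig, build_covariances


TABLE_DEFAULTS = dict(
    nc_initial=500, mu_return_day=10.0, mu_rls=5.0,
    var_return_day=20.0, var_rls=20.0, rho=-0.3, omega_scalar=2.0,
    var_theta_return_day=20.0, var_theta_rls=1.0,
)


@pytest.fixture
def default_config() -> SimulationConfig:
    return SimulationConfig(**TABLE_DEFAULTS)


@pytest.fixture
def default_covs(default_config):
    return build_covariances(default_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230520)
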