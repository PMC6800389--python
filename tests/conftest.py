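import numpy as np
import pytest

from mortmap.histories import qc_filter, tabulate_cbh
from mortmap.model import ModelData
from mortmap.params import GPHyper, ModelParams
from mortmap.synthetic import (
    SurveyConfig,
    WorldConfig,
    simulate_gp_field,
    simulate_surveys,
    simulate_true_mortality,
    simulate_world,
)

TINY_WORLD_CONFIG = WorldConfig(
    n_rows=4, n_cols=4, cell_size=10.0, years=(2000, 2001, 2002),
    countries=(2, 1), admin1_per_country=(1, 1), admin2_per_admin1=(2, 2),
    mean_births_per_cell_year=60.0,
)

TINY_GP = GPHyper(spatial_range=15.0, sigma_z=0.3, rho_t=0.7, rho_a=0.7)


@pytest.fixture(scope="session")
def tiny_world():
    return simulate_world(TINY_WORLD_CONFIG, 123)


@pytest.fixture(scope="session")
def tiny_truth(tiny_world):
    z = simulate_gp_field(tiny_world.grid, tiny_world.age_scheme, TINY_GP, 7)
    params = ModelParams(
        beta0=-3.2, beta_age=np.array([-0.9, -1.1, -0.9, -1.3, -1.6, -1.8]),
        beta_cov=np.array([0.5, -0.3]), beta_time=-0.05,
        nu_country=np.array([0.2, -0.2]), sigma_c=0.3,
        nu_survey=np.zeros(0), sigma_k=0.1, z=z, gp=TINY_GP,
    )
    return params, simulate_true_mortality(params, tiny_world)


@pytest.fixture(scope="session")
def tiny_surveys(tiny_world, tiny_truth):
    _, truth = tiny_truth
    return simulate_surveys(
        truth, tiny_world,
        SurveyConfig(n_surveys=3, clusters_per_survey=10,
                     births_per_cluster=40, sigma_k=0.1),
        seed=9,
    )


@pytest.fixture(scope="session")
def tiny_obs(tiny_world, tiny_surveys):
    obs = tabulate_cbh(tiny_surveys.children, tiny_surveys.clusters,
                       tiny_world.age_scheme, tiny_world.grid.years)
    kept, _ = qc_filter(obs, tiny_world.grid.years)
    return kept


@pytest.fixture(scope="session")
def tiny_data(tiny_world, tiny_obs):
    return ModelData.from_world(tiny_obs, tiny_world)
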