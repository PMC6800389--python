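"""Hazards model: likelihood values, gradients, MAP fit, draws, prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import approx_fprime
from scipy.special import logit

from mortmap.histories import OBS_COLUMNS
from mortmap.model import (
    FitConfig,
    HazardsPosterior,
    ModelData,
    draw_posterior,
    fit_map,
    neg_log_likelihood,
    predict_probability_surfaces,
)
from mortmap.params import ModelParams
from tests.conftest import TINY_GP


def _flat_params(data, beta0=0.0, nu_k=None):
    grid = data.grid
    return ModelParams(
        beta0=beta0, beta_age=np.zeros(6), beta_cov=np.zeros(data.n_covariates),
        beta_time=0.0, nu_country=np.zeros(data.n_countries), sigma_c=1.0,
        nu_survey=np.zeros(data.n_surveys) if nu_k is None else nu_k,
        sigma_k=1.0, z=np.zeros((7, grid.n_years, grid.n_cells)), gp=TINY_GP,
    )


def _single_obs_data(world, n, y):
    centre = world.grid.cell_centres()[0]
    obs = pd.DataFrame([{
        "obs_id": 0, "survey_id": "S0", "country_id": "C00",
        "cluster_id": "c0", "x": centre[0], "y": centre[1], "polygon_id": "",
        "year": world.grid.years[0], "age_bin": 1, "entrants": n, "deaths": y,
        "weight": 1.0, "source_type": "cbh",
    }])[OBS_COLUMNS]
    return ModelData.from_world(obs, world)


class TestLikelihood:
    def test_single_bernoulli_at_half(self, tiny_world):
        data = _single_obs_data(tiny_world, 1.0, 0.0)
        val = neg_log_likelihood(_flat_params(data), data)
        assert val == pytest.approx(np.log(2.0), abs=1e-9)

    def test_all_deaths_at_probability_one_limit(self, tiny_world):
        data = _single_obs_data(tiny_world, 10.0, 10.0)
        val = neg_log_likelihood(_flat_params(data, beta0=30.0), data)
        assert val == pytest.approx(0.0, abs=1e-8)

    def test_shift_invariance_between_intercept_and_country_effects(
            self, tiny_data):
        p1 = _flat_params(tiny_data, beta0=-2.0)
        p2 = _flat_params(tiny_data, beta0=-2.0 + 0.7)
        p2.nu_country = p2.nu_country - 0.7
        assert neg_log_likelihood(p1, tiny_data) \
            == pytest.approx(neg_log_likelihood(p2, tiny_data), rel=1e-12)

    def test_polygon_rows_rejected(self, tiny_world, tiny_obs):
        obs = tiny_obs.copy()
        obs.loc[obs.index[0], "polygon_id"] = "C00_A1000_A2000"
        with pytest.raises(ValueError, match="resample"):
            ModelData.from_world(obs, tiny_world)

    def test_analytic_gradient_matches_finite_differences(self, tiny_data):
        post = HazardsPosterior(tiny_data)
        rng = np.random.default_rng(0)
        params = _flat_params(tiny_data, beta0=-3.0)
        vec = post.layout.pack(params)
        vec = vec + 0.05 * rng.standard_normal(vec.size)
        _, g = post.value_and_grad(vec)
        g_num = approx_fprime(vec, lambda x: post.value_and_grad(x)[0], 1e-6)
        assert np.max(np.abs(g - g_num) / (1.0 + np.abs(g_num))) < 1e-3


class TestFit:
    def test_zero_observations_mode_is_prior_mode(self, tiny_world):
        empty = pd.DataFrame(columns=OBS_COLUMNS)
        data = ModelData.from_world(empty, tiny_world)
        fit = fit_map(data, config=FitConfig(precision_mode="none",
                                             outer_maxfev=150))
        p = fit.params
        assert p.beta0 == pytest.approx(0.0, abs=1e-4)
        assert np.allclose(p.beta_age, 0.0, atol=1e-4)
        assert np.allclose(p.nu_country, 0.0, atol=1e-6)
        assert not p.z.any()
        # hyperparameter marginal criterion reduces to the hyper priors:
        # half-Normal(0,1) modes at sigma = 1, Uniform rho at 0, range at
        # its log-Normal median
        assert p.sigma_c == pytest.approx(1.0, abs=0.05)
        assert p.sigma_k == pytest.approx(1.0, abs=0.05)
        assert p.gp.sigma_z == pytest.approx(1.0, abs=0.05)
        assert p.gp.rho_t == pytest.approx(0.0, abs=0.05)
        assert p.gp.rho_a == pytest.approx(0.0, abs=0.05)
        med = np.median(tiny_world.grid.distances()[
            np.triu_indices(tiny_world.grid.n_cells, k=1)])
        assert np.log(p.gp.spatial_range) == pytest.approx(np.log(med), abs=0.1)

    def test_fit_is_deterministic(self, tiny_data):
        cfg = FitConfig(outer_maxfev=15, precision_mode="none")
        f1 = fit_map(tiny_data, config=cfg, seed=1)
        f2 = fit_map(tiny_data, config=cfg, seed=2)
        assert np.array_equal(f1.vec, f2.vec)

    def test_objective_path_monotone_nonincreasing(self, tiny_data):
        fit = fit_map(tiny_data, config=FitConfig(outer_maxfev=10,
                                                  precision_mode="none"))
        path = np.array(fit.diagnostics["objective_path"])
        assert np.all(np.diff(path) <= 1e-8 * np.maximum(1.0, np.abs(path[:-1])))

    def test_head_covariance_routes_agree(self, tiny_data):
        cfg_dense = FitConfig(outer_maxfev=10, precision_mode="dense")
        cfg_schur = FitConfig(outer_maxfev=10, precision_mode="fixed_marginal")
        f1 = fit_map(tiny_data, config=cfg_dense)
        f2 = fit_map(tiny_data, config=cfg_schur)
        assert np.allclose(f1.head_cov, f2.head_cov, rtol=1e-4, atol=1e-8)

    def test_non_finite_init_raises(self, tiny_data):
        bad = _flat_params(tiny_data, beta0=np.inf)
        with pytest.raises(ValueError, match="finite"):
            fit_map(tiny_data, init=bad)


@pytest.fixture(scope="module")
def tiny_fit(tiny_data):
    return fit_map(tiny_data, config=FitConfig(outer_maxfev=25))


class TestDraws:
    def test_requested_number_of_draws(self, tiny_fit):
        draws = draw_posterior(tiny_fit, n_draws=1000, seed=3)
        assert draws.draws.shape[0] == 1000

    def test_draw_mean_near_mode(self, tiny_fit):
        draws = draw_posterior(tiny_fit, n_draws=1000, seed=4)
        dev = draws.draws[:, tiny_fit.precision_index] \
            - tiny_fit.vec[tiny_fit.precision_index]
        sd = dev.std(axis=0)
        assert np.all(np.abs(dev.mean(axis=0)) <= 4.0 * sd / np.sqrt(1000) + 1e-12)

    def test_fixed_seed_reproducible(self, tiny_fit):
        d1 = draw_posterior(tiny_fit, n_draws=50, seed=5)
        d2 = draw_posterior(tiny_fit, n_draws=50, seed=5)
        assert np.array_equal(d1.draws, d2.draws)

    def test_too_few_draws_rejected(self, tiny_fit):
        with pytest.raises(ValueError):
            draw_posterior(tiny_fit, n_draws=1)

    def test_missing_precision_raises_with_hint(self, tiny_data):
        fit = fit_map(tiny_data, config=FitConfig(outer_maxfev=5,
                                                  precision_mode="none"))
        with pytest.raises(ValueError, match="precision_mode='dense'"):
            draw_posterior(fit)


class TestPrediction:
    def test_survey_effects_excluded_from_prediction(self, tiny_fit, tiny_data):
        draws = draw_posterior(tiny_fit, n_draws=20, seed=6)
        cube1 = predict_probability_surfaces(draws, tiny_data)
        sl, _ = draws.layout.slices()
        perturbed = draws
        perturbed.draws[:, sl["nu_k"]] += 5.0
        cube2 = predict_probability_surfaces(perturbed, tiny_data)
        assert np.array_equal(cube1.p_bins, cube2.p_bins)

    def test_predictions_strictly_inside_unit_interval(self, tiny_fit, tiny_data):
        draws = draw_posterior(tiny_fit, n_draws=20, seed=7)
        cube = predict_probability_surfaces(draws, tiny_data)
        assert np.all(cube.p_bins > 0) and np.all(cube.p_bins < 1)

    def test_mean_prediction_tracks_crude_rates(self, tiny_fit, tiny_data):
        # at observed support the fitted bin-1 probability should be close
        # to the pooled crude bin-1 ratio
        draws = draw_posterior(tiny_fit, n_draws=100, seed=8)
        cube = predict_probability_surfaces(draws, tiny_data)
        mask = tiny_data.a_idx == 0
        crude = tiny_data.y[mask].sum() / tiny_data.n[mask].sum()
        pooled = np.average(
            cube.p_bins[:, 0, tiny_data.t_idx[mask], tiny_data.cell_idx[mask]],
            weights=np.broadcast_to(tiny_data.n[mask],
                                    (100, mask.sum())), axis=None)
        assert logit(pooled) == pytest.approx(logit(crude), abs=0.35)
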