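"""Synthetic world generator: grids, admin nesting, GP fields, surveys."""

import numpy as np
import pandas as pd
import pytest

from mortmap.covariance import SeparableCovariance, ar1_correlation, matern_covariance
from mortmap.params import GPHyper, ModelParams
from mortmap.synthetic import (
    AgeBinScheme,
    GridDefinition,
    SurveyConfig,
    WorldConfig,
    nested_rectangles,
    simulate_gp_field,
    simulate_surveys,
    simulate_true_mortality,
    simulate_world,
)
from tests.conftest import TINY_WORLD_CONFIG


class TestGridDefinition:
    def test_cell_centres_and_index_roundtrip(self):
        g = GridDefinition(0.0, 0.0, 10.0, 3, 4, (2000, 2001))
        centres = g.cell_centres()
        assert centres.shape == (12, 2)
        assert np.array_equal(g.cells_of_points(centres[:, 0], centres[:, 1]),
                              np.arange(12))

    def test_nearest_cell_tie_breaks_to_lower_index(self):
        g = GridDefinition(0.0, 0.0, 10.0, 1, 3, (2000,))
        # x = 10 is equidistant from centres at 5 and 15
        assert g.cells_of_points(10.0, 5.0)[0] == 0

    def test_point_outside_raises(self):
        g = GridDefinition(0.0, 0.0, 10.0, 2, 2, (2000,))
        with pytest.raises(ValueError, match="outside"):
            g.cells_of_points(-1.0, 5.0)

    @pytest.mark.parametrize("kwargs", [
        dict(cell_size=0.0), dict(n_rows=0), dict(years=(2000, 2002)),
    ])
    def test_invalid_definitions_raise(self, kwargs):
        base = dict(origin_x=0.0, origin_y=0.0, cell_size=5.0,
                    n_rows=2, n_cols=2, years=(2000, 2001))
        base.update(kwargs)
        with pytest.raises(ValueError):
            GridDefinition(**base)


class TestAgeBins:
    def test_default_scheme_covers_under_five(self):
        s = AgeBinScheme.default()
        assert [b.width_months for b in s.bins] == [1, 5, 6, 12, 12, 12, 12]
        assert s.bins[0].lower_month == 0 and s.bins[-1].upper_month == 60

    def test_bin_lookup(self):
        s = AgeBinScheme.default()
        assert list(s.bin_of_age_months([0.5, 3, 8, 14, 30, 40, 59.9])) \
            == [1, 2, 3, 4, 5, 6, 7]
        assert s.bin_of_age_months([60.0])[0] == -1


class TestAdminTessellation:
    def test_nesting_and_coverage(self, tiny_world):
        admin = tiny_world.admin
        for level in (1, 2):
            for u in admin.units_at(level):
                assert u.parent_id in admin.unit_ids(level - 1)
        for level in (0, 1, 2):
            assert np.all(admin.cell_to_unit[level] >= 0)
        # children cells are subsets of the parent's cells
        for u in admin.units_at(2):
            parent = admin.by_id(u.parent_id)
            assert set(u.cells) <= set(parent.cells)

    def test_incompatible_split_raises(self):
        g = GridDefinition(0.0, 0.0, 10.0, 4, 4, (2000,))
        with pytest.raises(ValueError, match="tessellation"):
            nested_rectangles(g, (3, 1), (1, 1), (1, 1))


class TestSimulateWorld:
    def test_same_seed_bit_identical(self):
        w1 = simulate_world(TINY_WORLD_CONFIG, 5)
        w2 = simulate_world(TINY_WORLD_CONFIG, 5)
        for c1, c2 in zip(w1.covariates, w2.covariates):
            assert np.array_equal(c1.values, c2.values)
        assert np.array_equal(w1.population.live_births, w2.population.live_births)

    def test_zero_covariates_is_valid(self):
        w = simulate_world(
            WorldConfig(n_rows=4, n_cols=4, n_covariates=0,
                        countries=(2, 1), admin1_per_country=(1, 1),
                        admin2_per_admin1=(2, 2)), 1)
        assert w.covariates == []
        assert w.covariate_stack.shape[0] == 0

    def test_covariates_standardized(self, tiny_world):
        for c in tiny_world.covariates:
            assert c.standardized
            assert abs(c.values.mean()) < 1e-6
            assert abs(c.values.std() - 1.0) < 1e-6

    def test_population_strictly_positive(self, tiny_world):
        assert np.all(tiny_world.population.live_births > 0)
        assert np.all(tiny_world.population.under5 > 0)


class TestGPField:
    def test_zero_variance_gives_zero_field(self, tiny_world):
        z = simulate_gp_field(tiny_world.grid, tiny_world.age_scheme,
                              GPHyper(15.0, 0.0, 0.5, 0.5), 1)
        assert not z.any()

    def test_invalid_hyper_raises(self):
        with pytest.raises(ValueError):
            GPHyper(15.0, 0.3, 1.0, 0.5)
        with pytest.raises(ValueError):
            GPHyper(-1.0, 0.3, 0.5, 0.5)

    def test_same_seed_identical(self, tiny_world):
        h = GPHyper(15.0, 0.4, 0.6, 0.6)
        z1 = simulate_gp_field(tiny_world.grid, tiny_world.age_scheme, h, 3)
        z2 = simulate_gp_field(tiny_world.grid, tiny_world.age_scheme, h, 3)
        assert np.array_equal(z1, z2)

    def test_scalar_draw_variance(self):
        # 1 age x 1 year x 1 cell: the draw is Normal(0, sigma^2)
        sigma = 0.7
        cov = SeparableCovariance(np.eye(1), np.eye(1),
                                  np.array([[sigma**2]]))
        rng = np.random.default_rng(11)
        draws = np.array([cov.sample(rng)[0, 0, 0] for _ in range(10_000)])
        mc_se = sigma**2 * np.sqrt(2.0 / len(draws))
        assert abs(draws.var() - sigma**2) < 3 * mc_se

    def test_kron_sampler_covariance_matches_kernel(self):
        # 2 ages x 2 years x 4 cells: empirical covariance of 20,000 draws
        # matches the analytic Kronecker kernel entrywise within 3 MC ses
        rng = np.random.default_rng(12)
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [20.0, 20.0]])
        from scipy.spatial.distance import pdist, squareform
        cov = SeparableCovariance(
            ar1_correlation(2, 0.6), ar1_correlation(2, 0.4),
            matern_covariance(squareform(pdist(pts)), 25.0, 0.9),
        )
        n = 20_000
        draws = np.stack([cov.sample(rng).ravel() for _ in range(n)])
        emp = np.cov(draws, rowvar=False)
        k = cov.dense()
        mc_se = np.sqrt((np.outer(np.diag(k), np.diag(k)) + k**2) / n)
        assert np.all(np.abs(emp - k) < 3.0 * mc_se + 1e-12)


class TestTrueMortality:
    def test_zero_effects_give_half(self, tiny_world):
        g = tiny_world.grid
        params = ModelParams(
            beta0=0.0, beta_age=np.zeros(6), beta_cov=np.zeros(0),
            beta_time=0.0, nu_country=np.zeros(2), sigma_c=1.0,
            nu_survey=np.zeros(0), sigma_k=1.0,
            z=np.zeros((7, g.n_years, g.n_cells)),
            gp=GPHyper(10.0, 0.1, 0.5, 0.5),
        )
        world = type(tiny_world)(g, tiny_world.age_scheme, [],
                                 tiny_world.population, tiny_world.admin)
        p = simulate_true_mortality(params, world)
        assert np.allclose(p, 0.5)

    def test_intercept_closed_form(self, tiny_world):
        g = tiny_world.grid
        params = ModelParams(
            beta0=-3.0, beta_age=np.zeros(6), beta_cov=np.zeros(0),
            beta_time=0.0, nu_country=np.zeros(2), sigma_c=1.0,
            nu_survey=np.zeros(0), sigma_k=1.0,
            z=np.zeros((7, g.n_years, g.n_cells)),
            gp=GPHyper(10.0, 0.1, 0.5, 0.5),
        )
        world = type(tiny_world)(g, tiny_world.age_scheme, [],
                                 tiny_world.population, tiny_world.admin)
        p = simulate_true_mortality(params, world)
        assert np.allclose(p, 1.0 / (1.0 + np.exp(3.0)))

    def test_single_covariate_closed_form(self, tiny_world):
        g = tiny_world.grid
        from mortmap.params import mortality_cube
        params = ModelParams(
            beta0=-3.0, beta_age=np.zeros(6), beta_cov=np.array([0.5]),
            beta_time=0.0, nu_country=np.zeros(2), sigma_c=1.0,
            nu_survey=np.zeros(0), sigma_k=1.0,
            z=np.zeros((7, g.n_years, g.n_cells)),
            gp=GPHyper(10.0, 0.1, 0.5, 0.5),
        )
        x = np.full((1, g.n_years, g.n_cells), 2.0)
        p = mortality_cube(params, x, tiny_world.admin.country_of_cell)
        assert np.allclose(p, 1.0 / (1.0 + np.exp(2.0)))

    def test_values_strictly_inside_unit_interval(self, tiny_truth):
        _, truth = tiny_truth
        assert np.all(truth > 0) and np.all(truth < 1)


class TestSimulateSurveys:
    def test_zero_sigma_k_gives_zero_biases(self, tiny_world, tiny_truth):
        _, truth = tiny_truth
        sd = simulate_surveys(truth, tiny_world,
                              SurveyConfig(n_surveys=2, clusters_per_survey=5,
                                           births_per_cluster=10, sigma_k=0.0), 1)
        assert np.allclose(sd.survey_bias["nu_k"], 0.0)

    def test_zero_polygon_fraction_gives_coordinates_everywhere(
            self, tiny_world, tiny_truth):
        _, truth = tiny_truth
        sd = simulate_surveys(truth, tiny_world,
                              SurveyConfig(n_surveys=2, clusters_per_survey=5,
                                           births_per_cluster=10,
                                           polygon_fraction=0.0), 2)
        assert sd.clusters["x"].notna().all()
        assert (sd.clusters["polygon_id"] == "").all()

    def test_polygon_clusters_carry_no_coordinates(self, tiny_world, tiny_truth):
        _, truth = tiny_truth
        sd = simulate_surveys(truth, tiny_world,
                              SurveyConfig(n_surveys=2, clusters_per_survey=20,
                                           births_per_cluster=5,
                                           polygon_fraction=1.0), 3)
        assert sd.clusters["x"].isna().all()
        assert (sd.clusters["polygon_id"] != "").all()

    def test_invalid_polygon_fraction_raises(self):
        with pytest.raises(ValueError):
            SurveyConfig(polygon_fraction=1.5)

    def test_same_seed_identical(self, tiny_world, tiny_truth):
        _, truth = tiny_truth
        cfg = SurveyConfig(n_surveys=2, clusters_per_survey=5, births_per_cluster=10)
        s1 = simulate_surveys(truth, tiny_world, cfg, 42)
        s2 = simulate_surveys(truth, tiny_world, cfg, 42)
        pd.testing.assert_frame_equal(s1.children, s2.children)
        pd.testing.assert_frame_equal(s1.clusters, s2.clusters)

    def test_bin1_death_fraction_matches_hazard(self, tiny_world):
        # constant truth: bin-1 hazard 0.1; the fraction of births dying in
        # bin 1 converges at the binomial rate
        g = tiny_world.grid
        truth = np.full((7, g.n_years, g.n_cells), 0.02)
        truth[0] = 0.1
        n_births = 10_000
        sd = simulate_surveys(
            truth, tiny_world,
            SurveyConfig(n_surveys=1, clusters_per_survey=10,
                         births_per_cluster=n_births // 10, sigma_k=0.0),
            seed=21,
        )
        died_bin1 = (
            (sd.children["outcome"] == "died")
            & (sd.children["age_at_death_months"] < 1.0)
        ).sum()
        se = np.sqrt(0.1 * 0.9 / n_births)
        assert abs(died_bin1 / n_births - 0.1) < 3 * se

    def test_sbh_sources_emit_bin_level_rows(self, tiny_world, tiny_truth):
        _, truth = tiny_truth
        sd = simulate_surveys(truth, tiny_world,
                              SurveyConfig(n_surveys=1, clusters_per_survey=4,
                                           births_per_cluster=5,
                                           n_sbh_surveys=1), 4)
        sbh = sd.sbh_observations
        assert not sbh.empty
        assert (sbh["source_type"] == "sbh").all()
        assert (sbh["deaths"] <= sbh["entrants"]).all()
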