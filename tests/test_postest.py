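"""Post-estimation: composition, deaths, raking, aggregation, scenarios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mortmap.postest import (
    AdminAggregate,
    aggregate_to_admin,
    compose_mortality,
    counterfactual_averted_draws,
    counterfactual_deaths_averted,
    estimate_deaths,
    exceedance_probability,
    inequality_metrics,
    neonatal_fraction,
    rake_to_reference,
)
from mortmap.synthetic import (
    AgeBinScheme,
    GridDefinition,
    PopulationSurface,
    nested_rectangles,
)


def _two_country_world(n_years=2):
    grid = GridDefinition(0.0, 0.0, 10.0, 2, 4, tuple(2000 + t for t in range(n_years)))
    admin = nested_rectangles(grid, (2, 1), (1, 1), (2, 2))
    rng = np.random.default_rng(0)
    births = rng.uniform(50, 150, (grid.n_years, grid.n_cells))
    return grid, admin, PopulationSurface(grid, births, 4.8 * births)


class TestComposeMortality:
    def test_single_bin_is_identity(self):
        p = np.random.default_rng(1).uniform(0.01, 0.2, (3, 7, 2, 4))
        assert np.array_equal(compose_mortality(p, 1), p[:, 0])

    def test_direct_product_oracle(self):
        bins = np.array([0.02, 0.01, 0.01, 0.005, 0.004, 0.003, 0.002])
        p = bins.reshape(1, 7, 1, 1)
        expected = 1.0 - np.prod(1.0 - bins)
        assert expected == pytest.approx(0.05288, abs=5e-6)
        assert compose_mortality(p, 7)[0, 0, 0] == pytest.approx(expected, rel=1e-12)

    def test_invalid_upto_bin(self):
        with pytest.raises(ValueError):
            compose_mortality(np.full((1, 7, 1, 1), 0.1), 2)

    def test_out_of_range_probability_rejected(self):
        p = np.full((1, 7, 1, 1), 0.1)
        p[0, 0] = 0.0
        with pytest.raises(ValueError):
            compose_mortality(p, 7)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_composition_depth(self, seed):
        p = np.random.default_rng(seed).uniform(1e-4, 0.3, (2, 7, 2, 3))
        q1, q3, q7 = (compose_mortality(p, u) for u in (1, 3, 7))
        assert np.all(q1 <= q3 + 1e-15) and np.all(q3 <= q7 + 1e-15)


class TestEstimateDeaths:
    def test_cohort_mode_arithmetic(self):
        grid, admin, pop = _two_country_world()
        pop.live_births[:] = 1000.0
        q = np.full((2, grid.n_years, grid.n_cells), 0.1)
        deaths = estimate_deaths(pop, q=q, mode="cohort")
        assert np.allclose(deaths, 100.0)

    def test_period_rate_closed_form(self):
        grid, admin, pop = _two_country_world()
        pop.under5[:] = 60_000.0   # 10,000 per 1-year-equivalent of bin width
        p = np.full((1, 7, grid.n_years, grid.n_cells), 1e-9)
        p[0, 3] = 0.01             # bin 4 spans 12 months
        deaths = estimate_deaths(pop, p_bins=p, mode="period_rate",
                                 age_scheme=AgeBinScheme.default())
        # bin-4 population share = 12/60 of under-5 = 12,000; m = -ln(0.99)
        expected = 12_000.0 * (-np.log(0.99))
        assert deaths[0, 3, 0, 0] == pytest.approx(expected, rel=1e-9)

    def test_zero_probability_gives_zero_deaths(self):
        grid, admin, pop = _two_country_world()
        q = np.zeros((1, grid.n_years, grid.n_cells))
        assert not estimate_deaths(pop, q=q, mode="cohort").any()

    def test_unknown_mode_raises(self):
        grid, admin, pop = _two_country_world()
        with pytest.raises(ValueError):
            estimate_deaths(pop, q=np.zeros((1, 2, 8)), mode="cohorts")


class TestRaking:
    def _setup(self, q_value=0.08):
        grid, admin, pop = _two_country_world()
        rng = np.random.default_rng(2)
        q = {"q_u5": rng.uniform(0.05, 0.12, (50, grid.n_years, grid.n_cells))}
        return grid, admin, pop, q

    def test_constant_ratio_raking(self):
        grid, admin, pop, _ = self._setup()
        q = {"q_u5": np.full((10, grid.n_years, grid.n_cells), 0.08)}
        ref = pd.DataFrame(
            [(c, y, "q_u5", 0.10) for c in admin.unit_ids(0) for y in grid.years],
            columns=["country_id", "year", "measure", "value"])
        res = rake_to_reference(q, ref, pop, admin)
        assert np.allclose(res.raked["q_u5"], 0.10)
        assert np.allclose(res.factors["mean_factor"], 1.25)

    def test_reference_equal_to_aggregate_is_identity(self):
        # a single-draw cube whose own national aggregates are the reference
        grid, admin, pop, q = self._setup()
        births = pop.live_births
        q1 = {"q_u5": q["q_u5"][:1]}
        rows = []
        for ci, cid in enumerate(admin.unit_ids(0)):
            cells = np.flatnonzero(admin.country_of_cell == ci)
            for ti, y in enumerate(grid.years):
                w = births[ti, cells] / births[ti, cells].sum()
                rows.append((cid, y, "q_u5", float(q1["q_u5"][0, ti, cells] @ w)))
        ref = pd.DataFrame(rows, columns=["country_id", "year", "measure", "value"])
        res = rake_to_reference(q1, ref, pop, admin)
        assert np.allclose(res.raked["q_u5"], q1["q_u5"], rtol=1e-12)
        assert res.n_clipped == 0

    def test_each_country_hits_its_own_reference(self):
        grid, admin, pop, q = self._setup()
        targets = {"C00": 0.06, "C01": 0.11}
        ref = pd.DataFrame(
            [(c, y, "q_u5", targets[c]) for c in admin.unit_ids(0)
             for y in grid.years],
            columns=["country_id", "year", "measure", "value"])
        res = rake_to_reference(q, ref, pop, admin)
        births = pop.live_births
        for ci, cid in enumerate(admin.unit_ids(0)):
            cells = np.flatnonzero(admin.country_of_cell == ci)
            for ti in range(grid.n_years):
                w = births[ti, cells] / births[ti, cells].sum()
                agg = res.raked["q_u5"][:, ti, cells] @ w
                assert np.allclose(agg, targets[cid], rtol=1e-9)


class TestAggregation:
    def test_single_cell_unit_equals_cell_value(self):
        grid, admin, pop = _two_country_world()
        values = np.arange(2 * grid.n_years * grid.n_cells, dtype=float) \
            .reshape(2, grid.n_years, grid.n_cells)
        agg = aggregate_to_admin(values, admin, 2, kind="rate",
                                 weights=pop.live_births)
        for ui, unit in enumerate(admin.units_at(2)):
            assert unit.cells.size == 1
            assert np.allclose(agg.draws[:, ui, :], values[:, :, unit.cells[0]])

    def test_weighted_mean_example(self):
        grid = GridDefinition(0.0, 0.0, 10.0, 1, 2, (2000,))
        admin = nested_rectangles(grid, (1, 1), (1, 1), (1, 1))
        pop = PopulationSurface(grid, np.array([[100.0, 300.0]]),
                                np.array([[480.0, 1440.0]]))
        values = np.array([[[0.1, 0.2]]])
        agg = aggregate_to_admin(values, admin, 2, kind="rate",
                                 weights=pop.live_births)
        assert agg.draws[0, 0, 0] == pytest.approx(0.175)

    def test_death_counts_sum_exactly_across_levels(self):
        grid, admin, pop = _two_country_world()
        rng = np.random.default_rng(3)
        deaths = rng.uniform(0, 50, (20, grid.n_years, grid.n_cells))
        totals = {}
        for level in (0, 1, 2):
            agg = aggregate_to_admin(deaths, admin, level, kind="count")
            totals[level] = agg.draws.sum(axis=1)
        assert np.allclose(totals[2], totals[1], rtol=1e-12)
        assert np.allclose(totals[1], totals[0], rtol=1e-12)
        assert np.allclose(totals[0], deaths.sum(axis=2), rtol=1e-12)

    def test_summary_orders_bounds(self):
        grid, admin, pop = _two_country_world()
        values = np.random.default_rng(4).uniform(0.01, 0.2,
                                                  (200, grid.n_years, grid.n_cells))
        agg = aggregate_to_admin(values, admin, 1, kind="rate",
                                 weights=pop.live_births)
        s = agg.summary_frame()
        assert (s["lower"] <= s["mean"]).all() and (s["mean"] <= s["upper"]).all()


class TestExceedance:
    def _agg(self, draws):
        return AdminAggregate(["u0"], 2, (2000,), draws, "q_u5", "rate")

    def test_all_draws_below_threshold(self):
        agg = self._agg(np.full((200, 1, 1), 0.010))
        assert exceedance_probability(agg, 25.0)[0, 0] == 1.0

    def test_exact_fraction_at_ninety_percent(self):
        draws = np.full((1000, 1, 1), 0.030)
        draws[:900, 0, 0] = 0.020    # 900 of 1,000 draws at/below 25 per 1,000
        assert exceedance_probability(self._agg(draws), 25.0)[0, 0] == 0.9

    def test_neonatal_threshold_twelve(self):
        draws = np.full((500, 1, 1), 0.0119)
        assert exceedance_probability(self._agg(draws), 12.0)[0, 0] == 1.0
        assert exceedance_probability(self._agg(draws), 12.0, "exceed")[0, 0] == 0.0

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            exceedance_probability(self._agg(np.full((50, 1, 1), 0.01)), 25.0)


class TestNeonatalFraction:
    def test_ratio_arithmetic(self):
        nn = np.full((10, 2, 1), 40.0)
        u5 = np.full((10, 2, 1), 100.0)
        assert np.allclose(neonatal_fraction(nn, u5), 0.4)

    def test_all_neonatal_gives_one(self):
        nn = u5 = np.full((5, 1, 1), 7.0)
        assert np.allclose(neonatal_fraction(nn, u5), 1.0)

    def test_zero_denominator_excluded_as_nan(self):
        nn = np.ones((4, 1, 1))
        u5 = np.ones((4, 1, 1))
        u5[2] = 0.0
        out = neonatal_fraction(nn, u5)
        assert np.isnan(out[2, 0, 0]) and np.isfinite(out[[0, 1, 3]]).all()


class TestInequality:
    def test_identical_units_give_zero_range_unit_ratios(self):
        grid, admin, pop = _two_country_world()
        values = np.full((100, grid.n_years, grid.n_cells), 0.05)
        agg = aggregate_to_admin(values, admin, 2, kind="rate",
                                 weights=pop.live_births)
        country_df, unit_df = inequality_metrics(
            agg, admin, pop, year_pair=(grid.years[0], grid.years[-1]))
        assert np.allclose(country_df["absolute_range_per1000"], 0.0)
        assert np.allclose(unit_df["ratio_to_country_mean"], 1.0)
        assert not unit_df["significant"].any()

    def test_ratio_of_double_rate_unit(self):
        grid = GridDefinition(0.0, 0.0, 10.0, 1, 2, (2000,))
        admin = nested_rectangles(grid, (1, 1), (1, 1), (2, 1))
        pop = PopulationSurface(grid, np.array([[100.0, 100.0]]),
                                np.array([[1.0, 1.0]]))
        values = np.zeros((100, 1, 2))
        values[:, 0, 0] = 0.050
        values[:, 0, 1] = 0.025 * 2 / 3  # country mean -> 0.0333
        agg = aggregate_to_admin(values, admin, 2, kind="rate",
                                 weights=pop.live_births)
        _, unit_df = inequality_metrics(agg, admin, pop)
        r = unit_df.set_index("unit_id")["ratio_to_country_mean"]
        assert r.iloc[0] == pytest.approx(0.05 / ((0.05 + 0.025 * 2 / 3) / 2))

    def test_disjoint_intervals_flag_significant_decrease(self):
        grid = GridDefinition(0.0, 0.0, 10.0, 1, 1, (2000, 2001))
        admin = nested_rectangles(grid, (1, 1), (1, 1), (1, 1))
        pop = PopulationSurface(grid, np.full((2, 1), 10.0), np.full((2, 1), 48.0))
        rng = np.random.default_rng(5)
        values = np.zeros((500, 2, 1))                     # (draws, years, cells)
        values[:, 0, 0] = rng.uniform(0.030, 0.040, 500)   # first year
        values[:, 1, 0] = rng.uniform(0.010, 0.020, 500)   # last year
        agg = aggregate_to_admin(values, admin, 2, kind="rate",
                                 weights=pop.live_births)
        _, unit_df = inequality_metrics(agg, admin, pop, year_pair=(2000, 2001))
        assert unit_df["significant"].all()
        assert (unit_df["direction"] == "decrease").all()


class TestCounterfactuals:
    def _world(self):
        grid = GridDefinition(0.0, 0.0, 10.0, 1, 2, (2000,))
        admin = nested_rectangles(grid, (1, 1), (1, 1), (2, 1))
        pop = PopulationSurface(grid, np.array([[1000.0, 1000.0]]),
                                np.array([[1.0, 1.0]]))
        return grid, admin, pop

    def _agg(self, draws, admin):
        return AdminAggregate([u.unit_id for u in admin.units_at(2)], 2,
                              (2000,), draws, "q_u5", "rate")

    def test_best_unit_two_unit_arithmetic(self):
        grid, admin, pop = self._world()
        draws = np.zeros((200, 2, 1))
        draws[:, 0, 0] = 0.10
        draws[:, 1, 0] = 0.05
        out = counterfactual_deaths_averted(self._agg(draws, admin), admin,
                                            pop, "best_unit")
        assert out.loc[0, "mean"] == pytest.approx(50.0)

    def test_uniform_rates_avert_nothing(self):
        grid, admin, pop = self._world()
        draws = np.full((200, 2, 1), 0.07)
        out = counterfactual_deaths_averted(self._agg(draws, admin), admin,
                                            pop, "best_unit")
        assert out.loc[0, "mean"] == pytest.approx(0.0, abs=1e-12)

    def test_threshold_with_everyone_below_averts_nothing(self):
        grid, admin, pop = self._world()
        draws = np.full((200, 2, 1), 0.020)
        out = counterfactual_deaths_averted(self._agg(draws, admin), admin,
                                            pop, "threshold",
                                            threshold_per_1000=25.0)
        assert out.loc[0, "mean"] == pytest.approx(0.0, abs=1e-12)

    def test_rates_of_year_is_signed_difference(self):
        grid = GridDefinition(0.0, 0.0, 10.0, 1, 1, (2000, 2001))
        admin = nested_rectangles(grid, (1, 1), (1, 1), (1, 1))
        pop = PopulationSurface(grid, np.full((2, 1), 100.0), np.full((2, 1), 1.0))
        draws = np.zeros((200, 1, 2))
        draws[:, 0, 0] = 0.08
        draws[:, 0, 1] = 0.05   # mortality fell below the 2000 reference
        agg = AdminAggregate(["u"], 2, (2000, 2001), draws, "q_u5", "rate")
        averted = counterfactual_averted_draws(agg, admin, pop, "rates_of_year",
                                               reference_year=2000)
        assert np.allclose(averted[:, 1], (0.05 - 0.08) * 100.0)
        assert np.allclose(averted[:, 0], 0.0)

    def test_unknown_scenario_raises(self):
        grid, admin, pop = self._world()
        with pytest.raises(ValueError, match="scenario"):
            counterfactual_deaths_averted(
                self._agg(np.full((10, 2, 1), 0.05), admin), admin, pop, "magic")

    @given(st.integers(0, 5000))
    @settings(max_examples=25, deadline=None)
    def test_min_clamp_scenarios_never_negative(self, seed):
        grid, admin, pop = self._world()
        draws = np.random.default_rng(seed).uniform(0.001, 0.3, (50, 2, 1))
        agg = self._agg(draws, admin)
        for scenario, kwargs in (("best_unit", {}),
                                 ("threshold", {"threshold_per_1000": 25.0})):
            averted = counterfactual_averted_draws(agg, admin, pop, scenario,
                                                   **kwargs)
            assert np.all(averted >= -1e-12)
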