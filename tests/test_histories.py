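"""Birth-history tabulation, SBH down-weighting and QC screening."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mortmap.histories import (
    OBS_COLUMNS,
    apply_sbh_adjustment,
    qc_filter,
    read_observations,
    tabulate_cbh,
    write_observations,
)
from mortmap.synthetic import AgeBinScheme

DATA = Path(__file__).parent / "data"
AGE = AgeBinScheme.default()
YEARS = tuple(range(1998, 2008))

CLUSTERS = pd.DataFrame({
    "survey_id": ["S01"], "cluster_id": ["S01_c01"], "country_id": ["C00"],
    "x": [5.0], "y": [5.0], "polygon_id": [""],
})


def _children(rows):
    return pd.DataFrame(rows, columns=["survey_id", "cluster_id", "birth_date",
                                       "interview_date", "outcome",
                                       "age_at_death_months"])


class TestTabulateCBH:
    def test_three_child_fixture_matches_hand_tabulation(self):
        children = pd.read_csv(DATA / "cbh_three_children.csv")
        clusters = pd.read_csv(DATA / "cbh_three_children_clusters.csv",
                               dtype={"polygon_id": str}).fillna({"polygon_id": ""})
        expected = pd.read_csv(DATA / "cbh_three_children_expected.csv")
        obs = tabulate_cbh(children, clusters, AGE, YEARS)
        got = obs[["year", "age_bin", "entrants", "deaths"]].reset_index(drop=True)
        pd.testing.assert_frame_equal(
            got.astype(float), expected.astype(float), check_dtype=False)

    def test_neonatal_death_censors_later_bins(self):
        children = _children([("S01", "S01_c01", 2003.0, 2005.5, "died", 0.2)])
        obs = tabulate_cbh(children, CLUSTERS, AGE, YEARS)
        assert len(obs) == 1
        row = obs.iloc[0]
        assert (row.age_bin, row.year, row.entrants, row.deaths) == (1, 2003, 1.0, 1.0)

    def test_six_month_old_contributes_two_complete_bins(self):
        # alive at interview at exactly 6.0 months: bins 1 and 2 fully
        # observed, bin 3 incompletely observed and therefore excluded
        children = _children(
            [("S01", "S01_c01", 2004.5, 2005.0, "alive_at_interview", np.nan)])
        obs = tabulate_cbh(children, CLUSTERS, AGE, YEARS)
        assert list(obs["age_bin"]) == [1, 2]
        assert (obs["year"] == 2004).all()
        assert (obs["deaths"] == 0).all()

    @pytest.mark.parametrize("age_months,expected_bins", [
        (30.0, [1, 2, 3, 4]),   # alive at 30 months: bins 1..4 complete
        (60.0, [1, 2, 3, 4, 5, 6, 7]),
    ])
    def test_entries_are_monotone_in_age(self, age_months, expected_bins):
        children = _children([("S01", "S01_c01", 2001.0, 2001.0 + age_months / 12.0,
                               "alive_at_interview", np.nan)])
        obs = tabulate_cbh(children, CLUSTERS, AGE, YEARS)
        assert list(obs["age_bin"]) == expected_bins

    def test_death_conservation(self):
        rng = np.random.default_rng(8)
        n = 400
        birth = rng.uniform(1999.0, 2003.0, n)
        died = rng.random(n) < 0.4
        age = np.where(died, rng.uniform(0, 70, n), np.nan)
        children = pd.DataFrame({
            "survey_id": "S01", "cluster_id": "S01_c01",
            "birth_date": birth, "interview_date": 2009.5,
            "outcome": np.where(died & (age < 70), "died", "alive_at_interview"),
            "age_at_death_months": age,
        })
        children.loc[children["outcome"] != "died", "age_at_death_months"] = np.nan
        obs = tabulate_cbh(children, CLUSTERS, AGE, tuple(range(1998, 2010)),
                           max_recall_years=None)
        in_scope = (children["outcome"] == "died") & \
            (children["age_at_death_months"] < 60)
        assert obs["deaths"].sum() == in_scope.sum()

    def test_death_at_or_beyond_sixty_months_skipped_with_warning(self, caplog):
        children = _children([
            ("S01", "S01_c01", 2000.0, 2006.0, "died", 61.0),
            ("S01", "S01_c01", 2000.0, 2006.0, "alive_at_interview", np.nan),
        ])
        with caplog.at_level("WARNING"):
            obs = tabulate_cbh(children, CLUSTERS, AGE, YEARS)
        assert "60 months" in caplog.text
        assert obs["deaths"].sum() == 0

    def test_birth_after_interview_raises(self):
        children = _children(
            [("S01", "S01_c01", 2006.0, 2005.0, "alive_at_interview", np.nan)])
        with pytest.raises(ValueError, match="precede"):
            tabulate_cbh(children, CLUSTERS, AGE, YEARS)

    def test_recall_limit_drops_old_periods(self):
        children = _children(
            [("S01", "S01_c01", 2000.0, 2005.0, "alive_at_interview", np.nan)])
        full = tabulate_cbh(children, CLUSTERS, AGE, YEARS, max_recall_years=None)
        trimmed = tabulate_cbh(children, CLUSTERS, AGE, YEARS, max_recall_years=3)
        assert trimmed["year"].min() >= 2002
        assert len(trimmed) < len(full)

    def test_empty_input_gives_empty_table(self):
        obs = tabulate_cbh(_children([]), CLUSTERS, AGE, YEARS)
        assert obs.empty and list(obs.columns) == OBS_COLUMNS


class TestSBHAdjustment:
    def _obs(self, n, y, source):
        return pd.DataFrame({
            "obs_id": [0], "survey_id": ["S"], "country_id": ["C00"],
            "cluster_id": ["c"], "x": [1.0], "y": [1.0], "polygon_id": [""],
            "year": [2000], "age_bin": [1], "entrants": [n], "deaths": [y],
            "weight": [1.0], "source_type": [source],
        })

    def test_halving_rule(self):
        out = apply_sbh_adjustment(self._obs(10.0, 2.0, "sbh"), 0.5)
        assert out.loc[0, "entrants"] == 5.0 and out.loc[0, "deaths"] == 1.0

    def test_factor_one_is_identity(self):
        obs = self._obs(10.0, 2.0, "sbh")
        pd.testing.assert_frame_equal(apply_sbh_adjustment(obs, 1.0), obs)

    def test_cbh_rows_untouched(self):
        obs = self._obs(10.0, 2.0, "cbh")
        pd.testing.assert_frame_equal(apply_sbh_adjustment(obs, 0.5), obs)

    @pytest.mark.parametrize("factor", [0.0, -0.1, 1.5])
    def test_invalid_factor_raises(self, factor):
        with pytest.raises(ValueError):
            apply_sbh_adjustment(self._obs(10.0, 2.0, "sbh"), factor)

    @given(n=st.floats(1.0, 1e4), ratio=st.floats(0.0, 1.0),
           factor=st.floats(0.01, 1.0))
    @settings(max_examples=40, deadline=None)
    def test_ratio_preserved(self, n, ratio, factor):
        y = n * ratio
        out = apply_sbh_adjustment(self._obs(n, y, "sbh"), factor)
        assert out.loc[0, "deaths"] / out.loc[0, "entrants"] \
            == pytest.approx(ratio, abs=1e-12)


class TestQCFilter:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=OBS_COLUMNS)

    def test_reasons_reported(self):
        rows = [
            [0, "S1", "C00", "c", 1.0, 1.0, "", 2000, 1, 2.0, 3.0, 1.0, "cbh"],
            [1, "S1", "C00", "c", 1.0, 1.0, "", 2000, 1, 0.0, 0.0, 1.0, "cbh"],
            [2, "S1", "C00", "c", 1.0, 1.0, "", 1990, 1, 5.0, 1.0, 1.0, "cbh"],
            [3, "S1", "C00", "c", np.nan, np.nan, "", 2000, 1, 5.0, 1.0, 1.0, "cbh"],
            [4, "S1", "C00", "c", 1.0, 1.0, "", 2000, 2, 5.0, 1.0, 1.0, "cbh"],
        ]
        kept, report = qc_filter(self._table(rows), YEARS)
        assert list(kept["obs_id"]) == [4]
        assert set(report["reason"]) == {
            "deaths_exceed_entrants", "nonpositive_entrants",
            "year_out_of_window", "missing_location",
        }

    def test_clean_input_unchanged(self):
        rows = [[0, "S1", "C00", "c", 1.0, 1.0, "", 2000, 1, 5.0, 1.0, 1.0, "cbh"]]
        obs = self._table(rows)
        kept, report = qc_filter(obs, YEARS)
        pd.testing.assert_frame_equal(kept, obs)
        assert report.empty

    def test_empty_input(self):
        kept, report = qc_filter(self._table([]), YEARS)
        assert kept.empty and report.empty

    def test_polygon_reference_counts_as_location(self):
        rows = [[0, "S1", "C00", "c", np.nan, np.nan, "P1", 2000, 1, 5.0, 1.0,
                 1.0, "cbh"]]
        kept, _ = qc_filter(self._table(rows), YEARS)
        assert len(kept) == 1


def test_observation_csv_round_trip(tmp_path, tiny_obs):
    path = tmp_path / "obs.csv"
    write_observations(path, tiny_obs)
    back = read_observations(path)
    pd.testing.assert_frame_equal(
        back.reset_index(drop=True), tiny_obs.reset_index(drop=True),
        check_dtype=False)
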