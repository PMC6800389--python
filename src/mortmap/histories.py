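"""Tabulation of complete birth histories into cluster x period x age-bin counts.

The model's analytical unit is a (survey, cluster, year, age bin) row with a
number of entrants ``n`` and deaths ``Y``.  Tabulation slices each child's
retrospective exposure into period-age cells (the synthetic cohort method):

* a child contributes one entrant to every age bin it enters before the
  interview, assigned to the calendar year containing the midpoint of the
  bin's interval on the child's own calendar axis;
* a death contributes ``Y = 1`` to the bin containing the age at death and
  censors all later bins;
* a bin whose full width is not observed before the interview contributes
  nothing unless the child died in it (conservative right-censoring: ``n``
  stays interpretable as binomial trials).

Summary-birth-history (SBH) sources arrive as bin-level rows already and are
only down-weighted here: their effective sample size is multiplied by a
factor (0.5 by default, i.e. the halved effective sample size rule), which
preserves every empirical ratio Y/n.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .synthetic import AgeBinScheme

logger = logging.getLogger(__name__)

OBS_COLUMNS = [
    "obs_id", "survey_id", "country_id", "cluster_id", "x", "y", "polygon_id",
    "year", "age_bin", "entrants", "deaths", "weight", "source_type",
]

_EPS = 1e-9  # float tolerance for "interview exactly at bin completion"


def _empty_observations() -> pd.DataFrame:
    return pd.DataFrame(columns=OBS_COLUMNS)


def tabulate_cbh(
    children: pd.DataFrame,
    clusters: pd.DataFrame,
    age_scheme: AgeBinScheme,
    years,
    max_recall_years: int | None = 17,
) -> pd.DataFrame:
    """Tabulate child records into ClusterObservation rows.

    ``years`` is the study window; bin contributions whose period falls
    outside it, or further than ``max_recall_years`` before the interview,
    are dropped (with a logged count).  Records of deaths at >= 60 months are
    skipped with a warning; malformed dates raise.
    """
    years = [int(y) for y in years]
    if not children.empty:
        birth = children["birth_date"].to_numpy(dtype=float)
        interview = children["interview_date"].to_numpy(dtype=float)
        if not (np.all(np.isfinite(birth)) and np.all(np.isfinite(interview))):
            raise ValueError("malformed birth or interview dates (non-finite)")
        if np.any(birth >= interview):
            raise ValueError("every birth date must precede the interview date")
    else:
        return _empty_observations()

    died = children["outcome"].to_numpy() == "died"
    age_death = children["age_at_death_months"].to_numpy(dtype=float)
    if np.any(died & ~np.isfinite(age_death)):
        raise ValueError("died records must carry age_at_death_months")
    out_of_scope = died & (age_death >= 60.0)
    if out_of_scope.any():
        logger.warning(
            "skipping %d record(s) with death age >= 60 months", int(out_of_scope.sum())
        )
    keep = ~out_of_scope
    birth, interview = birth[keep], interview[keep]
    died, age_death = died[keep], age_death[keep]
    survey = children["survey_id"].to_numpy()[keep]
    cluster = children["cluster_id"].to_numpy()[keep]

    lo, hi = age_scheme.lower_months, age_scheme.upper_months
    mid_years = (lo + hi) / 24.0

    frames = []
    n_dropped_window = 0
    for a in range(len(age_scheme.bins)):
        alive_at_start = ~(died & (age_death < lo[a]))
        death_in_bin = died & (age_death >= lo[a]) & (age_death < hi[a])
        fully_observed = interview + _EPS >= birth + hi[a] / 12.0
        enters = alive_at_start & (fully_observed | death_in_bin)
        if not enters.any():
            continue
        yr = np.floor(birth[enters] + mid_years[a]).astype(int)
        in_window = np.isin(yr, years)
        if max_recall_years is not None:
            in_window &= (np.floor(interview[enters]).astype(int) - yr) <= max_recall_years
        n_dropped_window += int((~in_window).sum())
        if not in_window.any():
            continue
        sel = np.flatnonzero(enters)[in_window]
        frames.append(pd.DataFrame({
            "survey_id": survey[sel],
            "cluster_id": cluster[sel],
            "year": yr[in_window],
            "age_bin": a + 1,
            "death": death_in_bin[sel].astype(float),
        }))
    if n_dropped_window:
        logger.info(
            "dropped %d bin contribution(s) outside the study window or recall limit",
            n_dropped_window,
        )
    if not frames:
        return _empty_observations()
    long = pd.concat(frames, ignore_index=True)
    obs = (
        long.groupby(["survey_id", "cluster_id", "year", "age_bin"], as_index=False)
        .agg(entrants=("death", "size"), deaths=("death", "sum"))
    )
    obs["entrants"] = obs["entrants"].astype(float)
    obs = obs.merge(
        clusters[["survey_id", "cluster_id", "country_id", "x", "y", "polygon_id"]],
        on=["survey_id", "cluster_id"], how="left", validate="many_to_one",
    )
    if obs["country_id"].isna().any():
        raise ValueError("child records reference clusters missing from the cluster table")
    obs["weight"] = 1.0
    obs["source_type"] = "cbh"
    obs = obs.sort_values(["survey_id", "cluster_id", "year", "age_bin"], kind="stable")
    obs = obs.reset_index(drop=True)
    obs["obs_id"] = np.arange(len(obs))
    return obs[OBS_COLUMNS]


def apply_sbh_adjustment(obs: pd.DataFrame, factor: float = 0.5) -> pd.DataFrame:
    """Scale the effective sample size of SBH-flagged rows by ``factor``.

    Both ``entrants`` and ``deaths`` are multiplied, so every empirical ratio
    Y/n is preserved exactly.  CBH rows are untouched.
    """
    if not 0.0 < factor <= 1.0:
        raise ValueError(f"SBH adjustment factor must lie in (0, 1], got {factor}")
    out = obs.copy()
    mask = out["source_type"] == "sbh"
    out.loc[mask, "entrants"] = out.loc[mask, "entrants"] * factor
    out.loc[mask, "deaths"] = out.loc[mask, "deaths"] * factor
    return out


def qc_filter(obs: pd.DataFrame, years=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sanity screening of observation rows; never raises on content.

    Drops rows with deaths > entrants, non-positive entrants, a period outside
    the study window, or neither coordinates nor a polygon reference.  Returns
    the kept rows and a per-survey, per-reason report of dropped counts.
    """
    if obs.empty:
        return obs.copy(), pd.DataFrame(columns=["survey_id", "reason", "n_dropped"])
    reasons = pd.Series("", index=obs.index, dtype=object)
    bad_deaths = obs["deaths"] > obs["entrants"]
    bad_n = obs["entrants"] <= 0
    if years is not None:
        years = [int(y) for y in years]
        bad_year = ~obs["year"].isin(years)
    else:
        bad_year = pd.Series(False, index=obs.index)
    has_xy = obs["x"].notna() & obs["y"].notna()
    has_poly = obs["polygon_id"].notna() & (obs["polygon_id"].astype(str) != "")
    bad_loc = ~(has_xy | has_poly)
    # first matching reason wins, in severity order
    reasons[bad_loc] = "missing_location"
    reasons[bad_year] = "year_out_of_window"
    reasons[bad_n] = "nonpositive_entrants"
    reasons[bad_deaths] = "deaths_exceed_entrants"
    dropped = reasons != ""
    report = (
        pd.DataFrame({"survey_id": obs.loc[dropped, "survey_id"],
                      "reason": reasons[dropped]})
        .groupby(["survey_id", "reason"], as_index=False)
        .size()
        .rename(columns={"size": "n_dropped"})
    )
    kept = obs.loc[~dropped].reset_index(drop=True)
    if dropped.any():
        logger.info("qc_filter dropped %d of %d rows", int(dropped.sum()), len(obs))
    return kept, report


# ---------------------------------------------------------------------------
# CSV round trips
# ---------------------------------------------------------------------------

def write_observations(path, obs: pd.DataFrame) -> None:
    obs.to_csv(path, index=False)


def read_observations(path) -> pd.DataFrame:
    obs = pd.read_csv(path, dtype={"polygon_id": str}, keep_default_na=True)
    obs["polygon_id"] = obs["polygon_id"].fillna("")
    missing = [c for c in OBS_COLUMNS if c not in obs.columns]
    if missing:
        raise ValueError(f"observation table missing columns: {missing}")
    return obs[OBS_COLUMNS]


def write_children(path, children: pd.DataFrame) -> None:
    children.to_csv(path, index=False)


def read_children(path) -> pd.DataFrame:
    return pd.read_csv(path)
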