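"""From per-draw bin-probability surfaces to reported mortality measures.

All operations act across posterior draws so that model uncertainty
propagates into every derived quantity: composed neonatal / infant / under-5
probabilities, death counts, raking (multiplicative calibration) to a
national reference envelope, population-weighted admin aggregation with 95%
uncertainty intervals, exceedance probabilities against per-1,000 thresholds,
the neonatal share of under-5 deaths, within-country inequality metrics, and
counterfactual deaths-averted scenarios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import N_AGE_BINS
from .synthetic import AdminTessellation, AgeBinScheme, GridDefinition, PopulationSurface

logger = logging.getLogger(__name__)

#: composition depth for the three headline measures
MEASURE_BINS = {"q_nn": 1, "q_inf": 3, "q_u5": 7}


# ---------------------------------------------------------------------------
# draw cube and composition
# ---------------------------------------------------------------------------

def compose_mortality(p_bins: np.ndarray, upto_bin: int) -> np.ndarray:
    """Cumulative mortality 1 - prod_{a<=upto}(1 - P_a) along the bin axis.

    ``p_bins`` has the bin axis second: (D, 7, ...).  ``upto_bin`` is 1
    (neonatal), 3 (infant) or 7 (under-5).
    """
    if upto_bin not in (1, 3, 7):
        raise ValueError(f"upto_bin must be 1, 3 or 7, got {upto_bin}")
    p = np.asarray(p_bins, dtype=float)
    if p.shape[1] != N_AGE_BINS:
        raise ValueError(f"expected {N_AGE_BINS} bins on axis 1, got {p.shape[1]}")
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("bin probabilities must lie strictly in (0, 1)")
    if upto_bin == 1:
        return p[:, 0].copy()   # single factor: exactly the bin-1 probability
    return 1.0 - np.prod(1.0 - p[:, :upto_bin], axis=1)


@dataclass
class MortalityDrawCube:
    """Per-draw gridded conditional bin probabilities P[d, a, t, s]."""

    p_bins: np.ndarray  # (D, 7, T, S)
    grid: GridDefinition
    age_scheme: AgeBinScheme

    def __post_init__(self):
        p = np.asarray(self.p_bins, dtype=float)
        if p.ndim != 4 or p.shape[1] != N_AGE_BINS:
            raise ValueError(f"p_bins must have shape (D, 7, T, S), got {p.shape}")
        if p.shape[2] != self.grid.n_years or p.shape[3] != self.grid.n_cells:
            raise ValueError("p_bins does not match the grid support")
        if np.any(p <= 0) or np.any(p >= 1):
            raise ValueError("probabilities must lie strictly in (0, 1)")
        self.p_bins = p

    @property
    def n_draws(self) -> int:
        return self.p_bins.shape[0]

    def q(self, measure: str) -> np.ndarray:
        """Composed probability cube (D, T, S) for q_nn / q_inf / q_u5."""
        return compose_mortality(self.p_bins, MEASURE_BINS[measure])

    def measures(self) -> dict[str, np.ndarray]:
        return {m: self.q(m) for m in MEASURE_BINS}


# ---------------------------------------------------------------------------
# death counts
# ---------------------------------------------------------------------------

def estimate_deaths(
    population: PopulationSurface,
    q: np.ndarray | None = None,
    p_bins: np.ndarray | None = None,
    mode: str = "cohort",
    age_scheme: AgeBinScheme | None = None,
) -> np.ndarray:
    """Death counts per draw/year/cell.

    cohort mode: ``deaths = live_births * q`` for a composed probability cube
    ``q`` of shape (D, T, S) — the deaths a birth cohort will experience.

    period_rate mode: per-bin counts from the resident under-5 population:
    ``deaths_a = pop_a * m_a`` with the mortality rate ``m_a = -ln(1 - P_a)/width_a``
    (widths in years) and ``pop_a`` the under-5 population apportioned to the
    bin by its width; returns shape (D, 7, T, S).
    """
    if mode == "cohort":
        if q is None:
            raise ValueError("cohort mode needs the composed probability cube q")
        return population.live_births[None, :, :] * np.asarray(q, dtype=float)
    if mode == "period_rate":
        if p_bins is None or age_scheme is None:
            raise ValueError("period_rate mode needs p_bins and the age scheme")
        widths = age_scheme.width_years  # (7,)
        m = -np.log1p(-np.asarray(p_bins, dtype=float)) / widths[None, :, None, None]
        pop_a = population.under5[None, None, :, :] * (widths / widths.sum())[None, :, None, None]
        return pop_a * m
    raise ValueError(f"unknown death-count mode {mode!r}")


# ---------------------------------------------------------------------------
# raking to a national reference envelope
# ---------------------------------------------------------------------------

@dataclass
class RakingResult:
    raked: dict[str, np.ndarray]   # measure -> (D, T, S)
    factors: pd.DataFrame          # country, year, measure, draw-mean factor
    n_clipped: int


def rake_to_reference(
    q_measures: dict[str, np.ndarray],
    reference: pd.DataFrame,
    population: PopulationSurface,
    admin: AdminTessellation,
    clip_at: float = 0.999,
) -> RakingResult:
    """Multiplicatively calibrate gridded draws to national reference values.

    ``reference`` has columns (country_id, year, measure, value) giving one
    target per country-year-measure.  Per draw, the birth-weighted national
    aggregate of the draw is computed; every cell of that country-year is
    multiplied by ``reference / aggregate`` and clipped at ``clip_at`` (clip
    events are counted and logged).  Without clipping the recomputed national
    aggregate equals the reference exactly.
    """
    grid = admin.grid
    country_of_cell = admin.country_of_cell
    country_ids = admin.unit_ids(0)
    births = population.live_births  # (T, S)
    raked = {m: np.array(v, dtype=float, copy=True) for m, v in q_measures.items()}
    n_clipped = 0
    factor_rows = []
    ref = reference.set_index(["country_id", "year", "measure"])["value"]

    for m, cube in raked.items():
        for ci, cid in enumerate(country_ids):
            cells = np.flatnonzero(country_of_cell == ci)
            w = births[:, cells]                       # (T, |cells|)
            wsum = w.sum(axis=1)                       # (T,)
            for t, year in enumerate(grid.years):
                try:
                    target = float(ref.loc[(cid, year, m)])
                except KeyError:
                    continue
                if wsum[t] <= 0:
                    raise ValueError(f"country {cid} has zero births in {year}")
                agg = cube[:, t, cells] @ (w[t] / wsum[t])   # (D,)
                if np.any(agg <= 0):
                    raise ValueError(
                        f"zero national aggregate for {cid}/{year}/{m} with a "
                        "non-zero reference"
                    )
                factor = target / agg                   # (D,)
                scaled = cube[:, t, cells] * factor[:, None]
                over = scaled > clip_at
                n_clipped += int(over.sum())
                cube[:, t, cells] = np.minimum(scaled, clip_at)
                factor_rows.append((cid, year, m, float(factor.mean())))
    if n_clipped:
        logger.warning("raking clipped %d cell-draw value(s) at %.3f", n_clipped, clip_at)
    factors = pd.DataFrame(factor_rows,
                           columns=["country_id", "year", "measure", "mean_factor"])
    return RakingResult(raked, factors, n_clipped)


# ---------------------------------------------------------------------------
# admin aggregation
# ---------------------------------------------------------------------------

@dataclass
class AdminAggregate:
    """Per-unit, per-year draws of one measure, with summaries on demand."""

    unit_ids: list[str]
    level: int
    years: tuple[int, ...]
    draws: np.ndarray        # (D, U, T); NaN where undefined
    measure: str
    kind: str                # "rate" or "count"

    def mean(self) -> np.ndarray:
        return np.nanmean(self.draws, axis=0)

    def interval(self, lo: float = 2.5, hi: float = 97.5):
        return (np.nanpercentile(self.draws, lo, axis=0),
                np.nanpercentile(self.draws, hi, axis=0))

    def summary_frame(self) -> pd.DataFrame:
        mean = self.mean()
        lower, upper = self.interval()
        rows = []
        for ui, uid in enumerate(self.unit_ids):
            for ti, year in enumerate(self.years):
                rows.append((uid, self.level, year, self.measure,
                             mean[ui, ti], lower[ui, ti], upper[ui, ti]))
        return pd.DataFrame(
            rows, columns=["unit_id", "level", "year", "measure",
                           "mean", "lower", "upper"],
        )


def aggregate_to_admin(
    values: np.ndarray,
    admin: AdminTessellation,
    level: int,
    kind: str = "rate",
    weights: np.ndarray | None = None,
    measure: str = "q_u5",
) -> AdminAggregate:
    """Aggregate a (D, T, S) cube to admin units at ``level``.

    Rates are population-weighted means over member cells per draw (weights
    default to live births and must be supplied); counts are sums.  A unit
    with zero weight in a year yields NaN draws there (flagged, excluded from
    summaries).
    """
    values = np.asarray(values, dtype=float)
    d, t, s = values.shape
    units = admin.units_at(level)
    out = np.zeros((d, len(units), t))
    for ui, unit in enumerate(units):
        cells = unit.cells
        if kind == "count":
            out[:, ui, :] = values[:, :, cells].sum(axis=2)
        elif kind == "rate":
            if weights is None:
                raise ValueError("rate aggregation needs population weights")
            w = np.asarray(weights, dtype=float)[:, cells]     # (T, |cells|)
            wsum = w.sum(axis=1)
            empty = wsum <= 0
            if empty.any():
                logger.warning(
                    "unit %s has zero population in %d year(s); estimates undefined",
                    unit.unit_id, int(empty.sum()),
                )
            with np.errstate(invalid="ignore", divide="ignore"):
                out[:, ui, :] = np.einsum(
                    "dts,ts->dt", values[:, :, cells], w / np.where(empty, np.nan, wsum)[:, None]
                )
        else:
            raise ValueError(f"kind must be 'rate' or 'count', got {kind!r}")
    return AdminAggregate([u.unit_id for u in units], level, admin.grid.years,
                          out, measure, kind)


# ---------------------------------------------------------------------------
# derived measures
# ---------------------------------------------------------------------------

def exceedance_probability(
    agg: AdminAggregate,
    threshold_per_1000: float,
    direction: str = "achieve",
) -> np.ndarray:
    """Posterior probability each unit-year is on the target side of a threshold.

    ``achieve``: fraction of draws with q*1000 <= threshold (e.g. 25 for the
    under-5 target, 12 for the neonatal target); a unit meets the target "with
    90% certainty" when this fraction is >= 0.9.  ``exceed`` counts the
    opposite side.
    """
    if agg.draws.shape[0] < 100:
        raise ValueError("exceedance probabilities need at least 100 draws")
    per1000 = agg.draws * 1000.0
    if direction == "achieve":
        hits = per1000 <= threshold_per_1000
    elif direction == "exceed":
        hits = per1000 > threshold_per_1000
    else:
        raise ValueError(f"direction must be 'achieve' or 'exceed', got {direction!r}")
    return np.mean(hits, axis=0)


def neonatal_fraction(
    deaths_nn: AdminAggregate | np.ndarray,
    deaths_u5: AdminAggregate | np.ndarray,
) -> np.ndarray:
    """Per-draw share of under-5 deaths occurring in the neonatal bin.

    Draws with zero under-5 deaths are undefined (NaN) and excluded from any
    downstream summaries, with a logged count.
    """
    nn = deaths_nn.draws if isinstance(deaths_nn, AdminAggregate) else np.asarray(deaths_nn)
    u5 = deaths_u5.draws if isinstance(deaths_u5, AdminAggregate) else np.asarray(deaths_u5)
    undefined = u5 <= 0
    if undefined.any():
        logger.warning("neonatal fraction undefined in %d draw cell(s)", int(undefined.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(undefined, np.nan, nn / np.where(undefined, np.nan, u5))


def inequality_metrics(
    agg: AdminAggregate,
    admin: AdminTessellation,
    population: PopulationSurface,
    year_pair: tuple[int, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-country inequality in unit-level mortality.

    Returns (country_frame, unit_frame).  Per country-year: the absolute range
    of unit mean q*1000 (max - min).  Per unit-year: the ratio of the unit
    mean to the birth-weighted country mean.  If ``year_pair = (y0, y1)`` is
    given, each unit gets a significant-change flag between the two years
    when the two 95% uncertainty intervals do not overlap.
    """
    units = admin.units_at(agg.level)
    if [u.unit_id for u in units] != agg.unit_ids:
        raise ValueError("aggregate does not match the admin tessellation")
    country_ids = admin.unit_ids(0)
    unit_country = np.array(
        [admin.cell_to_unit[0][u.cells[0]] for u in units]
    )
    mean = agg.mean()                    # (U, T)
    lower, upper = agg.interval()
    births = population.live_births
    unit_births = np.stack(
        [births[:, u.cells].sum(axis=1) for u in units], axis=0
    )                                    # (U, T)

    country_rows, unit_rows = [], []
    for ci, cid in enumerate(country_ids):
        members = np.flatnonzero(unit_country == ci)
        for ti, year in enumerate(agg.years):
            vals = mean[members, ti] * 1000.0
            ok = np.isfinite(vals)
            if not ok.any():
                continue
            country_mean = float(
                np.average(mean[members, ti][ok], weights=unit_births[members, ti][ok])
            ) * 1000.0
            country_rows.append((cid, year, float(vals[ok].max() - vals[ok].min()),
                                 country_mean))
            for ui in members:
                ratio = mean[ui, ti] * 1000.0 / country_mean if country_mean > 0 else np.nan
                unit_rows.append((agg.unit_ids[ui], cid, year,
                                  mean[ui, ti] * 1000.0, ratio))
    country_df = pd.DataFrame(
        country_rows, columns=["country_id", "year", "absolute_range_per1000",
                               "country_mean_per1000"],
    )
    unit_df = pd.DataFrame(
        unit_rows, columns=["unit_id", "country_id", "year",
                            "mean_per1000", "ratio_to_country_mean"],
    )
    if year_pair is not None:
        y0, y1 = year_pair
        t0, t1 = agg.years.index(y0), agg.years.index(y1)
        flags = []
        for ui, uid in enumerate(agg.unit_ids):
            disjoint = upper[ui, t1] < lower[ui, t0] or lower[ui, t1] > upper[ui, t0]
            if not disjoint:
                change = "none"
            elif mean[ui, t1] < mean[ui, t0]:
                change = "decrease"
            else:
                change = "increase"
            flags.append((uid, y0, y1, bool(disjoint), change))
        changes = pd.DataFrame(
            flags, columns=["unit_id", "year_from", "year_to",
                            "significant", "direction"],
        )
        unit_df = unit_df.merge(changes[["unit_id", "significant", "direction"]],
                                on="unit_id", how="left")
    return country_df, unit_df


def counterfactual_averted_draws(
    agg: AdminAggregate,
    admin: AdminTessellation,
    population: PopulationSurface,
    scenario: str,
    threshold_per_1000: float | None = None,
    reference_year: int | None = None,
) -> np.ndarray:
    """Per-draw, per-year total deaths averted (D, T) under a scenario.

    Scenarios (cohort death mode, per year):

    * ``best_unit``: every unit matches the best-performing (lowest q_u5)
      unit of its country, selected per draw so the choice's uncertainty
      propagates; a unit's rate is never increased.
    * ``threshold``: every unit meets ``threshold_per_1000``; rates already
      below are unchanged.
    * ``rates_of_year``: units keep their ``reference_year`` rates exactly;
      averted = observed - counterfactual, so years with mortality below the
      reference year yield negative values.
    """
    units = admin.units_at(agg.level)
    q = agg.draws                              # (D, U, T)
    births = np.stack(
        [population.live_births[:, u.cells].sum(axis=1) for u in units], axis=0
    ).T                                        # (T, U)
    country_of_unit = np.array([admin.cell_to_unit[0][u.cells[0]] for u in units])

    if scenario == "best_unit":
        qcf = q.copy()
        for ci in np.unique(country_of_unit):
            members = np.flatnonzero(country_of_unit == ci)
            best = q[:, members, :].min(axis=1, keepdims=True)   # per draw/year
            qcf[:, members, :] = np.minimum(q[:, members, :], best)
    elif scenario == "threshold":
        if threshold_per_1000 is None:
            raise ValueError("threshold scenario needs threshold_per_1000")
        qcf = np.minimum(q, threshold_per_1000 / 1000.0)
    elif scenario == "rates_of_year":
        if reference_year is None:
            raise ValueError("rates_of_year scenario needs reference_year")
        t_ref = agg.years.index(reference_year)
        qcf = np.repeat(q[:, :, t_ref][:, :, None], q.shape[2], axis=2)
    else:
        raise ValueError(f"unknown counterfactual scenario {scenario!r}")

    return np.einsum("dut,tu->dt", q - qcf, births)   # (D, T)


def counterfactual_deaths_averted(
    agg: AdminAggregate,
    admin: AdminTessellation,
    population: PopulationSurface,
    scenario: str,
    threshold_per_1000: float | None = None,
    reference_year: int | None = None,
) -> pd.DataFrame:
    """Per-year summaries (mean, 95% interval) of total deaths averted."""
    averted = counterfactual_averted_draws(
        agg, admin, population, scenario, threshold_per_1000, reference_year
    )
    rows = []
    for ti, year in enumerate(agg.years):
        rows.append((scenario, year, float(np.mean(averted[:, ti])),
                     float(np.percentile(averted[:, ti], 2.5)),
                     float(np.percentile(averted[:, ti], 97.5))))
    return pd.DataFrame(rows, columns=["scenario", "year", "mean", "lower", "upper"])
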