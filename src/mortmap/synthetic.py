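"""Synthetic study worlds: grids, covariates, populations, admin units, truth
fields and household surveys.

Everything downstream of this module (tabulation, polygon resampling, model
fitting, post-estimation, cross-validation) consumes only the objects produced
here, so the whole pipeline can be exercised without any external data.  The
generator emulates the statistical structure the hazards model assumes:
geolocated (or polygon-referenced) survey clusters, complete-birth-history
child records produced by discrete bin-by-bin hazards, survey-level biases on
the logit scale, and a spatially/temporally/age-correlated residual field.

Geometry is a planar km coordinate system; admin units are axis-aligned nested
rectangles, which keeps nesting and population-weighted aggregation exactly
testable without shapefile machinery.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import squareform, pdist
from scipy.special import expit, logit
from shapely.geometry import box, mapping, shape

from .covariance import SeparableCovariance
from .params import GPHyper, ModelParams, N_AGE_BINS, mortality_cube

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# grid and age bins
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridDefinition:
    """Regular planar prediction grid (km) with an ordered run of study years.

    Cells are indexed row-major (row * n_cols + col) with row 0 at the bottom.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    n_rows: int
    n_cols: int
    years: tuple[int, ...]

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        yrs = tuple(int(y) for y in self.years)
        if len(yrs) < 1 or any(b - a != 1 for a, b in zip(yrs, yrs[1:])):
            raise ValueError(f"years must be consecutive integers, got {self.years}")
        object.__setattr__(self, "years", yrs)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_years(self) -> int:
        return len(self.years)

    def year_index(self, year) -> np.ndarray:
        idx = np.asarray(year) - self.years[0]
        if np.any(idx < 0) or np.any(idx >= self.n_years):
            raise ValueError("year outside the study window")
        return idx

    def cell_centres(self) -> np.ndarray:
        """(S, 2) array of cell-centre x, y coordinates."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        cx = self.origin_x + (cols + 0.5) * self.cell_size
        cy = self.origin_y + (rows + 0.5) * self.cell_size
        xx, yy = np.meshgrid(cx, cy)  # row-major: row varies along axis 0
        return np.column_stack([xx.ravel(), yy.ravel()])

    def distances(self) -> np.ndarray:
        """Symmetric inter-cell-centre distance matrix (km)."""
        return squareform(pdist(self.cell_centres()))

    def cells_of_points(self, x, y) -> np.ndarray:
        """Nearest cell centre for planar points; ties break to the lower index.

        Points outside the grid bounding box raise.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        w, h = self.n_cols * self.cell_size, self.n_rows * self.cell_size
        if np.any(x < self.origin_x) or np.any(x > self.origin_x + w) or \
           np.any(y < self.origin_y) or np.any(y > self.origin_y + h):
            raise ValueError("point outside the modelling grid")
        ux = (x - self.origin_x) / self.cell_size - 0.5
        uy = (y - self.origin_y) / self.cell_size - 0.5
        col = np.clip(np.ceil(ux - 0.5).astype(int), 0, self.n_cols - 1)
        row = np.clip(np.ceil(uy - 0.5).astype(int), 0, self.n_rows - 1)
        return row * self.n_cols + col


@dataclass(frozen=True)
class AgeBin:
    index: int
    label: str
    lower_month: int  # inclusive
    upper_month: int  # exclusive

    @property
    def width_months(self) -> int:
        return self.upper_month - self.lower_month


_CANONICAL_WIDTHS = (1, 5, 6, 12, 12, 12, 12)


@dataclass(frozen=True)
class AgeBinScheme:
    """The seven mutually exclusive age bands spanning 0-59 months.

    Bins are (0, 1-5, 6-11, 12-23, 24-35, 36-47, 48-59 months); bin 1 is the
    neonatal band, bins 1-3 compose infant mortality, bins 1-7 under-5.
    """

    bins: tuple[AgeBin, ...]

    def __post_init__(self):
        if len(self.bins) != N_AGE_BINS:
            raise ValueError(f"exactly {N_AGE_BINS} age bins required")
        lo = 0
        for i, (b, w) in enumerate(zip(self.bins, _CANONICAL_WIDTHS), start=1):
            if b.index != i:
                raise ValueError("age bins must be indexed 1..7 in order")
            if b.lower_month != lo or b.width_months != w:
                raise ValueError(
                    f"bin {i} must span [{lo}, {lo + w}) months, "
                    f"got [{b.lower_month}, {b.upper_month})"
                )
            lo += w
        if lo != 60:
            raise ValueError("age bins must jointly cover [0, 60) months")

    @classmethod
    def default(cls) -> "AgeBinScheme":
        labels = ["0mo", "1-5mo", "6-11mo", "12-23mo", "24-35mo", "36-47mo", "48-59mo"]
        bins, lo = [], 0
        for i, (lab, w) in enumerate(zip(labels, _CANONICAL_WIDTHS), start=1):
            bins.append(AgeBin(i, lab, lo, lo + w))
            lo += w
        return cls(tuple(bins))

    @property
    def lower_months(self) -> np.ndarray:
        return np.array([b.lower_month for b in self.bins], dtype=float)

    @property
    def upper_months(self) -> np.ndarray:
        return np.array([b.upper_month for b in self.bins], dtype=float)

    @property
    def width_years(self) -> np.ndarray:
        return np.array([b.width_months for b in self.bins], dtype=float) / 12.0

    def bin_of_age_months(self, age_months) -> np.ndarray:
        """1-based bin index containing each age; ages >= 60 map to -1."""
        age = np.atleast_1d(np.asarray(age_months, dtype=float))
        idx = np.searchsorted(self.upper_months, age, side="right") + 1
        idx[(age < 0) | (age >= 60)] = -1
        return idx


# ---------------------------------------------------------------------------
# covariates, population, admin units
# ---------------------------------------------------------------------------

@dataclass
class CovariateSurface:
    """One predictor surface: values per (year, cell), optionally standardised."""

    name: str
    grid: GridDefinition
    values: np.ndarray  # (T, S)
    standardized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_years, self.grid.n_cells):
            raise ValueError(
                f"covariate {self.name!r} must have shape (T, S) = "
                f"{(self.grid.n_years, self.grid.n_cells)}, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"covariate {self.name!r} contains non-finite values")
        if self.standardized:
            m, s = self.values.mean(), self.values.std()
            if abs(m) > 1e-6 or abs(s - 1.0) > 1e-6:
                raise ValueError(
                    f"covariate {self.name!r} flagged standardized but has "
                    f"mean {m:.2e}, sd {s:.4f}"
                )

    def standardize(self) -> "CovariateSurface":
        sd = self.values.std()
        if sd == 0:
            raise ValueError(f"covariate {self.name!r} is constant; cannot standardize")
        vals = (self.values - self.values.mean()) / sd
        return CovariateSurface(self.name, self.grid, vals, standardized=True)


def covariate_stack(covariates) -> np.ndarray:
    """Stack surfaces into a (p, T, S) array (p may be zero)."""
    if not covariates:
        return np.zeros((0, 0, 0))
    return np.stack([c.values for c in covariates], axis=0)


@dataclass
class PopulationSurface:
    """Gridded person counts per (year, cell) for two population classes.

    ``live_births`` is the birth cohort entering each cell-year (the exposure
    for cohort-mode death counts and the weight for probability aggregation);
    ``under5`` is the resident under-5 population (period-rate death mode).
    """

    grid: GridDefinition
    live_births: np.ndarray  # (T, S)
    under5: np.ndarray       # (T, S)

    def __post_init__(self):
        for name in ("live_births", "under5"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (self.grid.n_years, self.grid.n_cells):
                raise ValueError(f"{name} must have shape (T, S)")
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise ValueError(f"{name} must be finite and non-negative")
            setattr(self, name, v)


@dataclass
class AdminUnit:
    unit_id: str
    level: int  # 0 country, 1 admin1, 2 admin2
    parent_id: str | None
    geometry: object  # shapely polygon in grid km coordinates
    cells: np.ndarray  # member cell indices


@dataclass
class AdminTessellation:
    """Nested rectangular admin units covering the grid.

    ``cell_to_unit[level]`` maps each cell to the index of its unit within
    ``units_at(level)``; levels are 0 (country), 1 and 2.
    """

    grid: GridDefinition
    units: list[AdminUnit]
    cell_to_unit: dict[int, np.ndarray]

    def units_at(self, level: int) -> list[AdminUnit]:
        return [u for u in self.units if u.level == level]

    def unit_ids(self, level: int) -> list[str]:
        return [u.unit_id for u in self.units_at(level)]

    def by_id(self, unit_id: str) -> AdminUnit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(f"unknown admin unit {unit_id!r}")

    @property
    def country_of_cell(self) -> np.ndarray:
        return self.cell_to_unit[0]

    @property
    def n_countries(self) -> int:
        return len(self.units_at(0))

    def parent_index(self, level: int) -> np.ndarray:
        """For each unit at `level`, the index of its parent at `level - 1`."""
        parents = self.unit_ids(level - 1)
        lookup = {uid: i for i, uid in enumerate(parents)}
        return np.array([lookup[u.parent_id] for u in self.units_at(level)])


def nested_rectangles(
    grid: GridDefinition,
    countries: tuple[int, int],
    admin1: tuple[int, int],
    admin2: tuple[int, int],
) -> AdminTessellation:
    """Axis-aligned nested tessellation: countries -> admin1 -> admin2.

    ``countries = (cx, cy)`` splits the grid into cx columns x cy rows of
    country blocks; ``admin1``/``admin2`` give the per-parent sub-splits.
    All splits must divide the grid dimensions exactly.
    """
    cx, cy = countries
    ax, ay = admin1
    bx, by = admin2
    for n, div, name in ((grid.n_cols, cx * ax * bx, "columns"),
                         (grid.n_rows, cy * ay * by, "rows")):
        if div < 1 or n % div != 0:
            raise ValueError(
                f"admin tessellation incompatible with grid: {div} nested splits "
                f"do not divide {n} {name}"
            )

    col = np.arange(grid.n_cells) % grid.n_cols
    row = np.arange(grid.n_cells) // grid.n_cols

    def blocks(n_cols_splits, n_rows_splits):
        wc = grid.n_cols // n_cols_splits
        wr = grid.n_rows // n_rows_splits
        bc = col // wc
        br = row // wr
        return br * n_cols_splits + bc, wc, wr

    units: list[AdminUnit] = []
    cell_to_unit: dict[int, np.ndarray] = {}

    specs = [
        (0, cx, cy, None),
        (1, cx * ax, cy * ay, 0),
        (2, cx * ax * bx, cy * ay * by, 1),
    ]
    ids_at_level: dict[int, list[str]] = {}
    for level, nx, ny, parent_level in specs:
        block_of_cell, wc, wr = blocks(nx, ny)
        cell_to_unit[level] = block_of_cell
        ids = []
        for b in range(nx * ny):
            cells = np.flatnonzero(block_of_cell == b)
            brow, bcol = b // nx, b % nx
            x0 = grid.origin_x + bcol * wc * grid.cell_size
            y0 = grid.origin_y + brow * wr * grid.cell_size
            geom = box(x0, y0, x0 + wc * grid.cell_size, y0 + wr * grid.cell_size)
            if parent_level is None:
                uid, parent = f"C{b:02d}", None
            else:
                parent_idx = cell_to_unit[parent_level][cells[0]]
                parent = ids_at_level[parent_level][parent_idx]
                tag = "A1" if level == 1 else "A2"
                uid = f"{parent}_{tag}{b:03d}"
            units.append(AdminUnit(uid, level, parent, geom, cells))
            ids.append(uid)
        ids_at_level[level] = ids
    return AdminTessellation(grid, units, cell_to_unit)


# ---------------------------------------------------------------------------
# world simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WorldConfig:
    """Shape and texture of a synthetic study region.

    The defaults describe a modest multi-country region: a 12x12 grid of
    10 km cells over six study years, four countries in a 2x2 block layout,
    each split into 2x2 provinces and each province into 3x3 districts, two
    standardized covariate surfaces and log-normal population texture.
    """

    n_rows: int = 12
    n_cols: int = 12
    cell_size: float = 10.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    years: tuple[int, ...] = (2000, 2001, 2002, 2003, 2004, 2005)
    n_covariates: int = 2
    covariate_smooth_cells: float = 1.5
    # the smoothed white-noise base field has sd ~0.2; the year-trend
    # component stays subordinate to it so standardized covariates remain
    # predominantly spatial (strongly trended covariates would drive
    # implausible secular swings in the truth field)
    covariate_trend_sd: float = 0.06
    countries: tuple[int, int] = (2, 2)
    admin1_per_country: tuple[int, int] = (2, 2)
    admin2_per_admin1: tuple[int, int] = (3, 3)
    mean_births_per_cell_year: float = 350.0
    population_log_sd: float = 0.5
    population_smooth_cells: float = 1.0
    births_growth_rate: float = 0.01
    under5_per_birth: float = 4.8


@dataclass
class World:
    grid: GridDefinition
    age_scheme: AgeBinScheme
    covariates: list[CovariateSurface]
    population: PopulationSurface
    admin: AdminTessellation

    @property
    def covariate_stack(self) -> np.ndarray:
        if not self.covariates:
            return np.zeros((0, self.grid.n_years, self.grid.n_cells))
        return covariate_stack(self.covariates)


def _smooth_field(rng, grid, sigma_cells):
    """Kernel-smoothed white noise on the grid, unit-free texture."""
    noise = rng.standard_normal((grid.n_rows, grid.n_cols))
    if sigma_cells > 0:
        noise = gaussian_filter(noise, sigma=sigma_cells, mode="nearest")
    return noise.ravel()


def simulate_world(config: WorldConfig, seed: int) -> World:
    """Generate grid, covariates, population and admin units.

    Covariates are smoothed white-noise fields plus an optional linear year
    trend, standardised to mean 0 / sd 1 over the full (year, cell) support.
    Population is strictly positive log-normal texture with mild growth.
    """
    if config.n_covariates < 0:
        raise ValueError("n_covariates must be >= 0")
    grid = GridDefinition(
        config.origin_x, config.origin_y, config.cell_size,
        config.n_rows, config.n_cols, tuple(config.years),
    )
    rng = np.random.default_rng(seed)
    admin = nested_rectangles(
        grid, config.countries, config.admin1_per_country, config.admin2_per_admin1
    )

    tc = np.arange(grid.n_years) - (grid.n_years - 1) / 2.0
    covariates = []
    for j in range(config.n_covariates):
        base = _smooth_field(rng, grid, config.covariate_smooth_cells)
        trend = rng.normal(0.0, config.covariate_trend_sd)
        values = base[None, :] + trend * tc[:, None] * np.ones(grid.n_cells)[None, :]
        cov = CovariateSurface(f"cov{j}", grid, values).standardize()
        covariates.append(cov)

    log_base = np.log(config.mean_births_per_cell_year) + \
        config.population_log_sd * _smooth_field(rng, grid, config.population_smooth_cells)
    growth = (1.0 + config.births_growth_rate) ** np.arange(grid.n_years)
    births = np.exp(log_base)[None, :] * growth[:, None]
    under5 = config.under5_per_birth * births
    population = PopulationSurface(grid, births, under5)

    return World(grid, AgeBinScheme.default(), covariates, population, admin)


def simulate_gp_field(
    grid: GridDefinition,
    age_scheme: AgeBinScheme,
    hyper: GPHyper,
    seed: int,
) -> np.ndarray:
    """Draw a mean-zero separable GP field of shape (7, T, S).

    Sampling is Kronecker-factored: per-axis Cholesky factors applied to iid
    normals, so the dense covariance is never formed.
    """
    rng = np.random.default_rng(seed)
    shape = (len(age_scheme.bins), grid.n_years, grid.n_cells)
    if hyper.sigma_z == 0:
        return np.zeros(shape)
    cov = SeparableCovariance.from_hyper(grid.distances(), grid.n_years, hyper)
    return cov.sample(rng)


def simulate_true_mortality(
    params: ModelParams,
    world: World,
) -> np.ndarray:
    """True conditional bin probabilities P[a,t,s] on the logit-linear model.

    Survey effects are deliberately absent: they describe data sources, not
    places, so the truth field carries only beta terms, country effects and Z.
    """
    return mortality_cube(params, world.covariate_stack, world.admin.country_of_cell)


# ---------------------------------------------------------------------------
# surveys
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurveyConfig:
    """Design of the synthetic household surveys.

    ``area`` is "region" (clusters anywhere, proportional to births) or
    "admin1" (each survey confined to one admin-1 unit, assigned round-robin,
    which mimics the spatially segregated data sources that survey-holdout
    cross-validation is designed to stress).  ``polygon_fraction`` of clusters
    are referenced only to their admin-2 polygon (no coordinates).  SBH-style
    sources, when requested, are emitted directly as bin-level observations to
    be down-weighted later; the indirect estimation that would produce them
    from real summary histories is out of scope by design.
    """

    n_surveys: int = 12
    clusters_per_survey: int = 60
    births_per_cluster: int = 120
    polygon_fraction: float = 0.0
    sigma_k: float = 0.1
    area: str = "region"
    interview_lag_years: float = 0.5
    n_sbh_surveys: int = 0
    sbh_entrants_per_bin: float = 40.0

    def __post_init__(self):
        if not 0.0 <= self.polygon_fraction <= 1.0:
            raise ValueError(
                f"polygon_fraction must lie in [0, 1], got {self.polygon_fraction}"
            )
        if self.sigma_k < 0:
            raise ValueError("sigma_k must be >= 0")
        if self.area not in ("region", "admin1"):
            raise ValueError(f"area must be 'region' or 'admin1', got {self.area!r}")


@dataclass
class SurveyData:
    """Raw synthetic survey output: child records, cluster table, true biases."""

    children: pd.DataFrame   # survey_id, cluster_id, birth_date, interview_date,
                             # outcome, age_at_death_months
    clusters: pd.DataFrame   # survey_id, cluster_id, country_id, x, y, polygon_id
    survey_bias: pd.DataFrame  # survey_id, nu_k, source_type
    sbh_observations: pd.DataFrame  # bin-level rows for SBH-style sources


def _sample_cluster_cells(rng, weights, n):
    w = weights / weights.sum()
    return rng.choice(len(w), size=n, replace=True, p=w)


def simulate_surveys(
    truth: np.ndarray,
    world: World,
    config: SurveyConfig,
    seed: int,
) -> SurveyData:
    """Simulate surveys: biased hazards -> child life courses -> records.

    Each survey k draws a bias nu_k ~ N(0, sigma_k^2) added to the logit
    hazard of every child it observes.  Cluster cells are sampled proportional
    to live births; children are born uniformly over the study years and walk
    through the seven bins with the biased conditional probabilities; a death
    is placed at a uniform month within its bin.  The hazard year for a bin is
    the calendar year containing the midpoint of the child's traversal of that
    bin, matching the tabulation rule downstream.
    """
    grid, age = world.grid, world.age_scheme
    if truth.shape != (N_AGE_BINS, grid.n_years, grid.n_cells):
        raise ValueError("truth cube does not match the world grid")
    births_w = world.population.live_births.sum(axis=0)
    if births_w.sum() <= 0:
        raise ValueError("population is empty; cannot place survey clusters")
    rng = np.random.default_rng(seed)

    admin1_units = world.admin.units_at(1)
    admin2_of_cell = world.admin.cell_to_unit[2]
    admin2_ids = world.admin.unit_ids(2)
    country_ids = world.admin.unit_ids(0)
    country_of_cell = world.admin.country_of_cell

    lo_m, hi_m = age.lower_months, age.upper_months
    mid_years = (lo_m + hi_m) / 24.0
    # interviews happen `lag` years after the end of the final study year, so
    # final-year cohorts are partially observed (right-censored), as in real CBH
    interview = grid.years[-1] + 1.0 + config.interview_lag_years

    children_frames, cluster_frames, bias_rows = [], [], []
    logit_truth = logit(truth)

    n_cbh = config.n_surveys
    for k in range(n_cbh):
        survey_id = f"S{k:02d}"
        nu_k = rng.normal(0.0, config.sigma_k) if config.sigma_k > 0 else 0.0
        bias_rows.append((survey_id, nu_k, "cbh"))

        if config.area == "admin1":
            unit = admin1_units[k % len(admin1_units)]
            cand = unit.cells
        else:
            cand = np.arange(grid.n_cells)
        w = births_w[cand]
        if w.sum() <= 0:
            raise ValueError("survey area has zero population")
        cells = cand[_sample_cluster_cells(rng, w, config.clusters_per_survey)]

        jitter = rng.uniform(-0.5, 0.5, size=(config.clusters_per_survey, 2))
        centres = grid.cell_centres()[cells]
        xy = centres + jitter * grid.cell_size
        poly_mask = rng.random(config.clusters_per_survey) < config.polygon_fraction
        cluster_ids = np.array([f"{survey_id}_c{j:03d}" for j in range(config.clusters_per_survey)])
        cluster_frames.append(pd.DataFrame({
            "survey_id": survey_id,
            "cluster_id": cluster_ids,
            "country_id": np.array(country_ids)[country_of_cell[cells]],
            "x": np.where(poly_mask, np.nan, xy[:, 0]),
            "y": np.where(poly_mask, np.nan, xy[:, 1]),
            "polygon_id": np.where(poly_mask, np.array(admin2_ids)[admin2_of_cell[cells]], ""),
        }))

        n_children = config.clusters_per_survey * config.births_per_cluster
        child_cluster = np.repeat(np.arange(config.clusters_per_survey), config.births_per_cluster)
        child_cell = cells[child_cluster]
        birth = rng.uniform(grid.years[0], grid.years[-1] + 1.0, size=n_children)

        alive = np.ones(n_children, dtype=bool)
        death_bin = np.full(n_children, -1)
        for a in range(N_AGE_BINS):
            t_idx = np.clip(
                np.floor(birth + mid_years[a]).astype(int) - grid.years[0],
                0, grid.n_years - 1,
            )
            p = expit(logit_truth[a, t_idx, child_cell] + nu_k)
            dies = alive & (rng.random(n_children) < p)
            death_bin[dies] = a
            alive &= ~dies

        age_at_death = np.full(n_children, np.nan)
        died = death_bin >= 0
        if died.any():
            u = rng.random(died.sum())
            age_at_death[died] = lo_m[death_bin[died]] + u * (
                hi_m[death_bin[died]] - lo_m[death_bin[died]]
            )
        death_date = birth + age_at_death / 12.0
        observed_death = died & (death_date < interview)
        children_frames.append(pd.DataFrame({
            "survey_id": survey_id,
            "cluster_id": cluster_ids[child_cluster],
            "birth_date": birth,
            "interview_date": interview,
            "outcome": np.where(observed_death, "died", "alive_at_interview"),
            "age_at_death_months": np.where(observed_death, age_at_death, np.nan),
        }))

    sbh_frames = []
    for k in range(config.n_sbh_surveys):
        survey_id = f"SBH{k:02d}"
        nu_k = rng.normal(0.0, config.sigma_k) if config.sigma_k > 0 else 0.0
        bias_rows.append((survey_id, nu_k, "sbh"))
        cells = _sample_cluster_cells(rng, births_w, config.clusters_per_survey)
        jitter = rng.uniform(-0.5, 0.5, size=(config.clusters_per_survey, 2))
        xy = grid.cell_centres()[cells] + jitter * grid.cell_size
        cluster_ids = np.array([f"{survey_id}_c{j:03d}" for j in range(config.clusters_per_survey)])
        cluster_frames.append(pd.DataFrame({
            "survey_id": survey_id,
            "cluster_id": cluster_ids,
            "country_id": np.array(country_ids)[country_of_cell[cells]],
            "x": xy[:, 0],
            "y": xy[:, 1],
            "polygon_id": "",
        }))
        rows = []
        for a in range(N_AGE_BINS):
            for t in range(grid.n_years):
                p = expit(logit_truth[a, t, cells] + nu_k)
                n = rng.poisson(config.sbh_entrants_per_bin, size=len(cells)).astype(float)
                y = rng.binomial(np.maximum(n, 0).astype(int), p).astype(float)
                rows.append(pd.DataFrame({
                    "survey_id": survey_id,
                    "cluster_id": cluster_ids,
                    "country_id": np.array(country_ids)[country_of_cell[cells]],
                    "x": xy[:, 0],
                    "y": xy[:, 1],
                    "polygon_id": "",
                    "year": grid.years[0] + t,
                    "age_bin": a + 1,
                    "entrants": n,
                    "deaths": y,
                    "weight": 1.0,
                    "source_type": "sbh",
                }))
        sbh_frames.append(pd.concat(rows, ignore_index=True))

    children = pd.concat(children_frames, ignore_index=True) if children_frames else \
        pd.DataFrame(columns=["survey_id", "cluster_id", "birth_date",
                              "interview_date", "outcome", "age_at_death_months"])
    clusters = pd.concat(cluster_frames, ignore_index=True)
    sbh = pd.concat(sbh_frames, ignore_index=True) if sbh_frames else pd.DataFrame()
    bias = pd.DataFrame(bias_rows, columns=["survey_id", "nu_k", "source_type"])
    logger.info(
        "simulated %d CBH surveys (%d children), %d SBH sources",
        n_cbh, len(children), config.n_sbh_surveys,
    )
    return SurveyData(children, clusters, bias, sbh)


# ---------------------------------------------------------------------------
# writers / readers (planar TIFF rasters, GeoJSON admin, CSV tables)
# ---------------------------------------------------------------------------

def write_raster(path, grid: GridDefinition, values: np.ndarray) -> None:
    """Write a (T, S) surface as a multi-page TIFF, one page per year."""
    import tifffile

    arr = np.asarray(values, dtype=np.float32).reshape(
        grid.n_years, grid.n_rows, grid.n_cols
    )
    tifffile.imwrite(
        path, arr, photometric="minisblack",
        metadata={"years": list(grid.years), "cell_size_km": grid.cell_size,
                  "origin": [grid.origin_x, grid.origin_y]},
    )


def read_raster(path, grid: GridDefinition) -> np.ndarray:
    import tifffile

    arr = np.asarray(tifffile.imread(path), dtype=float)
    return arr.reshape(grid.n_years, grid.n_cells)


def write_admin_geojson(path, admin: AdminTessellation) -> None:
    features = []
    for u in admin.units:
        features.append({
            "type": "Feature",
            "properties": {"unit_id": u.unit_id, "level": u.level,
                           "parent_id": u.parent_id},
            "geometry": mapping(u.geometry),
        })
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_admin_geojson(path, grid: GridDefinition) -> AdminTessellation:
    with open(path, encoding="utf-8") as fh:
        fc = json.load(fh)
    centres = grid.cell_centres()
    units = []
    cell_to_unit = {}
    per_level_ids: dict[int, list[str]] = {0: [], 1: [], 2: []}
    per_level_units: dict[int, list[AdminUnit]] = {0: [], 1: [], 2: []}
    for feat in fc["features"]:
        props = feat["properties"]
        geom = shape(feat["geometry"])
        level = int(props["level"])
        minx, miny, maxx, maxy = geom.bounds
        # strict inequalities: cell centres never sit on rectangle edges
        inside = (
            (centres[:, 0] > minx) & (centres[:, 0] < maxx)
            & (centres[:, 1] > miny) & (centres[:, 1] < maxy)
        )
        u = AdminUnit(props["unit_id"], level, props.get("parent_id"),
                      geom, np.flatnonzero(inside))
        per_level_units[level].append(u)
        per_level_ids[level].append(u.unit_id)
    units = per_level_units[0] + per_level_units[1] + per_level_units[2]
    for level in (0, 1, 2):
        mapping_arr = np.full(grid.n_cells, -1)
        for i, u in enumerate(per_level_units[level]):
            mapping_arr[u.cells] = i
        if np.any(mapping_arr < 0):
            raise ValueError(f"admin level {level} does not cover the grid")
        cell_to_unit[level] = mapping_arr
    return AdminTessellation(grid, units, cell_to_unit)
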