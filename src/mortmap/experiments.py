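"""Reference simulation studies: parameter recovery, interval calibration, CV.

These functions define the package's standing evaluation conditions — the
synthetic study designs under which the model's statistical behaviour is
checked — and are used both by the test suite and by the acceptance script.

Two worlds are used:

* the *recovery* world: a 20 x 20 grid over six years with four countries,
  eight region-wide surveys (200 clusters per year in total) and known fixed
  effects; GP hyperparameters are supplied to the fit, and each replicate
  checks whether the 95% posterior intervals cover the generating values.
* the *evaluation* world: a 12 x 16 grid with 48 small admin-1 blocks, each
  carrying exactly one survey (the spatially segregated data-source pattern
  that survey-holdout cross-validation is designed to stress); used for
  interval calibration against the known truth and for fivefold CV against
  held-out direct estimates.  The number of blocks is a power choice: held-out
  prediction errors are correlated within a block, so the Monte-Carlo sd of
  the pooled mean error scales with 1/sqrt(blocks), and ~48 blocks are needed
  to measure bias at the 0.005 scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .histories import qc_filter, tabulate_cbh
from .model import (
    FitConfig,
    ModelData,
    draw_posterior,
    fit_map,
    predict_probability_surfaces,
)
from .params import GPHyper, ModelParams
from .postest import aggregate_to_admin, compose_mortality
from .synthetic import (
    SurveyConfig,
    World,
    WorldConfig,
    simulate_gp_field,
    simulate_surveys,
    simulate_true_mortality,
    simulate_world,
)
from .validation import CrossValidationResult, run_cross_validation

logger = logging.getLogger(__name__)

#: generating values shared by both study worlds (fixed effects on the logit
#: scale; a plausible high-mortality region declining ~5%/year in odds)
TRUE_FIXED = {
    "beta0": -3.48,
    "beta_age": np.array([-0.93, -1.12, -0.93, -1.34, -1.63, -1.82]),
    "beta_time": -0.05,
}
TRUE_GP = GPHyper(spatial_range=15.0, sigma_z=0.45, rho_t=0.85, rho_a=0.85)
TRUE_SIGMA_C = 0.3
TRUE_SIGMA_K = 0.1

RECOVERY_BETA_COV = np.array([0.8, -0.5])
EVAL_BETA_COV = np.array([0.5, -0.3])

RECOVERY_WORLD = WorldConfig(
    n_rows=20, n_cols=20, countries=(2, 2), admin1_per_country=(2, 2),
    admin2_per_admin1=(5, 5), mean_births_per_cell_year=150.0,
)
RECOVERY_SURVEYS = SurveyConfig(
    n_surveys=8, clusters_per_survey=25, births_per_cluster=180,
    sigma_k=TRUE_SIGMA_K, area="region",
)

EVAL_WORLD = WorldConfig(
    n_rows=12, n_cols=16, countries=(2, 2), admin1_per_country=(4, 3),
    admin2_per_admin1=(2, 2),
)
EVAL_SURVEYS = SurveyConfig(
    n_surveys=48, clusters_per_survey=50, births_per_cluster=550,
    sigma_k=TRUE_SIGMA_K, area="admin1",
)
EVAL_GP = GPHyper(spatial_range=15.0, sigma_z=0.4, rho_t=0.85, rho_a=0.85)

FIXED_EFFECT_NAMES = (
    ["beta0"] + [f"beta_age_{a}" for a in range(2, 8)]
    + ["beta_cov_0", "beta_cov_1", "beta_time"]
)


@dataclass
class StudyWorld:
    world: World
    truth_params: ModelParams
    truth_cube: np.ndarray      # (7, T, S)
    data: ModelData


def _truth_params(world: World, beta_cov: np.ndarray, z: np.ndarray,
                  seed: int, gp: GPHyper) -> ModelParams:
    rng = np.random.default_rng(seed)
    return ModelParams(
        beta0=TRUE_FIXED["beta0"], beta_age=TRUE_FIXED["beta_age"].copy(),
        beta_cov=np.asarray(beta_cov, dtype=float),
        beta_time=TRUE_FIXED["beta_time"],
        nu_country=rng.normal(0.0, TRUE_SIGMA_C, world.admin.n_countries),
        sigma_c=TRUE_SIGMA_C, nu_survey=np.zeros(0), sigma_k=TRUE_SIGMA_K,
        z=z, gp=gp,
    )


def make_study_world(
    seed: int,
    world_config: WorldConfig,
    survey_config: SurveyConfig,
    beta_cov: np.ndarray,
    gp: GPHyper | None = None,
) -> StudyWorld:
    """Simulate a world with known truth and tabulated, QC'd observations."""
    gp = gp or TRUE_GP
    world = simulate_world(world_config, seed)
    z = simulate_gp_field(world.grid, world.age_scheme, gp, seed + 1)
    params = _truth_params(world, beta_cov, z, seed + 2, gp)
    truth = simulate_true_mortality(params, world)
    surveys = simulate_surveys(truth, world, survey_config, seed + 3)
    obs = tabulate_cbh(surveys.children, surveys.clusters,
                       world.age_scheme, world.grid.years)
    obs, _ = qc_filter(obs, world.grid.years)
    data = ModelData.from_world(obs, world)
    return StudyWorld(world, params, truth, data)


def make_recovery_world(seed: int) -> StudyWorld:
    return make_study_world(seed, RECOVERY_WORLD, RECOVERY_SURVEYS, RECOVERY_BETA_COV)


def make_eval_world(seed: int) -> StudyWorld:
    return make_study_world(seed, EVAL_WORLD, EVAL_SURVEYS, EVAL_BETA_COV,
                            gp=EVAL_GP)


def recovery_study(n_replicates: int = 20, seed: int = 0) -> pd.DataFrame:
    """Fixed-effect recovery across seeded replicates of the recovery world.

    GP hyperparameters are supplied at their generating values (the study
    evaluates fixed-effect inference under known residual structure); each
    replicate refits from a neutral initial point and records each fixed
    effect's estimate, posterior sd and whether the 95% interval covers the
    truth.
    """
    truth_values = np.concatenate([
        [TRUE_FIXED["beta0"]], TRUE_FIXED["beta_age"],
        RECOVERY_BETA_COV, [TRUE_FIXED["beta_time"]],
    ])
    cfg = FitConfig(estimate_hypers=False, precision_mode="fixed_marginal")
    rows = []
    for rep in range(n_replicates):
        rep_seed = seed + 1000 * (rep + 1)
        study = make_recovery_world(rep_seed)
        grid = study.world.grid
        init = ModelParams(
            beta0=-3.0, beta_age=np.zeros(6), beta_cov=np.zeros(2),
            beta_time=0.0, nu_country=np.zeros(study.world.admin.n_countries),
            sigma_c=TRUE_SIGMA_C, nu_survey=np.zeros(study.data.n_surveys),
            sigma_k=TRUE_SIGMA_K,
            z=np.zeros((7, grid.n_years, grid.n_cells)), gp=TRUE_GP,
        )
        fit = fit_map(study.data, config=cfg, init=init)
        tab = fit.fixed_effect_table().set_index("name")
        for j, name in enumerate(FIXED_EFFECT_NAMES):
            r = tab.loc[name]
            rows.append({
                "replicate": rep, "name": name, "truth": truth_values[j],
                "estimate": r.estimate, "sd": r.sd,
                "lower": r.lower, "upper": r.upper,
                "covered": bool(r.lower <= truth_values[j] <= r.upper),
                "within_3sd": bool(abs(r.estimate - truth_values[j]) <= 3 * r.sd),
            })
        logger.info("recovery replicate %d/%d done", rep + 1, n_replicates)
    return pd.DataFrame(rows)


def recovery_summary(results: pd.DataFrame) -> pd.DataFrame:
    return results.groupby("name").agg(
        n=("covered", "size"), n_covered=("covered", "sum"),
        n_within_3sd=("within_3sd", "sum"),
        mean_estimate=("estimate", "mean"), truth=("truth", "first"),
    ).reset_index()


def calibration_study(seed: int = 0, n_worlds: int = 2,
                      n_draws: int = 500) -> dict:
    """Admin-2 interval calibration against the known truth.

    Fits the evaluation world in full, draws from the joint precision,
    aggregates under-5 mortality to admin-2 units (birth-weighted), and
    reports the fraction of unit-years whose true aggregated probability
    falls inside the 95% uncertainty interval.
    """
    covered, total = 0, 0
    for i in range(n_worlds):
        study = make_eval_world(seed + 7000 * (i + 1))
        world = study.world
        fit = fit_map(study.data)
        draws = draw_posterior(fit, n_draws=n_draws, seed=seed + i)
        cube = predict_probability_surfaces(draws, study.data)
        births = world.population.live_births
        agg = aggregate_to_admin(cube.q("q_u5"), world.admin, 2,
                                 kind="rate", weights=births, measure="q_u5")
        q_true = compose_mortality(study.truth_cube[None, ...], 7)  # (1, T, S)
        true_agg = aggregate_to_admin(q_true, world.admin, 2, kind="rate",
                                      weights=births, measure="q_u5")
        lower, upper = agg.interval()
        truth_vals = true_agg.draws[0]              # (U, T)
        inside = (truth_vals >= lower) & (truth_vals <= upper)
        covered += int(inside.sum())
        total += inside.size
    return {"coverage": covered / total, "n_unit_years": total,
            "n_worlds": n_worlds}


def cv_study(seed: int = 0, n_draws: int = 500) -> CrossValidationResult:
    """Fivefold survey-holdout CV on the evaluation world (admin-2, under-5)."""
    study = make_eval_world(seed + 31000)
    return run_cross_validation(study.data, study.world, k=5, level=2,
                                measure="q_u5", n_draws=n_draws, seed=seed)
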