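"""End-to-end pipeline: simulate -> prepare -> fit -> post-estimate -> validate.

A single :class:`RunConfig` (YAML on disk) drives every stage; a master seed
deterministically derives per-stage seeds (stage-name hashing), and all
randomness flows through explicitly constructed generators, so the whole run
is a pure function of (config, seed) at the level of artifact checksums.
Every stage writes its artifacts under the configured output directory and
records them in a manifest with SHA-256 checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import histories, resampling
from .model import (
    FitConfig,
    FitResult,
    ModelData,
    PosteriorDraws,
    PriorSpec,
    draw_posterior,
    fit_map,
    predict_probability_surfaces,
)
from .params import GPHyper, ModelParams
from .postest import (
    MEASURE_BINS,
    aggregate_to_admin,
    compose_mortality,
    counterfactual_deaths_averted,
    estimate_deaths,
    exceedance_probability,
    inequality_metrics,
    neonatal_fraction,
    rake_to_reference,
)
from .synthetic import (
    AgeBinScheme,
    GridDefinition,
    SurveyConfig,
    World,
    WorldConfig,
    read_admin_geojson,
    read_raster,
    simulate_gp_field,
    simulate_surveys,
    simulate_true_mortality,
    simulate_world,
    write_admin_geojson,
    write_raster,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "prepare", "fit", "postest", "validate")


def setup_logging(verbose: bool = False, logfile=None) -> None:
    handlers = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(levelname)s %(name)s | %(message)s",
        handlers=handlers, force=True,
    )


def derive_seed(master_seed: int, stage: str) -> int:
    """Stage seed from the master seed via stable hashing (below 2^31)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthConfig:
    """True model parameters used to generate the synthetic mortality field.

    Defaults encode a plausible high-mortality region: a neonatal hazard of
    ~0.03 declining with age, under-5 mortality around 70 per 1,000 live
    births, a secular decline of about 5% per year on the odds scale, and
    moderate country effects and residual structure.
    """

    beta0: float = -3.48
    beta_age: tuple = (-0.93, -1.12, -0.93, -1.34, -1.63, -1.82)
    beta_cov: tuple = (0.5, -0.3)
    beta_time: float = -0.05
    sigma_c: float = 0.3
    spatial_range: float = 15.0
    sigma_z: float = 0.45
    rho_t: float = 0.85
    rho_a: float = 0.85
    smoothness: float = 1.5


@dataclass(frozen=True)
class ModelConfig:
    n_draws: int = 1000
    maxiter: int = 60
    gtol: float = 1e-3
    estimate_hypers: bool = True
    outer_maxfev: int = 60
    smoothness: float = 1.5
    beta_sd: float = 5.0
    sigma_c_scale: float = 1.0
    sigma_k_scale: float = 1.0
    sigma_z_scale: float = 1.0
    log_range_sd: float = 1.0
    precision_mode: str = "auto"
    dense_limit: int = 9000


@dataclass(frozen=True)
class PostestConfig:
    rake: bool = True
    u5_threshold: float = 25.0
    nn_threshold: float = 12.0
    certainty: float = 0.9
    counterfactual_reference_year: int | None = None
    inequality_year_pair: tuple | None = None

    def __post_init__(self):
        if self.u5_threshold <= 0 or self.nn_threshold <= 0:
            raise ValueError("threshold values must be positive")
        if not 0 < self.certainty < 1:
            raise ValueError("certainty must lie in (0, 1)")


@dataclass(frozen=True)
class CVConfig:
    enabled: bool = True
    k: int = 5
    level: int = 2
    measure: str = "q_u5"
    n_draws: int = 500


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    outdir: str = "mortmap_run"
    sbh_factor: float = 0.5
    resample_k: int = 10
    world: WorldConfig = field(default_factory=WorldConfig)
    truth: TruthConfig = field(default_factory=TruthConfig)
    surveys: SurveyConfig = field(default_factory=SurveyConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    postest: PostestConfig = field(default_factory=PostestConfig)
    cv: CVConfig = field(default_factory=CVConfig)

    def __post_init__(self):
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ValueError(f"seed must be a non-negative integer, got {self.seed!r}")
        if not 0 < self.sbh_factor <= 1:
            raise ValueError(f"sbh_factor must lie in (0, 1], got {self.sbh_factor}")
        if len(self.truth.beta_cov) != self.world.n_covariates:
            raise ValueError(
                "truth.beta_cov length must equal world.n_covariates "
                f"({len(self.truth.beta_cov)} vs {self.world.n_covariates})"
            )


_SECTION_TYPES = {
    "world": WorldConfig, "truth": TruthConfig, "surveys": SurveyConfig,
    "model": ModelConfig, "postest": PostestConfig, "cv": CVConfig,
}


def _build_section(cls, payload, path):
    if payload is None:
        payload = {}
    if not isinstance(payload, dict):
        raise ValueError(f"config section {path!r} must be a mapping")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown config key(s) under {path!r}: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in payload:
            v = payload[f.name]
            if isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid value in config section {path!r}: {exc}") from exc


def config_from_dict(payload: dict) -> RunConfig:
    if not isinstance(payload, dict):
        raise ValueError("run config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTION_TYPES.items():
        if name in payload:
            kwargs[name] = _build_section(cls, payload[name], name)
    for name in ("seed", "outdir", "sbh_factor", "resample_k"):
        if name in payload:
            kwargs[name] = payload[name]
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        try:
            payload = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ValueError(f"could not parse config {path}: {exc}") from exc
    return config_from_dict(payload)


def config_to_dict(config: RunConfig) -> dict:
    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        return obj
    return clean(dataclasses.asdict(config))


def write_config(path, config: RunConfig) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    """Stage-by-stage pipeline state over a shared output directory.

    Stages can be executed in one process (run_all) or in separate CLI
    invocations: each stage reloads its inputs from the output directory if
    they are not already in memory.
    """

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: list[dict] = []
        self.world: World | None = None
        self.truth: np.ndarray | None = None
        self.obs: pd.DataFrame | None = None
        self.fit: FitResult | None = None
        self.draws: PosteriorDraws | None = None
        self.data: ModelData | None = None

    # -- manifest -----------------------------------------------------------

    def _record(self, stage: str, *paths) -> None:
        for p in paths:
            p = Path(p)
            self.manifest.append({
                "stage": stage, "file": p.name, "sha256": _sha256(p),
            })

    def write_manifest(self) -> Path:
        path = self.outdir / "manifest.json"
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"artifacts": self.manifest}, fh, indent=1, sort_keys=True)
        return path

    # -- loaders for stage-by-stage execution --------------------------------

    def _truth_params(self, world: World, z: np.ndarray) -> ModelParams:
        t = self.config.truth
        rng = np.random.default_rng(derive_seed(self.config.seed, "country-effects"))
        nu_c = rng.normal(0.0, t.sigma_c, size=world.admin.n_countries)
        return ModelParams(
            beta0=t.beta0, beta_age=np.array(t.beta_age),
            beta_cov=np.array(t.beta_cov), beta_time=t.beta_time,
            nu_country=nu_c, sigma_c=t.sigma_c,
            nu_survey=np.zeros(0), sigma_k=max(self.config.surveys.sigma_k, 1e-6),
            z=z, gp=GPHyper(t.spatial_range, t.sigma_z, t.rho_t, t.rho_a, t.smoothness),
        )

    def _ensure_world(self) -> World:
        if self.world is None:
            w = self.config.world
            grid = GridDefinition(w.origin_x, w.origin_y, w.cell_size,
                                  w.n_rows, w.n_cols, tuple(w.years))
            admin = read_admin_geojson(self.outdir / "admin.geojson", grid)
            covs = []
            for j in range(w.n_covariates):
                vals = read_raster(self.outdir / f"covariate_{j}.tif", grid)
                from .synthetic import CovariateSurface
                covs.append(CovariateSurface(f"cov{j}", grid, vals, standardized=False))
            births = read_raster(self.outdir / "population_births.tif", grid)
            under5 = read_raster(self.outdir / "population_under5.tif", grid)
            from .synthetic import PopulationSurface
            self.world = World(grid, AgeBinScheme.default(), covs,
                               PopulationSurface(grid, births, under5), admin)
        return self.world

    def _ensure_obs(self) -> pd.DataFrame:
        if self.obs is None:
            self.obs = histories.read_observations(self.outdir / "observations.csv")
        return self.obs

    def _ensure_fit_outputs(self):
        if self.draws is None:
            world = self._ensure_world()
            obs = self._ensure_obs()
            self.data = ModelData.from_world(obs, world)
            payload = np.load(self.outdir / "draws.npz")
            from .model import ParamLayout
            layout = ParamLayout(
                p=int(payload["p"]), n_countries=int(payload["n_countries"]),
                n_surveys=int(payload["n_surveys"]), n_years=world.grid.n_years,
                n_cells=world.grid.n_cells, smoothness=float(payload["smoothness"]),
            )
            self.draws = PosteriorDraws(
                payload["draws"], layout, payload["mode_vec"], int(payload["seed"])
            )
        return self.draws

    # -- stages ---------------------------------------------------------------

    def simulate(self) -> list[Path]:
        cfg = self.config
        t0 = time.time()
        world = simulate_world(cfg.world, derive_seed(cfg.seed, "world"))
        z = simulate_gp_field(
            world.grid, world.age_scheme,
            GPHyper(cfg.truth.spatial_range, cfg.truth.sigma_z,
                    cfg.truth.rho_t, cfg.truth.rho_a, cfg.truth.smoothness),
            derive_seed(cfg.seed, "gp-field"),
        )
        truth_params = self._truth_params(world, z)
        truth = simulate_true_mortality(truth_params, world)
        surveys = simulate_surveys(truth, world, cfg.surveys,
                                   derive_seed(cfg.seed, "surveys"))
        self.world, self.truth, self._surveys = world, truth, surveys

        out = self.outdir
        paths = []
        for j, cov in enumerate(world.covariates):
            p = out / f"covariate_{j}.tif"
            write_raster(p, world.grid, cov.values)
            paths.append(p)
        write_raster(out / "population_births.tif", world.grid,
                     world.population.live_births)
        write_raster(out / "population_under5.tif", world.grid,
                     world.population.under5)
        write_admin_geojson(out / "admin.geojson", world.admin)
        np.savez_compressed(out / "truth_cube.npz", p_bins=truth,
                            nu_country=truth_params.nu_country, z=z)
        surveys.children.to_csv(out / "children.csv", index=False)
        surveys.clusters.to_csv(out / "clusters.csv", index=False)
        surveys.survey_bias.to_csv(out / "survey_bias.csv", index=False)
        if not surveys.sbh_observations.empty:
            surveys.sbh_observations.to_csv(out / "sbh_observations.csv", index=False)
            paths.append(out / "sbh_observations.csv")

        # national reference envelope from the truth field (stands in for the
        # vital-registration-informed national series real runs calibrate to)
        ref_rows = []
        births = world.population.live_births
        country_of_cell = world.admin.country_of_cell
        truth4 = truth[None, ...]
        for m, upto in MEASURE_BINS.items():
            q = compose_mortality(truth4, upto)[0]   # (T, S)
            for ci, cid in enumerate(world.admin.unit_ids(0)):
                cells = np.flatnonzero(country_of_cell == ci)
                w = births[:, cells]
                agg = (q[:, cells] * w).sum(axis=1) / w.sum(axis=1)
                for ti, year in enumerate(world.grid.years):
                    ref_rows.append((cid, year, m, float(agg[ti])))
        pd.DataFrame(ref_rows, columns=["country_id", "year", "measure", "value"]) \
            .to_csv(out / "reference.csv", index=False)

        paths += [out / "population_births.tif", out / "population_under5.tif",
                  out / "admin.geojson", out / "truth_cube.npz",
                  out / "children.csv", out / "clusters.csv",
                  out / "survey_bias.csv", out / "reference.csv"]
        self._record("simulate", *paths)
        logger.info("simulate stage done in %.1fs", time.time() - t0)
        return paths

    def prepare(self) -> list[Path]:
        cfg = self.config
        t0 = time.time()
        world = self._ensure_world()
        children = getattr(self, "_surveys", None)
        if children is not None:
            children_df, clusters_df = self._surveys.children, self._surveys.clusters
            sbh = self._surveys.sbh_observations
        else:
            children_df = histories.read_children(self.outdir / "children.csv")
            clusters_df = pd.read_csv(self.outdir / "clusters.csv",
                                      dtype={"polygon_id": str}, keep_default_na=True)
            clusters_df["polygon_id"] = clusters_df["polygon_id"].fillna("")
            p = self.outdir / "sbh_observations.csv"
            sbh = pd.read_csv(p) if p.exists() else pd.DataFrame()

        obs = histories.tabulate_cbh(children_df, clusters_df, world.age_scheme,
                                     world.grid.years)
        if not sbh.empty:
            sbh = sbh.copy()
            sbh["obs_id"] = np.arange(len(obs), len(obs) + len(sbh))
            obs = pd.concat([obs, sbh[histories.OBS_COLUMNS]], ignore_index=True)
        obs = histories.apply_sbh_adjustment(obs, cfg.sbh_factor)
        obs, report = histories.qc_filter(obs, world.grid.years)
        obs = resampling.resample_polygon_observations(
            obs, world.population, world.admin, world.grid,
            k_points=cfg.resample_k, seed=derive_seed(cfg.seed, "resample"),
        )
        self.obs = obs
        histories.write_observations(self.outdir / "observations.csv", obs)
        report.to_csv(self.outdir / "qc_report.csv", index=False)
        paths = [self.outdir / "observations.csv", self.outdir / "qc_report.csv"]
        self._record("prepare", *paths)
        logger.info("prepare stage done in %.1fs (%d rows)", time.time() - t0, len(obs))
        return paths

    def fit_stage(self) -> list[Path]:
        cfg = self.config
        t0 = time.time()
        world = self._ensure_world()
        obs = self._ensure_obs()
        self.data = ModelData.from_world(obs, world)
        priors = PriorSpec(
            beta_sd=cfg.model.beta_sd, sigma_c_scale=cfg.model.sigma_c_scale,
            sigma_k_scale=cfg.model.sigma_k_scale, sigma_z_scale=cfg.model.sigma_z_scale,
            log_range_sd=cfg.model.log_range_sd,
        )
        fit_cfg = FitConfig(
            maxiter=cfg.model.maxiter, gtol=cfg.model.gtol,
            estimate_hypers=cfg.model.estimate_hypers,
            outer_maxfev=cfg.model.outer_maxfev,
            smoothness=cfg.model.smoothness,
            precision_mode=cfg.model.precision_mode, dense_limit=cfg.model.dense_limit,
        )
        self.fit = fit_map(self.data, priors=priors, config=fit_cfg,
                           seed=derive_seed(cfg.seed, "fit"))
        self.draws = draw_posterior(self.fit, n_draws=cfg.model.n_draws,
                                    seed=derive_seed(cfg.seed, "draws"))

        mode = self.fit.params
        mode_payload = {
            "beta0": mode.beta0, "beta_age": mode.beta_age.tolist(),
            "beta_cov": mode.beta_cov.tolist(), "beta_time": mode.beta_time,
            "nu_country": mode.nu_country.tolist(), "sigma_c": mode.sigma_c,
            "nu_survey": mode.nu_survey.tolist(), "sigma_k": mode.sigma_k,
            "gp": {"spatial_range": mode.gp.spatial_range, "sigma_z": mode.gp.sigma_z,
                   "rho_t": mode.gp.rho_t, "rho_a": mode.gp.rho_a,
                   "smoothness": mode.gp.smoothness},
        }
        with open(self.outdir / "fit_mode.json", "w", encoding="utf-8") as fh:
            json.dump(mode_payload, fh, indent=1, sort_keys=True)
        diag = {k: v for k, v in self.fit.diagnostics.items() if k != "objective_path"}
        with open(self.outdir / "fit_diagnostics.json", "w", encoding="utf-8") as fh:
            json.dump(diag, fh, indent=1, sort_keys=True)
        np.savez_compressed(
            self.outdir / "draws.npz", draws=self.draws.draws,
            mode_vec=self.fit.vec, p=self.data.n_covariates,
            n_countries=self.data.n_countries, n_surveys=self.data.n_surveys,
            smoothness=cfg.model.smoothness, seed=self.draws.seed,
        )
        np.savez_compressed(self.outdir / "fit_z.npz", z=mode.z)
        paths = [self.outdir / n for n in
                 ("fit_mode.json", "fit_diagnostics.json", "draws.npz", "fit_z.npz")]
        self._record("fit", *paths)
        logger.info("fit stage done in %.1fs", time.time() - t0)
        return paths

    def postest_stage(self) -> list[Path]:
        cfg = self.config
        t0 = time.time()
        world = self._ensure_world()
        draws = self._ensure_fit_outputs()
        cube = predict_probability_surfaces(draws, self.data)
        measures = cube.measures()

        paths = []
        out = self.outdir
        if cfg.postest.rake:
            reference = pd.read_csv(out / "reference.csv")
            raking = rake_to_reference(measures, reference, world.population, world.admin)
            measures = raking.raked
            raking.factors.to_csv(out / "raking_factors.csv", index=False)
            paths.append(out / "raking_factors.csv")

        births = world.population.live_births
        deaths = {m: estimate_deaths(world.population, q=measures[m], mode="cohort")
                  for m in ("q_nn", "q_u5")}

        summary_frames = []
        level_aggs = {}
        for level in (1, 2):
            for m, qcube in measures.items():
                agg = aggregate_to_admin(qcube, world.admin, level, kind="rate",
                                         weights=births, measure=m)
                level_aggs[(level, m)] = agg
                summary_frames.append(agg.summary_frame())
            for m, dcube in deaths.items():
                agg = aggregate_to_admin(dcube, world.admin, level, kind="count",
                                         measure=m.replace("q_", "deaths_"))
                level_aggs[(level, m.replace("q_", "deaths_"))] = agg
                summary_frames.append(agg.summary_frame())
        admin_df = pd.concat(summary_frames, ignore_index=True)
        admin_df.to_csv(out / "admin_estimates.csv", index=False)
        paths.append(out / "admin_estimates.csv")

        ex_rows = []
        for m, thr in (("q_u5", cfg.postest.u5_threshold),
                       ("q_nn", cfg.postest.nn_threshold)):
            agg = level_aggs[(2, m)]
            prob = exceedance_probability(agg, thr, "achieve")
            for ui, uid in enumerate(agg.unit_ids):
                for ti, year in enumerate(agg.years):
                    ex_rows.append((uid, year, m, thr, prob[ui, ti],
                                    bool(prob[ui, ti] >= cfg.postest.certainty)))
        pd.DataFrame(ex_rows, columns=["unit_id", "year", "measure",
                                       "threshold_per_1000", "prob_achieve",
                                       "meets_with_certainty"]) \
            .to_csv(out / "exceedance.csv", index=False)
        paths.append(out / "exceedance.csv")

        frac = neonatal_fraction(level_aggs[(2, "deaths_nn")],
                                 level_aggs[(2, "deaths_u5")])
        agg2 = level_aggs[(2, "deaths_u5")]
        nf_rows = []
        for ui, uid in enumerate(agg2.unit_ids):
            for ti, year in enumerate(agg2.years):
                v = frac[:, ui, ti]
                v = v[np.isfinite(v)]
                if v.size == 0:
                    continue
                nf_rows.append((uid, year, float(v.mean()),
                                float(np.percentile(v, 2.5)),
                                float(np.percentile(v, 97.5))))
        pd.DataFrame(nf_rows, columns=["unit_id", "year", "mean", "lower", "upper"]) \
            .to_csv(out / "neonatal_fraction.csv", index=False)
        paths.append(out / "neonatal_fraction.csv")

        year_pair = cfg.postest.inequality_year_pair or \
            (world.grid.years[0], world.grid.years[-1])
        country_df, unit_df = inequality_metrics(
            level_aggs[(2, "q_u5")], world.admin, world.population,
            year_pair=tuple(year_pair),
        )
        country_df.to_csv(out / "inequality_country.csv", index=False)
        unit_df.to_csv(out / "inequality_units.csv", index=False)
        paths += [out / "inequality_country.csv", out / "inequality_units.csv"]

        ref_year = cfg.postest.counterfactual_reference_year or world.grid.years[0]
        cf_frames = []
        for scenario, kwargs in (
            ("best_unit", {}),
            ("threshold", {"threshold_per_1000": cfg.postest.u5_threshold}),
            ("rates_of_year", {"reference_year": ref_year}),
        ):
            cf_frames.append(counterfactual_deaths_averted(
                level_aggs[(2, "q_u5")], world.admin, world.population,
                scenario, **kwargs,
            ))
        pd.concat(cf_frames, ignore_index=True) \
            .to_csv(out / "counterfactuals.csv", index=False)
        paths.append(out / "counterfactuals.csv")

        q_u5 = measures["q_u5"]
        write_raster(out / "q_u5_mean.tif", world.grid, q_u5.mean(axis=0))
        width = np.percentile(q_u5, 97.5, axis=0) - np.percentile(q_u5, 2.5, axis=0)
        write_raster(out / "q_u5_ui_width.tif", world.grid, width)
        paths += [out / "q_u5_mean.tif", out / "q_u5_ui_width.tif"]

        self._record("postest", *paths)
        logger.info("postest stage done in %.1fs", time.time() - t0)
        return paths

    def validate_stage(self) -> list[Path]:
        from .validation import run_cross_validation

        cfg = self.config
        if not cfg.cv.enabled:
            logger.info("cross-validation disabled in config; skipping")
            return []
        t0 = time.time()
        world = self._ensure_world()
        obs = self._ensure_obs()
        data = ModelData.from_world(obs, world)
        priors = PriorSpec(
            beta_sd=cfg.model.beta_sd, sigma_c_scale=cfg.model.sigma_c_scale,
            sigma_k_scale=cfg.model.sigma_k_scale, sigma_z_scale=cfg.model.sigma_z_scale,
            log_range_sd=cfg.model.log_range_sd,
        )
        fit_cfg = FitConfig(maxiter=cfg.model.maxiter, gtol=cfg.model.gtol,
                            estimate_hypers=cfg.model.estimate_hypers,
                            outer_maxfev=cfg.model.outer_maxfev,
                            smoothness=cfg.model.smoothness,
                            dense_limit=cfg.model.dense_limit)
        result = run_cross_validation(
            data, world, k=cfg.cv.k, level=cfg.cv.level, measure=cfg.cv.measure,
            n_draws=cfg.cv.n_draws, priors=priors, fit_config=fit_cfg,
            seed=derive_seed(cfg.seed, "cv"),
        )
        out = self.outdir
        pd.DataFrame(
            [(s, f) for s, f in result.folds.assignment.items()],
            columns=["survey_id", "fold"],
        ).to_csv(out / "cv_folds.csv", index=False)
        pd.DataFrame([result.report.as_row()]).to_csv(out / "cv_report.csv", index=False)
        result.per_fold.to_csv(out / "cv_per_fold.csv", index=False)
        result.pairs.to_csv(out / "cv_pairs.csv", index=False)
        paths = [out / n for n in
                 ("cv_folds.csv", "cv_report.csv", "cv_per_fold.csv", "cv_pairs.csv")]
        self._record("validate", *paths)
        logger.info("validate stage done in %.1fs", time.time() - t0)
        return paths

    def run_all(self) -> Path:
        for stage, fn in (
            ("simulate", self.simulate), ("prepare", self.prepare),
            ("fit", self.fit_stage), ("postest", self.postest_stage),
            ("validate", self.validate_stage),
        ):
            try:
                fn()
            except Exception as exc:
                self.write_manifest()
                raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        return self.write_manifest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest mapping."""
    run = PipelineRun(config)
    manifest_path = run.run_all()
    with open(manifest_path, encoding="utf-8") as fh:
        return json.load(fh)
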