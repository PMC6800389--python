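"""Discrete-hazards geostatistical model: likelihood, MAP fit, draws, prediction.

The data are (survey, cluster, year, age-bin) rows with entrants ``n`` and
deaths ``Y`` (possibly fractional after polygon resampling / SBH
down-weighting).  Deaths follow a weighted binomial likelihood with a logit
link on the linear predictor described in :mod:`mortmap.params`; the residual
field ``Z`` carries the separable Matern x AR1 x AR1 Gaussian-process prior of
:mod:`mortmap.covariance`.

Inference is maximum a posteriori: the effect parameters (fixed effects,
country and survey effects, the full Z field) are a strictly convex problem
given hyperparameters and are profiled by quasi-Newton minimisation; the
transformed hyperparameters (log standard deviations, log spatial
length-scale, atanh AR1 correlations) maximise a Laplace-type marginal
criterion whose Occam log-determinant term keeps the problem well-posed.
Uncertainty comes from the curvature at the mode: the negative Hessian over
the effect parameters (hyperparameters plugged in) is the joint precision,
and posterior draws come from N(mode, precision^-1).

Exact objective (negative log posterior), as also re-summed term-by-term by
the test oracle:

    NLL        = - sum_i w_i [ Y_i eta_i - n_i log(1 + exp(eta_i)) ]
                 (binomial coefficient omitted: constant in P)
    beta prior =   sum_j [ beta_j^2 / (2 s^2) + log s + log(2 pi)/2 ]
    nu priors  =   sum_c [ nu_c^2 / (2 sigma_c^2) + log sigma_c + log(2 pi)/2 ]
                 (and likewise for nu_k)
    Z prior    = - log N(z; 0, sigma_z^2 * R_a (x) R_t (x) R_s)
    sd priors  =   sigma^2 / (2 scale^2) + log scale - log(2/pi)/2 - log sigma
                 (half-Normal on sigma, with the log-transform Jacobian)
    range      =   (log range - mu)^2 / (2 sd^2) + log sd + log(2 pi)/2
    rho priors = - log( (1 - rho^2) / 2 )       (Uniform(-1,1) via tanh)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.sparse.linalg import LinearOperator, cg
from scipy.special import expit

from .covariance import (
    SeparableCovariance,
    ar1_correlation,
    kron_apply,
    lengthscale_to_range,
    matern_covariance,
    matern_correlation,
    matern_dcorr_dlog_ell,
    range_factor,
    range_to_lengthscale,
    separable_gp_logpdf,
)
from .params import (
    GPHyper,
    ModelParams,
    N_AGE_BINS,
    PriorSpec,
    linear_predictor,
    time_index_centred,
)
from .postest import MortalityDrawCube
from .synthetic import AgeBinScheme, GridDefinition, World

__all__ = [
    "ar1_correlation", "matern_covariance", "separable_gp_logpdf",
    "SeparableCovariance", "GPHyper", "ModelParams", "PriorSpec",
    "ModelData", "FitConfig", "FitResult", "PosteriorDraws",
    "HazardsPosterior", "neg_log_posterior", "neg_log_likelihood",
    "fit_map", "draw_posterior", "predict_probability_surfaces",
]

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# data bundle
# ---------------------------------------------------------------------------

@dataclass
class ModelData:
    """Observations resolved against the model support.

    Every row is mapped to a grid cell (nearest centre; ties to the lower
    index), a year index, an age-bin index, a country (the cell's country)
    and a survey.  Polygon-referenced rows must be resampled to points first.
    """

    obs: pd.DataFrame
    grid: GridDefinition
    age_scheme: AgeBinScheme
    covariate_stack: np.ndarray     # (p, T, S)
    country_of_cell: np.ndarray     # (S,)
    country_ids: list[str]
    survey_ids: list[str]
    # resolved arrays
    y: np.ndarray = field(default=None, repr=False)
    n: np.ndarray = field(default=None, repr=False)
    w: np.ndarray = field(default=None, repr=False)
    a_idx: np.ndarray = field(default=None, repr=False)
    t_idx: np.ndarray = field(default=None, repr=False)
    cell_idx: np.ndarray = field(default=None, repr=False)
    c_idx: np.ndarray = field(default=None, repr=False)
    k_idx: np.ndarray = field(default=None, repr=False)
    x_obs: np.ndarray = field(default=None, repr=False)   # (n_obs, p)

    def __post_init__(self):
        obs = self.obs
        self.covariate_stack = np.asarray(self.covariate_stack, dtype=float)
        if self.covariate_stack.size and self.covariate_stack.shape[1:] != (
            self.grid.n_years, self.grid.n_cells
        ):
            raise ValueError("covariate stack does not match the grid support")
        if obs.empty:
            p = self.n_covariates
            for name in ("y", "n", "w"):
                setattr(self, name, np.zeros(0))
            for name in ("a_idx", "t_idx", "cell_idx", "c_idx", "k_idx"):
                setattr(self, name, np.zeros(0, dtype=int))
            self.x_obs = np.zeros((0, p))
            return
        has_poly = obs["polygon_id"].notna() & (obs["polygon_id"].astype(str) != "")
        if has_poly.any():
            raise ValueError(
                "observations still carry polygon references; resample them to "
                "points before model fitting"
            )
        self.y = obs["deaths"].to_numpy(dtype=float)
        self.n = obs["entrants"].to_numpy(dtype=float)
        self.w = obs["weight"].to_numpy(dtype=float)
        a = obs["age_bin"].to_numpy(dtype=int)
        if np.any((a < 1) | (a > N_AGE_BINS)):
            raise ValueError("age_bin outside 1..7")
        self.a_idx = a - 1
        self.t_idx = np.asarray(self.grid.year_index(obs["year"].to_numpy()), dtype=int)
        self.cell_idx = self.grid.cells_of_points(
            obs["x"].to_numpy(dtype=float), obs["y"].to_numpy(dtype=float)
        )
        self.c_idx = np.asarray(self.country_of_cell)[self.cell_idx]
        survey_lookup = {s: i for i, s in enumerate(self.survey_ids)}
        try:
            self.k_idx = np.array([survey_lookup[s] for s in obs["survey_id"]])
        except KeyError as exc:
            raise ValueError(f"observation references unknown survey {exc}") from exc
        # rows sharing (survey, cell, year, bin) have identical linear
        # predictors, so the weighted likelihood aggregates exactly:
        # sum w_i (Y_i eta - n_i A(eta)) = (sum w Y) eta - (sum w n) A(eta)
        T, S = self.grid.n_years, self.grid.n_cells
        key = ((self.k_idx * N_AGE_BINS + self.a_idx) * T + self.t_idx) * S + self.cell_idx
        uniq, inv = np.unique(key, return_inverse=True)
        m = uniq.size
        wy = np.bincount(inv, weights=self.w * self.y, minlength=m)
        wn = np.bincount(inv, weights=self.w * self.n, minlength=m)
        first = np.zeros(m, dtype=int)
        first[inv[::-1]] = np.arange(len(inv) - 1, -1, -1)
        self.y, self.n, self.w = wy, wn, np.ones(m)
        for name in ("a_idx", "t_idx", "cell_idx", "c_idx", "k_idx"):
            setattr(self, name, getattr(self, name)[first])
        if self.n_covariates:
            self.x_obs = self.covariate_stack[:, self.t_idx, self.cell_idx].T
        else:
            self.x_obs = np.zeros((m, 0))

    @classmethod
    def from_world(cls, obs: pd.DataFrame, world: World) -> "ModelData":
        survey_ids = sorted(obs["survey_id"].unique()) if not obs.empty else []
        return cls(
            obs=obs,
            grid=world.grid,
            age_scheme=world.age_scheme,
            covariate_stack=world.covariate_stack,
            country_of_cell=world.admin.country_of_cell,
            country_ids=world.admin.unit_ids(0),
            survey_ids=survey_ids,
        )

    def subset(self, keep_mask: np.ndarray) -> "ModelData":
        """New ModelData on the same support with a row subset (e.g. CV folds)."""
        sub = self.obs.loc[np.asarray(keep_mask)].reset_index(drop=True)
        survey_ids = sorted(sub["survey_id"].unique()) if not sub.empty else []
        return ModelData(
            obs=sub, grid=self.grid, age_scheme=self.age_scheme,
            covariate_stack=self.covariate_stack,
            country_of_cell=self.country_of_cell,
            country_ids=self.country_ids, survey_ids=survey_ids,
        )

    @property
    def n_covariates(self) -> int:
        return self.covariate_stack.shape[0] if self.covariate_stack.size else 0

    @property
    def n_countries(self) -> int:
        return len(self.country_ids)

    @property
    def n_surveys(self) -> int:
        return len(self.survey_ids)

    @property
    def n_obs(self) -> int:
        """Number of aggregated likelihood rows (see __post_init__)."""
        return 0 if self.y is None else len(self.y)

    def median_distance(self) -> float:
        d = self.grid.distances()
        off = d[np.triu_indices_from(d, k=1)]
        return float(np.median(off)) if off.size else 1.0


# ---------------------------------------------------------------------------
# parameter vector layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamLayout:
    """Slices of the packed unconstrained parameter vector.

    Order: beta0, beta_age(6), beta_cov(p), beta_time, nu_c(C), nu_k(K),
    log sigma_c, log sigma_k, log sigma_z, log ell, atanh rho_t, atanh rho_a,
    z (7*T*S, last so the non-field block is contiguous at the front).
    """

    p: int
    n_countries: int
    n_surveys: int
    n_years: int
    n_cells: int
    smoothness: float = 1.5

    @property
    def n_field(self) -> int:
        return N_AGE_BINS * self.n_years * self.n_cells

    def slices(self):
        i = 0
        def take(k):
            nonlocal i
            s = slice(i, i + k)
            i += k
            return s
        out = {
            "beta0": take(1), "beta_age": take(N_AGE_BINS - 1),
            "beta_cov": take(self.p), "beta_time": take(1),
            "nu_c": take(self.n_countries), "nu_k": take(self.n_surveys),
            "log_sigma_c": take(1), "log_sigma_k": take(1),
            "log_sigma_z": take(1), "log_ell": take(1),
            "ath_rho_t": take(1), "ath_rho_a": take(1),
            "z": take(self.n_field),
        }
        return out, i

    @property
    def dim(self) -> int:
        return self.slices()[1]

    @property
    def head_dim(self) -> int:
        """Number of non-field parameters (everything before z)."""
        return self.dim - self.n_field

    def head_names(self) -> list[str]:
        names = ["beta0"]
        names += [f"beta_age_{a}" for a in range(2, N_AGE_BINS + 1)]
        names += [f"beta_cov_{j}" for j in range(self.p)]
        names += ["beta_time"]
        names += [f"nu_c_{c}" for c in range(self.n_countries)]
        names += [f"nu_k_{k}" for k in range(self.n_surveys)]
        names += ["log_sigma_c", "log_sigma_k", "log_sigma_z", "log_ell",
                  "ath_rho_t", "ath_rho_a"]
        return names

    def pack(self, params: ModelParams) -> np.ndarray:
        sl, dim = self.slices()
        vec = np.zeros(dim)
        vec[sl["beta0"]] = params.beta0
        vec[sl["beta_age"]] = params.beta_age
        vec[sl["beta_cov"]] = params.beta_cov
        vec[sl["beta_time"]] = params.beta_time
        vec[sl["nu_c"]] = params.nu_country
        vec[sl["nu_k"]] = params.nu_survey
        vec[sl["log_sigma_c"]] = np.log(params.sigma_c)
        vec[sl["log_sigma_k"]] = np.log(params.sigma_k)
        vec[sl["log_sigma_z"]] = np.log(params.gp.sigma_z)
        vec[sl["log_ell"]] = np.log(
            range_to_lengthscale(params.gp.spatial_range, self.smoothness)
        )
        vec[sl["ath_rho_t"]] = np.arctanh(params.gp.rho_t)
        vec[sl["ath_rho_a"]] = np.arctanh(params.gp.rho_a)
        vec[sl["z"]] = params.z.ravel()
        return vec

    def unpack(self, vec: np.ndarray) -> ModelParams:
        sl, _ = self.slices()
        ell = float(np.exp(vec[sl["log_ell"]][0]))
        gp = GPHyper(
            spatial_range=lengthscale_to_range(ell, self.smoothness),
            sigma_z=float(np.exp(vec[sl["log_sigma_z"]][0])),
            rho_t=float(np.tanh(vec[sl["ath_rho_t"]][0])),
            rho_a=float(np.tanh(vec[sl["ath_rho_a"]][0])),
            smoothness=self.smoothness,
        )
        return ModelParams(
            beta0=float(vec[sl["beta0"]][0]),
            beta_age=vec[sl["beta_age"]].copy(),
            beta_cov=vec[sl["beta_cov"]].copy(),
            beta_time=float(vec[sl["beta_time"]][0]),
            nu_country=vec[sl["nu_c"]].copy(),
            sigma_c=float(np.exp(vec[sl["log_sigma_c"]][0])),
            nu_survey=vec[sl["nu_k"]].copy(),
            sigma_k=float(np.exp(vec[sl["log_sigma_k"]][0])),
            z=vec[sl["z"]].reshape(N_AGE_BINS, self.n_years, self.n_cells).copy(),
            gp=gp,
        )


# ---------------------------------------------------------------------------
# posterior object
# ---------------------------------------------------------------------------

class HazardsPosterior:
    """Negative log posterior and its analytic gradient on the packed vector."""

    def __init__(self, data: ModelData, priors: PriorSpec | None = None,
                 smoothness: float = 1.5):
        self.data = data
        self.priors = priors if priors is not None else PriorSpec()
        if self.priors.log_range_mu is None:
            self.priors = replace(self.priors, log_range_mu=np.log(data.median_distance()))
        self.layout = ParamLayout(
            p=data.n_covariates, n_countries=data.n_countries,
            n_surveys=data.n_surveys, n_years=data.grid.n_years,
            n_cells=data.grid.n_cells, smoothness=smoothness,
        )
        self.smoothness = smoothness
        self._distances = data.grid.distances()
        self._tc = time_index_centred(data.grid.n_years)
        self._tc_obs = self._tc[data.t_idx] if data.n_obs else np.zeros(0)
        # flat z index of each observation
        T, S = data.grid.n_years, data.grid.n_cells
        self._z_flat_idx = (data.a_idx * T + data.t_idx) * S + data.cell_idx
        self._factor_cache: tuple | None = None
        self._head_design: np.ndarray | None = None

    # -- factors ------------------------------------------------------------

    def _gp_factors(self, sigma_z, ell, rho_t, rho_a):
        key = (sigma_z, ell, rho_t, rho_a)
        if self._factor_cache is not None and self._factor_cache[0] == key:
            return self._factor_cache[1]
        T = self.layout.n_years
        ra = ar1_correlation(N_AGE_BINS, rho_a)
        rt = ar1_correlation(T, rho_t)
        rs = matern_correlation(self._distances, ell, self.smoothness)
        ca = cho_factor(ra, lower=True)
        ct = cho_factor(rt, lower=True)
        try:
            cs = cho_factor(rs, lower=True)
        except np.linalg.LinAlgError:
            # near-singular spatial kernel (e.g. huge length-scales): jitter
            jitter = 1e-10
            while True:
                try:
                    cs = cho_factor(rs + jitter * np.eye(rs.shape[0]), lower=True)
                    logger.warning("spatial factor needed jitter %.1e", jitter)
                    break
                except np.linalg.LinAlgError:
                    jitter *= 100.0
                    if jitter > 1.0:
                        raise
        out = (ra, rt, rs, ca, ct, cs)
        self._factor_cache = (key, out)
        return out

    # -- linear predictor at observations ------------------------------------

    def _eta_obs(self, vec):
        sl, _ = self.layout.slices()
        d = self.data
        eta = np.full(d.n_obs, vec[sl["beta0"]][0])
        age_eff = np.concatenate(([0.0], vec[sl["beta_age"]]))
        eta += age_eff[d.a_idx]
        if self.layout.p:
            eta += d.x_obs @ vec[sl["beta_cov"]]
        eta += vec[sl["beta_time"]][0] * self._tc_obs
        if self.layout.n_countries:
            eta += vec[sl["nu_c"]][d.c_idx]
        if self.layout.n_surveys:
            eta += vec[sl["nu_k"]][d.k_idx]
        eta += vec[sl["z"]][self._z_flat_idx]
        return eta

    # -- objective + gradient -------------------------------------------------

    def value_and_grad(self, vec, include_priors=True):
        sl, dim = self.layout.slices()
        d = self.data
        pr = self.priors
        grad = np.zeros(dim)

        # binomial likelihood
        eta = self._eta_obs(vec)
        if d.n_obs:
            nll = -float(np.sum(d.w * (d.y * eta - d.n * np.logaddexp(0.0, eta))))
            g_eta = -d.w * (d.y - d.n * expit(eta))
            grad[sl["beta0"]] = g_eta.sum()
            ga = np.bincount(d.a_idx, weights=g_eta, minlength=N_AGE_BINS)
            grad[sl["beta_age"]] = ga[1:]
            if self.layout.p:
                grad[sl["beta_cov"]] = d.x_obs.T @ g_eta
            grad[sl["beta_time"]] = float(g_eta @ self._tc_obs)
            if self.layout.n_countries:
                grad[sl["nu_c"]] = np.bincount(
                    d.c_idx, weights=g_eta, minlength=self.layout.n_countries
                )
            if self.layout.n_surveys:
                grad[sl["nu_k"]] = np.bincount(
                    d.k_idx, weights=g_eta, minlength=self.layout.n_surveys
                )
            grad[sl["z"]] = np.bincount(
                self._z_flat_idx, weights=g_eta, minlength=self.layout.n_field
            )
        else:
            nll = 0.0

        if not include_priors:
            return nll, grad

        value = nll

        # fixed-effect priors
        s2 = pr.beta_sd ** 2
        beta_idx = np.r_[
            np.arange(sl["beta0"].start, sl["beta0"].stop),
            np.arange(sl["beta_age"].start, sl["beta_age"].stop),
            np.arange(sl["beta_cov"].start, sl["beta_cov"].stop),
            np.arange(sl["beta_time"].start, sl["beta_time"].stop),
        ]
        b = vec[beta_idx]
        value += float(np.sum(0.5 * b * b / s2 + np.log(pr.beta_sd) + 0.5 * _LOG2PI))
        grad[beta_idx] += b / s2

        # random-effect Gaussians and half-Normal scale priors (log scale)
        for block, logsig_key, scale in (
            ("nu_c", "log_sigma_c", pr.sigma_c_scale),
            ("nu_k", "log_sigma_k", pr.sigma_k_scale),
        ):
            nu = vec[sl[block]]
            logsig = vec[sl[logsig_key]][0]
            sig = np.exp(logsig)
            m = nu.size
            q = float(nu @ nu)
            value += 0.5 * q / sig**2 + m * logsig + 0.5 * m * _LOG2PI
            grad[sl[block]] += nu / sig**2
            grad[sl[logsig_key]] += m - q / sig**2
            # half-Normal(0, scale) on sigma, with log-transform Jacobian
            value += 0.5 * sig**2 / scale**2 + np.log(scale) \
                - 0.5 * np.log(2.0 / np.pi) - logsig
            grad[sl[logsig_key]] += sig**2 / scale**2 - 1.0

        # GP prior on the field
        tau = vec[sl["log_sigma_z"]][0]
        lam = vec[sl["log_ell"]][0]
        xt = vec[sl["ath_rho_t"]][0]
        xa = vec[sl["ath_rho_a"]][0]
        sigma_z, ell = np.exp(tau), np.exp(lam)
        rho_t, rho_a = np.tanh(xt), np.tanh(xa)
        ra, rt, rs, ca, ct, cs = self._gp_factors(sigma_z, ell, rho_t, rho_a)
        T, S, N = self.layout.n_years, self.layout.n_cells, self.layout.n_field
        z = vec[sl["z"]].reshape(N_AGE_BINS, T, S)
        u = z
        for axis, cf in ((0, ca), (1, ct), (2, cs)):
            moved = np.moveaxis(u, axis, 0)
            u = np.moveaxis(
                cho_solve(cf, moved.reshape(moved.shape[0], -1)).reshape(moved.shape),
                0, axis,
            )
        quad = float(np.sum(z * u))
        logdet_r = (
            T * S * 2.0 * np.sum(np.log(np.diag(ca[0])))
            + N_AGE_BINS * S * 2.0 * np.sum(np.log(np.diag(ct[0])))
            + N_AGE_BINS * T * 2.0 * np.sum(np.log(np.diag(cs[0])))
        )
        value += 0.5 * quad / sigma_z**2 + N * tau + 0.5 * logdet_r + 0.5 * N * _LOG2PI
        grad[sl["z"]] += (u / sigma_z**2).ravel()
        grad[sl["log_sigma_z"]] += N - quad / sigma_z**2
        # half-Normal on sigma_z
        value += 0.5 * sigma_z**2 / pr.sigma_z_scale**2 + np.log(pr.sigma_z_scale) \
            - 0.5 * np.log(2.0 / np.pi) - tau
        grad[sl["log_sigma_z"]] += sigma_z**2 / pr.sigma_z_scale**2 - 1.0

        # hyperparameter derivatives via Kronecker identities
        ra_inv = cho_solve(ca, np.eye(N_AGE_BINS))
        rt_inv = cho_solve(ct, np.eye(T))
        rs_inv = cho_solve(cs, np.eye(S))

        idx_t = np.arange(T)
        abs_dt = np.abs(idx_t[:, None] - idx_t[None, :])
        drt = np.where(abs_dt > 0, abs_dt * rho_t ** np.maximum(abs_dt - 1, 0), 0.0)
        idx_a = np.arange(N_AGE_BINS)
        abs_da = np.abs(idx_a[:, None] - idx_a[None, :])
        dra = np.where(abs_da > 0, abs_da * rho_a ** np.maximum(abs_da - 1, 0), 0.0)
        drs = matern_dcorr_dlog_ell(self._distances, ell, self.smoothness)

        # rho_t
        dq = -float(np.sum(u * kron_apply((ra, drt, rs), u)))
        dld = N_AGE_BINS * S * float(np.sum(rt_inv * drt))
        grad[sl["ath_rho_t"]] += (0.5 * dq / sigma_z**2 + 0.5 * dld) * (1 - rho_t**2)
        # rho_a
        dq = -float(np.sum(u * kron_apply((dra, rt, rs), u)))
        dld = T * S * float(np.sum(ra_inv * dra))
        grad[sl["ath_rho_a"]] += (0.5 * dq / sigma_z**2 + 0.5 * dld) * (1 - rho_a**2)
        # log ell
        dq = -float(np.sum(u * kron_apply((ra, rt, drs), u)))
        dld = N_AGE_BINS * T * float(np.sum(rs_inv * drs))
        grad[sl["log_ell"]] += 0.5 * dq / sigma_z**2 + 0.5 * dld

        # log-Normal prior on the correlation-0.1 range (theta = log range)
        theta_r = lam + np.log(range_factor(self.smoothness))
        value += 0.5 * (theta_r - pr.log_range_mu) ** 2 / pr.log_range_sd**2 \
            + np.log(pr.log_range_sd) + 0.5 * _LOG2PI
        grad[sl["log_ell"]] += (theta_r - pr.log_range_mu) / pr.log_range_sd**2

        # Uniform(-1,1) priors on the AR1 correlations via tanh transform
        for key, rho in (("ath_rho_t", rho_t), ("ath_rho_a", rho_a)):
            value += -np.log(0.5 * (1.0 - rho**2))
            grad[sl[key]] += 2.0 * rho

        return value, grad

    def neg_log_posterior(self, params: ModelParams) -> float:
        return self.value_and_grad(self.layout.pack(params))[0]

    def neg_log_likelihood(self, params: ModelParams) -> float:
        return self.value_and_grad(self.layout.pack(params), include_priors=False)[0]

    # -- Hessian pieces -------------------------------------------------------

    def likelihood_weights(self, vec) -> np.ndarray:
        """Per-observation GLM curvature w * n * p * (1 - p) at ``vec``."""
        d = self.data
        if not d.n_obs:
            return np.zeros(0)
        p = expit(self._eta_obs(vec))
        return d.w * d.n * p * (1.0 - p)

    def likelihood_curvature(self, vec) -> np.ndarray:
        """Diagonal curvature scattered onto the z field."""
        if not self.data.n_obs:
            return np.zeros(self.layout.n_field)
        return np.bincount(self._z_flat_idx, weights=self.likelihood_weights(vec),
                           minlength=self.layout.n_field)

    def head_design(self) -> np.ndarray:
        """Dense design matrix of the effect head block, one row per observation.

        Columns follow the packed order: intercept, age-bin indicators (2..7),
        covariates, centred time, country indicators, survey indicators.
        """
        if self._head_design is not None:
            return self._head_design
        d = self.data
        nb = self.layout.head_dim - len(HYPER_KEYS)
        x = np.zeros((d.n_obs, nb))
        col = 0
        x[:, col] = 1.0
        col += 1
        for a in range(1, N_AGE_BINS):
            x[d.a_idx == a, col] = 1.0
            col += 1
        if self.layout.p:
            x[:, col:col + self.layout.p] = d.x_obs
            col += self.layout.p
        x[:, col] = self._tc_obs
        col += 1
        for c in range(self.layout.n_countries):
            x[d.c_idx == c, col] = 1.0
            col += 1
        for k in range(self.layout.n_surveys):
            x[d.k_idx == k, col] = 1.0
            col += 1
        self._head_design = x
        return x

    def inner_hessian_blocks(self, vec):
        """Analytic Hessian blocks over (effect head, z): (H_bb, H_bz, D_z).

        The likelihood is a weighted GLM, so the blocks are exact: X' W X plus
        diagonal prior precisions for the head, the scatter of W onto the
        field for the cross block, and the diagonal field curvature (the field
        prior K^{-1} is added by the caller).
        """
        sl, _ = self.layout.slices()
        d = self.data
        nb = self.layout.head_dim - len(HYPER_KEYS)
        x = self.head_design()
        w_lik = self.likelihood_weights(vec)
        h_bb = x.T @ (w_lik[:, None] * x) if d.n_obs else np.zeros((nb, nb))
        prior_diag = np.zeros(nb)
        n_fixed = 8 + self.layout.p
        prior_diag[:n_fixed] = 1.0 / self.priors.beta_sd**2
        sigma_c = float(np.exp(vec[sl["log_sigma_c"]][0]))
        sigma_k = float(np.exp(vec[sl["log_sigma_k"]][0]))
        i0 = n_fixed
        prior_diag[i0:i0 + self.layout.n_countries] = 1.0 / sigma_c**2
        i0 += self.layout.n_countries
        prior_diag[i0:i0 + self.layout.n_surveys] = 1.0 / sigma_k**2
        h_bb = h_bb + np.diag(prior_diag)
        h_bz = np.zeros((self.layout.n_field, nb))
        if d.n_obs:
            np.add.at(h_bz, self._z_flat_idx, w_lik[:, None] * x)
        d_z = self.likelihood_curvature(vec)
        return h_bb, h_bz.T, d_z

    def field_prior_precision_dense(self, vec) -> np.ndarray:
        """Dense K^{-1} on the field block (only for moderate supports)."""
        sl, _ = self.layout.slices()
        sigma_z = float(np.exp(vec[sl["log_sigma_z"]][0]))
        ell = float(np.exp(vec[sl["log_ell"]][0]))
        rho_t = float(np.tanh(vec[sl["ath_rho_t"]][0]))
        rho_a = float(np.tanh(vec[sl["ath_rho_a"]][0]))
        ra, rt, rs, ca, ct, cs = self._gp_factors(sigma_z, ell, rho_t, rho_a)
        ra_inv = cho_solve(ca, np.eye(ra.shape[0]))
        rt_inv = cho_solve(ct, np.eye(rt.shape[0]))
        rs_inv = cho_solve(cs, np.eye(rs.shape[0]))
        return np.kron(np.kron(ra_inv, rt_inv), rs_inv) / sigma_z**2

    def field_prior_solve_op(self, vec):
        """LinearOperator v -> (K^{-1} + D_lik) v on the field block."""
        sl, _ = self.layout.slices()
        sigma_z = float(np.exp(vec[sl["log_sigma_z"]][0]))
        ell = float(np.exp(vec[sl["log_ell"]][0]))
        rho_t = float(np.tanh(vec[sl["ath_rho_t"]][0]))
        rho_a = float(np.tanh(vec[sl["ath_rho_a"]][0]))
        ra, rt, rs, ca, ct, cs = self._gp_factors(sigma_z, ell, rho_t, rho_a)
        d_lik = self.likelihood_curvature(vec)
        shape3 = (N_AGE_BINS, self.layout.n_years, self.layout.n_cells)

        def matvec(v):
            x = v.reshape(shape3)
            out = x
            for axis, cf in ((0, ca), (1, ct), (2, cs)):
                moved = np.moveaxis(out, axis, 0)
                out = np.moveaxis(
                    cho_solve(cf, moved.reshape(moved.shape[0], -1)).reshape(moved.shape),
                    0, axis,
                )
            return (out / sigma_z**2).ravel() + d_lik * v

        def prec(v):
            # preconditioner: multiply by K (the inverse of the dominant term)
            x = v.reshape(shape3)
            return (sigma_z**2 * kron_apply((ra, rt, rs), x)).ravel()

        n = self.layout.n_field
        return (LinearOperator((n, n), matvec=matvec),
                LinearOperator((n, n), matvec=prec))


# ---------------------------------------------------------------------------
# public op wrappers (ModelParams in, scalar out)
# ---------------------------------------------------------------------------

def neg_log_posterior(params: ModelParams, data: ModelData,
                      priors: PriorSpec | None = None) -> float:
    return HazardsPosterior(data, priors, params.gp.smoothness).neg_log_posterior(params)


def neg_log_likelihood(params: ModelParams, data: ModelData) -> float:
    return HazardsPosterior(data, None, params.gp.smoothness).neg_log_likelihood(params)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

HYPER_KEYS = ("log_sigma_c", "log_sigma_k", "log_sigma_z", "log_ell",
              "ath_rho_t", "ath_rho_a")


@dataclass(frozen=True)
class FitConfig:
    """Optimizer and precision settings for MAP estimation.

    The fit splits the parameters into a strictly convex *inner* set (fixed
    effects, country/survey effects, the Z field) and the six transformed
    hyperparameters, which are estimated by maximising a Laplace-type marginal
    criterion (profiled inner mode plus half the log-determinant of the inner
    Hessian); see :func:`fit_map`.
    """

    maxiter: int = 60               # inner Newton iterations (final polish)
    ftol: float = 1e-12
    gtol: float = 1e-3              # inf-norm tolerance on the inner gradient
    grad_rtol: float = 5e-7         # ... relative to the objective magnitude
    lbfgs_memory: int = 30
    smoothness: float = 1.5
    estimate_hypers: bool = True
    outer_maxfev: int = 60          # Nelder-Mead evaluations over hypers
    outer_xatol: float = 0.03
    outer_fatol: float = 0.5
    outer_simplex_step: float = 0.8
    inner_warm_maxiter: int = 12    # inner refits inside the outer loop
    warm_gtol_factor: float = 10.0  # looser gradient tolerance for warm refits
    precision_mode: str = "auto"    # auto | dense | fixed_marginal | none
    dense_limit: int = 9000
    hyper_uncertainty: bool = True  # propagate hyperparameter uncertainty
    # the propagated subset: the field scale/length-scale dominate predictive
    # interval width at data-free cells; the AR1 correlations matter next
    hyper_uncertainty_params: tuple = ("log_sigma_z", "log_ell",
                                       "ath_rho_t", "ath_rho_a")
    hyper_fd_step: float = 0.1      # FD step on the transformed hyper scale
    hyper_fd_cross: int = 2         # cross terms only among the leading params
    hyper_fd_maxiter: int = 3       # warm inner refits inside the FD stencil
    hyper_fd_cg_maxiter: int = 60   # capped CG for those refits
    cg_tol: float = 1e-9
    cg_maxiter: int = 5000          # Schur-complement covariance solves
    cg_newton_maxiter: int = 250    # Hessian solves inside Newton steps
    # sanity box for the transformed hyperparameters in the outer search
    log_sigma_bounds: tuple = (np.log(1e-3), np.log(20.0))
    ath_rho_bounds: tuple = (-4.0, 4.0)
    log_ell_span: tuple = (1e-2, 1e4)   # multiples of the grid cell size


@dataclass
class FitResult:
    """Posterior mode, curvature and diagnostics.

    ``joint_precision`` is the negative Hessian over the effect parameters
    (fixed effects, nu_c, nu_k, z) at the mode, with hyperparameters held at
    their marginal estimates (empirical-Bayes plug-in); ``precision_index``
    gives the coordinates of the packed vector it covers.  ``head_cov`` is the
    marginal covariance of the non-field effect block.
    """

    params: ModelParams
    vec: np.ndarray
    layout: ParamLayout
    data: ModelData
    priors: PriorSpec
    joint_precision: np.ndarray | None
    precision_index: np.ndarray | None
    head_cov: np.ndarray | None
    diagnostics: dict
    # hyperparameter uncertainty (marginal-criterion curvature at the mode):
    # covariance of the propagated transformed hyperparameters, the Jacobian
    # of the profiled inner mode with respect to them, and their positions
    # within the hyperparameter block
    hyper_cov: np.ndarray | None = None
    hyper_jacobian: np.ndarray | None = None
    hyper_cols: np.ndarray | None = None

    def head_sd(self) -> np.ndarray:
        if self.head_cov is None:
            raise ValueError("no head covariance available; refit with precision")
        return np.sqrt(np.diag(self.head_cov))

    def fixed_effect_table(self) -> pd.DataFrame:
        """Mode, sd and 95% interval for the fixed effects (Gaussian approx)."""
        names = self.layout.head_names()
        sd = self.head_sd()
        est = self.vec[: len(sd)]
        n_fixed = 8 + self.layout.p
        rows = []
        for i in range(n_fixed):
            rows.append((names[i], est[i], sd[i],
                         est[i] - 1.959964 * sd[i], est[i] + 1.959964 * sd[i]))
        return pd.DataFrame(rows, columns=["name", "estimate", "sd", "lower", "upper"])


def _initial_vector(post: HazardsPosterior) -> np.ndarray:
    d, layout = post.data, post.layout
    sl, dim = layout.slices()
    vec = np.zeros(dim)
    # crude pooled per-bin hazards seed the intercept and age effects
    if d.n_obs:
        rates = np.full(N_AGE_BINS, 0.02)
        for a in range(N_AGE_BINS):
            m = d.a_idx == a
            if m.any() and d.n[m].sum() > 0:
                rates[a] = np.clip(d.y[m].sum() / d.n[m].sum(), 1e-5, 0.5)
        vec[sl["beta0"]] = np.log(rates[0] / (1 - rates[0]))
        vec[sl["beta_age"]] = np.log(rates[1:] / (1 - rates[1:])) - vec[sl["beta0"]][0]
    vec[sl["log_sigma_c"]] = np.log(0.2)
    vec[sl["log_sigma_k"]] = np.log(0.1)
    vec[sl["log_sigma_z"]] = np.log(0.3)
    vec[sl["log_ell"]] = post.priors.log_range_mu - np.log(range_factor(post.smoothness))
    vec[sl["ath_rho_t"]] = np.arctanh(0.5)
    vec[sl["ath_rho_a"]] = np.arctanh(0.5)
    return vec


def _hyper_positions(layout: ParamLayout) -> np.ndarray:
    sl, _ = layout.slices()
    return np.array([sl[k].start for k in HYPER_KEYS])


@dataclass
class _SolveReport:
    success: bool
    nit: int
    nfev: int
    fun: float
    message: str


def _inner_solve(post, vec, maxiter, cfg, gtol=None, cg_maxiter=None):
    """Inexact Newton over the convex inner set with hyperparameters pinned.

    The inner objective (binomial GLM + Gaussian priors + GP quadratic form)
    is strictly convex, so damped Newton with conjugate-gradient solves of
    the exact Hessian-vector product converges in a handful of iterations.
    The CG preconditioner is block-diagonal: a dense solve on the small
    effect head and multiplication by K on the field block.
    """
    layout = post.layout
    gtol = cfg.gtol if gtol is None else gtol
    sl, dim = layout.slices()
    nb = layout.head_dim - len(HYPER_KEYS)
    n_field = layout.n_field
    hyper_pos = _hyper_positions(layout)
    inner_idx = np.setdiff1d(np.arange(dim), hyper_pos)

    sigma_z = float(np.exp(vec[sl["log_sigma_z"]][0]))
    ell = float(np.exp(vec[sl["log_ell"]][0]))
    rho_t = float(np.tanh(vec[sl["ath_rho_t"]][0]))
    rho_a = float(np.tanh(vec[sl["ath_rho_a"]][0]))
    ra, rt, rs, ca, ct, cs = post._gp_factors(sigma_z, ell, rho_t, rho_a)
    shape3 = (N_AGE_BINS, layout.n_years, layout.n_cells)

    # Kronecker eigendecompositions: used both for K^-1 products and for the
    # spectral preconditioner (K^-1 + dbar I)^-1 on the field block
    eva, qa = np.linalg.eigh(ra)
    evt, qt = np.linalg.eigh(rt)
    evs, qs = np.linalg.eigh(rs)
    eig_k = sigma_z**2 * np.einsum("a,t,s->ats", eva, evt, evs)
    eig_k = np.maximum(eig_k, 1e-300)
    qts = (qa.T, qt.T, qs.T)
    qf = (qa, qt, qs)

    def kinv(vz):
        y = kron_apply(qts, vz.reshape(shape3)) / eig_k
        return kron_apply(qf, y).ravel()

    def field_precond(vz, dbar):
        y = kron_apply(qts, vz.reshape(shape3)) / (1.0 / eig_k + dbar)
        return kron_apply(qf, y).ravel()

    d = post.data
    x_head = post.head_design()
    sl_z = sl["z"]
    path = []
    f, g = post.value_and_grad(vec)
    nfev = 1
    it = 0
    message = "converged"
    success = False
    # achievable gradient precision scales with the objective magnitude
    # (CG-truncated Newton steps cannot resolve finer than ~rel eps of f)
    tol_eff = max(gtol, cfg.grad_rtol * abs(float(f)))
    for it in range(1, maxiter + 1):
        g_inner = g[inner_idx]
        gnorm = float(np.max(np.abs(g_inner))) if inner_idx.size else 0.0
        if gnorm < tol_eff:
            success = True
            break
        # exact Hessian-vector products at the current point
        w_lik = post.likelihood_weights(vec)
        d_z = post.likelihood_curvature(vec)
        prior_diag = np.zeros(nb)
        n_fixed = 8 + layout.p
        prior_diag[:n_fixed] = 1.0 / post.priors.beta_sd**2
        sigma_c = float(np.exp(vec[sl["log_sigma_c"]][0]))
        sigma_k = float(np.exp(vec[sl["log_sigma_k"]][0]))
        prior_diag[n_fixed:n_fixed + layout.n_countries] = 1.0 / sigma_c**2
        prior_diag[n_fixed + layout.n_countries:] = 1.0 / sigma_k**2
        if d.n_obs:
            h_bb = x_head.T @ (w_lik[:, None] * x_head) + np.diag(prior_diag)
        else:
            h_bb = np.diag(prior_diag)
        bb_chol = cho_factor(h_bb, lower=True, check_finite=False)

        def matvec(v):
            vb, vz = v[:nb], v[nb:]
            out_b = prior_diag * vb
            out_z = kinv(vz) + d_z * vz
            if d.n_obs:
                eta_dir = x_head @ vb + vz[post._z_flat_idx]
                w_dir = w_lik * eta_dir
                out_b += x_head.T @ w_dir
                out_z += np.bincount(post._z_flat_idx, weights=w_dir,
                                     minlength=n_field)
            return np.concatenate([out_b, out_z])

        dbar = float(d_z.mean())

        def precond(v):
            vb, vz = v[:nb], v[nb:]
            return np.concatenate([
                cho_solve(bb_chol, vb, check_finite=False),
                field_precond(vz, dbar),
            ])

        n_in = nb + n_field
        op = LinearOperator((n_in, n_in), matvec=matvec)
        pre = LinearOperator((n_in, n_in), matvec=precond)
        forcing = min(0.1, np.sqrt(gnorm / (1.0 + gnorm)))
        step, info = cg(op, -g_inner, M=pre, rtol=max(cfg.cg_tol, forcing * 1e-2),
                        maxiter=cg_maxiter or cfg.cg_newton_maxiter)
        descent = float(step @ g_inner)
        if descent >= 0:
            step = -g_inner
            descent = float(step @ g_inner)
        alpha = 1.0
        accepted = False
        for _ in range(30):
            trial = vec.copy()
            trial[inner_idx] += alpha * step
            f_try, g_try = post.value_and_grad(trial)
            nfev += 1
            if np.isfinite(f_try) and f_try <= f + 1e-4 * alpha * descent:
                vec, f, g = trial, f_try, g_try
                accepted = True
                break
            alpha *= 0.5
        path.append(f)
        if not accepted:
            gnorm = float(np.max(np.abs(g[inner_idx]))) if inner_idx.size else 0.0
            success = gnorm < tol_eff
            message = "converged" if success else "line search failed to make progress"
            break
    else:
        gnorm = float(np.max(np.abs(g[inner_idx]))) if inner_idx.size else 0.0
        success = gnorm < tol_eff
        message = "converged" if success else "maximum Newton iterations reached"
    report = _SolveReport(success=success, nit=it, nfev=nfev, fun=float(f),
                          message=message)
    return vec, report, path


class _MarginalCriterion:
    """Laplace/Occam criterion for the hyperparameters.

    criterion(theta) = NLP(theta, inner mode) + 0.5 log|H_inner|.  The field
    block log|K^-1 + D| is evaluated exactly for a rank-1 Kronecker-separable
    surrogate of the likelihood curvature diagonal D (curvature factorises
    well over age x year x cell because it is entrants x p(1-p)), via small
    per-factor eigenproblems; the nu blocks use their exact diagonal
    curvature.  The constant -(n_inner/2) log 2pi is dropped.  This Occam
    term is what keeps hyperparameter estimation well-posed: it exactly
    offsets the degenerate |K| -> 0 ridges of the fully joint criterion.
    """

    def __init__(self, post: HazardsPosterior, cfg: FitConfig):
        self.post = post
        self.cfg = cfg
        self.layout = post.layout
        self.hyper_pos = _hyper_positions(self.layout)
        self.n_eval = 0

    def logdet_correction(self, vec) -> float:
        post, layout = self.post, self.layout
        sl, _ = layout.slices()
        sigma_z = float(np.exp(vec[sl["log_sigma_z"]][0]))
        ell = float(np.exp(vec[sl["log_ell"]][0]))
        rho_t = float(np.tanh(vec[sl["ath_rho_t"]][0]))
        rho_a = float(np.tanh(vec[sl["ath_rho_a"]][0]))
        ra, rt, rs, *_ = post._gp_factors(sigma_z, ell, rho_t, rho_a)
        la = np.linalg.eigvalsh(ra)
        lt = np.linalg.eigvalsh(rt)
        ls = np.linalg.eigvalsh(rs)
        eig_k = sigma_z**2 * np.einsum("a,t,s->ats", la, lt, ls).ravel()
        eig_k = np.maximum(eig_k, 1e-300)
        d_lik = post.likelihood_curvature(vec).reshape(
            N_AGE_BINS, layout.n_years, layout.n_cells
        )
        d_mean = float(d_lik.mean())
        if d_mean > 0:
            # log|K^-1 + D| for the separable surrogate D ~ da (x) dt (x) ds:
            # -log|K| + sum log(1 + alpha_i beta_j gamma_k), with the factor
            # spectra of sqrt(d) R sqrt(d) (sigma_z^2 on the spatial factor)
            da = d_lik.mean(axis=(1, 2))
            dt = d_lik.mean(axis=(0, 2))
            ds = d_lik.mean(axis=(0, 1))
            alpha = np.linalg.eigvalsh(np.sqrt(da)[:, None] * ra * np.sqrt(da)[None, :])
            beta = np.linalg.eigvalsh(np.sqrt(dt)[:, None] * rt * np.sqrt(dt)[None, :])
            gamma = np.linalg.eigvalsh(
                sigma_z**2 * np.sqrt(ds)[:, None] * rs * np.sqrt(ds)[None, :]
            )
            prod = np.einsum("a,t,s->ats", alpha, beta, gamma).ravel() / d_mean**2
            z_term = float(-np.sum(np.log(eig_k))
                           + np.sum(np.log1p(np.maximum(prod, 0.0))))
        else:
            z_term = float(-np.sum(np.log(eig_k)))
        # exact diagonal curvature of the nu blocks
        w_lik = post.likelihood_weights(vec)
        sigma_c = float(np.exp(vec[sl["log_sigma_c"]][0]))
        sigma_k = float(np.exp(vec[sl["log_sigma_k"]][0]))
        c_term = k_term = 0.0
        if layout.n_countries:
            s_c = np.zeros(layout.n_countries)
            np.add.at(s_c, post.data.c_idx, w_lik)
            c_term = float(np.sum(np.log(1.0 / sigma_c**2 + s_c)))
        if layout.n_surveys:
            s_k = np.zeros(layout.n_surveys)
            np.add.at(s_k, post.data.k_idx, w_lik)
            k_term = float(np.sum(np.log(1.0 / sigma_k**2 + s_k)))
        return 0.5 * (z_term + c_term + k_term)

    def in_box(self, theta) -> bool:
        cfg = self.cfg
        lo_s, hi_s = cfg.log_sigma_bounds
        if np.any(theta[:3] < lo_s) or np.any(theta[:3] > hi_s):
            return False
        cell = self.post.data.grid.cell_size
        if not np.log(cell * cfg.log_ell_span[0]) <= theta[3] <= \
               np.log(cell * cfg.log_ell_span[1]):
            return False
        lo_r, hi_r = cfg.ath_rho_bounds
        return bool(np.all(theta[4:] >= lo_r) and np.all(theta[4:] <= hi_r))

    def make_objective(self, vec0):
        state = {"vec": vec0.copy(), "best": (np.inf, vec0.copy())}

        def objective(theta):
            self.n_eval += 1
            if not self.in_box(theta):
                return 1e12 + float(np.sum(theta**2))
            vec = state["vec"].copy()
            vec[self.hyper_pos] = theta
            vec, res, _ = _inner_solve(
                self.post, vec, self.cfg.inner_warm_maxiter, self.cfg,
                gtol=self.cfg.gtol * self.cfg.warm_gtol_factor,
            )
            state["vec"] = vec
            value = float(res.fun) + self.logdet_correction(vec)
            if value < state["best"][0]:
                state["best"] = (value, vec.copy())
            return value

        return objective, state


def _chol_precision(H, label="joint precision"):
    scale = float(np.mean(np.diag(H)))
    jitter = 0.0
    for _ in range(9):
        try:
            L = cholesky(H + jitter * np.eye(H.shape[0]), lower=True)
            if jitter:
                logger.warning("%s required jitter %.3e", label, jitter)
            return L, jitter
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-10 * max(scale, 1.0))
    raise np.linalg.LinAlgError(
        f"{label} is not positive definite; the mode may not have converged "
        "(try more iterations or stronger priors)"
    )


def _dense_inner_precision(post: HazardsPosterior, vec):
    """Analytic negative Hessian over (effects, z) with hypers plugged in."""
    h_bb, h_bz, d_z = post.inner_hessian_blocks(vec)
    nb = h_bb.shape[0]
    n = nb + post.layout.n_field
    H = np.zeros((n, n))
    H[:nb, :nb] = h_bb
    H[:nb, nb:] = h_bz
    H[nb:, :nb] = h_bz.T
    H[nb:, nb:] = post.field_prior_precision_dense(vec)
    H[np.arange(nb, n), np.arange(nb, n)] += d_z
    return 0.5 * (H + H.T)


def _head_cov_schur(post: HazardsPosterior, vec, cfg: FitConfig):
    """Exact effect-head marginal covariance via Schur complement + CG solves."""
    h_bb, h_bz, _ = post.inner_hessian_blocks(vec)
    nb = h_bb.shape[0]
    op, prec = post.field_prior_solve_op(vec)
    w = np.zeros((post.layout.n_field, nb))
    for j in range(nb):
        sol, info = cg(op, h_bz[j], M=prec, rtol=cfg.cg_tol, maxiter=cfg.cg_maxiter)
        if info != 0:
            logger.warning("CG solve for head column %d did not fully converge", j)
        w[:, j] = sol
    schur = h_bb - h_bz @ w
    schur = 0.5 * (schur + schur.T)
    L, _ = _chol_precision(schur, "head-block Schur complement")
    return cho_solve((L, True), np.eye(nb))


def _hyper_curvature(post, vec, cfg):
    """FD Hessian of the marginal criterion over the propagated
    hyperparameters, plus the Jacobian of the profiled inner mode.

    Only the subset in ``cfg.hyper_uncertainty_params`` is propagated (by
    default the field scale and spatial length-scale, which dominate
    predictive interval width at data-free cells).  Returns
    ``(hyper_cov, jacobian, columns)`` where ``jacobian[:, j]`` is the
    derivative of the inner mode with respect to propagated hyperparameter j
    and ``columns`` are their positions within the hyperparameter block.
    The curvature uses warm, loosely converged inner refits; FD noise is
    handled by an eigenvalue floor before inversion.
    """
    crit = _MarginalCriterion(post, cfg)
    hyper_pos = crit.hyper_pos
    inner_idx = np.setdiff1d(np.arange(post.layout.dim), hyper_pos)
    cols = [list(HYPER_KEYS).index(k) for k in cfg.hyper_uncertainty_params]
    h = cfg.hyper_fd_step
    theta0 = vec[hyper_pos]
    m = len(cols)

    def evaluate(theta):
        v = vec.copy()
        v[hyper_pos] = theta
        v, res, _ = _inner_solve(post, v, cfg.hyper_fd_maxiter, cfg,
                                 gtol=cfg.gtol * 100.0,
                                 cg_maxiter=cfg.hyper_fd_cg_maxiter)
        return float(res.fun) + crit.logdet_correction(v), v

    f0, _ = evaluate(theta0)
    f_plus, f_minus = np.zeros(m), np.zeros(m)
    modes_plus, modes_minus = [], []
    for j, cj in enumerate(cols):
        tp, tm = theta0.copy(), theta0.copy()
        tp[cj] += h
        tm[cj] -= h
        f_plus[j], vp = evaluate(tp)
        f_minus[j], vm = evaluate(tm)
        modes_plus.append(vp[inner_idx])
        modes_minus.append(vm[inner_idx])
    hess = np.zeros((m, m))
    for j in range(m):
        hess[j, j] = (f_plus[j] - 2.0 * f0 + f_minus[j]) / h**2
    n_cross = min(cfg.hyper_fd_cross, m)
    for i in range(n_cross):
        for j in range(i + 1, n_cross):
            stencil = {}
            for si, sj in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                t = theta0.copy()
                t[cols[i]] += si * h
                t[cols[j]] += sj * h
                stencil[(si, sj)], _ = evaluate(t)
            hess[i, j] = hess[j, i] = (
                stencil[(1, 1)] - stencil[(1, -1)]
                - stencil[(-1, 1)] + stencil[(-1, -1)]
            ) / (4.0 * h**2)
    # FD noise can break positive definiteness: floor the spectrum
    w, q = np.linalg.eigh(0.5 * (hess + hess.T))
    floor = max(1e-6 * max(w.max(), 1.0), 1e-8)
    w = np.maximum(w, floor)
    hyper_cov = (q / w) @ q.T
    jac = np.stack(
        [(p - mn) / (2.0 * h) for p, mn in zip(modes_plus, modes_minus)], axis=1
    )
    return hyper_cov, jac, np.array(cols)


def fit_map(
    data: ModelData,
    priors: PriorSpec | None = None,
    config: FitConfig | None = None,
    seed: int = 0,
    init: ModelParams | None = None,
) -> FitResult:
    """Maximum a posteriori fit of the discrete-hazards model.

    Two nested problems: the *inner* parameters (all fixed effects, country
    and survey effects, the Z field) form a strictly convex objective given
    hyperparameters and are minimised by L-BFGS with analytic gradients; the
    six transformed hyperparameters (log sds, log spatial length-scale, atanh
    AR1 correlations) maximise a Laplace-type marginal criterion — the
    profiled objective plus half the log-determinant of the inner Hessian —
    searched by Nelder-Mead with warm-started inner refits.  (A fully joint
    mode over hyperparameters is degenerate: the prior log-determinant
    diverges along |rho| -> 1 / range -> inf, so the Occam term is what makes
    hyperparameter estimation well-posed.)

    Uncertainty: the joint precision is the analytic negative Hessian over
    the effect parameters at the mode with hyperparameters plugged in
    (empirical Bayes); it is positive definite by convexity.  For large
    fields the dense matrix is replaced by the exact head-block marginal
    covariance via a Kronecker-structured Schur complement
    (``precision_mode='fixed_marginal'``).

    Non-convergence is flagged in diagnostics, not raised.  The fit is
    deterministic; ``seed`` is accepted for interface symmetry.
    """
    cfg = config or FitConfig()
    post = HazardsPosterior(data, priors, cfg.smoothness)
    layout = post.layout
    vec = layout.pack(init) if init is not None else _initial_vector(post)
    f0, _ = post.value_and_grad(vec)
    if not np.isfinite(f0):
        raise ValueError("objective not finite at the initial point")

    # phase 1: convex inner fit at the initial hyperparameters
    vec, res, _ = _inner_solve(post, vec, cfg.maxiter, cfg)

    outer_nfev = 0
    if cfg.estimate_hypers:
        crit = _MarginalCriterion(post, cfg)
        objective, state = crit.make_objective(vec)
        theta0 = vec[crit.hyper_pos]
        # a wide initial simplex matters: the criterion lives on log/atanh
        # scales and the default 5% perturbations explore far too little
        simplex = np.vstack([theta0] + [theta0 + cfg.outer_simplex_step * e
                                        for e in np.eye(len(theta0))])
        from scipy.optimize import minimize as _min
        _min(objective, theta0, method="Nelder-Mead",
             options={"maxfev": cfg.outer_maxfev, "xatol": cfg.outer_xatol,
                      "fatol": cfg.outer_fatol, "initial_simplex": simplex})
        outer_nfev = crit.n_eval
        vec = state["best"][1]

    # final polish of the inner problem at the selected hyperparameters
    vec, res, path = _inner_solve(post, vec, cfg.maxiter, cfg)
    value, grad = post.value_and_grad(vec)
    inner_idx = np.setdiff1d(np.arange(layout.dim), _hyper_positions(layout))
    grad_norm = float(np.max(np.abs(grad[inner_idx]))) if inner_idx.size else 0.0
    converged = bool(res.success)
    if not converged:
        logger.warning("MAP optimisation flagged non-convergence: %s", res.message)

    mode = layout.unpack(vec)
    precision_mode = cfg.precision_mode
    if precision_mode == "auto":
        precision_mode = "dense" if layout.dim <= cfg.dense_limit else "fixed_marginal"

    joint_precision, head_cov, precision_index = None, None, None
    if precision_mode == "dense":
        if layout.dim > cfg.dense_limit:
            raise ValueError(
                f"dense precision requested for dimension {layout.dim} above the "
                f"limit {cfg.dense_limit}; use precision_mode='fixed_marginal'"
            )
        joint_precision = _dense_inner_precision(post, vec)
        precision_index = inner_idx
        nb = layout.head_dim - len(HYPER_KEYS)
        L, _ = _chol_precision(joint_precision)
        cols = np.zeros((joint_precision.shape[0], nb))
        cols[:nb, :] = np.eye(nb)
        sol = cho_solve((L, True), cols)
        head_cov = 0.5 * (sol[:nb, :] + sol[:nb, :].T)
    elif precision_mode == "fixed_marginal":
        head_cov = _head_cov_schur(post, vec, cfg)
    elif precision_mode != "none":
        raise ValueError(f"unknown precision_mode {precision_mode!r}")

    hyper_cov, hyper_jac, hyper_cols = None, None, None
    if cfg.estimate_hypers and cfg.hyper_uncertainty and data.n_obs:
        hyper_cov, hyper_jac, hyper_cols = _hyper_curvature(post, vec, cfg)

    diagnostics = {
        "converged": converged, "n_iterations": int(res.nit),
        "n_evaluations": int(res.nfev), "outer_evaluations": outer_nfev,
        "grad_norm": grad_norm, "neg_log_posterior": float(value),
        "objective_path": path, "precision_mode": precision_mode,
        "message": str(res.message),
    }
    logger.info(
        "MAP fit: %d inner iterations (final), %d outer evaluations, nlp=%.3f, "
        "grad max %.2e, converged=%s",
        res.nit, outer_nfev, value, grad_norm, converged,
    )
    return FitResult(mode, vec, layout, data, post.priors,
                     joint_precision, precision_index, head_cov, diagnostics,
                     hyper_cov=hyper_cov, hyper_jacobian=hyper_jac,
                     hyper_cols=hyper_cols)


# ---------------------------------------------------------------------------
# posterior draws and prediction
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Draws from the multivariate-normal approximation at the mode.

    Hyperparameter coordinates are held at their marginal estimates in every
    draw (empirical-Bayes plug-in).
    """

    draws: np.ndarray          # (D, dim)
    layout: ParamLayout
    mode_vec: np.ndarray
    seed: int

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def unpack(self, i: int) -> ModelParams:
        return self.layout.unpack(self.draws[i])

    def block(self, name: str) -> np.ndarray:
        sl, _ = self.layout.slices()
        return self.draws[:, sl[name]]


def draw_posterior(fit: FitResult, n_draws: int = 1000, seed: int = 0) -> PosteriorDraws:
    """Draw from the Gaussian approximation at the mode.

    Effect parameters are drawn from N(mode, precision^-1) via a precision
    Cholesky solve.  When the fit carries hyperparameter curvature, each draw
    also perturbs the six transformed hyperparameters from their marginal
    Gaussian approximation and propagates the perturbation to the effects:
    a first-order mean shift through the profiled-mode Jacobian, and a
    rescaling of the field deviation by the drawn sigma_z (the conditional
    field dispersion scales with the prior sd where data are thin).
    """
    if n_draws < 2:
        raise ValueError("at least 2 draws are required")
    if fit.joint_precision is None:
        raise ValueError(
            "fit carries no joint precision (precision_mode was "
            f"{fit.diagnostics.get('precision_mode')!r}); refit with "
            "precision_mode='dense' to enable posterior draws"
        )
    L, _ = _chol_precision(fit.joint_precision)
    rng = np.random.default_rng(seed)
    n_inner = fit.joint_precision.shape[0]
    eps = rng.standard_normal((n_inner, n_draws))
    dev = solve_triangular(L, eps, lower=True, trans="T").T   # (D, n_inner)
    draws = np.tile(fit.vec, (n_draws, 1))
    if fit.hyper_cov is not None:
        hyper_pos = _hyper_positions(fit.layout)[fit.hyper_cols]
        l_h = cholesky(fit.hyper_cov, lower=True)
        d_theta = (l_h @ rng.standard_normal((len(hyper_pos), n_draws))).T
        draws[:, hyper_pos] += d_theta
        if fit.hyper_jacobian is not None:
            draws[:, fit.precision_index] += d_theta @ fit.hyper_jacobian.T
        # scale the field deviation by the drawn sigma_z, if propagated
        tau_col = list(HYPER_KEYS).index("log_sigma_z")
        if tau_col in fit.hyper_cols:
            j = int(np.flatnonzero(fit.hyper_cols == tau_col)[0])
            nb = fit.layout.head_dim - len(HYPER_KEYS)
            dev[:, nb:] *= np.exp(d_theta[:, j])[:, None]
    draws[:, fit.precision_index] += dev
    if not np.all(np.isfinite(draws)):
        raise FloatingPointError("non-finite posterior draws")
    return PosteriorDraws(draws, fit.layout, fit.vec.copy(), seed)


def predict_probability_surfaces(
    draws: PosteriorDraws,
    data: ModelData,
) -> MortalityDrawCube:
    """Per-draw bin probability cubes P[d, a, t, s]; survey effects excluded.

    The country effect of each cell's country is included; the data-source
    effect is an attribute of observations, not of places, and never enters
    prediction.
    """
    layout = draws.layout
    T, S, p = layout.n_years, layout.n_cells, layout.p
    country = np.asarray(data.country_of_cell)
    if country.shape != (S,) or np.any(country < 0):
        raise ValueError("every cell needs a country assignment")
    tc = time_index_centred(T)

    beta0 = draws.block("beta0")[:, 0]
    beta_age = draws.block("beta_age")
    beta_cov = draws.block("beta_cov")
    beta_time = draws.block("beta_time")[:, 0]
    nu_c = draws.block("nu_c")
    z = draws.block("z").reshape(-1, N_AGE_BINS, T, S)

    age_eff = np.concatenate([np.zeros((draws.n_draws, 1)), beta_age], axis=1)
    eta = (
        beta0[:, None, None, None]
        + age_eff[:, :, None, None]
        + beta_time[:, None, None, None] * tc[None, None, :, None]
        + nu_c[:, country][:, None, None, :]
        + z
    )
    if p:
        cov_term = np.tensordot(beta_cov, data.covariate_stack, axes=(1, 0))  # (D,T,S)
        eta = eta + cov_term[:, None, :, :]
    pcube = expit(eta)
    np.clip(pcube, 1e-12, 1.0 - 1e-12, out=pcube)
    return MortalityDrawCube(pcube, data.grid, data.age_scheme)
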