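"""Parameter containers and the shared linear predictor.

The discrete-hazards model relates the conditional death probability in age
bin ``a``, year ``t`` and cell ``s`` to a linear predictor through a logit
link:

    logit(P[a,t,s]) = beta0 + 1{a>1} beta_age[a] + beta_cov . X[:,t,s]
                      + beta_time * t_centred + nu_country[c(s)]
                      + (nu_survey[k] during fitting only) + Z[a,t,s]

Bin 1 (month 0) is the reference age band, so ``beta_age`` has six entries
for bins 2..7.  Survey effects attach to observations, not to places, and are
therefore excluded both from the synthetic truth and from prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

N_AGE_BINS = 7


@dataclass(frozen=True)
class GPHyper:
    """Hyperparameters of the separable age x time x space residual process.

    spatial_range
        Distance (km) at which spatial correlation drops to ~0.1.
    sigma_z
        Marginal standard deviation of the field on the logit scale.
    rho_t, rho_a
        AR1 correlations across consecutive years / age bins.
    smoothness
        Matern smoothness; 1.5 by default (once-differentiable sample paths).
    """

    spatial_range: float
    sigma_z: float
    rho_t: float
    rho_a: float
    smoothness: float = 1.5

    def __post_init__(self):
        if self.spatial_range <= 0:
            raise ValueError(f"spatial_range must be > 0, got {self.spatial_range}")
        if self.sigma_z < 0:
            raise ValueError(f"sigma_z must be >= 0, got {self.sigma_z}")
        for name in ("rho_t", "rho_a"):
            v = getattr(self, name)
            if not -1 < v < 1:
                raise ValueError(f"{name} must lie in (-1, 1), got {v}")
        if self.smoothness not in (0.5, 1.5, 2.5):
            raise ValueError(f"smoothness must be 0.5, 1.5 or 2.5, got {self.smoothness}")


@dataclass
class ModelParams:
    """All fixed effects, random effects and GP hyperparameters.

    ``z`` has shape (7, T, S) on the age x year x cell support.  ``beta_age``
    holds the six deviations of bins 2..7 from the bin-1 intercept.
    """

    beta0: float
    beta_age: np.ndarray
    beta_cov: np.ndarray
    beta_time: float
    nu_country: np.ndarray
    sigma_c: float
    nu_survey: np.ndarray
    sigma_k: float
    z: np.ndarray
    gp: GPHyper

    def __post_init__(self):
        self.beta_age = np.asarray(self.beta_age, dtype=float)
        self.beta_cov = np.asarray(self.beta_cov, dtype=float)
        self.nu_country = np.asarray(self.nu_country, dtype=float)
        self.nu_survey = np.asarray(self.nu_survey, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.beta_age.shape != (N_AGE_BINS - 1,):
            raise ValueError(
                f"beta_age must have {N_AGE_BINS - 1} entries (bins 2..7), "
                f"got shape {self.beta_age.shape}"
            )
        if self.z.ndim != 3 or self.z.shape[0] != N_AGE_BINS:
            raise ValueError(f"z must have shape (7, T, S), got {self.z.shape}")
        if self.sigma_c <= 0 or self.sigma_k <= 0:
            raise ValueError("sigma_c and sigma_k must be positive")

    @property
    def n_covariates(self) -> int:
        return self.beta_cov.shape[0]

    def copy(self) -> "ModelParams":
        return replace(
            self,
            beta_age=self.beta_age.copy(),
            beta_cov=self.beta_cov.copy(),
            nu_country=self.nu_country.copy(),
            nu_survey=self.nu_survey.copy(),
            z=self.z.copy(),
        )


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative priors for MAP estimation.

    Normal(0, beta_sd^2) on every fixed effect; half-Normal(0, scale^2) on the
    standard deviations sigma_c, sigma_k, sigma_z; log-Normal on the spatial
    range (mu defaulting to the log median inter-cell distance); Uniform(-1, 1)
    on the AR1 correlations via a tanh transform.
    """

    beta_sd: float = 5.0
    sigma_c_scale: float = 1.0
    sigma_k_scale: float = 1.0
    sigma_z_scale: float = 1.0
    log_range_mu: float | None = None
    log_range_sd: float = 1.0


def time_index_centred(n_years: int) -> np.ndarray:
    """Year index centred on the middle study year (numerical conditioning)."""
    t = np.arange(n_years, dtype=float)
    return t - t.mean()


def linear_predictor(
    params: ModelParams,
    covariate_stack: np.ndarray | None,
    country_of_cell: np.ndarray,
) -> np.ndarray:
    """Logit-scale linear predictor cube of shape (7, T, S), survey effect excluded."""
    n_ages, n_years, n_cells = params.z.shape
    if covariate_stack is None:
        covariate_stack = np.zeros((0, n_years, n_cells))
    covariate_stack = np.asarray(covariate_stack, dtype=float)
    if covariate_stack.shape[0] != params.n_covariates:
        raise ValueError(
            f"{params.n_covariates} covariate effects but "
            f"{covariate_stack.shape[0]} covariate surfaces"
        )
    if covariate_stack.shape[1:] != (n_years, n_cells):
        raise ValueError(
            f"covariate stack shape {covariate_stack.shape[1:]} does not match "
            f"(T, S) = {(n_years, n_cells)}"
        )
    country_of_cell = np.asarray(country_of_cell)
    if country_of_cell.shape != (n_cells,):
        raise ValueError("country_of_cell must assign every cell to a country")

    age_effect = np.concatenate(([0.0], params.beta_age))          # (7,)
    tc = time_index_centred(n_years)
    eta = (
        params.beta0
        + age_effect[:, None, None]
        + np.tensordot(params.beta_cov, covariate_stack, axes=(0, 0))[None, :, :]
        + params.beta_time * tc[None, :, None]
        + params.nu_country[country_of_cell][None, None, :]
        + params.z
    )
    return eta


def mortality_cube(
    params: ModelParams,
    covariate_stack: np.ndarray | None,
    country_of_cell: np.ndarray,
) -> np.ndarray:
    """Conditional death probabilities P[a,t,s] = expit(linear predictor)."""
    p = expit(linear_predictor(params, covariate_stack, country_of_cell))
    # expit is strictly inside (0,1) for finite eta; guard float rounding
    return np.clip(p, 1e-15, 1.0 - 1e-15)
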