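"""Separable space-time-age covariance primitives.

The residual field of the discrete-hazards model is a mean-zero Gaussian
process over (age bin, year, grid cell) with a Kronecker-separable covariance

    K = sigma_z^2 * (R_a (x) R_t (x) R_s),

where ``R_a`` and ``R_t`` are AR1 correlation matrices over the 7 age bins and
the study years, and ``R_s`` is a Matern correlation matrix over inter-cell
distances.  Everything here exploits the Kronecker factorisation: the dense
``K`` is never formed for realistically sized supports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_solve, cholesky
from scipy.optimize import brentq

logger = logging.getLogger(__name__)

#: dense Kronecker products are refused above this total dimension
DENSE_KRON_LIMIT = 5000

_SQRT3 = np.sqrt(3.0)
_SQRT5 = np.sqrt(5.0)


# ---------------------------------------------------------------------------
# correlation kernels
# ---------------------------------------------------------------------------

def ar1_correlation(k: int, rho: float) -> np.ndarray:
    """AR1 correlation matrix with entries ``rho ** |i - j|``.

    Symmetric positive-definite for any ``|rho| < 1``.
    """
    if k < 1:
        raise ValueError(f"AR1 dimension must be >= 1, got {k}")
    if not np.isfinite(rho) or abs(rho) >= 1:
        raise ValueError(f"AR1 coefficient must satisfy |rho| < 1, got {rho}")
    idx = np.arange(k)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def matern_correlation(d: np.ndarray, ell: float, smoothness: float) -> np.ndarray:
    """Matern correlation at distances ``d`` with length-scale ``ell``.

    Half-integer smoothness only (0.5, 1.5, 2.5), where the kernel has the
    standard closed forms (exponential, once- and twice-differentiable).
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if ell <= 0:
        raise ValueError(f"length-scale must be positive, got {ell}")
    u = d / ell
    if smoothness == 0.5:
        return np.exp(-u)
    if smoothness == 1.5:
        s = _SQRT3 * u
        return (1.0 + s) * np.exp(-s)
    if smoothness == 2.5:
        s = _SQRT5 * u
        return (1.0 + s + s * s / 3.0) * np.exp(-s)
    raise ValueError(f"smoothness must be one of 0.5, 1.5, 2.5; got {smoothness}")


def matern_dcorr_dlog_ell(d: np.ndarray, ell: float, smoothness: float) -> np.ndarray:
    """d r(d; ell) / d log(ell) for the half-integer Matern kernels."""
    d = np.asarray(d, dtype=float)
    u = d / ell
    if smoothness == 0.5:
        return u * np.exp(-u)
    if smoothness == 1.5:
        s = _SQRT3 * u
        return s * s * np.exp(-s)
    if smoothness == 2.5:
        s = _SQRT5 * u
        return (s * s * (1.0 + s) / 3.0) * np.exp(-s)
    raise ValueError(f"smoothness must be one of 0.5, 1.5, 2.5; got {smoothness}")


_RANGE_FACTOR_CACHE: dict[float, float] = {}


def range_factor(smoothness: float) -> float:
    """Scaled distance ``u* = d/ell`` at which the Matern correlation is 0.1.

    The user-facing ``spatial_range`` is the distance at which correlation
    drops to approximately 0.1; internally the kernel uses the length-scale
    ``ell = spatial_range / range_factor(smoothness)``.
    """
    if smoothness not in _RANGE_FACTOR_CACHE:
        f = lambda u: float(matern_correlation(np.array(u), 1.0, smoothness)) - 0.1
        _RANGE_FACTOR_CACHE[smoothness] = brentq(f, 1e-9, 60.0)
    return _RANGE_FACTOR_CACHE[smoothness]


def range_to_lengthscale(spatial_range: float, smoothness: float) -> float:
    if spatial_range <= 0:
        raise ValueError(f"spatial range must be positive, got {spatial_range}")
    return spatial_range / range_factor(smoothness)


def lengthscale_to_range(ell: float, smoothness: float) -> float:
    return ell * range_factor(smoothness)


def matern_covariance(
    distances: np.ndarray,
    spatial_range: float,
    sigma: float,
    smoothness: float = 1.5,
    jitter: float = 0.0,
) -> np.ndarray:
    """Matern covariance ``sigma^2 * r(d)`` from a symmetric distance matrix.

    ``spatial_range`` follows the correlation-0.1 convention (see
    :func:`range_factor`).  A diagonal jitter may be requested; additional
    jitter for positive-definiteness is the caller's concern.
    """
    distances = np.asarray(distances, dtype=float)
    if distances.ndim != 2 or distances.shape[0] != distances.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(distances, distances.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(distances) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    ell = range_to_lengthscale(spatial_range, smoothness)
    cov = sigma * sigma * matern_correlation(distances, ell, smoothness)
    if jitter:
        cov = cov + jitter * np.eye(cov.shape[0])
    return cov


def chol_with_jitter(mat: np.ndarray, label: str = "matrix") -> tuple[np.ndarray, float]:
    """Lower Cholesky factor, escalating a tiny diagonal jitter if needed."""
    scale = float(np.mean(np.diag(mat)))
    jitter = 0.0
    for _ in range(8):
        try:
            return cholesky(mat + jitter * np.eye(mat.shape[0]), lower=True), jitter
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-12 * max(scale, 1.0))
            logger.warning("%s not positive definite; adding jitter %.3e", label, jitter)
    raise np.linalg.LinAlgError(f"{label} is not positive definite even with jitter")


# ---------------------------------------------------------------------------
# Kronecker algebra on (A, T, S)-shaped fields
# ---------------------------------------------------------------------------

def kron_apply(mats: tuple[np.ndarray, np.ndarray, np.ndarray], x: np.ndarray) -> np.ndarray:
    """Apply ``(Ma (x) Mt (x) Ms)`` to a field of shape (A, T, S)."""
    ma, mt, ms = mats
    y = np.tensordot(ma, x, axes=(1, 0))                      # (A, T, S)
    y = np.moveaxis(np.tensordot(mt, y, axes=(1, 1)), 0, 1)   # (A, T, S)
    y = np.moveaxis(np.tensordot(ms, y, axes=(1, 2)), 0, 2)   # (A, T, S)
    return y


def kron_chol_solve(
    chols: tuple[np.ndarray, np.ndarray, np.ndarray], x: np.ndarray
) -> np.ndarray:
    """Solve ``(Ma (x) Mt (x) Ms) y = x`` given lower Cholesky factors."""
    out = x
    for axis, lo in enumerate(chols):
        moved = np.moveaxis(out, axis, 0)
        flat = moved.reshape(lo.shape[0], -1)
        sol = cho_solve((lo, True), flat)
        out = np.moveaxis(sol.reshape(moved.shape), 0, axis)
    return out


def kron_chol_apply(
    chols: tuple[np.ndarray, np.ndarray, np.ndarray], x: np.ndarray
) -> np.ndarray:
    """Apply ``(La (x) Lt (x) Ls)`` (lower factors) to a field: K^(1/2) action."""
    out = x
    for axis, lo in enumerate(chols):
        moved = np.moveaxis(out, axis, 0)
        flat = moved.reshape(lo.shape[0], -1)
        out = np.moveaxis((lo @ flat).reshape(moved.shape), 0, axis)
    return out


@dataclass
class SeparableCovariance:
    """Kronecker-structured covariance ``K = Sigma_a (x) Sigma_t (x) Sigma_s``.

    ``sigma_a`` and ``sigma_t`` are AR1 correlation matrices; ``sigma_s`` is a
    Matern covariance carrying the marginal variance ``sigma_z^2``.  The dense
    ``K`` is only ever materialised for tiny test instances.
    """

    sigma_a: np.ndarray
    sigma_t: np.ndarray
    sigma_s: np.ndarray
    _chols: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        for name, m in (("sigma_a", self.sigma_a), ("sigma_t", self.sigma_t),
                        ("sigma_s", self.sigma_s)):
            m = np.asarray(m, dtype=float)
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ValueError(f"{name} must be square")
            if not np.allclose(m, m.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
            setattr(self, name, m)

    @classmethod
    def from_hyper(
        cls,
        distances: np.ndarray,
        n_years: int,
        hyper,
        n_ages: int = 7,
    ) -> "SeparableCovariance":
        """Build the three factors from GP hyperparameters (see GPHyper)."""
        return cls(
            sigma_a=ar1_correlation(n_ages, hyper.rho_a),
            sigma_t=ar1_correlation(n_years, hyper.rho_t),
            sigma_s=matern_covariance(
                distances, hyper.spatial_range, hyper.sigma_z, hyper.smoothness
            ),
        )

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.sigma_a.shape[0], self.sigma_t.shape[0], self.sigma_s.shape[0])

    @property
    def dim(self) -> int:
        a, t, s = self.shape
        return a * t * s

    def chol_factors(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if self._chols is None:
            la, _ = chol_with_jitter(self.sigma_a, "Sigma_a")
            lt, _ = chol_with_jitter(self.sigma_t, "Sigma_t")
            ls, _ = chol_with_jitter(self.sigma_s, "Sigma_s")
            self._chols = (la, lt, ls)
        return self._chols

    def logdet(self) -> float:
        la, lt, ls = self.chol_factors()
        a, t, s = self.shape
        lds = [2.0 * np.sum(np.log(np.diag(l))) for l in (la, lt, ls)]
        return t * s * lds[0] + a * s * lds[1] + a * t * lds[2]

    def solve(self, z: np.ndarray) -> np.ndarray:
        """K^{-1} z for a field of shape (A, T, S)."""
        return kron_chol_solve(self.chol_factors(), z)

    def dense(self) -> np.ndarray:
        """Materialise K; refused above DENSE_KRON_LIMIT (tests only)."""
        if self.dim > DENSE_KRON_LIMIT:
            raise ValueError(
                f"refusing to materialise a dense {self.dim}x{self.dim} Kronecker "
                f"covariance (limit {DENSE_KRON_LIMIT})"
            )
        return np.kron(np.kron(self.sigma_a, self.sigma_t), self.sigma_s)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        """One mean-zero draw with covariance K, shape (A, T, S)."""
        eps = rng.standard_normal(self.shape)
        return kron_chol_apply(self.chol_factors(), eps)


def separable_gp_logpdf(z_field: np.ndarray, cov: SeparableCovariance) -> float:
    """Exact mean-zero Gaussian log-density of a field under K.

    Uses the Kronecker identities ``log|K| = TS log|Sigma_a| + AS log|Sigma_t|
    + AT log|Sigma_s|`` and per-axis Cholesky solves for the quadratic form;
    K itself is never formed.
    """
    z = np.asarray(z_field, dtype=float)
    if z.shape != cov.shape:
        if z.size != cov.dim:
            raise ValueError(
                f"field of size {z.size} does not match covariance dimension {cov.dim}"
            )
        z = z.reshape(cov.shape)
    u = cov.solve(z)
    quad = float(np.sum(z * u))
    return -0.5 * (cov.dim * np.log(2.0 * np.pi) + cov.logdet() + quad)
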