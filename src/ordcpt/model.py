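"""Cumulative logistic regression (proportional-odds) model for ordinal
time series.

The response ``Y_t`` takes ordered categories ``1..m``.  With ``q = m - 1``
thresholds ``alpha_1 < ... < alpha_q`` and a shared slope ``beta`` on a
covariate vector ``z_{t-1}`` observable before ``Y_t``, the model is

    logit P(Y_t <= j | F_{t-1}) = alpha_j + beta' z_{t-1},   j = 1..q.

Inference is by partial likelihood: the product of the one-step conditional
category probabilities.  This module provides the per-observation building
blocks (category probabilities, link-derivative and conditional-covariance
matrices, score contributions, log partial likelihood) together with
vectorized batch versions used by the fitting and testing code.

Sign convention: the linear predictor is always ``alpha_j + beta' z``.
Data generators that want minus signs on the slopes (e.g. a latent-variable
formulation ``X_t = -beta' z_{t-1} + e_t``) encode them by negating the
covariate columns they pass in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .exceptions import (
    DegenerateProbabilityError,
    InvalidInputError,
    InvalidParameterError,
)

# Category probabilities below this are treated as numerically degenerate
# inside covariance computations; the log-likelihood clips instead (see
# log_partial_likelihood) so extreme fits stay finite.
_PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class OrdinalSeries:
    """An ordinal series ``y_1..y_n`` with integer categories ``1..m``.

    The indicator representation ``Y_t = (Y_t1, ..., Y_tq)`` drops the last
    category ``m`` as reference, so a row of zeros means ``y_t = m``.
    """

    y: np.ndarray
    m: int

    def __post_init__(self):
        y = np.asarray(self.y, dtype=np.int64)
        if y.ndim != 1 or y.size < 1:
            raise InvalidInputError("y must be a non-empty 1-d integer sequence")
        if self.m < 2:
            raise InvalidInputError(f"need at least 2 categories, got m={self.m}")
        if y.min() < 1 or y.max() > self.m:
            bad = np.where((y < 1) | (y > self.m))[0]
            raise InvalidInputError(
                f"category codes outside 1..{self.m} at rows {bad[:10] + 1}"
            )
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def q(self) -> int:
        return self.m - 1

    @property
    def indicators(self) -> np.ndarray:
        """n x q matrix with ``Y_tj = 1`` iff ``y_t = j`` (category m -> zero row)."""
        ind = np.zeros((self.n, self.q))
        j = self.y - 1
        keep = j < self.q
        ind[np.nonzero(keep)[0], j[keep]] = 1.0
        return ind


@dataclass(frozen=True)
class CovariateSeries:
    """Covariate rows aligned with the response: row ``t`` pairs with ``y_t``
    and holds ``z_{t-1}``, the covariate known before ``Y_t`` is observed."""

    z: np.ndarray

    def __post_init__(self):
        z = np.atleast_2d(np.asarray(self.z, dtype=float))
        if z.size and not np.all(np.isfinite(z)):
            raise InvalidInputError("covariates must be finite")
        object.__setattr__(self, "z", z)

    @property
    def n(self) -> int:
        return self.z.shape[0]

    @property
    def d(self) -> int:
        return self.z.shape[1]

    @staticmethod
    def empty(n: int) -> "CovariateSeries":
        return CovariateSeries(np.zeros((n, 0)))


@dataclass(frozen=True)
class ModelParams:
    """theta = (alpha_1..alpha_q, beta')' with strictly ordered thresholds."""

    alpha: np.ndarray
    beta: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        beta = np.atleast_1d(np.asarray(self.beta, dtype=float)) if np.size(self.beta) else np.zeros(0)
        if not (np.all(np.isfinite(alpha)) and np.all(np.isfinite(beta))):
            raise InvalidParameterError("parameters must be finite")
        if alpha.size < 1:
            raise InvalidParameterError("need at least one threshold")
        if np.any(np.diff(alpha) <= 0):
            raise InvalidParameterError(
                f"thresholds must be strictly increasing, got {alpha}"
            )
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", beta)

    @property
    def q(self) -> int:
        return self.alpha.size

    @property
    def d(self) -> int:
        return self.beta.size

    @property
    def p(self) -> int:
        return self.q + self.d

    @property
    def theta(self) -> np.ndarray:
        return np.concatenate([self.alpha, self.beta])

    @classmethod
    def from_theta(cls, theta: np.ndarray, q: int) -> "ModelParams":
        theta = np.asarray(theta, dtype=float)
        return cls(alpha=theta[:q], beta=theta[q:])

    def names(self) -> list[str]:
        return [f"alpha{j + 1}" for j in range(self.q)] + [
            f"beta{i + 1}" for i in range(self.d)
        ]


def build_design_block(z_row: np.ndarray, q: int) -> np.ndarray:
    """The p x q design block Z_{t-1} whose column j is d(eta_tj)/d(theta).

    Rows 1..q form the q x q identity (thresholds enter their own cumulative
    logit only); rows q+1..q+d repeat ``z_row`` in every column (the slope is
    shared across categories).
    """
    if q < 1:
        raise InvalidInputError("q must be >= 1")
    z_row = np.atleast_1d(np.asarray(z_row, dtype=float))
    if z_row.size and not np.all(np.isfinite(z_row)):
        raise InvalidInputError("covariate row must be finite")
    return np.vstack([np.eye(q), np.tile(z_row[:, None], (1, q))])


def linear_predictor(params: ModelParams, z: np.ndarray) -> np.ndarray:
    """eta (n x q): eta_tj = alpha_j + beta' z_{t-1} for each row of ``z``."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    shift = z @ params.beta if params.d else np.zeros(z.shape[0])
    return params.alpha[None, :] + shift[:, None]


def category_probs_matrix(params: ModelParams, z: np.ndarray) -> np.ndarray:
    """n x m matrix of conditional category probabilities pi_t."""
    cum = expit(linear_predictor(params, z))
    n = cum.shape[0]
    pi = np.empty((n, params.q + 1))
    pi[:, 0] = cum[:, 0]
    pi[:, 1:-1] = np.diff(cum, axis=1)
    pi[:, -1] = 1.0 - cum[:, -1]
    return pi


def category_probs(params: ModelParams, z_row: np.ndarray | None = None) -> np.ndarray:
    """m-vector of category probabilities for a single covariate row.

    ``pi_1 = F(eta_1)``, ``pi_j = F(eta_j) - F(eta_{j-1})``,
    ``pi_m = 1 - F(eta_q)``, with F the logistic CDF.  Ordered thresholds
    guarantee every entry is positive and the vector sums to one.
    """
    if z_row is None:
        z_row = np.zeros(params.d)
    return category_probs_matrix(params, np.atleast_2d(z_row))[0]


def _logistic_density(x: np.ndarray) -> np.ndarray:
    f = expit(x)
    return f * (1.0 - f)


def weight_matrices(
    params: ModelParams, z_row: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-observation matrices (D, Sigma, U) of the score decomposition.

    D is the q x q Jacobian of the response function h(eta) (lower
    bidiagonal: ``D[j,j] = f(eta_j)``, ``D[j,j-1] = -f(eta_{j-1})`` with f
    the logistic density); Sigma is the conditional covariance of the
    indicator vector; ``U = D' Sigma^{-1}``.

    Orientation note: with D[i, j] = d h_i / d eta_j as returned here, the
    chain rule for the score runs through the transpose, so U carries D'.
    """
    if z_row is None:
        z_row = np.zeros(params.d)
    eta = linear_predictor(params, np.atleast_2d(z_row))[0]
    pi = category_probs(params, z_row)
    if pi.min() <= _PROB_FLOOR:
        raise DegenerateProbabilityError(0)
    f = _logistic_density(eta)
    q = params.q
    D = np.diag(f)
    if q > 1:
        D[np.arange(1, q), np.arange(q - 1)] = -f[:-1]
    piq = pi[:q]
    Sigma = np.diag(piq) - np.outer(piq, piq)
    U = np.linalg.solve(Sigma, D).T  # D' Sigma^{-1}, Sigma symmetric
    return D, Sigma, U


def score_contribution(
    params: ModelParams, y_ind: np.ndarray, z_row: np.ndarray | None = None
) -> np.ndarray:
    """Single-observation score s_t = Z_{t-1} U_t (Y_t - pi_t).

    Summing over t yields the partial score vector S_n(theta), the gradient
    of the log partial likelihood.
    """
    if z_row is None:
        z_row = np.zeros(params.d)
    y_ind = np.asarray(y_ind, dtype=float)
    if y_ind.shape != (params.q,) or not set(np.unique(y_ind)) <= {0.0, 1.0} or y_ind.sum() > 1:
        raise InvalidInputError("y_ind must be a valid 0/1 indicator row")
    D, Sigma, _ = weight_matrices(params, z_row)
    pi = category_probs(params, z_row)[: params.q]
    u = D.T @ np.linalg.solve(Sigma, y_ind - pi)
    Z = build_design_block(np.atleast_1d(z_row), params.q)
    return Z @ u


def score_contributions(
    params: ModelParams, series: OrdinalSeries, cov: CovariateSeries
) -> np.ndarray:
    """n x p matrix of per-observation score contributions (vectorized).

    Row t is ``Z_{t-1} D_t Sigma_t^{-1} (Y_t - pi_t)`` evaluated at
    ``params``; the column sums give S_n(theta).
    """
    pi = category_probs_matrix(params, cov.z)
    _check_degenerate(pi)
    q, d = params.q, params.d
    eta = linear_predictor(params, cov.z)
    f = _logistic_density(eta)  # (n, q)
    resid = series.indicators - pi[:, :q]  # (n, q)
    v = _solve_sigma(pi[:, :q], resid[..., None])[..., 0]  # Sigma^{-1}(Y-pi)
    # u = D' v with D lower bidiagonal: u_j = f_j (v_j - v_{j+1}), v_{q+1} = 0
    u = f * v
    if q > 1:
        u[:, :-1] -= f[:, :-1] * v[:, 1:]
    s = np.empty((series.n, q + d))
    s[:, :q] = u
    if d:
        s[:, q:] = cov.z * u.sum(axis=1, keepdims=True)
    return s


def _check_degenerate(pi: np.ndarray) -> None:
    if pi.min() <= _PROB_FLOOR:
        t = int(np.argmax(np.any(pi <= _PROB_FLOOR, axis=1))) + 1
        raise DegenerateProbabilityError(t)


def _sigma_batch(piq: np.ndarray) -> np.ndarray:
    """(n, q, q) stack of conditional covariance matrices from (n, q) probs."""
    n, q = piq.shape
    Sigma = -piq[:, :, None] * piq[:, None, :]
    idx = np.arange(q)
    Sigma[:, idx, idx] = piq * (1.0 - piq)
    return Sigma


def _solve_sigma(piq: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Batched solve Sigma_t x = rhs_t for the q x q conditional covariances."""
    q = piq.shape[1]
    if q == 1:
        return rhs / (piq * (1.0 - piq))[..., None]
    return np.linalg.solve(_sigma_batch(piq), rhs)


def fisher_blocks(
    params: ModelParams, series: OrdinalSeries, cov: CovariateSeries
) -> np.ndarray:
    """(n, q, q) stack A_t = D_t' Sigma_t^{-1} D_t = U_t Sigma_t U_t'.

    These are the per-observation conditional information kernels; the full
    information G_n sums ``Z_{t-1} A_t Z_{t-1}'``.
    """
    pi = category_probs_matrix(params, cov.z)
    _check_degenerate(pi)
    q = params.q
    eta = linear_predictor(params, cov.z)
    f = _logistic_density(eta)
    # D as a batch of lower-bidiagonal matrices
    n = series.n
    D = np.zeros((n, q, q))
    idx = np.arange(q)
    D[:, idx, idx] = f
    if q > 1:
        D[:, idx[1:], idx[:-1]] = -f[:, :-1]
    SinvD = _solve_sigma(pi[:, :q], D)
    return D.transpose(0, 2, 1) @ SinvD


def log_partial_likelihood(
    params: ModelParams, series: OrdinalSeries, cov: CovariateSeries | None = None
) -> float:
    """Log partial likelihood l(theta) = sum_t sum_j Y_tj log pi_tj(theta).

    Probabilities are clipped at 1e-12 before taking logs so a zero fitted
    probability for an observed category yields -inf-ish finite values with
    a warning path left to the caller, never an exception.
    """
    if cov is None:
        cov = CovariateSeries.empty(series.n)
    pi = category_probs_matrix(params, cov.z)
    obs = pi[np.arange(series.n), series.y - 1]
    return float(np.log(np.clip(obs, _PROB_FLOOR, None)).sum())
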