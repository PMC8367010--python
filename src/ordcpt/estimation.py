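"""Maximum partial-likelihood estimation and the score-variance normalizer.

Fitting is by Fisher scoring on the partial log-likelihood, with
step-halving to keep the likelihood non-decreasing and the thresholds
strictly ordered.  Initial values are the logits of the empirical
cumulative category frequencies with zero slopes, which puts the start
inside the parameter space for any series in which every category occurs.

Two estimators of the limiting score variance T are offered:

``outer``  (default)  T_hat = (1/n) sum_t s_t(theta_hat) s_t(theta_hat)'
``model``             T_hat = G_n(theta_hat) / n

Both are consistent for the same limit under a correctly specified model;
the outer-product form is the one a score test constructs directly from
the per-observation contributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import (
    ConvergenceError,
    DegenerateProbabilityError,
    InvalidInputError,
    SeparationError,
    SingularNormalizerError,
)
from .model import (
    CovariateSeries,
    ModelParams,
    OrdinalSeries,
    fisher_blocks,
    log_partial_likelihood,
    score_contributions,
)

_EIG_FLOOR = 1e-10
_MAX_HALVINGS = 20
_SEPARATION_NORM = 1e4


@dataclass(frozen=True)
class FittedModel:
    """Result of maximum partial-likelihood estimation."""

    theta_hat: ModelParams
    G_n: np.ndarray
    T_hat: np.ndarray
    converged: bool
    n_iter: int
    loglik: float
    n_obs: int
    tau_method: str = "outer"

    @property
    def cov_params(self) -> np.ndarray:
        """Asymptotic covariance of theta_hat, G_n(theta_hat)^{-1}."""
        return np.linalg.inv(self.G_n)

    @property
    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.theta_hat.p

    def summary_dict(self) -> dict:
        names = self.theta_hat.names()
        se = self.standard_errors
        return {
            "estimates": dict(zip(names, self.theta_hat.theta.tolist())),
            "standard_errors": dict(zip(names, se.tolist())),
            "loglik": self.loglik,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "tau_method": self.tau_method,
        }


def information_matrix(
    params: ModelParams, series: OrdinalSeries, cov: CovariateSeries
) -> np.ndarray:
    """Conditional information G_n = sum_t Z_{t-1} U_t Sigma_t U_t' Z_{t-1}'.

    Assembled blockwise from the q x q kernels A_t = U_t Sigma_t U_t':
    the threshold block sums A_t, the cross block sums (A_t 1) z_t', and
    the slope block sums (1' A_t 1) z_t z_t'.
    """
    A = fisher_blocks(params, series, cov)  # (n, q, q)
    q, d = params.q, params.d
    G = np.empty((q + d, q + d))
    G[:q, :q] = A.sum(axis=0)
    if d:
        r = A.sum(axis=2)  # (n, q): A_t @ 1
        G[:q, q:] = np.einsum("tq,td->qd", r, cov.z)
        G[q:, :q] = G[:q, q:].T
        w = r.sum(axis=1)  # 1' A_t 1
        G[q:, q:] = np.einsum("t,td,te->de", w, cov.z, cov.z)
    return G


def _initial_params(series: OrdinalSeries, d: int) -> ModelParams:
    counts = np.bincount(series.y, minlength=series.m + 1)[1:]
    if np.any(counts == 0):
        missing = np.where(counts == 0)[0] + 1
        raise InvalidInputError(
            f"categories {missing.tolist()} never observed; thresholds unidentified"
        )
    cum = np.cumsum(counts[:-1]) / series.n
    alpha = np.log(cum / (1.0 - cum))
    return ModelParams(alpha=alpha, beta=np.zeros(d))


def fit_mple(
    series: OrdinalSeries,
    cov: CovariateSeries | None = None,
    init: ModelParams | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    tau_method: str = "outer",
) -> FittedModel:
    """Fit the cumulative-logit model by Fisher scoring.

    Convergence is declared when the sup-norm of the score S_n(theta)
    drops below ``tol``.  Steps that decrease the log-likelihood, break
    the threshold ordering or hit degenerate probabilities are halved
    (up to 20 times) before the iteration is abandoned.
    """
    if cov is None:
        cov = CovariateSeries.empty(series.n)
    if cov.n != series.n:
        raise InvalidInputError(
            f"covariate rows ({cov.n}) must match series length ({series.n})"
        )
    q, d = series.q, cov.d
    if series.n <= q + d:
        raise InvalidInputError("need n > p observations to fit")
    params = init if init is not None else _initial_params(series, d)
    if params.q != q or params.d != d:
        raise InvalidInputError("init dimensions do not match data")

    loglik = log_partial_likelihood(params, series, cov)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        S = score_contributions(params, series, cov).sum(axis=0)
        if np.abs(S).max() < tol:
            converged = True
            n_iter -= 1
            break
        G = information_matrix(params, series, cov)
        try:
            step = np.linalg.solve(G, S)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"singular information at iteration {n_iter}", params, n_iter
            ) from exc
        theta = params.theta
        scale = 1.0
        for _ in range(_MAX_HALVINGS + 1):
            cand_theta = theta + scale * step
            if np.any(np.diff(cand_theta[:q]) <= 0):
                scale *= 0.5
                continue
            cand = ModelParams.from_theta(cand_theta, q)
            cand_ll = log_partial_likelihood(cand, series, cov)
            if np.isfinite(cand_ll) and cand_ll >= loglik - 1e-10:
                params, loglik = cand, cand_ll
                break
            scale *= 0.5
        else:
            raise ConvergenceError(
                f"step-halving failed at iteration {n_iter}", params, n_iter
            )
        if np.linalg.norm(params.theta) > _SEPARATION_NORM:
            raise SeparationError(
                "estimates diverged (possible separation)", params, n_iter
            )
    else:
        S = score_contributions(params, series, cov).sum(axis=0)
        if np.abs(S).max() < tol:
            converged = True
    if not converged:
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations (||S||_inf = {np.abs(S).max():.3g})",
            params,
            max_iter,
        )

    G = information_matrix(params, series, cov)
    T = _tau_from(params, series, cov, G, tau_method)
    return FittedModel(
        theta_hat=params,
        G_n=G,
        T_hat=T,
        converged=True,
        n_iter=n_iter,
        loglik=loglik,
        n_obs=series.n,
        tau_method=tau_method,
    )


def _tau_from(params, series, cov, G, method: str) -> np.ndarray:
    if method == "outer":
        s = score_contributions(params, series, cov)
        return (s.T @ s) / series.n
    if method == "model":
        return G / series.n
    raise InvalidInputError(f"unknown tau method {method!r}")


def tau_hat(
    fitted: FittedModel,
    series: OrdinalSeries,
    cov: CovariateSeries | None = None,
    method: str = "outer",
) -> np.ndarray:
    """Score-variance estimate T_hat at theta_hat.

    ``outer`` averages the per-observation score outer products; ``model``
    uses G_n / n.  Both are symmetric positive semidefinite and estimate
    the same limiting matrix under correct specification.
    """
    if not fitted.converged:
        raise InvalidInputError("tau_hat requires a converged fit")
    if cov is None:
        cov = CovariateSeries.empty(series.n)
    return _tau_from(fitted.theta_hat, series, cov, fitted.G_n, method)


def inverse_sqrt(T: np.ndarray, floor: float = _EIG_FLOOR) -> np.ndarray:
    """Symmetric inverse square root of a PSD matrix by eigendecomposition.

    Eigenvalues at or below ``floor`` indicate a rank-deficient normalizer;
    the error names the offending null-space components (largest-loading
    coordinate of each deficient eigenvector).
    """
    w, V = np.linalg.eigh((T + T.T) / 2.0)
    if np.any(w <= floor):
        bad = [int(np.argmax(np.abs(V[:, i]))) for i in np.where(w <= floor)[0]]
        raise SingularNormalizerError(
            f"score-variance estimate rank deficient; null space loads on components {bad}"
        )
    return (V / np.sqrt(w)) @ V.T
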