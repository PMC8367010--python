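"""Score-process change-point statistics and their asymptotic critical values.

Under parameter stability the standardized cumulative score path

    k  |->  n^{-1/2} T_hat^{-1/2} S_k(theta_hat),   k = 1..n,

behaves asymptotically like a vector of independent Brownian bridges (it is
pinned to zero at k = n because the full-sample score vanishes at the MPLE).
Two functionals of the path are used:

* ``W1`` — the maximum over k of the absolute standardized component(s),
  rejected component-wise against the sup-Brownian-bridge quantile at the
  Sidak-split level ``alpha* = 1 - (1-alpha)^(1/j)`` over the j tested
  components.  A rejection names the unstable parameter.

* ``W2`` — the maximum over a trimmed window l < k/n < u of the weighted
  quadratic form ``||xi_k||^2 / ((k/n)(1-k/n))``, whose weight restores
  power against changes near either end of the series where the bridge is
  tied down.  Critical values come from the classical large-x tail
  approximation for sup of a weighted sum of squared bridges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.optimize import brentq

from .exceptions import InvalidInputError
from .estimation import FittedModel, inverse_sqrt, tau_hat
from .model import CovariateSeries, OrdinalSeries, score_contributions


@dataclass(frozen=True)
class ScoreProcess:
    """Standardized cumulative score path; row k-1 holds
    n^{-1/2} (T_hat^{-1/2} S_k(theta_hat))' for k = 1..n."""

    path: np.ndarray
    param_names: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.path.shape[0]

    @property
    def p(self) -> int:
        return self.path.shape[1]

    def resolve_components(self, components) -> np.ndarray:
        """Map parameter names or 0-based indices to column indices."""
        if components is None:
            return np.arange(self.p)
        idx = []
        for c in components:
            if isinstance(c, str):
                try:
                    idx.append(self.param_names.index(c))
                except ValueError:
                    raise InvalidInputError(
                        f"unknown component {c!r}; have {list(self.param_names)}"
                    ) from None
            else:
                if not 0 <= int(c) < self.p:
                    raise InvalidInputError(f"component index {c} outside 0..{self.p - 1}")
                idx.append(int(c))
        if not idx:
            raise InvalidInputError("component set must be nonempty")
        return np.asarray(sorted(set(idx)))


@dataclass(frozen=True)
class TestResult:
    """Outcome of a W1 or W2 change-point test."""

    statistic: float
    critical_value: float
    alpha: float
    rejected: bool
    argmax_k: int
    statistic_name: str
    components: tuple[int, ...]
    component_names: tuple[str, ...]
    per_component: np.ndarray | None = None
    per_component_argmax: np.ndarray | None = None
    window: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        d = {
            "statistic": self.statistic_name,
            "value": self.statistic,
            "critical_value": self.critical_value,
            "alpha": self.alpha,
            "rejected": self.rejected,
            "argmax_k": self.argmax_k,
            "components": list(self.component_names),
        }
        if self.per_component is not None:
            d["per_component_max"] = dict(
                zip(self.component_names, self.per_component.tolist())
            )
            d["per_component_argmax"] = dict(
                zip(self.component_names, self.per_component_argmax.tolist())
            )
        if self.window is not None:
            d["window"] = list(self.window)
        return d


def score_process(
    fitted: FittedModel,
    series: OrdinalSeries,
    cov: CovariateSeries | None = None,
    tau_method: str | None = None,
) -> ScoreProcess:
    """Standardized cumulative score path at the full-sample estimate.

    The final row is numerically zero: the MPLE annihilates the full-sample
    score, so the path is a discrete bridge.
    """
    if cov is None:
        cov = CovariateSeries.empty(series.n)
    method = tau_method if tau_method is not None else fitted.tau_method
    T = fitted.T_hat if method == fitted.tau_method else tau_hat(fitted, series, cov, method)
    Tinv_sqrt = inverse_sqrt(T)
    s = score_contributions(fitted.theta_hat, series, cov)
    path = np.cumsum(s, axis=0) @ Tinv_sqrt / np.sqrt(series.n)
    return ScoreProcess(path=path, param_names=tuple(fitted.theta_hat.names()))


def sup_bridge_tail(x: float) -> float:
    """P(sup_{0<=u<=1} |B(u)| >= x) for a one-dimensional Brownian bridge.

    Alternating series 2 sum_{k>=1} (-1)^{k+1} exp(-2 k^2 x^2), summed until
    the next term falls below 1e-14.
    """
    if x <= 0:
        raise InvalidInputError("x must be positive")
    total = 0.0
    for k in range(1, 1000):
        term = 2.0 * np.exp(-2.0 * k * k * x * x)
        if term < 1e-14:
            break
        total += term if k % 2 == 1 else -term
    return float(min(total, 1.0))


def w1_critical_value(alpha: float, j: int = 1) -> float:
    """Quantile C(alpha*) of sup|B| at the Sidak-split level
    alpha* = 1 - (1-alpha)^(1/j) for j simultaneously tested components."""
    if not 0 < alpha < 1:
        raise InvalidInputError("alpha must be in (0, 1)")
    if j < 1:
        raise InvalidInputError("j must be >= 1")
    alpha_star = 1.0 - (1.0 - alpha) ** (1.0 / j)
    return float(brentq(lambda x: sup_bridge_tail(x) - alpha_star, 1e-6, 10.0, xtol=1e-10))


def w1_statistic(
    proc: ScoreProcess, components=None, alpha: float = 0.05
) -> TestResult:
    """Component-wise maximum of the absolute standardized score path.

    For each tested component i the statistic is max_k |path[k, i]|; the
    null is rejected when any of them reaches C(alpha*) with
    alpha* = 1 - (1-alpha)^(1/j), j the number of tested components.
    """
    idx = proc.resolve_components(components)
    sub = np.abs(proc.path[:, idx])
    per_comp = sub.max(axis=0)
    per_argmax = sub.argmax(axis=0) + 1  # 1-based k
    best = int(np.argmax(per_comp))
    cv = w1_critical_value(alpha, idx.size)
    stat = float(per_comp[best])
    return TestResult(
        statistic=stat,
        critical_value=cv,
        alpha=alpha,
        rejected=bool(stat >= cv),
        argmax_k=int(per_argmax[best]),
        statistic_name="W1",
        components=tuple(int(i) for i in idx),
        component_names=tuple(proc.param_names[i] for i in idx),
        per_component=per_comp,
        per_component_argmax=per_argmax,
    )


def weighted_sup_tail(x: float, j: int, l: float = 0.05, u: float = 0.95) -> float:
    """Large-x tail approximation for sup_{l<t<u} sum_i B_i^2(t) / (t(1-t)).

    Two-term expansion
        x^{j/2} e^{-x/2} / (2^{j/2} Gamma(j/2))
            * { (1 - j/x) log((1-l)u / (l(1-u))) + 4/x },
    valid as x -> infinity; the O(1/x^2) remainder is dropped.  Only
    meaningful for x > j (the mode of the chi-square_j factor).
    """
    if not 0 < l < u < 1:
        raise InvalidInputError("need 0 < l < u < 1")
    if x <= j:
        raise InvalidInputError(f"approximation requires x > j (got x={x}, j={j})")
    log_pref = 0.5 * j * np.log(x) - 0.5 * x - 0.5 * j * np.log(2.0) - gammaln(0.5 * j)
    bracket = (1.0 - j / x) * np.log((1.0 - l) * u / (l * (1.0 - u))) + 4.0 / x
    return float(np.exp(log_pref) * bracket)


def w2_critical_value(
    alpha: float, j: int, l: float = 0.05, u: float = 0.95
) -> float:
    """Root of weighted_sup_tail(x) = alpha, bisected on (j + 1, 200)."""
    if not 0 < alpha < 1:
        raise InvalidInputError("alpha must be in (0, 1)")
    lo, hi = j + 1.0, 200.0
    flo = weighted_sup_tail(lo, j, l, u) - alpha
    fhi = weighted_sup_tail(hi, j, l, u) - alpha
    if flo * fhi > 0:
        raise InvalidInputError(
            f"no root in bracket ({lo}, {hi}) for alpha={alpha}, j={j}"
        )
    return float(brentq(lambda x: weighted_sup_tail(x, j, l, u) - alpha, lo, hi, xtol=1e-8))


def w2_statistic(
    proc: ScoreProcess,
    components=None,
    l: float = 0.05,
    u: float = 0.95,
    alpha: float = 0.05,
) -> TestResult:
    """Weighted quadratic form of the standardized score over a trimmed window.

    W2 = max over k with l < k/n < u of
    sum_i path[k, i]^2 / ((k/n)(1 - k/n)); the path rows already carry the
    n^{-1/2} factor, so squaring supplies the n^{-1} scaling.
    """
    if not 0 < l < u < 1:
        raise InvalidInputError("need 0 < l < u < 1")
    idx = proc.resolve_components(components)
    n = proc.n
    k = np.arange(1, n + 1)
    frac = k / n
    mask = (frac > l) & (frac < u)
    if not mask.any():
        raise InvalidInputError("window contains no observation index")
    quad = (proc.path[mask][:, idx] ** 2).sum(axis=1)
    weight = frac[mask] * (1.0 - frac[mask])
    vals = quad / weight
    best = int(np.argmax(vals))
    stat = float(vals[best])
    cv = w2_critical_value(alpha, idx.size, l, u)
    return TestResult(
        statistic=stat,
        critical_value=cv,
        alpha=alpha,
        rejected=bool(stat >= cv),
        argmax_k=int(k[mask][best]),
        statistic_name="W2",
        components=tuple(int(i) for i in idx),
        component_names=tuple(proc.param_names[i] for i in idx),
        window=(l, u),
    )
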