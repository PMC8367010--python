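"""Synthetic ordinal time series and Monte-Carlo size/power experiments.

The generator emulates a three-category series driven by an annual-style
cosine covariate and the two lagged category indicators:

    logit P(Y_t <= j) = alpha_j - beta1 cos(2 pi t / 12)
                        - beta2 Y_{(t-1)1} - beta3 Y_{(t-1)2},   j = 1, 2,

with baseline parameters theta0 = (-0.5, 0.2, 2, 0.5, 1).  The engine's
canonical predictor is ``alpha_j + beta' z``, so the generator passes the
negated covariates ``z_t = (-cos(2 pi t/12), -Y_{(t-1)1}, -Y_{(t-1)2})``
and the slopes are recovered with their positive signs.  An abrupt change
replaces theta0 by theta_star from index k* + 1 onward.

Because the covariate vector takes only 12 x 3 distinct values (cosine
phase times lag state) per regime, the sequential draw runs off a
precomputed cumulative-probability table.

The three stock alternatives shift theta0 at k*:

    ha1:  alpha1 -0.5 -> -1   and  beta1 2 -> 3
    ha2:  alpha1 -0.5 -> -1
    ha3:  beta1 2 -> 3

Rejection rates are reported for the component-wise tests of alpha1 and
beta1 (each at the Sidak-split level), their joint version, and the
weighted quadratic form on the same two components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, OrdcptError
from .estimation import fit_mple
from .model import CovariateSeries, ModelParams, OrdinalSeries, category_probs
from .score_tests import score_process, w1_critical_value, w2_critical_value

THETA0 = (-0.5, 0.2, 2.0, 0.5, 1.0)
#: indices of (alpha1, beta1) in theta = (alpha1, alpha2, beta1, beta2, beta3)
TESTED_COMPONENTS = (0, 2)
_M = 3


@dataclass(frozen=True)
class ScenarioSpec:
    """One Monte-Carlo experiment: DGP parameters, change and replication."""

    n: int = 1000
    theta0: tuple = THETA0
    theta_star: tuple | None = None
    k_star: int | None = None
    reps: int = 1000
    seed: int = 0
    level: float = 0.05
    window: tuple[float, float] = (0.05, 0.95)
    tau_method: str = "outer"
    burn_in: int = 0

    def __post_init__(self):
        if len(self.theta0) != 5:
            raise InvalidInputError("theta0 must be (alpha1, alpha2, beta1, beta2, beta3)")
        if self.k_star is not None and not 1 <= self.k_star < self.n:
            raise InvalidInputError(f"k_star must lie in 1..n-1, got {self.k_star}")
        if (self.theta_star is None) != (self.k_star is None):
            raise InvalidInputError("theta_star and k_star must be given together")


def scenario(name: str, n: int = 1000, k_frac: float = 0.5, **kw) -> ScenarioSpec:
    """Stock scenarios: 'h0' (no change) or 'ha1'/'ha2'/'ha3' at k* = k_frac*n."""
    name = name.lower()
    if name == "h0":
        return ScenarioSpec(n=n, **kw)
    shifts = {
        "ha1": {0: -1.0, 2: 3.0},
        "ha2": {0: -1.0},
        "ha3": {2: 3.0},
    }
    if name not in shifts:
        raise InvalidInputError(f"unknown scenario {name!r}")
    theta_star = list(THETA0)
    for i, v in shifts[name].items():
        theta_star[i] = v
    return ScenarioSpec(
        n=n, theta_star=tuple(theta_star), k_star=int(round(k_frac * n)), **kw
    )


def _params_of(theta) -> ModelParams:
    theta = np.asarray(theta, dtype=float)
    return ModelParams(alpha=theta[:2], beta=theta[2:])


def _cum_table(theta) -> list[list[tuple[float, float]]]:
    """Cumulative category probabilities by (cosine phase, lag state).

    Lag state s encodes Y_{t-1} = s + 1; state 2 (the reference category)
    zeroes both indicators.
    """
    params = _params_of(theta)
    table = []
    for r in range(12):
        c = math.cos(2.0 * math.pi * r / 12.0)
        row = []
        for s in range(3):
            z = (-c, -1.0 if s == 0 else 0.0, -1.0 if s == 1 else 0.0)
            pi = category_probs(params, np.array(z))
            row.append((pi[0], pi[0] + pi[1]))
        table.append(row)
    return table


def simulate_series(
    spec: ScenarioSpec, rng: np.random.Generator | None = None
) -> tuple[OrdinalSeries, CovariateSeries]:
    """Draw one series of length spec.n from the (possibly changing) DGP.

    The pre-sample state Y_0 is the reference category m (both lag
    indicators zero); an optional burn-in prepends extra transitions that
    are discarded, with the cosine phase of the retained samples unchanged.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    pre = _cum_table(spec.theta0)
    post = _cum_table(spec.theta_star) if spec.theta_star is not None else pre
    k_star = spec.k_star if spec.k_star is not None else spec.n
    n, burn = spec.n, spec.burn_in
    u = rng.random(n + burn)
    y = np.empty(n + burn, dtype=np.int64)
    state = 2  # Y_0 = category m
    for i in range(n + burn):
        t = i - burn + 1  # burn-in runs at t <= 0 so phases line up
        table = pre if t <= k_star else post
        c1, c2 = table[t % 12][state]
        ui = u[i]
        cat = 0 if ui < c1 else (1 if ui < c2 else 2)
        y[i] = cat + 1
        state = cat
    y_full = y
    y = y_full[burn:]
    t_idx = np.arange(1, n + 1)
    prev = np.empty(n, dtype=np.int64)
    prev[1:] = y[:-1]
    prev[0] = y_full[burn - 1] if burn else _M  # Y_0 is the reference category
    lag1 = (prev == 1).astype(float)
    lag2 = (prev == 2).astype(float)
    z = np.column_stack([-np.cos(2.0 * np.pi * t_idx / 12.0), -lag1, -lag2])
    return OrdinalSeries(y, _M), CovariateSeries(z)


def simulate_piecewise(
    n: int,
    thetas,
    breaks,
    rng: np.random.Generator | None = None,
) -> tuple[OrdinalSeries, CovariateSeries]:
    """Series with several parameter regimes for multi-change experiments.

    ``breaks`` lists the last index of each regime but the final one
    (strictly increasing, within 1..n-1); ``thetas`` has one parameter
    tuple per regime, len(breaks) + 1 in total.
    """
    if rng is None:
        rng = np.random.default_rng()
    breaks = list(breaks)
    if len(thetas) != len(breaks) + 1:
        raise InvalidInputError("need len(thetas) == len(breaks) + 1")
    if breaks != sorted(breaks) or (breaks and not 1 <= breaks[0] <= breaks[-1] < n):
        raise InvalidInputError("breaks must be strictly increasing within 1..n-1")
    tables = [_cum_table(th) for th in thetas]
    bounds = breaks + [n]
    u = rng.random(n)
    y = np.empty(n, dtype=np.int64)
    state = 2
    regime = 0
    for i in range(n):
        t = i + 1
        while t > bounds[regime]:
            regime += 1
        c1, c2 = tables[regime][t % 12][state]
        cat = 0 if u[i] < c1 else (1 if u[i] < c2 else 2)
        y[i] = cat + 1
        state = cat
    t_idx = np.arange(1, n + 1)
    prev = np.empty(n, dtype=np.int64)
    prev[1:] = y[:-1]
    prev[0] = _M
    z = np.column_stack([
        -np.cos(2.0 * np.pi * t_idx / 12.0),
        -(prev == 1).astype(float),
        -(prev == 2).astype(float),
    ])
    return OrdinalSeries(y, _M), CovariateSeries(z)


@dataclass
class StudyResult:
    """Rejection rates from one Monte-Carlo experiment."""

    spec: ScenarioSpec
    rates: dict[str, float]
    reps_used: int
    reps_failed: int
    w1_stats: np.ndarray = field(repr=False, default=None)
    w2_stats: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "statistic": list(self.rates),
                "rejection_rate": list(self.rates.values()),
                "n": self.spec.n,
                "k_star": self.spec.k_star,
                "reps": self.reps_used,
            }
        )


def rejection_rates(spec: ScenarioSpec, progress: bool = False) -> StudyResult:
    """Monte-Carlo rejection frequencies of the four test variants.

    ``w11`` and ``w12`` test alpha1 and beta1 one at a time at the
    Sidak-split level alpha* = 1 - (1-alpha)^(1/2); ``w1`` is the joint
    rule (reject if either component does); ``w2`` compares the weighted
    quadratic form on both components with its asymptotic critical value.
    Replicates whose fit fails are dropped and counted; power experiments
    reuse the asymptotic (null) critical values.
    """
    comp = np.asarray(TESTED_COMPONENTS)
    c_star = w1_critical_value(spec.level, comp.size)
    l, uwin = spec.window
    c2 = w2_critical_value(spec.level, comp.size, l, uwin)

    master = np.random.SeedSequence(spec.seed)
    children = master.spawn(spec.reps)
    n = spec.n
    k = np.arange(1, n + 1)
    frac = k / n
    wmask = (frac > l) & (frac < uwin)
    weight = frac[wmask] * (1.0 - frac[wmask])

    m1 = np.full(spec.reps, np.nan)
    m2 = np.full(spec.reps, np.nan)
    w2v = np.full(spec.reps, np.nan)
    failed = 0
    for r in range(spec.reps):
        rng = np.random.default_rng(children[r])
        series, cov = simulate_series(spec, rng)
        try:
            fitted = fit_mple(series, cov, tau_method=spec.tau_method)
            proc = score_process(fitted, series, cov)
        except OrdcptError:
            failed += 1
            continue
        sub = proc.path[:, comp]
        m1[r] = np.abs(sub[:, 0]).max()
        m2[r] = np.abs(sub[:, 1]).max()
        w2v[r] = ((sub[wmask] ** 2).sum(axis=1) / weight).max()
        if progress and (r + 1) % 100 == 0:
            print(f"  replicate {r + 1}/{spec.reps}", flush=True)
    ok = ~np.isnan(m1)
    used = int(ok.sum())
    if used == 0:
        raise OrdcptError("every replicate failed to fit")
    if failed > 0.05 * spec.reps:
        import warnings

        warnings.warn(f"{failed}/{spec.reps} replicates dropped (fit failures)")
    rates = {
        "w11": float((m1[ok] >= c_star).mean()),
        "w12": float((m2[ok] >= c_star).mean()),
        "w1": float(((m1[ok] >= c_star) | (m2[ok] >= c_star)).mean()),
        "w2": float((w2v[ok] >= c2).mean()),
    }
    return StudyResult(spec, rates, used, failed,
                       w1_stats=np.maximum(m1[ok], m2[ok]), w2_stats=w2v[ok])


def empirical_size(spec: ScenarioSpec, progress: bool = False) -> StudyResult:
    """Size experiment: requires a no-change spec."""
    if spec.k_star is not None:
        raise InvalidInputError("size experiment needs k_star = None")
    return rejection_rates(spec, progress)


def empirical_power(spec: ScenarioSpec, progress: bool = False) -> StudyResult:
    """Power experiment under a shifted DGP (falls back to size if no shift)."""
    return rejection_rates(spec, progress)


def power_curve(
    spec: ScenarioSpec, k_fracs, progress: bool = False
) -> pd.DataFrame:
    """Rejection rates of W1 and W2 across change locations k* = frac * n."""
    if spec.theta_star is None:
        raise InvalidInputError("power_curve needs an alternative (theta_star)")
    rows = []
    for fkr in k_fracs:
        if not 0 < fkr < 1:
            raise InvalidInputError("k_fracs must lie in (0, 1)")
        sub = replace(spec, k_star=int(round(fkr * spec.n)))
        res = rejection_rates(sub, progress)
        rows.append({"k_frac": fkr, "k_star": sub.k_star, **res.rates,
                     "reps_used": res.reps_used})
    return pd.DataFrame(rows)
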