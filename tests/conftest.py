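import numpy as np
import pytest

import ordcpt as oc


@pytest.fixture(scope="session")
def h0_fit():
    """One simulated stable series with its fit and score process,
    shared across read-only tests."""
    spec = oc.scenario("h0", n=1000, reps=1, seed=12345)
    series, cov = oc.simulate_series(spec, np.random.default_rng(12345))
    fitted = oc.fit_mple(series, cov)
    proc = oc.score_process(fitted, series, cov)
    return series, cov, fitted, proc


@pytest.fixture()
def small_instance():
    """A small random 3-category instance with two external covariates."""
    rng = np.random.default_rng(99)
    n = 60
    series = oc.OrdinalSeries(rng.integers(1, 4, n), 3)
    cov = oc.CovariateSeries(rng.normal(size=(n, 2)))
    params = oc.ModelParams(alpha=[-0.4, 0.3], beta=[0.25, -0.15])
    return params, series, cov


def finite_diff_gradient(params, series, cov, eps=1e-6):
    """Central-difference gradient of the log partial likelihood."""
    theta = params.theta
    g = np.empty(theta.size)
    for i in range(theta.size):
        up, dn = theta.copy(), theta.copy()
        up[i] += eps
        dn[i] -= eps
        g[i] = (
            oc.log_partial_likelihood(oc.ModelParams.from_theta(up, params.q), series, cov)
            - oc.log_partial_likelihood(oc.ModelParams.from_theta(dn, params.q), series, cov)
        ) / (2 * eps)
    return g
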