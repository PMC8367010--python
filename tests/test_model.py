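"""Unit tests for the cumulative-logit building blocks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

import ordcpt as oc
from ordcpt.model import category_probs_matrix, linear_predictor

from conftest import finite_diff_gradient


class TestDesignBlock:
    @pytest.mark.parametrize(
        "z_row, q, expected",
        [
            ([], 2, np.eye(2)),
            ([5.0], 1, np.array([[1.0], [5.0]])),
            ([2.0, -3.0], 2, np.array([[1, 0], [0, 1], [2, 2], [-3, -3]], dtype=float)),
        ],
    )
    def test_layout(self, z_row, q, expected):
        np.testing.assert_allclose(oc.build_design_block(np.array(z_row), q), expected)

    def test_columns_are_predictor_gradients(self):
        # column j of the block is d(eta_j)/d(theta), by finite differences
        params = oc.ModelParams(alpha=[-0.5, 0.2], beta=[1.0, -2.0])
        z_row = np.array([0.7, 0.3])
        Z = oc.build_design_block(z_row, params.q)
        eps = 1e-6
        for a in range(params.p):
            up, dn = params.theta.copy(), params.theta.copy()
            up[a] += eps
            dn[a] -= eps
            d_eta = (
                linear_predictor(oc.ModelParams.from_theta(up, 2), z_row[None]) -
                linear_predictor(oc.ModelParams.from_theta(dn, 2), z_row[None])
            )[0] / (2 * eps)
            np.testing.assert_allclose(Z[a], d_eta, atol=1e-8)

    def test_nonfinite_rejected(self):
        with pytest.raises(oc.InvalidInputError):
            oc.build_design_block(np.array([np.nan]), 2)


class TestCategoryProbs:
    def test_binary_symmetric(self):
        np.testing.assert_allclose(
            oc.category_probs(oc.ModelParams(alpha=[0.0])), [0.5, 0.5]
        )

    def test_three_category_closed_form(self):
        pi = oc.category_probs(oc.ModelParams(alpha=[-0.5, 0.2]))
        np.testing.assert_allclose(pi, [0.37754, 0.17229, 0.45017], atol=5e-6)

    def test_four_category_tail(self):
        pi = oc.category_probs(oc.ModelParams(alpha=[-14.722, -10.389, -4.078]))
        assert pi[3] == pytest.approx(1.0 - expit(-4.078), abs=1e-12)
        assert pi[3] == pytest.approx(0.98334, abs=1e-5)

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(oc.InvalidParameterError):
            oc.ModelParams(alpha=[0.5, 0.2])

    @given(
        a1=st.floats(-4, 4),
        gap=st.floats(0.01, 4),
        b=st.floats(-2, 2),
        z=st.floats(-3, 3),
    )
    @settings(max_examples=50, deadline=None)
    def test_probability_conservation_and_positivity(self, a1, gap, b, z):
        params = oc.ModelParams(alpha=[a1, a1 + gap], beta=[b])
        pi = oc.category_probs(params, np.array([z]))
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(pi > 0)

    def test_cumulative_monotone_in_threshold(self):
        # raising alpha_1 (order kept) weakly raises P(Y <= 1)
        lo = oc.category_probs(oc.ModelParams(alpha=[-0.5, 0.2]))
        hi = oc.category_probs(oc.ModelParams(alpha=[-0.3, 0.2]))
        assert hi[0] > lo[0]


class TestWeightMatrices:
    def test_binary_at_zero(self):
        D, Sigma, U = oc.weight_matrices(oc.ModelParams(alpha=[0.0]))
        np.testing.assert_allclose(D, [[0.25]])
        np.testing.assert_allclose(Sigma, [[0.25]])
        np.testing.assert_allclose(U, [[1.0]])

    def test_three_category_jacobian_entries(self):
        D, _, _ = oc.weight_matrices(oc.ModelParams(alpha=[-0.5, 0.2]))
        assert D[0, 0] == pytest.approx(0.23500, abs=5e-6)
        assert D[1, 0] == pytest.approx(-0.23500, abs=5e-6)
        assert D[1, 1] == pytest.approx(0.247517, abs=5e-6)
        assert D[0, 1] == 0.0

    def test_jacobian_matches_finite_differences(self):
        params = oc.ModelParams(alpha=[-0.8, -0.1, 0.9], beta=[0.4])
        z = np.array([0.6])
        D, Sigma, U = oc.weight_matrices(params, z)
        eta = linear_predictor(params, z[None])[0]
        eps = 1e-6
        fd = np.empty_like(D)
        for j in range(params.q):
            up, dn = eta.copy(), eta.copy()
            up[j] += eps
            dn[j] -= eps

            def h(e):
                cum = expit(e)
                return np.concatenate([[cum[0]], np.diff(cum)])

            fd[:, j] = (h(up) - h(dn)) / (2 * eps)
        np.testing.assert_allclose(D, fd, atol=1e-6)
        # Sigma symmetric PD, U consistent with D' Sigma^{-1}
        np.testing.assert_allclose(Sigma, Sigma.T)
        assert np.all(np.linalg.eigvalsh(Sigma) > 0)
        np.testing.assert_allclose(U, D.T @ np.linalg.inv(Sigma), atol=1e-10)


class TestScore:
    def test_sum_matches_gradient(self, small_instance):
        params, series, cov = small_instance
        S = oc.score_contributions(params, series, cov).sum(axis=0)
        g = finite_diff_gradient(params, series, cov)
        np.testing.assert_allclose(S, g, rtol=1e-5, atol=1e-7)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_gradient_identity_randomized(self, seed):
        rng = np.random.default_rng(seed)
        n = 25
        m = int(rng.integers(2, 5))
        d = int(rng.integers(0, 3))
        y = rng.integers(1, m + 1, n)
        y[:m] = np.arange(1, m + 1)  # every category occurs
        series = oc.OrdinalSeries(y, m)
        cov = oc.CovariateSeries(rng.normal(size=(n, d)) * 0.5)
        alpha = np.sort(rng.normal(size=m - 1))
        alpha += np.arange(m - 1) * 0.05  # guard strict ordering
        params = oc.ModelParams(alpha=alpha, beta=rng.normal(size=d) * 0.3)
        S = oc.score_contributions(params, series, cov).sum(axis=0)
        g = finite_diff_gradient(params, series, cov)
        np.testing.assert_allclose(S, g, rtol=2e-5, atol=1e-6)

    def test_single_observation_matches_batch(self, small_instance):
        params, series, cov = small_instance
        batch = oc.score_contributions(params, series, cov)
        ind = series.indicators
        for t in [0, 17, 59]:
            single = oc.score_contribution(params, ind[t], cov.z[t])
            np.testing.assert_allclose(single, batch[t], atol=1e-12)

    def test_binary_collapse(self):
        # for m = 2 the contribution reduces to y - pi, the logistic score
        params = oc.ModelParams(alpha=[0.3])
        pi1 = oc.category_probs(params)[0]
        for y_ind in ([1.0], [0.0]):
            s = oc.score_contribution(params, np.array(y_ind))
            assert s[0] == pytest.approx(y_ind[0] - pi1, abs=1e-12)

    def test_zero_mean_under_model(self):
        # E(score | F_{t-1}) = 0: Monte-Carlo mean within 3 SE at 1e5 draws
        params = oc.ModelParams(alpha=[-0.5, 0.2], beta=[0.8])
        rng = np.random.default_rng(5)
        z = rng.normal(size=(100_000, 1))
        pi = category_probs_matrix(params, z)
        u = rng.random(len(z))
        cum = np.cumsum(pi, axis=1)
        y = 1 + (u[:, None] > cum[:, :-1]).sum(axis=1)
        series = oc.OrdinalSeries(y, 3)
        s = oc.score_contributions(params, series, oc.CovariateSeries(z))
        mean = s.mean(axis=0)
        se = s.std(axis=0, ddof=1) / np.sqrt(len(z))
        assert np.all(np.abs(mean) < 3 * se + 1e-12)


class TestLogLikelihood:
    def test_single_binary_observation(self):
        series = oc.OrdinalSeries([1], 2)
        ll = oc.log_partial_likelihood(oc.ModelParams(alpha=[0.0]), series)
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    def test_two_observation_sum(self):
        series = oc.OrdinalSeries([1, 3], 3)
        ll = oc.log_partial_likelihood(oc.ModelParams(alpha=[-0.5, 0.2]), series)
        assert ll == pytest.approx(-1.77222, abs=5e-5)

    def test_additive_over_time(self, small_instance):
        params, series, cov = small_instance
        full = oc.log_partial_likelihood(params, series, cov)
        first = oc.log_partial_likelihood(
            params, oc.OrdinalSeries(series.y[:30], 3), oc.CovariateSeries(cov.z[:30])
        )
        second = oc.log_partial_likelihood(
            params, oc.OrdinalSeries(series.y[30:], 3), oc.CovariateSeries(cov.z[30:])
        )
        assert full == pytest.approx(first + second, abs=1e-10)

    def test_zero_probability_is_finite_not_raising(self):
        # observed category with essentially zero fitted probability
        series = oc.OrdinalSeries([3], 3)
        ll = oc.log_partial_likelihood(oc.ModelParams(alpha=[-1.0, 40.0]), series)
        assert np.isfinite(ll) and ll < -20
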