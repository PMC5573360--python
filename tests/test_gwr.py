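"""GWR engine: kernels, bandwidths, local fits, CV selection, diagnostics.

The reference for the full fit is an independent dense implementation that
builds every local hat row by explicit per-point matrix inversion in a
plain Python loop.
"""

import math

import numpy as np
import pytest

from spastab import gwr
from spastab.exceptions import DegenerateStatisticError, DomainError, SingularFitError


def dense_gwr_oracle(y, x, coords, q):
    """Loop-based GWR: per-point normal equations and hat rows."""
    y = np.asarray(y, float)
    X = np.column_stack([np.ones(len(y)), np.asarray(x, float)])
    n = len(y)
    D = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    k = min(max(2, round(q * (n - 1))), n - 1)
    S = np.zeros((n, n))
    beta = np.zeros((n, 2))
    for i in range(n):
        b = np.sort(D[i])[1:][k - 1]
        w = np.exp(-0.5 * (D[i] / b) ** 2)
        A = X.T @ np.diag(w) @ X
        Ainv = np.linalg.inv(A)
        beta[i] = Ainv @ X.T @ np.diag(w) @ y
        S[i] = X[i] @ Ainv @ X.T @ np.diag(w)
    fitted = S @ y
    rss = float(np.sum((y - fitted) ** 2))
    tr_s = float(np.trace(S))
    sigma2 = rss / n
    aicc = n * math.log(sigma2) + n * math.log(2 * math.pi) + n * (n + tr_s) / (n - 2 - tr_s)
    return beta, rss, tr_s, aicc


class TestDistances:
    def test_pythagorean_triple(self):
        D = gwr.distance_matrix(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert D[0, 1] == 5.0 and D[1, 0] == 5.0
        assert D[0, 0] == 0.0 and D[1, 1] == 0.0

    def test_matches_bruteforce(self, rng):
        pts = rng.uniform(0, 50, size=(10, 2))
        D = gwr.distance_matrix(pts)
        for i in range(10):
            for j in range(10):
                assert D[i, j] == pytest.approx(math.hypot(*(pts[i] - pts[j])), abs=1e-12)

    def test_haversine_quarter_meridian(self):
        # pole to equator along a meridian: pi/2 * R
        D = gwr.distance_matrix(np.array([[0.0, 0.0], [0.0, 90.0]]), mode="haversine")
        assert D[0, 1] == pytest.approx(math.pi / 2 * 6371.0, rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(DomainError):
            gwr.distance_matrix(np.array([[0.0, 0.0]]))
        with pytest.raises(DomainError):
            gwr.distance_matrix(np.array([[0.0, np.inf], [1.0, 1.0]]))
        with pytest.raises(DomainError):
            gwr.distance_matrix(np.zeros((3, 2)), mode="mercator")


class TestAdaptiveBandwidths:
    def test_full_fraction_reaches_farthest(self, rng):
        pts = rng.uniform(0, 10, size=(8, 2))
        D = gwr.distance_matrix(pts)
        bw = gwr.adaptive_bandwidths(D, 1.0)
        assert np.allclose(bw, D.max(axis=1))

    def test_collinear_grid_second_nearest(self):
        pts = np.column_stack([np.arange(5.0), np.zeros(5)])
        D = gwr.distance_matrix(pts)
        bw = gwr.adaptive_bandwidths(D, 0.01)  # k clamps to 2
        # interior point 2 km: both neighbours at 1 km, 2nd nearest also 1 km
        assert bw[2] == 1.0
        # endpoint 0: nearest 1 km, 2nd nearest 2 km
        assert bw[0] == 2.0

    def test_duplicate_coordinates_degenerate(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [0.0, 0.0], [5.0, 0.0]])
        D = gwr.distance_matrix(pts)
        with pytest.raises(DegenerateStatisticError):
            gwr.adaptive_bandwidths(D, 0.5)

    def test_needs_three_points(self):
        with pytest.raises(DomainError):
            gwr.adaptive_bandwidths(np.zeros((2, 2)), 0.5)


class TestGaussianWeights:
    @pytest.mark.parametrize(
        "d,b,expected",
        [(0.0, 2.0, 1.0), (2.0, 2.0, math.exp(-0.5)), (6.0, 2.0, math.exp(-4.5))],
    )
    def test_closed_form(self, d, b, expected):
        assert gwr.gaussian_weights(d, b) == pytest.approx(expected, rel=1e-12)

    def test_strictly_decreasing(self):
        d = np.linspace(0, 10, 50)
        w = gwr.gaussian_weights(d, 3.0)
        assert np.all(np.diff(w) < 0)

    def test_nonpositive_bandwidth(self):
        with pytest.raises(DomainError):
            gwr.gaussian_weights(1.0, 0.0)


class TestFitLocal:
    def test_equal_weights_equals_ols(self, rng):
        x = rng.normal(size=30)
        y = 1.0 + 2.0 * x + rng.normal(0, 0.1, size=30)
        X = np.column_stack([np.ones(30), x])
        beta, _ = gwr.fit_local(y, X, np.full(30, 0.7))
        ols = gwr.fit_ols(y, x)
        assert beta == pytest.approx(ols.params, abs=1e-10)

    def test_normal_equations_oracle_n4(self):
        X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0], [1.0, 4.0]])
        y = np.array([0.5, 1.0, 2.5, 3.0])
        w = np.array([1.0, 0.5, 0.25, 2.0])
        A = np.zeros((2, 2))
        b = np.zeros(2)
        for i in range(4):
            A += w[i] * np.outer(X[i], X[i])
            b += w[i] * X[i] * y[i]
        det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
        expect = np.array(
            [(A[1, 1] * b[0] - A[0, 1] * b[1]) / det, (A[0, 0] * b[1] - A[1, 0] * b[0]) / det]
        )
        beta, _ = gwr.fit_local(y, X, w)
        assert beta == pytest.approx(expect, abs=1e-10)

    def test_two_point_interpolation(self):
        X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0], [1.0, 3.0]])
        y = np.array([5.0, 7.0, -100.0, 42.0])
        beta, _ = gwr.fit_local(y, X, np.array([1.0, 1.0, 0.0, 0.0]))
        assert X[0] @ beta == pytest.approx(5.0) and X[1] @ beta == pytest.approx(7.0)

    def test_singular_system_raises(self):
        X = np.ones((4, 2))  # intercept duplicated
        with pytest.raises(SingularFitError):
            gwr.fit_local(np.arange(4.0), X, np.ones(4))


class TestCVScore:
    def test_noiseless_global_line_scores_zero(self, rng):
        coords = rng.uniform(0, 10, size=(20, 2))
        x = rng.normal(size=20)
        y = 3.0 - 1.5 * x
        D = gwr.distance_matrix(coords)
        assert gwr.cv_score(y, x, D, 1.0) == pytest.approx(0.0, abs=1e-18)

    def test_matches_bruteforce_loo(self, rng):
        n = 6
        coords = rng.uniform(0, 10, size=(n, 2))
        x = rng.normal(size=n)
        y = 1 + x + rng.normal(0, 0.5, size=n)
        D = gwr.distance_matrix(coords)
        q = 0.8
        k = min(max(2, round(q * (n - 1))), n - 1)
        X = np.column_stack([np.ones(n), x])
        score = 0.0
        for i in range(n):
            b = np.sort(D[i])[1:][k - 1]
            w = np.exp(-0.5 * (D[i] / b) ** 2)
            w[i] = 0.0
            beta = np.linalg.solve(X.T @ np.diag(w) @ X, X.T @ np.diag(w) @ y)
            score += (y[i] - X[i] @ beta) ** 2
        assert gwr.cv_score(y, x, D, q) == pytest.approx(score, rel=1e-12)

    def test_noisy_score_finite_positive(self, rng):
        coords = rng.uniform(0, 10, size=(25, 2))
        x = rng.normal(size=25)
        y = x + rng.normal(0, 1, size=25)
        D = gwr.distance_matrix(coords)
        s = gwr.cv_score(y, x, D, 0.5)
        assert np.isfinite(s) and s > 0


class TestSelectBandwidth:
    def test_deterministic_given_data(self, rng):
        coords = rng.uniform(0, 100, size=(30, 2))
        x = rng.normal(size=30)
        y = x + rng.normal(0, 0.5, size=30)
        q1, _ = gwr.select_bandwidth(y, x, coords)
        q2, _ = gwr.select_bandwidth(y, x, coords)
        assert q1 == q2

    def test_varying_surface_selects_local_bandwidth(self):
        hits = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            coords = r.uniform(0, 100, size=(129, 2))
            x = r.normal(size=129)
            beta = 1.0 + 4.0 * np.sin(coords[:, 0] / 15)
            y = beta * x + r.normal(0, 0.3, size=129)
            q, _ = gwr.select_bandwidth(y, x, coords)
            hits += q < 0.5
        assert hits >= 45  # >= 90% of 50 seeds

    def test_constant_surface_fits_near_global(self):
        """With spatially constant truth the selected model must behave like
        OLS: every local slope close to the global one."""
        hits = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            coords = r.uniform(0, 100, size=(129, 2))
            x = r.normal(size=129)
            y = 1.0 + 2.0 * x + r.normal(0, 0.5, size=129)
            q, _ = gwr.select_bandwidth(y, x, coords)
            fit = gwr.fit_gwr(y, x, coords, q)
            ols = gwr.fit_ols(y, x)
            hits += np.max(np.abs(fit.slopes - ols.params[1])) < 0.3
        assert hits >= 45

    def test_too_few_points(self, rng):
        with pytest.raises(DomainError):
            gwr.select_bandwidth(np.ones(5), np.ones(5), rng.uniform(size=(5, 2)))


class TestFitGWR:
    def test_ols_limit_at_huge_bandwidth(self, rng):
        coords = rng.uniform(0, 100, size=(40, 2))
        x = rng.normal(size=40)
        y = 2.0 - 0.7 * x + rng.normal(0, 0.3, size=40)
        fit = gwr.fit_gwr(y, x, coords, 1.0, bandwidth_override=1e6 * 100)
        ols = gwr.fit_ols(y, x)
        assert np.max(np.abs(fit.slopes - ols.params[1])) < 1e-6
        assert fit.r2 == pytest.approx(ols.r2, abs=1e-6)

    def test_exact_fit_noiseless(self, rng):
        coords = rng.uniform(0, 100, size=(30, 2))
        x = rng.normal(size=30)
        y = 0.5 + 3.0 * x
        for q in (0.1, 0.5, 1.0):
            fit = gwr.fit_gwr(y, x, coords, q)
            assert fit.rss < 1e-16 * fit.tss + 1e-20

    def test_dense_oracle_equivalence(self, rng):
        n = 8
        coords = rng.uniform(0, 10, size=(n, 2))
        x = rng.normal(size=n)
        y = 1 + x + rng.normal(0, 0.4, size=n)
        q = 0.7
        beta_o, rss_o, trs_o, aicc_o = dense_gwr_oracle(y, x, coords, q)
        fit = gwr.fit_gwr(y, x, coords, q)
        assert fit.params == pytest.approx(beta_o, abs=1e-8)
        assert fit.rss == pytest.approx(rss_o, abs=1e-8)
        assert fit.trace_s == pytest.approx(trs_o, abs=1e-8)
        assert fit.aicc == pytest.approx(aicc_o, abs=1e-8)

    def test_rigid_motion_invariance(self, rng):
        coords = rng.uniform(0, 100, size=(35, 2))
        x = rng.normal(size=35)
        y = x + rng.normal(0, 0.5, size=35)
        fit = gwr.fit_gwr(y, x, coords, 0.5)
        th = 0.83
        R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        moved = coords @ R.T + np.array([250.0, -40.0])
        fit2 = gwr.fit_gwr(y, x, moved, 0.5)
        assert fit2.rss == pytest.approx(fit.rss, rel=1e-9)
        assert fit2.aicc == pytest.approx(fit.aicc, rel=1e-9)
        assert fit2.params == pytest.approx(fit.params, abs=1e-9)
        assert fit2.local_r2 == pytest.approx(fit.local_r2, abs=1e-9)

    def test_linear_gradient_slope_recovery(self):
        """beta(x) = 1 + x/extent with small noise: local slopes recovered to
        mean absolute error < 0.15 in every one of 20 seeds."""
        for seed in range(20):
            r = np.random.default_rng(seed)
            coords = r.uniform(0, 100, size=(129, 2))
            x = r.normal(size=129)
            beta = 1.0 + coords[:, 0] / 100.0
            y = beta * x + r.normal(0, 0.1, size=129)
            q, _ = gwr.select_bandwidth(y, x, coords)
            fit = gwr.fit_gwr(y, x, coords, q)
            assert np.mean(np.abs(fit.slopes - beta)) < 0.15

    def test_local_r2_within_bounds(self, rng):
        coords = rng.uniform(0, 100, size=(50, 2))
        x = rng.normal(size=50)
        y = x + rng.normal(0, 1, size=50)
        fit = gwr.fit_gwr(y, x, coords, 0.3)
        assert np.all(fit.local_r2 >= 0) and np.all(fit.local_r2 <= 1)


class TestFitOLS:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = gwr.fit_ols(2 * x, x)
        assert fit.params == pytest.approx([0.0, 2.0], abs=1e-12)
        assert fit.r2 == pytest.approx(1.0) and fit.rss == pytest.approx(0.0, abs=1e-20)

    def test_hand_normal_equations(self):
        fit = gwr.fit_ols(np.array([0.0, 1.0, 4.0]), np.array([0.0, 1.0, 2.0]))
        assert fit.params[1] == pytest.approx(2.0)
        assert fit.params[0] == pytest.approx(-1.0 / 3.0)

    def test_zero_slope_truth(self, rng):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = np.array([1.0, -1.0, 0.0, -1.0, 1.0])  # symmetric, slope 0
        fit = gwr.fit_ols(y, x)
        # closed form: slope = sum(x*y)/sum(x^2)
        assert fit.params[1] == pytest.approx(float(np.sum(x * y) / np.sum(x * x)), abs=1e-12)

    def test_rank_deficient_errors(self):
        x = np.column_stack([np.ones(5), np.ones(5)])
        with pytest.raises(SingularFitError):
            gwr.fit_ols(np.arange(5.0), x)
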