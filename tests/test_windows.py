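"""Tapered windows, graphical LASSO, Fisher z and variability metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynconn.synthetic import SyntheticSpec, generate_subject_timecourses
from dynconn.windows import (
    PrecisionEstimate,
    TaperSpec,
    build_taper,
    connectivity_variability,
    enumerate_windows,
    glasso_precision,
    precision_to_z,
    residualize_edges,
    select_lambda_cv,
    windowed_covariance,
    WindowedConnectivityStack,
)


def brute_force_taper(L: int, sigma: float) -> np.ndarray:
    """O(L*K) direct double-sum convolution oracle."""
    radius = max(1, int(np.ceil(4 * sigma)))
    offsets = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (offsets / sigma) ** 2)
    kernel /= kernel.sum()
    full = np.zeros(L + 2 * radius)
    for m in range(len(full)):
        for k in range(L):
            j = m - k
            if 0 <= j < len(kernel):
                full[m] += kernel[j]
    w = full[radius : radius + L]
    return w / w.sum()


class TestTaper:
    def test_default_window_22tr_sigma3(self):
        w = build_taper(TaperSpec(22, 3.0, 1))
        assert len(w) == 22
        assert np.all(w >= 0)
        assert abs(w.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(w, w[::-1], atol=1e-12)
        peak = np.argmax(w)
        assert np.all(np.diff(w[: peak + 1]) >= -1e-15)
        assert np.all(np.diff(w[peak:]) <= 1e-15)

    def test_sigma_to_zero_limit_is_uniform(self):
        w = build_taper(TaperSpec(10, 1e-9, 1))
        np.testing.assert_allclose(w, np.full(10, 0.1), atol=1e-12)

    @pytest.mark.parametrize("L,sigma", [(4, 1.0), (7, 2.5), (22, 3.0)])
    def test_matches_direct_convolution_oracle(self, L, sigma):
        np.testing.assert_allclose(
            build_taper(TaperSpec(L, sigma, 1)), brute_force_taper(L, sigma), atol=1e-12
        )


class TestEnumerateWindows:
    def test_printed_count_for_290_volumes(self):
        assert len(enumerate_windows(290, TaperSpec(22, 3.0, 1))) == 269

    def test_degenerate_and_stepped_cases(self):
        assert enumerate_windows(22, TaperSpec(22, 3.0, 1)) == [(0, 22)]
        assert len(enumerate_windows(10, TaperSpec(3, 1.0, 2))) == 4

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter than window"):
            enumerate_windows(10, TaperSpec(22, 3.0, 1))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        T=st.integers(2, 400),
        L=st.integers(2, 50),
        step=st.integers(1, 7),
    )
    def test_count_formula_matches_enumeration(self, T, L, step):
        if T < L:
            return
        wins = enumerate_windows(T, TaperSpec(L, 1.0, step))
        assert len(wins) == (T - L) // step + 1
        assert all(e - s == L for s, e in wins)
        assert wins == sorted(wins)


class TestWindowedCovariance:
    def test_identical_columns_give_unit_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=22)
        data = np.column_stack([x, x])
        S = windowed_covariance(data, (0, 22), build_taper(TaperSpec(22, 3.0, 1)))
        r = S[0, 1] / np.sqrt(S[0, 0] * S[1, 1])
        assert abs(r - 1.0) < 1e-12

    def test_uniform_taper_equals_biased_sample_covariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(22, 4))
        S = windowed_covariance(X, (0, 22), np.ones(22))
        np.testing.assert_allclose(S, np.cov(X, rowvar=False, bias=True), atol=1e-12)

    def test_matches_elementwise_double_loop(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(22, 5))
        w = rng.uniform(0.1, 1.0, 22)
        S = windowed_covariance(X, (0, 22), w)
        wn = w / w.sum()
        mu = np.array([np.sum(wn * X[:, j]) for j in range(5)])
        oracle = np.zeros((5, 5))
        for i in range(5):
            for j in range(5):
                oracle[i, j] = np.sum(wn * (X[:, i] - mu[i]) * (X[:, j] - mu[j]))
        np.testing.assert_allclose(S, oracle, atol=1e-12)

    def test_zero_variance_column_rejected(self):
        X = np.column_stack([np.ones(22), np.random.default_rng(3).normal(size=22)])
        with pytest.raises(ValueError, match="zero-variance column 1"):
            windowed_covariance(X, (0, 22), np.ones(22))


def glasso_proximal_oracle(S, lam, n_iter=60000, step=1e-3):
    """Slow proximal-gradient minimiser of the penalised negative log-likelihood.

    Independent of sklearn: gradient descent on -logdet(T) + tr(S T) with
    soft-thresholding of off-diagonal entries, eigenvalue floor for PD.
    """
    n = S.shape[0]
    T = np.linalg.inv(S + 0.1 * np.eye(n))
    off = ~np.eye(n, dtype=bool)
    for _ in range(n_iter):
        grad = S - np.linalg.inv(T)
        T = T - step * grad
        T[off] = np.sign(T[off]) * np.maximum(np.abs(T[off]) - step * lam, 0.0)
        T = 0.5 * (T + T.T)
        vals, vecs = np.linalg.eigh(T)
        if vals[0] < 1e-8:
            T = vecs @ np.diag(np.maximum(vals, 1e-8)) @ vecs.T
    return T


class TestGlasso:
    def test_lambda_zero_equals_direct_inverse(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(6, 6))
        S = A @ A.T + 6 * np.eye(6)
        est = glasso_precision(S, 0.0)
        np.testing.assert_allclose(est.precision, np.linalg.inv(S), rtol=1e-6)

    def test_diagonal_covariance_unpenalised_diagonal(self):
        S = np.diag([2.0, 0.5, 1.5])
        for lam in (0.01, 0.3, 2.0):
            est = glasso_precision(S, lam)
            np.testing.assert_allclose(est.precision, np.diag(1 / np.diag(S)), atol=1e-8)

    def test_matches_proximal_gradient_oracle(self):
        S = np.array([[1.0, 0.4, 0.1], [0.4, 1.2, 0.3], [0.1, 0.3, 0.9]])
        lam = 0.1
        est = glasso_precision(S, lam)
        oracle = glasso_proximal_oracle(S, lam)
        assert np.max(np.abs(est.precision - oracle)) < 1e-3

    def test_large_lambda_zeroes_all_off_diagonals(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(5, 5))
        S = A @ A.T + 5 * np.eye(5)
        lam = 10 * np.max(np.abs(S - np.diag(np.diag(S))))
        est = glasso_precision(S, lam)
        off = est.precision[~np.eye(5, dtype=bool)]
        assert np.max(np.abs(off)) < 1e-10

    def test_singular_covariance_at_lambda_zero_rejected(self):
        S = np.ones((3, 3))
        with pytest.raises(np.linalg.LinAlgError, match="lambda > 0"):
            glasso_precision(S, 0.0)


class TestLambdaCV:
    @staticmethod
    def _window_covs(rng, precision, n_windows, samples_per_window):
        C = np.linalg.inv(precision)
        L = np.linalg.cholesky(C)
        covs = []
        for _ in range(n_windows):
            X = rng.standard_normal((samples_per_window, C.shape[0])) @ L.T
            covs.append(np.cov(X, rowvar=False, bias=True))
        return covs

    def test_sparse_truth_prefers_positive_lambda(self):
        # tridiagonal (sparse) precision; training samples barely exceed the
        # dimension, so the unregularised MLE overfits the held-out windows
        n = 12
        prec = np.eye(n) * 1.5
        for i in range(n - 1):
            prec[i, i + 1] = prec[i + 1, i] = 0.4
        grid = np.array([0.0, 0.05, 0.2, 0.5])
        wins = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            covs = self._window_covs(rng, prec, n_windows=10, samples_per_window=5)
            lam = select_lambda_cv(covs, grid=grid, n_folds=5)
            wins += lam > 0
        assert wins >= 18

    def test_single_value_grid_returned(self):
        rng = np.random.default_rng(6)
        covs = self._window_covs(rng, np.eye(3), 25, 30)
        assert select_lambda_cv(covs, grid=np.array([0.07]), n_folds=5) == 0.07

    def test_ties_break_toward_larger_lambda(self):
        rng = np.random.default_rng(7)
        covs = self._window_covs(rng, np.eye(3), 25, 30)
        # duplicate grid entries score identically; the duplicate value wins
        lam = select_lambda_cv(covs, grid=np.array([0.2, 0.2]), n_folds=5)
        assert lam == 0.2

    def test_fewer_windows_than_folds_rejected(self):
        with pytest.raises(ValueError, match="fold"):
            select_lambda_cv([np.eye(3)] * 5, grid=np.array([0.1]), n_folds=20)


class TestPrecisionToZ:
    def test_known_values_and_oddness(self):
        # correlation 0.5 -> z = atanh(0.5) = 0.5*ln(3)
        C = np.array([[1.0, 0.5], [0.5, 1.0]])
        est = PrecisionEstimate(C, np.linalg.inv(C), 0.0)
        z = precision_to_z(est)
        assert abs(z[0, 1] - 0.5 * np.log(3.0)) < 1e-12
        Cm = np.array([[1.0, -0.5], [-0.5, 1.0]])
        zm = precision_to_z(PrecisionEstimate(Cm, np.linalg.inv(Cm), 0.0))
        assert abs(zm[0, 1] + z[0, 1]) < 1e-12
        assert z[0, 0] == 0.0 and z[1, 1] == 0.0

    def test_lambda_zero_pipeline_equals_plain_fisher_z(self):
        rng = np.random.default_rng(8)
        A = rng.normal(size=(5, 5))
        S = A @ A.T + 5 * np.eye(5)
        z = precision_to_z(glasso_precision(S, 0.0))
        d = np.sqrt(np.diag(S))
        r = S / np.outer(d, d)
        np.fill_diagonal(r, 0.0)
        assert np.max(np.abs(z - np.arctanh(r))) < 1e-5


class TestResidualize:
    def test_values_linear_in_age_fully_explained(self):
        rng = np.random.default_rng(9)
        age = rng.uniform(65, 85, 40)
        sex = rng.integers(0, 2, 40).astype(float)
        values = np.column_stack([3 * age + 1, -0.5 * age + 7])
        out = residualize_edges(values, age, sex)
        assert np.var(out - out.mean(axis=0)) < 1e-12 * np.var(values)

    def test_independent_covariates_leave_values_nearly_unchanged(self):
        rng = np.random.default_rng(10)
        n = 200
        values = rng.normal(size=(n, 3))
        age = rng.uniform(65, 85, n)
        sex = rng.integers(0, 2, n).astype(float)
        out = residualize_edges(values, age, sex)
        for j in range(3):
            r = np.corrcoef(out[:, j], values[:, j] - values[:, j].mean())[0, 1]
            assert r > 0.99

    def test_grand_intercept_preserves_scale(self):
        rng = np.random.default_rng(11)
        values = rng.normal(loc=0.6, size=(50, 2))
        age = rng.uniform(65, 85, 50)
        sex = rng.integers(0, 2, 50).astype(float)
        out = residualize_edges(values, age, sex)
        np.testing.assert_allclose(out.mean(axis=0), values.mean(axis=0), atol=1e-10)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            residualize_edges(np.array([[1.0]]), np.array([70.0]), np.array([1.0]))

    def test_constant_sex_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(12)
        values = rng.normal(size=(20, 2))
        age = rng.uniform(65, 85, 20)
        with caplog.at_level("WARNING"):
            out = residualize_edges(values, age, np.ones(20))
        assert "sex" in caplog.text
        assert out.shape == values.shape


def random_stack(rng, W=6, N=5):
    z = rng.normal(size=(W, N, N))
    z = (z + z.transpose(0, 2, 1)) / 2
    for i in range(W):
        np.fill_diagonal(z[i], 0.0)
    return WindowedConnectivityStack(z, np.arange(W), "s")


class TestVariability:
    def test_identical_windows_have_zero_sd(self):
        rng = np.random.default_rng(13)
        base = random_stack(rng, W=1).z[0]
        stack = WindowedConnectivityStack(np.repeat(base[None], 5, axis=0), np.arange(5), "s")
        v = connectivity_variability(stack)
        assert np.max(v.per_edge_sd) < 1e-12 and v.global_mean_sd < 1e-12

    def test_alternating_edge_formula(self):
        a = 0.7
        N, W = 4, 4
        z = np.zeros((W, N, N))
        for w in range(W):
            z[w, 0, 1] = z[w, 1, 0] = a if w % 2 == 0 else -a
        v = connectivity_variability(WindowedConnectivityStack(z, np.arange(W), "s"))
        expected = a * np.sqrt(4 / 3)
        assert abs(v.per_edge_sd[0, 1] - expected) < 1e-12
        n_edges = N * (N - 1) // 2
        assert abs(v.global_mean_sd - expected / n_edges) < 1e-12

    def test_global_equals_mean_of_upper_triangle(self):
        rng = np.random.default_rng(14)
        stack = random_stack(rng)
        v = connectivity_variability(stack)
        iu = np.triu_indices(stack.n_networks, k=1)
        assert abs(v.global_mean_sd - v.per_edge_sd[iu].mean()) < 1e-12

    def test_invariant_under_network_permutation(self):
        rng = np.random.default_rng(15)
        stack = random_stack(rng)
        perm = rng.permutation(stack.n_networks)
        permuted = WindowedConnectivityStack(
            stack.z[:, perm][:, :, perm], stack.window_centers, "s"
        )
        v0 = connectivity_variability(stack)
        v1 = connectivity_variability(permuted)
        np.testing.assert_allclose(v1.per_edge_sd, v0.per_edge_sd[perm][:, perm], atol=1e-12)
        np.testing.assert_allclose(v1.per_network_mean_sd, v0.per_network_mean_sd[perm], atol=1e-12)
        assert abs(v1.global_mean_sd - v0.global_mean_sd) < 1e-12

    def test_single_window_rejected(self):
        rng = np.random.default_rng(16)
        with pytest.raises(ValueError, match="2 windows"):
            connectivity_variability(random_stack(rng, W=1))


class TestWindowedBias:
    def test_mean_windowed_correlation_near_planted(self):
        # single planted state r=0.5; average over windows and seeds
        C = np.array([[1.0, 0.5], [0.5, 1.0]])
        spec22 = TaperSpec(22, 3.0, 1)
        taper = build_taper(spec22)
        sspec = SyntheticSpec(1, [C], np.eye(1), n_volumes=80)
        rs = []
        for seed in range(50):
            tc = generate_subject_timecourses(np.ones(80, dtype=int), sspec, seed=seed)
            for win in enumerate_windows(80, spec22):
                S = windowed_covariance(tc.data, win, taper)
                rs.append(S[0, 1] / np.sqrt(S[0, 0] * S[1, 1]))
        assert abs(np.mean(rs) - 0.5) < 0.05
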