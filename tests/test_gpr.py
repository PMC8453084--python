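"""GP regression internals against independent linear-algebra oracles."""

import numpy as np
import pytest

from ageatlas.brainage import (GPRHyperparams, _chol_with_retry, _jitter,
                               _profile_nll_grad, fit_gpr, kernel_matrix,
                               log_marginal_likelihood, predict_gpr)


class TestKernelMatrix:
    def test_zero_input_gives_bias_only(self):
        hp = GPRHyperparams(log_sigma_b=np.log(1.7))
        K = kernel_matrix(np.zeros((1, 4)), np.zeros((1, 4)), hp)
        assert K == pytest.approx(np.array([[1.7 ** 2]]))

    def test_orthonormal_rows_no_bias(self):
        hp = GPRHyperparams(log_sigma_f=0.0, log_sigma_b=-30.0)
        K = kernel_matrix(np.eye(2), np.eye(2), hp)
        assert np.allclose(K, np.eye(2), atol=1e-12)

    @pytest.mark.parametrize("kernel", ["linear", "linear+rbf"])
    def test_brute_force_pairwise_oracle(self, kernel):
        rng = np.random.default_rng(0)
        X1, X2 = rng.normal(size=(4, 3)), rng.normal(size=(5, 3))
        hp = GPRHyperparams(0.2, -0.3, -1.0, kernel=kernel, log_length=0.4)
        K = kernel_matrix(X1, X2, hp)
        sf2, sb2 = hp.sigma_f ** 2, hp.sigma_b ** 2
        for i in range(4):
            for j in range(5):
                want = sf2 * float(X1[i] @ X2[j]) + sb2
                if kernel == "linear+rbf":
                    d2 = float(np.sum((X1[i] - X2[j]) ** 2))
                    want += sf2 * np.exp(-0.5 * d2 / hp.length ** 2)
                assert K[i, j] == pytest.approx(want, rel=1e-12)

    def test_psd_after_jitter(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 2))
        hp = GPRHyperparams()
        K = kernel_matrix(X, X, hp)
        L = _chol_with_retry(K, hp.sigma_n ** 2)
        assert np.all(np.isfinite(L))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="feature dimensions"):
            kernel_matrix(np.zeros((2, 3)), np.zeros((2, 4)), GPRHyperparams())


class TestLogMarginalLikelihood:
    def test_closed_form_n1(self):
        # single subject at x=0: K + sigma_n^2 = sigma_b^2 + sigma_n^2 = 2
        hp = GPRHyperparams(log_sigma_b=0.0, log_sigma_n=0.0)
        y = np.array([0.7])
        lml, _ = log_marginal_likelihood(hp, np.zeros((1, 1)), y)
        want = -0.5 * 0.7 ** 2 / 2 - 0.5 * np.log(2) - 0.5 * np.log(2 * np.pi)
        assert lml == pytest.approx(want, abs=1e-6)

    @pytest.mark.parametrize("kernel", ["linear", "linear+rbf"])
    def test_gradient_matches_central_differences(self, kernel):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(9, 4))
        y = rng.normal(size=9)
        hp = GPRHyperparams(0.3, -0.2, -0.8, kernel=kernel, log_length=0.2)
        _, grad = log_marginal_likelihood(hp, X, y)
        theta = hp.to_vector()
        eps = 1e-6
        for i in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            lp, _ = log_marginal_likelihood(hp.with_vector(tp), X, y)
            lm, _ = log_marginal_likelihood(hp.with_vector(tm), X, y)
            fd = (lp - lm) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_profile_objective_equals_dense(self):
        # the O(n) eigen/Woodbury path is the same function as the dense one
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        G = X @ X.T
        lam, U = np.linalg.eigh(G)
        lam = np.maximum(lam, 0.0)
        u, v = U.T @ np.ones(12), U.T @ y
        for theta in ([0.0, 0.0, -1.0], [0.5, -0.4, 0.2], [-1.0, 1.0, -2.0]):
            hp = GPRHyperparams(*theta)
            K = kernel_matrix(X, X, hp)
            jit = _jitter(K) + 1e-12  # replicate the dense factorization jitter
            nll, _ = _profile_nll_grad(np.array(theta), lam, u, v, jit)
            lml, _ = log_marginal_likelihood(hp, X, y)
            assert nll == pytest.approx(-lml, abs=1e-8)

    def test_profile_gradient_matches_fd(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=15)
        lam, U = np.linalg.eigh(X @ X.T)
        lam = np.maximum(lam, 0.0)
        u, v = U.T @ np.ones(15), U.T @ y
        theta = np.array([0.3, -0.1, -0.5])
        _, grad = _profile_nll_grad(theta, lam, u, v, 0.0)
        eps = 1e-6
        for i in range(3):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            fp, _ = _profile_nll_grad(tp, lam, u, v, 0.0)
            fm, _ = _profile_nll_grad(tm, lam, u, v, 0.0)
            assert grad[i] == pytest.approx((fp - fm) / (2 * eps), rel=1e-5)


class TestFitPredict:
    def test_noiseless_linear_data_interpolated(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0]) + 40.0
        model = fit_gpr(X, y)
        assert model.hyperparams.sigma_n < 0.05
        pred = predict_gpr(model, X)
        assert np.mean(np.abs(pred - y)) < 1e-3

    def test_constant_target_predicts_mean(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 3))
        y = np.full(10, 37.0)
        model = fit_gpr(X, y)
        assert np.allclose(predict_gpr(model, rng.normal(size=(4, 3))), 37.0,
                           atol=1e-6)

    def test_fit_deterministic(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        a = fit_gpr(X, y)
        b = fit_gpr(X, y)
        assert np.array_equal(a.hyperparams.to_vector(),
                              b.hyperparams.to_vector())

    def test_predictive_mean_matches_direct_solve(self):
        # fixed hyperparameters: mean must equal k*' (K + sn^2 I)^-1 y_c + ybar
        # via an independent dense solve, to < 1e-8
        rng = np.random.default_rng(8)
        X = rng.normal(size=(3, 2))
        y = np.array([10.0, 12.0, 9.0])
        hp = GPRHyperparams(0.1, -0.2, np.log(0.5))
        model = fit_gpr(X, y, init=hp, maxiter=0)  # keep init hyperparams
        Xz = (X - model.x_offset) / model.x_scale
        Xnew = rng.normal(size=(6, 2))
        Xnz = (Xnew - model.x_offset) / model.x_scale
        hpf = model.hyperparams
        K = hpf.sigma_f ** 2 * (Xz @ Xz.T) + hpf.sigma_b ** 2
        jit = 1e-8 * np.trace(K) / 3 + 1e-12
        Ks = hpf.sigma_f ** 2 * (Xnz @ Xz.T) + hpf.sigma_b ** 2
        want = Ks @ np.linalg.solve(
            K + (hpf.sigma_n ** 2 + jit) * np.eye(3), y - y.mean()) + y.mean()
        got = predict_gpr(model, Xnew)
        assert np.max(np.abs(got - want)) < 1e-8

    def test_interpolation_at_training_points(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(8, 3))
        y = X @ np.array([2.0, 1.0, -1.0])
        hp = GPRHyperparams(0.0, 0.0, np.log(1e-4))
        model = fit_gpr(X, y, init=hp, maxiter=0)
        assert np.allclose(predict_gpr(model, X), y, atol=1e-6)

    def test_empty_input_empty_output(self):
        rng = np.random.default_rng(10)
        model = fit_gpr(rng.normal(size=(5, 2)), rng.normal(size=5))
        mean, sd = predict_gpr(model, np.empty((0, 2)), return_sd=True)
        assert mean.size == 0 and sd.size == 0

    def test_dimension_mismatch(self):
        rng = np.random.default_rng(11)
        model = fit_gpr(rng.normal(size=(5, 2)), rng.normal(size=5))
        with pytest.raises(ValueError, match="feature dimension"):
            predict_gpr(model, np.zeros((2, 3)))

    def test_sklearn_cross_check(self):
        # same kernel family, fixed hyperparameters, independent implementation
        sklearn = pytest.importorskip("sklearn")
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import ConstantKernel, DotProduct

        rng = np.random.default_rng(12)
        X = rng.normal(size=(12, 3))
        y = rng.normal(size=12) + 5.0
        hp = GPRHyperparams(np.log(1.3), np.log(0.7), np.log(0.4))
        model = fit_gpr(X, y, init=hp, maxiter=0)
        Xz = (X - model.x_offset) / model.x_scale
        k = ConstantKernel(hp.sigma_f ** 2, "fixed") * DotProduct(
            sigma_0=hp.sigma_b / hp.sigma_f, sigma_0_bounds="fixed")
        gp = GaussianProcessRegressor(kernel=k, alpha=hp.sigma_n ** 2,
                                      optimizer=None, normalize_y=False)
        gp.fit(Xz, y - y.mean())
        Xnew = rng.normal(size=(5, 3))
        Xnz = (Xnew - model.x_offset) / model.x_scale
        want = gp.predict(Xnz) + y.mean()
        got = predict_gpr(model, Xnew)
        assert np.allclose(got, want, atol=1e-6)
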