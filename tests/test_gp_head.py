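"""Kernel math, sparse/KISS approximations, and the classification heads."""

import numpy as np
import pytest
from scipy.stats import norm

from bgpseq.autodiff import Parameter, Tensor
from bgpseq.gp_head import (
    InducingPointSet,
    KernelParams,
    KissGPHead,
    SparseGPHead,
    _expected_bernoulli_loglik,
    exact_gp_log_marginal,
    kiss_interpolation,
    kiss_q_ff,
    latent_to_probability,
    predictive_latent,
    rbf_kernel,
    sparse_free_energy,
    svgp_classification_elbo,
)

RNG = np.random.default_rng(3)


class TestRBFKernel:
    def test_unit_diagonal(self):
        x = RNG.standard_normal((5, 3))
        k = rbf_kernel(x, x, KernelParams(outputscale=1.0))
        assert np.allclose(np.diag(k), 1.0)

    def test_one_lengthscale_separation(self):
        k = rbf_kernel(np.array([[0.0]]), np.array([[1.3]]),
                       KernelParams(lengthscale=1.3))
        assert abs(k[0, 0] - np.exp(-0.5)) < 1e-12

    def test_gram_matrix_is_psd(self):
        x = RNG.standard_normal((20, 4))
        k = rbf_kernel(x, x, KernelParams(lengthscale=0.7, outputscale=2.0))
        assert np.linalg.eigvalsh(k).min() >= -1e-8

    def test_invalid_params_raise(self):
        with pytest.raises(ValueError):
            KernelParams(lengthscale=0.0)
        with pytest.raises(ValueError):
            KernelParams(outputscale=-1.0)


class TestExactGP:
    def test_single_point_closed_form(self):
        # k(x,x) + noise^2 = 1, y = 0 -> log p = -0.5 log(2 pi)
        params = KernelParams(outputscale=0.75, noise_sd=0.5)
        val = exact_gp_log_marginal(np.zeros((1, 1)), np.zeros(1), params)
        assert abs(val - (-0.5 * np.log(2 * np.pi))) < 1e-12

    def test_independence_limit_is_sum_of_univariate_densities(self):
        x = np.arange(6, dtype=float)[:, None]
        y = RNG.standard_normal(6)
        params = KernelParams(lengthscale=1e-3, outputscale=0.8, noise_sd=0.6)
        val = exact_gp_log_marginal(x, y, params)
        expected = norm.logpdf(y, 0.0, np.sqrt(0.8 + 0.36)).sum()
        assert abs(val - expected) < 1e-8

    def test_against_independent_dense_oracle(self):
        x = RNG.standard_normal((20, 2))
        y = RNG.standard_normal(20)
        params = KernelParams(lengthscale=1.1, outputscale=0.9, noise_sd=0.4)
        k_n = rbf_kernel(x, x, params) + 0.16 * np.eye(20)
        sign, logdet = np.linalg.slogdet(k_n)
        oracle = (-0.5 * y @ np.linalg.solve(k_n, y) - 0.5 * logdet
                  - 10 * np.log(2 * np.pi))
        assert abs(exact_gp_log_marginal(x, y, params) - oracle) < 1e-8


class TestSparseFreeEnergy:
    def test_full_inducing_set_recovers_exact(self):
        for trial in range(5):
            rng = np.random.default_rng(trial)
            x = rng.standard_normal((20, 2))
            y = rng.standard_normal(20)
            params = KernelParams(lengthscale=1.0 + trial * 0.2,
                                  outputscale=0.7, noise_sd=0.3)
            exact = exact_gp_log_marginal(x, y, params)
            bound = sparse_free_energy(x, y, InducingPointSet(x), params)
            assert abs(exact - bound) < 1e-6

    def test_lower_bound_for_random_subsets(self):
        x = RNG.standard_normal((20, 2))
        y = RNG.standard_normal(20)
        params = KernelParams(lengthscale=0.9, outputscale=1.2, noise_sd=0.35)
        exact = exact_gp_log_marginal(x, y, params)
        for trial in range(50):
            rng = np.random.default_rng(trial)
            sub = rng.choice(20, 5, replace=False)
            bound = sparse_free_energy(x, y, InducingPointSet(x[sub]), params)
            assert bound <= exact + 1e-8


class TestKissInterpolation:
    def test_exact_grid_point(self):
        grid = np.linspace(0, 1, 11)
        w = kiss_interpolation(np.array([0.3]), grid)
        assert np.allclose(sorted(w.weights[0], reverse=True), [1.0, 0.0])

    def test_midpoint_and_thirty_percent(self):
        grid = np.linspace(0.0, 1.0, 2)  # single interval
        w = kiss_interpolation(np.array([0.5, 0.3]), grid)
        assert np.allclose(w.weights[0], [0.5, 0.5])
        assert np.allclose(w.weights[1], [0.7, 0.3])

    def test_rows_sum_to_one_exactly(self):
        grid = np.linspace(-1.1, 1.1, 64)
        x = RNG.uniform(-1.1, 1.1, 200)
        w = kiss_interpolation(x, grid)
        assert np.all(w.weights >= 0)
        assert np.all(w.weights.sum(axis=1) == 1.0)

    def test_out_of_grid_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            w = kiss_interpolation(np.array([2.0]), np.linspace(0, 1, 5))
        assert np.allclose(w.weights.sum(axis=1), 1.0)


class TestKissQff:
    def test_on_grid_inputs_match_nystrom(self):
        grid = np.linspace(-1, 1, 9)
        x = grid[[0, 3, 5]]
        params = KernelParams(lengthscale=0.5)
        q = kiss_q_ff(x, grid, params)
        k_uu = rbf_kernel(grid[:, None], grid[:, None], params)
        k_uf = rbf_kernel(grid[:, None], x[:, None], params)
        nystrom = k_uf.T @ np.linalg.solve(k_uu, k_uf)
        assert np.allclose(q, nystrom, atol=1e-8)

    def test_error_decreases_with_grid_density(self):
        x = RNG.uniform(-1, 1, 40)
        params = KernelParams(lengthscale=0.5)
        k_ff = rbf_kernel(x[:, None], x[:, None], params)
        errs = [np.abs(kiss_q_ff(x, np.linspace(-1.1, 1.1, g), params) - k_ff).max()
                for g in (8, 64, 512)]
        assert errs[0] > errs[1] > errs[2]

    def test_empty_grid_raises(self):
        with pytest.raises(ValueError):
            kiss_q_ff(np.array([0.0]), np.array([]), KernelParams())


class TestLatentToProbability:
    def test_point_mass_at_zero(self):
        assert abs(latent_to_probability(0.0, 0.0) - 0.5) < 1e-12

    def test_large_variance_approaches_half(self):
        p = latent_to_probability(np.array([2.0]), np.array([400.0]))[0]
        assert abs(p - 0.5) < 0.06

    def test_monotone_in_mean(self):
        means = np.linspace(-3, 3, 13)
        probs = latent_to_probability(means, np.full_like(means, 0.7))
        assert np.all(np.diff(probs) > 0)

    def test_matches_antithetic_mc_oracle(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(500_000)
        mc = 0.5 * (
            1 / (1 + np.exp(-(1.0 + z))) + 1 / (1 + np.exp(-(1.0 - z)))
        ).mean()
        gh = latent_to_probability(np.array([1.0]), np.array([1.0]))[0]
        assert abs(gh - mc) < 1e-4

    def test_negative_variance_raises(self):
        with pytest.raises(ValueError):
            latent_to_probability(np.array([0.0]), np.array([-1.0]))


class TestClassificationElbo:
    def test_point_mass_latent_at_zero_gives_log_half(self):
        mean = Tensor(np.zeros(4))
        var = Tensor(np.zeros(4))
        ell = _expected_bernoulli_loglik(mean, var, np.array([0, 1, 0, 1]))
        assert np.allclose(ell.data, np.log(0.5), atol=1e-9)

    def test_quadrature_matches_adaptive_integration_oracle(self):
        from scipy.integrate import quad

        mean, var, y = 0.7, 1.3, 1
        ell = _expected_bernoulli_loglik(
            Tensor(np.array([mean])), Tensor(np.array([var])), np.array([y])
        ).data[0]
        sd = np.sqrt(var)
        oracle, _ = quad(
            lambda f: norm.pdf(f, mean, sd) * -np.logaddexp(0, -f),
            mean - 12 * sd, mean + 12 * sd, limit=200,
        )
        assert abs(ell - oracle) < 1e-4

    def test_whitened_kl_matches_quadratic_form_oracle(self):
        head = SparseGPHead(2, n_inducing=5, rng=np.random.default_rng(2))
        head.variational.mean.data[:] = RNG.standard_normal(5) * 0.5
        head.variational.raw_factor.data[:] += 0.1 * RNG.standard_normal((5, 5))
        c = head.variational.factor().data
        s = c @ c.T
        m = head.variational.mean.data
        sign, logdet = np.linalg.slogdet(s)
        oracle = 0.5 * (np.trace(s) + m @ m - 5 - logdet)
        assert abs(head.variational.kl().item() - oracle) < 1e-8

    def test_labels_must_be_binary(self):
        head = SparseGPHead(2, n_inducing=4, rng=RNG)
        with pytest.raises(ValueError):
            svgp_classification_elbo(Tensor(np.zeros((3, 2))),
                                     np.array([0, 1, 2]), head, 10)


class TestPredictiveLatent:
    def test_prior_state_gives_zero_mean_and_prior_variance(self):
        head = SparseGPHead(3, n_inducing=6, rng=np.random.default_rng(0))
        x = RNG.uniform(-0.5, 0.5, (7, 3))
        mean, var = predictive_latent(x, head)
        assert np.allclose(mean, 0.0, atol=1e-10)
        prior_var = np.logaddexp(0, head.raw_outputscale.data)
        assert np.allclose(var, prior_var, atol=1e-5)

    def test_query_at_inducing_point_recovers_point_mass(self):
        head = SparseGPHead(2, n_inducing=4, rng=np.random.default_rng(1))
        # make the variational distribution a point mass with latent mean 0.9
        # at every inducing point: v = L^{-1} m_vec in the whitened space
        from bgpseq.autodiff import cholesky

        k_uu = head._kernel(head.inducing, head.inducing).data
        l_uu = np.linalg.cholesky(k_uu + 1e-6 * np.eye(4))
        target = np.full(4, 0.9)
        head.variational.mean.data[:] = np.linalg.solve(l_uu, target)
        head.variational.raw_factor.data[:] = np.diag(np.full(4, -20.0))
        mean, var = predictive_latent(head.inducing.data, head)
        assert np.allclose(mean, 0.9, atol=1e-4)
        assert np.all(var < 1e-4)

    def test_batch_equals_one_at_a_time(self):
        head = KissGPHead(3, grid_size=12, rng=np.random.default_rng(2))
        head.variational[0] if False else None
        for v in head.variational:
            v.mean.data[:] = RNG.standard_normal(12) * 0.3
        x = np.tanh(RNG.standard_normal((50, 3)))
        mean_b, var_b = predictive_latent(x, head)
        for i in range(0, 50, 7):
            m1, v1 = predictive_latent(x[i:i + 1], head)
            assert abs(m1[0] - mean_b[i]) < 1e-10
            assert abs(v1[0] - var_b[i]) < 1e-10


class TestKissHead:
    def test_kiss_elbo_converges_to_sparse_elbo_on_grid(self):
        """With inducing points at the grid locations and matched kernels and
        variational states, the 1-D KISS ELBO approaches the free-inducing
        sparse ELBO as the grid refines (they coincide when inputs lie between
        dense grid points)."""
        rng = np.random.default_rng(5)
        x = np.tanh(rng.standard_normal((16, 1)))
        y = rng.integers(0, 2, 16)
        results = []
        for g in (8, 64, 256):
            kiss = KissGPHead(1, grid_size=g, rng=np.random.default_rng(0))
            kiss.raw_lengthscale.data[:] = 0.0
            kiss.raw_outputscale.data[:] = 0.0
            sparse = SparseGPHead(1, n_inducing=g, rng=np.random.default_rng(0))
            sparse.inducing.data[:] = kiss.grid[:, None]
            sparse.raw_lengthscale.data = np.array(0.0)
            sparse.raw_outputscale.data = np.array(0.0)
            # matched nontrivial variational states in the shared whitened space
            vrng = np.random.default_rng(7)
            vmean = 0.5 * np.sin(np.linspace(0, 3, g))
            vfact = 0.05 * np.tril(vrng.standard_normal((g, g)), -1)
            for head in (kiss.variational[0], sparse.variational):
                head.mean.data[:] = vmean
                head.raw_factor.data[:] = np.diag(np.full(g, -1.0)) + vfact
            e_kiss = svgp_classification_elbo(Tensor(x), y, kiss, 16).item()
            e_sparse = svgp_classification_elbo(Tensor(x), y, sparse, 16).item()
            results.append(abs(e_kiss - e_sparse))
        assert results[-1] < results[0]
        assert results[-1] < 5e-3

    def test_probability_outputs_monotone_in_latent_mean(self):
        var = np.full(9, 0.4)
        probs = latent_to_probability(np.linspace(-2, 2, 9), var)
        assert np.all(np.diff(probs) > 0)
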