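import numpy as np
import pytest

from shapeqtl import (
    QTLMixtureModel, e_step, fit_null, log_density, m_step, mixture_loglik,
    run_em,
)
from shapeqtl.errors import EmptyComponentError
from shapeqtl.mixture import fit_mixture_batch, init_from_weights


def sympy_posteriors(Y, omega, mu1, mu2, sigma2):
    """Exact-arithmetic Bayes-rule oracle for the E-step (tiny instances)."""
    import sympy as sp

    n, m = len(Y), len(Y[0])
    out = []
    for i in range(n):
        dens = []
        for mu in (mu1, mu2):
            d2 = sum((sp.Rational(Y[i][k]) - sp.Rational(mu[k])) ** 2
                     for k in range(m))
            dens.append(sp.exp(-d2 / (2 * sp.Rational(sigma2)))
                        / (2 * sp.pi * sp.Rational(sigma2)) ** sp.Rational(m, 2))
        num = [sp.Rational(omega[i][j]) * dens[j] for j in range(2)]
        tot = num[0] + num[1]
        out.append([sp.N(num[j] / tot, 30) for j in range(2)])
    return np.array(out, dtype=float)


class TestLogDensity:
    def test_standard_normal_at_mean(self):
        assert log_density([0.0], [0.0], 1.0) == pytest.approx(
            -0.5 * np.log(2 * np.pi))
        assert log_density([0.0], [0.0], 1.0) == pytest.approx(-0.918939, abs=1e-6)

    def test_zero_residual_any_m(self):
        y = np.arange(7.0)
        assert log_density(y, y, 1.0) == pytest.approx(-3.5 * np.log(2 * np.pi))

    def test_matches_product_of_univariate_densities(self, rng):
        from scipy.stats import norm

        y, mu = rng.standard_normal(4), rng.standard_normal(4)
        s2 = 0.7
        expected = sum(norm.logpdf(y[k], mu[k], np.sqrt(s2)) for k in range(4))
        assert log_density(y, mu, s2) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            log_density([0.0], [0.0], 0.0)


class TestMixtureLoglik:
    def test_identical_components_reduce_to_single_density(self, rng):
        Y = rng.standard_normal((5, 3))
        mu = rng.standard_normal(3)
        model = QTLMixtureModel(mu1=mu, mu2=mu.copy(), sigma2=1.3)
        omega = rng.dirichlet([1, 1], size=5)
        expected = sum(log_density(y, mu, 1.3) for y in Y)
        assert mixture_loglik(Y, omega, model) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_weights_select_one_component(self, rng):
        Y = rng.standard_normal((4, 2))
        model = QTLMixtureModel(mu1=np.zeros(2), mu2=np.ones(2), sigma2=0.5)
        omega = np.tile([1.0, 0.0], (4, 1))
        expected = sum(log_density(y, model.mu1, 0.5) for y in Y)
        assert mixture_loglik(Y, omega, model) == pytest.approx(expected, rel=1e-12)

    def test_matches_exact_arithmetic_oracle(self):
        import sympy as sp

        Y = [[0.5, -1.0], [1.5, 2.0]]
        omega = [[0.3, 0.7], [0.8, 0.2]]
        mu1, mu2, s2 = [0.0, 0.0], [1.0, 1.0], 0.5
        expected = 0
        for i in range(2):
            dens = []
            for mu in (mu1, mu2):
                d2 = sum((sp.Rational(Y[i][k]) - sp.Rational(mu[k])) ** 2
                         for k in range(2))
                dens.append(sp.exp(-d2 / sp.Rational(1)) / (2 * sp.pi * sp.Rational(1, 2)))
            expected += sp.log(sp.Rational(omega[i][0]) * dens[0]
                               + sp.Rational(omega[i][1]) * dens[1])
        model = QTLMixtureModel(mu1=mu1, mu2=mu2, sigma2=s2)
        assert mixture_loglik(np.array(Y), np.array(omega), model) == \
            pytest.approx(float(sp.N(expected, 30)), rel=1e-12)

    def test_invalid_weight_rows_rejected(self, rng):
        Y = rng.standard_normal((2, 2))
        model = QTLMixtureModel(mu1=np.zeros(2), mu2=np.ones(2), sigma2=1.0)
        with pytest.raises(ValueError):
            mixture_loglik(Y, np.array([[0.5, 0.6], [0.5, 0.5]]), model)


class TestEStep:
    def test_equal_means_return_prior(self, rng):
        Y = rng.standard_normal((6, 4))
        mu = rng.standard_normal(4)
        model = QTLMixtureModel(mu1=mu, mu2=mu.copy(), sigma2=0.9)
        omega = rng.dirichlet([2, 1], size=6)
        assert np.allclose(e_step(Y, omega, model), omega, atol=1e-14)

    def test_prior_certainty_is_preserved(self, rng):
        Y = rng.standard_normal((3, 2))
        model = QTLMixtureModel(mu1=np.zeros(2), mu2=np.ones(2), sigma2=1.0)
        omega = np.tile([1.0, 0.0], (3, 1))
        assert np.allclose(e_step(Y, omega, model), omega)

    def test_hand_computed_normal_ratio(self):
        model = QTLMixtureModel(mu1=[0.0], mu2=[2.0], sigma2=1.0)
        post = e_step(np.array([[0.0]]), np.array([[0.5, 0.5]]), model)
        assert post[0, 0] == pytest.approx(1 / (1 + np.exp(-2)), rel=1e-12)
        assert post[0, 0] == pytest.approx(0.880797, abs=1e-6)

    def test_matches_exact_bayes_oracle_to_twelve_digits(self, rng):
        Y = np.round(rng.standard_normal((4, 3)), 3)
        omega = np.round(rng.dirichlet([1, 1], size=4), 3)
        omega[:, 1] = 1 - omega[:, 0]
        mu1 = np.round(rng.standard_normal(3), 3)
        mu2 = np.round(rng.standard_normal(3), 3)
        model = QTLMixtureModel(mu1=mu1, mu2=mu2, sigma2=0.75)
        got = e_step(Y, omega, model)
        want = sympy_posteriors(Y.tolist(), omega.tolist(), mu1.tolist(),
                                mu2.tolist(), 0.75)
        assert np.abs(got - want).max() < 1e-12


class TestMStep:
    def test_hard_posteriors_give_group_means(self, rng):
        Y = rng.standard_normal((6, 3))
        post = np.zeros((6, 2))
        post[:3, 0] = 1
        post[3:, 1] = 1
        model = m_step(Y, post)
        assert np.allclose(model.mu1, Y[:3].mean(axis=0))
        assert np.allclose(model.mu2, Y[3:].mean(axis=0))
        pooled = (((Y[:3] - Y[:3].mean(0)) ** 2).sum()
                  + ((Y[3:] - Y[3:].mean(0)) ** 2).sum()) / Y.size
        assert model.sigma2 == pytest.approx(pooled, rel=1e-12)

    def test_uniform_posteriors_give_grand_mean(self, rng):
        Y = rng.standard_normal((5, 2))
        model = m_step(Y, np.full((5, 2), 0.5))
        assert np.allclose(model.mu1, Y.mean(axis=0))
        assert np.allclose(model.mu2, Y.mean(axis=0))

    def test_hand_computed_weighted_mean(self):
        Y = np.array([[1.0], [2.0], [4.0]])
        post = np.array([[0.8, 0.2], [0.5, 0.5], [0.1, 0.9]])
        model = m_step(Y, post)
        assert model.mu1[0] == pytest.approx(2.2 / 1.4, rel=1e-12)
        assert model.mu1[0] == pytest.approx(1.571429, abs=1e-6)

    def test_empty_component_rejected(self, rng):
        Y = rng.standard_normal((3, 2))
        post = np.tile([1.0, 0.0], (3, 1))
        with pytest.raises(EmptyComponentError):
            m_step(Y, post)


class TestFitNull:
    def test_hand_mle(self):
        mu0, s0, ll0 = fit_null(np.array([[0.0], [2.0]]))
        assert mu0[0] == pytest.approx(1.0)
        assert s0 == pytest.approx(1.0)
        assert ll0 == pytest.approx(2 * log_density([1.0], [1.0], 1.0) - 1.0)

    def test_identical_rows_hit_variance_floor(self):
        _, s0, _ = fit_null(np.ones((3, 2)))
        assert s0 == pytest.approx(1e-12)

    def test_null_never_beats_mixture(self, rng):
        Y = rng.standard_normal((10, 4)) + np.r_[np.zeros(5), np.full(5, 2.0)][:, None]
        omega = np.tile([0.5, 0.5], (10, 1))
        omega[:5] = [0.9, 0.1]
        omega[5:] = [0.1, 0.9]
        _, _, ll0 = fit_null(Y)
        model, _ = run_em(Y, omega)
        assert model.loglik >= ll0 - 1e-8


class TestRunEM:
    def _separated_data(self, rng, n=60, m=20, delta=3.0, sigma=1.0):
        xi = rng.random(n) < 0.5
        mu1 = np.zeros(m)
        mu2 = np.full(m, delta)
        Y = np.where(xi[:, None], mu1, mu2) + sigma * rng.standard_normal((n, m))
        omega = np.where(xi[:, None], [0.9, 0.1], [0.1, 0.9])
        return Y, omega, xi, mu1, mu2, sigma

    def test_recovers_well_separated_means(self, rng):
        Y, omega, xi, mu1, mu2, sigma = self._separated_data(rng)
        model, state = run_em(Y, omega)
        n1, n2 = xi.sum(), (~xi).sum()
        m = Y.shape[1]
        assert np.linalg.norm(model.mu1 - mu1) / np.sqrt(m) < 3 * sigma / np.sqrt(n1)
        assert np.linalg.norm(model.mu2 - mu2) / np.sqrt(m) < 3 * sigma / np.sqrt(n2)
        labels = state.posteriors[:, 0] > 0.5
        assert (labels == xi).mean() > 0.95

    def test_symmetric_start_is_a_fixed_point(self, rng):
        Y = rng.standard_normal((8, 3))
        grand = Y.mean(axis=0)
        _, s0, ll0 = fit_null(Y)
        init = QTLMixtureModel(mu1=grand, mu2=grand.copy(), sigma2=s0)
        omega = np.full((8, 2), 0.5)
        model, state = run_em(Y, omega, init=init)
        assert state.n_iter <= 1
        assert np.allclose(model.mu1, grand) and np.allclose(model.mu2, grand)
        # with equal components the mixture collapses to the null density
        assert model.loglik == pytest.approx(ll0, rel=1e-12)

    def test_loglik_trace_never_decreases(self, rng):
        Y, omega, *_ = self._separated_data(rng, delta=1.0)
        _, state = run_em(Y, omega)
        assert (np.diff(state.loglik_trace) >= -1e-8).all()

    def test_uninformative_weights_reduce_to_null_fit(self, rng):
        """Flat weights + symmetric init collapse to the single-component MLE."""
        Y = rng.standard_normal((10, 4))
        mu0, s0, _ = fit_null(Y)
        init = QTLMixtureModel(mu1=mu0, mu2=mu0.copy(), sigma2=s0)
        model, _ = run_em(Y, np.full((10, 2), 0.5), init=init)
        assert np.allclose(model.mu1, mu0)
        assert np.allclose(model.mu2, mu0)
        assert model.sigma2 == pytest.approx(s0, rel=1e-12)

    def test_posterior_rows_sum_to_one(self, rng):
        Y, omega, *_ = self._separated_data(rng)
        _, state = run_em(Y, omega)
        assert np.abs(state.posteriors.sum(axis=1) - 1).max() < 1e-10


class TestBatchedEM:
    def test_matches_reference_run_em(self, rng):
        """The batched scan core and the reference EM land on the same optimum."""
        n, m = 40, 12
        xi = rng.random(n) < 0.5
        Y = np.where(xi[:, None], 0.0, 2.5) + rng.standard_normal((n, m))
        omegas = []
        for _ in range(5):
            o = rng.dirichlet([1, 1], size=n)
            o[:, 1] = 1 - o[:, 0]
            omegas.append(o)
        omegas = np.stack(omegas)
        _, _, ll0 = fit_null(Y)
        ll_batch = fit_mixture_batch(Y, omegas, tol=1e-8)
        for b in range(5):
            model, _ = run_em(Y, omegas[b], tol=1e-8)
            ref = max(model.loglik, ll0)
            assert ll_batch[b] == pytest.approx(ref, abs=1e-3)

    def test_init_from_weights_uses_hard_assignment(self, rng):
        Y = rng.standard_normal((6, 2))
        omega = np.array([[0.9, 0.1]] * 3 + [[0.2, 0.8]] * 3)
        init = init_from_weights(Y, omega)
        assert np.allclose(init.mu1, Y[:3].mean(axis=0))
        assert np.allclose(init.mu2, Y[3:].mean(axis=0))
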