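"""SGHMC kernel: update arithmetic, stochastic-gradient unbiasedness,
stationary-distribution correctness."""

import numpy as np
import pytest

from sgais.engine import HistoryStore
from sgais.model_api import ContractError
from sgais.sghmc import (
    DivergenceError,
    PotentialSpec,
    SGHMCConfig,
    sghmc_run,
    sghmc_step,
    stochastic_potential_grad,
)


class TestStepArithmetic:
    def test_fixed_point_with_zero_noise(self, rng):
        cfg = SGHMCConfig(eta=0.1, alpha=0.2, beta_hat=0.2, n_steps=1)
        theta, v = sghmc_step(np.zeros(3), np.zeros(3), np.zeros(3), cfg, rng)
        np.testing.assert_array_equal(theta, 0.0)
        np.testing.assert_array_equal(v, 0.0)

    def test_momentum_decay_update(self, rng):
        # v' = v - eta*grad - alpha*v; theta' = theta + v'
        cfg = SGHMCConfig(eta=0.1, alpha=0.2, beta_hat=0.2, n_steps=1)
        theta, v = sghmc_step(np.array([1.0]), np.array([1.0]), np.array([0.0]), cfg, rng)
        assert v.item() == pytest.approx(0.8)
        assert theta.item() == pytest.approx(1.8)

    def test_deterministic_when_noise_cancelled(self):
        cfg = SGHMCConfig(eta=0.05, alpha=0.3, beta_hat=0.3, n_steps=1)
        out1 = sghmc_step(np.ones(2), np.ones(2), np.ones(2), cfg, np.random.default_rng(1))
        out2 = sghmc_step(np.ones(2), np.ones(2), np.ones(2), cfg, np.random.default_rng(99))
        np.testing.assert_array_equal(out1[0], out2[0])

    def test_same_rng_stream_reproduces(self):
        cfg = SGHMCConfig(eta=0.05, alpha=0.3, n_steps=1)
        a = sghmc_step(np.ones(2), np.zeros(2), np.ones(2), cfg, np.random.default_rng(7))
        b = sghmc_step(np.ones(2), np.zeros(2), np.ones(2), cfg, np.random.default_rng(7))
        np.testing.assert_array_equal(a[0], b[0])

    def test_non_finite_gradient_raises(self, rng):
        cfg = SGHMCConfig(eta=0.1)
        with pytest.raises(DivergenceError):
            sghmc_step(np.zeros(2), np.zeros(2), np.array([np.inf, 0.0]), cfg, rng)

    @pytest.mark.parametrize(
        "kw", [dict(eta=-1.0), dict(eta=0.1, alpha=0.0), dict(eta=0.1, beta_hat=0.5, alpha=0.2)]
    )
    def test_config_validation(self, kw):
        with pytest.raises(ContractError):
            SGHMCConfig(**kw)


class TestStochasticPotential:
    def test_no_history_term_when_stream_empty(self, conjugate_model):
        chunk = np.array([[1.0], [2.0]])
        pot = PotentialSpec(model=conjugate_model, lam=0.5, chunk=chunk, n_prev=0)
        theta = np.array([0.3])
        g = stochastic_potential_grad(pot, theta, None)
        expected = -0.5 * conjugate_model.grad_loglik_sum(theta, chunk) - (
            conjugate_model.grad_log_prior(theta)
        )
        np.testing.assert_allclose(g, expected)

    def test_full_batch_recovers_exact_gradient(self, conjugate_model, rng):
        hist = rng.normal(size=(20, 1))
        chunk = rng.normal(size=(5, 1))
        store = HistoryStore(1)
        store.extend(hist)
        pot = PotentialSpec(model=conjugate_model, lam=1.0, chunk=chunk,
                            history=store, n_prev=20)
        theta = np.array([0.1])
        g = stochastic_potential_grad(pot, theta, hist)
        exact = -(
            conjugate_model.grad_loglik_sum(theta, chunk)
            + conjugate_model.grad_loglik_sum(theta, hist)
            + conjugate_model.grad_log_prior(theta)
        )
        np.testing.assert_allclose(g, exact)

    def test_empty_batch_with_history_raises(self, conjugate_model):
        pot = PotentialSpec(model=conjugate_model, lam=1.0,
                            chunk=np.ones((1, 1)), history=HistoryStore(1), n_prev=3)
        with pytest.raises(ContractError):
            stochastic_potential_grad(pot, np.array([0.0]), np.empty((0, 1)))

    def test_minibatch_estimator_unbiased(self, conjugate_model, rng):
        # average over many batch draws approaches the full-history gradient
        hist = rng.normal(size=(50, 1)) + 0.4
        store = HistoryStore(1)
        store.extend(hist)
        chunk = np.empty((0, 1))
        pot = PotentialSpec(model=conjugate_model, lam=0.0, chunk=chunk,
                            history=store, n_prev=50)
        theta = np.array([0.2])
        exact = -(
            conjugate_model.grad_loglik_sum(theta, hist)
            + conjugate_model.grad_log_prior(theta)
        )
        draws = np.array(
            [
                stochastic_potential_grad(pot, theta, store.sample_batch(rng, 5))[0]
                for _ in range(10_000)
            ]
        )
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - exact[0]) < 3.0 * se


def _quadratic_variance(eta: float, alpha: float, n_chains: int, n_steps: int,
                        burn: int, seed: int) -> float:
    """Pooled stationary variance of theta for U = theta^2/2 (target var 1)."""
    rng = np.random.default_rng(seed)
    theta = rng.normal(size=n_chains)
    v = np.zeros(n_chains)
    cfg = SGHMCConfig(eta=eta, alpha=alpha, n_steps=1)
    acc = 0.0
    acc2 = 0.0
    count = 0
    for i in range(n_steps):
        theta, v = sghmc_step(theta, v, theta, cfg, rng)
        if i >= burn:
            acc += theta.sum()
            acc2 += (theta ** 2).sum()
            count += theta.size
    mean = acc / count
    return acc2 / count - mean ** 2


class TestStationaryDistribution:
    def test_quadratic_variance_near_target(self):
        var = _quadratic_variance(1e-3, 0.1, n_chains=200, n_steps=25_000,
                                  burn=5_000, seed=0)
        assert 0.95 <= var <= 1.05

    def test_bias_shrinks_with_step_size(self):
        biases = {
            eta: abs(
                _quadratic_variance(eta, 0.1, n_chains=200, n_steps=20_000,
                                    burn=3_000, seed=1) - 1.0
            )
            for eta in (1e-1, 1e-2, 1e-3)
        }
        assert biases[1e-1] > biases[1e-2]
        assert biases[1e-3] < biases[1e-1]

    def test_conjugate_posterior_moments(self, conjugate_model, rng):
        # target: posterior of the Gaussian-mean model given 10 observations
        records = conjugate_model.sample_records(np.array([0.8]), 10, rng)
        n, ybar = len(records), records.mean()
        post_var = 1.0 / (n + 1.0)
        post_mean = n * ybar * post_var
        pot = PotentialSpec(model=conjugate_model, lam=1.0, chunk=records, n_prev=0)
        cfg = SGHMCConfig(eta=2e-3, alpha=0.1, n_steps=1, batch_size=None)
        theta = np.zeros((100, 1))
        v = np.zeros_like(theta)
        samples = []
        for i in range(20_000):
            theta, v = sghmc_run(theta, v, pot, cfg, rng)
            if i >= 4_000:
                samples.append(theta[:, 0].copy())
        S = np.concatenate(samples)
        # autocorrelation-aware standard errors (tau ~ alpha/eta steps)
        n_eff = S.size / (0.1 / 2e-3)
        se_mean = np.sqrt(post_var / n_eff)
        assert abs(S.mean() - post_mean) < 3 * se_mean
        se_var = post_var * np.sqrt(2.0 / n_eff)
        assert abs(S.var() - post_var) < 3 * se_var + 0.05 * post_var


def test_run_with_one_step_equals_single_step(conjugate_model):
    records = np.array([[0.5]])
    pot = PotentialSpec(model=conjugate_model, lam=1.0, chunk=records, n_prev=0)
    cfg = SGHMCConfig(eta=0.01, alpha=0.2, n_steps=1, batch_size=None)
    theta0, v0 = np.array([[0.2]]), np.array([[0.1]])
    out_run = sghmc_run(theta0, v0, pot, cfg, np.random.default_rng(3))
    grad = stochastic_potential_grad(pot, theta0, None)
    out_step = sghmc_step(theta0, v0, grad, cfg, np.random.default_rng(3))
    np.testing.assert_allclose(out_run[0], out_step[0])


def test_run_reproducible_under_seed(conjugate_model, rng):
    records = rng.normal(size=(8, 1))
    store = HistoryStore(1)
    store.extend(records[:5])
    pot = PotentialSpec(model=conjugate_model, lam=0.7, chunk=records[5:],
                        history=store, n_prev=5)
    cfg = SGHMCConfig(eta=0.01, alpha=0.2, n_steps=10, batch_size=3)
    a = sghmc_run(np.zeros((4, 1)), np.zeros((4, 1)), pot, cfg, np.random.default_rng(11))
    b = sghmc_run(np.zeros((4, 1)), np.zeros((4, 1)), pot, cfg, np.random.default_rng(11))
    np.testing.assert_array_equal(a[0], b[0])
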