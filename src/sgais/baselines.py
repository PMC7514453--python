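"""Vanilla annealed importance sampling and nested sampling baselines.

Both serve as accuracy references for the online estimator and share its
SGHMC kernel: AIS uses full-data gradients along a sigmoidal temperature
ladder; nested sampling uses SGHMC on the *prior* with rejection of moves
that violate the rising likelihood constraint.  Neither can mini-batch —
AIS needs full-data likelihoods for its weights, NS for its constraint —
which is exactly the cost the online estimator avoids.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp

from . import model_api, sghmc
from .model_api import ContractError, Dataset, ModelSpec
from .results import EvidenceResults

__all__ = [
    "AISConfig",
    "NSConfig",
    "sigmoid_schedule",
    "ais_run",
    "ns_run",
    "AIS",
    "NestedSampler",
]


def _records_of(data) -> np.ndarray:
    return data.records if isinstance(data, Dataset) else np.asarray(data, float)


# ---------------------------------------------------------------------------
# AIS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AISConfig:
    """Vanilla AIS parameters: T temperatures on a sigmoidal ladder of
    sharpness delta, full-data SGHMC mutation between weight updates."""

    n_temps: int = 100
    delta: float = 4.0
    n_particles: int = 10
    steps_per_temp: int = 20
    lr: float = 0.1
    alpha: float = 0.2
    beta_hat: float = 0.0

    def __post_init__(self) -> None:
        if self.n_temps < 1:
            raise ContractError("n_temps must be >= 1")
        if self.delta <= 0:
            raise ContractError("delta must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def sigmoid_schedule(T: int, delta: float = 4.0) -> np.ndarray:
    """Sigmoidal temperature ladder, affinely rescaled to [0, 1].

    lam_t = sigma(delta * (2t/T - 1)) hits neither 0 nor 1 exactly, so the
    ladder is shifted and scaled so lam_0 = 0 and lam_T = 1; it is strictly
    increasing, and tends to the linear schedule as delta -> 0.
    """
    if T < 1:
        raise ContractError("T must be >= 1")
    t = np.arange(T + 1)
    raw = expit(delta * (2.0 * t / T - 1.0))
    return (raw - raw[0]) / (raw[-1] - raw[0])


def ais_run(model: ModelSpec, data, cfg: AISConfig = AISConfig(),
            seed: int = 0) -> float:
    """One AIS pass over the full dataset; returns log Zhat.

    Weights accumulate p(D|theta_i)^(lam_t - lam_{t-1}) at each rung, with
    the likelihood evaluated *before* the mutation, exactly as the weight
    recursion requires; mutation targets p(D|theta)^lam_t p(theta) with
    exact full-data gradients and step size lr/N.
    """
    records = _records_of(data)
    if records.shape[0] == 0:
        raise ContractError("AIS requires a nonempty dataset")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    M = cfg.n_particles
    theta = np.atleast_2d(model.sample_prior(rng, M)).reshape(M, model.dim)
    v = np.zeros_like(theta)
    log_w = np.zeros(M)
    lams = sigmoid_schedule(cfg.n_temps, cfg.delta)
    kernel_cfg = sghmc.SGHMCConfig(
        eta=cfg.lr / len(records),
        alpha=cfg.alpha,
        beta_hat=cfg.beta_hat,
        n_steps=cfg.steps_per_temp,
        batch_size=None,
    )
    for lam_prev, lam in zip(lams[:-1], lams[1:]):
        ell = model_api.loglik_terms(model, theta, records).sum(axis=-1)
        log_w = log_w + (lam - lam_prev) * ell
        if not np.any(log_w > -np.inf):
            raise RuntimeError("AIS weights degenerated to zero")
        pot = sghmc.PotentialSpec(model=model, lam=lam, chunk=records,
                                  history=None, n_prev=0)
        theta, v = sghmc.sghmc_run(theta, v, pot, kernel_cfg, rng)
    return float(logsumexp(log_w) - np.log(M))


class AIS:
    """Vanilla AIS estimator with the statsmodels-style fit() surface."""

    def __init__(self, model: ModelSpec, data, config: Optional[AISConfig] = None,
                 **overrides):
        self.model = model
        self.data = data
        base = config.to_dict() if config is not None else {}
        base.update(overrides)
        self.config = AISConfig(**base)

    def fit(self, seed: int = 0) -> EvidenceResults:
        t0 = time.perf_counter()
        records = _records_of(self.data)
        log_z = ais_run(self.model, records, self.config, seed=seed)
        n = len(records)
        grad_evals = (
            self.config.n_temps * self.config.steps_per_temp
            * self.config.n_particles * n
        )
        trace = pd.DataFrame(
            {
                "n_seen": [0, n],
                "log_evidence": [0.0, log_z],
                "annealing_steps": [0, self.config.n_temps],
                "predictive_logprob": [0.0, log_z],
                "cum_grad_evals": [0, grad_evals],
            }
        )
        return EvidenceResults(
            method="ais",
            model_name=self.model.name,
            n_obs=n,
            log_evidence=log_z,
            trace=trace,
            config=self.config.to_dict(),
            seed=seed,
            grad_evals=grad_evals,
            runtime_s=time.perf_counter() - t0,
        )


# ---------------------------------------------------------------------------
# Nested sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NSConfig:
    """Nested-sampling parameters.

    The constrained-prior sampler takes ``steps`` SGHMC moves on the prior
    potential, rejecting any move that violates the likelihood bound and
    *reflecting* the momentum on rejection so the chain bounces off the
    constraint surface instead of sticking to it (a chain that zeroes its
    momentum gets pinned against the boundary on the side the prior
    gradient pushes towards, which systematically biases the evidence low).
    The prior has no gradient noise, hence the fixed, absolute step size
    ``eta``.  Shrinkage uses the deterministic expectation
    X_k = exp(-k / n_live).
    """

    n_live: int = 2
    steps: int = 20
    eta: float = 1e-3
    alpha: float = 0.1
    beta_hat: float = 0.0
    stop_fraction: float = 0.01
    max_iter: int = 200_000
    stall_limit: int = 1000

    def __post_init__(self) -> None:
        if self.n_live < 2:
            raise ContractError("n_live must be >= 2")
        if not 0.0 < self.stop_fraction < 1.0:
            raise ContractError("stop_fraction must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


def _log_diff_exp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a > b."""
    return a + np.log1p(-np.exp(b - a))


def _constrained_prior_move(model: ModelSpec, theta: np.ndarray, l_min: float,
                            records: np.ndarray, cfg: NSConfig,
                            rng: np.random.Generator) -> tuple[np.ndarray, float, int]:
    """SGHMC walk on the prior restricted to loglik > l_min.

    Rejected proposals reverse the momentum, bouncing the chain back into
    the constrained region.  Returns (new theta, its log-likelihood,
    number of accepted moves).
    """
    kernel_cfg = sghmc.SGHMCConfig(
        eta=cfg.eta, alpha=cfg.alpha, beta_hat=cfg.beta_hat,
        n_steps=1, batch_size=None,
    )
    v = np.zeros_like(theta)
    ell = None
    accepted = 0
    for _ in range(cfg.steps):
        grad = -model_api.grad_log_prior(model, theta)
        prop, v_new = sghmc.sghmc_step(theta, v, grad, kernel_cfg, rng)
        prop_ell = float(model_api.loglik_terms(model, prop, records).sum())
        if prop_ell > l_min:
            theta, v, ell = prop, v_new, prop_ell
            accepted += 1
        else:
            v = -v_new  # reflect momentum off the constraint surface
    if ell is None:
        ell = float(model_api.loglik_terms(model, theta, records).sum())
    return theta, ell, accepted


def ns_run(model: ModelSpec, data, cfg: NSConfig = NSConfig(),
           seed: int = 0) -> float:
    """Standard nested-sampling evidence estimate; returns log Zhat.

    The lowest-likelihood live point is repeatedly retired with prior-volume
    weight X_{k-1} - X_k and replaced by a constrained-prior draw started
    from a surviving live point.  The loop stops once the largest possible
    remaining increment falls below ``stop_fraction`` of the running
    estimate, then the surviving live points contribute the final slab.
    """
    records = _records_of(data)
    if records.shape[0] == 0:
        raise ContractError("nested sampling requires a nonempty dataset")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    n_live = cfg.n_live
    live = np.atleast_2d(model.sample_prior(rng, n_live)).reshape(n_live, model.dim)
    log_l = model_api.loglik_terms(model, live, records).sum(axis=-1)

    log_z = -np.inf
    log_x_prev = 0.0
    stalled = 0
    for k in range(1, cfg.max_iter + 1):
        worst = int(np.argmin(log_l))
        l_min = float(log_l[worst])
        log_x = -k / n_live
        log_w = _log_diff_exp(log_x_prev, log_x)
        log_z = np.logaddexp(log_z, l_min + log_w)

        start = int(rng.choice([i for i in range(n_live) if i != worst]))
        theta, ell, accepted = _constrained_prior_move(
            model, live[start].copy(), l_min, records, cfg, rng
        )
        live[worst] = theta
        log_l[worst] = ell
        if accepted == 0:
            stalled += 1
            if stalled >= cfg.stall_limit:
                warnings.warn(
                    f"constrained sampler stalled for {stalled} consecutive "
                    "iterations; estimate may be degraded",
                    RuntimeWarning,
                )
                stalled = 0
        else:
            stalled = 0
        log_x_prev = log_x
        # largest possible remaining contribution vs. current estimate
        if float(np.max(log_l)) + log_x < np.log(cfg.stop_fraction) + log_z:
            break
    else:
        raise RuntimeError("nested sampling failed to terminate within max_iter")

    # final live-point slab: mean live likelihood times remaining volume
    log_z = np.logaddexp(log_z, logsumexp(log_l) - np.log(n_live) + log_x_prev)
    return float(log_z)


class NestedSampler:
    """Nested-sampling estimator with the statsmodels-style fit() surface."""

    def __init__(self, model: ModelSpec, data, config: Optional[NSConfig] = None,
                 **overrides):
        self.model = model
        self.data = data
        base = config.to_dict() if config is not None else {}
        base.update(overrides)
        self.config = NSConfig(**base)

    def fit(self, seed: int = 0) -> EvidenceResults:
        t0 = time.perf_counter()
        records = _records_of(self.data)
        log_z = ns_run(self.model, records, self.config, seed=seed)
        n = len(records)
        trace = pd.DataFrame(
            {
                "n_seen": [0, n],
                "log_evidence": [0.0, log_z],
                "annealing_steps": [0, 0],
                "predictive_logprob": [0.0, log_z],
                "cum_grad_evals": [0, 0],
            }
        )
        return EvidenceResults(
            method="ns",
            model_name=self.model.name,
            n_obs=n,
            log_evidence=log_z,
            trace=trace,
            config=self.config.to_dict(),
            seed=seed,
            grad_evals=0,
            runtime_s=time.perf_counter() - t0,
        )
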