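"""Stochastic gradient Hamiltonian Monte Carlo (SGHMC) transition kernel.

The kernel simulates underdamped Langevin dynamics whose stationary law is
``p(theta, v) ∝ exp(-U(theta) - v^2/2)``, discretised as

    v' = v - eta * grad_U(theta) - alpha * v + N(0, 2 (alpha - beta_hat) eta)
    theta' = theta + v'

where ``eta`` is the learning rate, ``1 - alpha`` the momentum decay and
``beta_hat`` an optional offset for the variance contributed by stochastic
gradient noise (0 by default: that noise is O(eta^2) against the O(eta)
injected noise, so it vanishes in the small-eta limit).  The velocity is
updated first and the position moved with the *new* velocity (semi-implicit
Euler), the standard stable discretisation.  No Metropolis correction is
applied — the kernel is approximate with O(eta) bias.

The potential is the annealed, partially-observed negative log joint

    U_hat(theta) = -lam * log p(chunk|theta)
                   - (n_prev/|B|) * sum_{y in B} log p(y|theta)
                   - log p(theta)

with the mini-batch B drawn i.i.d. with replacement from the history of
previously absorbed observations, making U_hat an unbiased estimator of the
full potential.  With ``batch_size=None`` the full history is used and the
gradient is exact.

All functions are shape-agnostic in the leading axes: ``theta`` and ``v``
may be single vectors ``(d,)`` or particle stacks ``(M, d)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import model_api
from .model_api import ContractError, ModelSpec

__all__ = [
    "SGHMCConfig",
    "PotentialSpec",
    "stochastic_potential_grad",
    "sghmc_step",
    "sghmc_run",
    "DivergenceError",
]


class DivergenceError(FloatingPointError):
    """A particle produced a non-finite gradient."""


@dataclass(frozen=True)
class SGHMCConfig:
    """Discretisation parameters of the SGHMC update.

    ``eta`` is the *absolute* step size actually used in the update; callers
    working with per-observation learning rates divide by the current number
    of observations before constructing the config.
    """

    eta: float
    alpha: float = 0.2
    beta_hat: float = 0.0
    n_steps: int = 20
    batch_size: Optional[int] = 500

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ContractError("eta must be positive")
        if not 0.0 < self.alpha <= 1.0:
            raise ContractError("alpha must lie in (0, 1]")
        if not 0.0 <= self.beta_hat <= self.alpha:
            raise ContractError("beta_hat must lie in [0, alpha]")
        if self.n_steps < 1:
            raise ContractError("n_steps must be >= 1")
        if self.batch_size is not None and self.batch_size < 1:
            raise ContractError("batch_size must be >= 1 (or None for full data)")


@dataclass(frozen=True)
class PotentialSpec:
    """The annealed stochastic potential over (chunk, history, prior).

    ``history`` is anything with ``sample_batch(rng, size)`` returning
    records (the exhaustive store or a reservoir); it may be None when
    ``n_prev == 0``.
    """

    model: ModelSpec
    lam: float
    chunk: np.ndarray
    history: Optional[object] = None
    n_prev: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ContractError("lam must lie in [0, 1]")
        if self.n_prev < 0:
            raise ContractError("n_prev must be >= 0")
        if self.n_prev > 0 and self.history is None:
            raise ContractError("history source required when n_prev > 0")


def stochastic_potential_grad(pot: PotentialSpec, theta: np.ndarray,
                              batch: Optional[np.ndarray]) -> np.ndarray:
    """Gradient of the annealed stochastic potential at ``theta``.

    Unbiased for the full-potential gradient over mini-batch draws; the
    history term is scaled by n_prev/|B| and omitted entirely when there is
    no history yet.
    """
    theta = pot.model.check_theta(np.asarray(theta, float))
    g = -model_api.grad_log_prior(pot.model, theta)
    if pot.lam > 0.0 and pot.chunk.shape[0] > 0:
        g = g - pot.lam * model_api.grad_loglik_sum(pot.model, theta, pot.chunk)
    if pot.n_prev > 0:
        if batch is None or len(batch) == 0:
            raise ContractError("empty mini-batch with non-empty history")
        scale = pot.n_prev / len(batch)
        g = g - scale * model_api.grad_loglik_sum(pot.model, theta, batch)
    return g


def sghmc_step(theta: np.ndarray, v: np.ndarray, grad: np.ndarray,
               cfg: SGHMCConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One discretised Langevin update (velocity first, then position)."""
    grad = np.asarray(grad, float)
    if not np.all(np.isfinite(grad)):
        bad = np.argwhere(~np.isfinite(grad).all(axis=-1) if grad.ndim > 1
                          else ~np.isfinite(grad))
        raise DivergenceError(f"non-finite potential gradient (particle index {bad.ravel()[:4]})")
    noise_scale = np.sqrt(2.0 * (cfg.alpha - cfg.beta_hat) * cfg.eta)
    v_new = v - cfg.eta * grad - cfg.alpha * v
    if noise_scale > 0.0:
        v_new = v_new + noise_scale * rng.standard_normal(size=np.shape(v))
    return theta + v_new, v_new


def sghmc_run(theta: np.ndarray, v: np.ndarray, pot: PotentialSpec,
              cfg: SGHMCConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Apply ``cfg.n_steps`` SGHMC updates with a fresh mini-batch each step.

    The velocity persists across steps within the run.
    """
    for _ in range(cfg.n_steps):
        batch = None
        if pot.n_prev > 0:
            batch = pot.history.sample_batch(rng, cfg.batch_size)
        grad = stochastic_potential_grad(pot, theta, batch)
        theta, v = sghmc_step(theta, v, grad, cfg, rng)
    return theta, v
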