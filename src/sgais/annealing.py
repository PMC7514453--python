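"""Adaptive thermal annealing: ESS statistic, temperature-step selection,
incremental importance weights, and optional resampling.

A chunk of new observations is absorbed through a ladder of intermediate
distributions ``p(chunk|theta)^lam * p(past|theta) * p(theta)`` with the
inverse temperature ``lam`` rising from 0 to 1.  Raising ``lam`` by ``delta``
multiplies each particle's importance weight by ``p(chunk|theta_i)^delta``,
whose effective sample size

    ESS(delta) = (sum_i w_i)^2 / sum_i w_i^2,   w_i = exp(delta * l_i)

lies between 1 and M.  Each step takes the largest ``delta`` that keeps the
ESS of the *incremental* weights at a target value, finishing the ladder in
one jump whenever the full remaining step already satisfies the target.
Everything is computed in the log domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .model_api import ContractError

__all__ = [
    "DegenerateEnsembleError",
    "ParticleEnsemble",
    "incremental_log_weights",
    "ess",
    "find_delta",
    "update_weights",
    "resample",
]


class DegenerateEnsembleError(RuntimeError):
    """Every particle has weight zero (all log-weights -inf)."""


@dataclass
class ParticleEnsemble:
    """M parameter particles with velocities and log importance weights."""

    theta: np.ndarray        # (M, dim)
    velocity: np.ndarray     # (M, dim)
    log_weights: np.ndarray  # (M,)

    def __post_init__(self) -> None:
        self.theta = np.atleast_2d(np.asarray(self.theta, float))
        self.velocity = np.atleast_2d(np.asarray(self.velocity, float))
        self.log_weights = np.asarray(self.log_weights, float).reshape(-1)
        if self.theta.shape != self.velocity.shape:
            raise ContractError("theta and velocity shapes differ")
        if self.log_weights.shape[0] != self.theta.shape[0]:
            raise ContractError("one log-weight per particle required")
        if self.M < 1:
            raise ContractError("at least one particle required")
        if not np.any(self.log_weights > -np.inf):
            raise DegenerateEnsembleError("all particle weights are zero")

    @property
    def M(self) -> int:
        return self.theta.shape[0]

    def log_mean_weight(self) -> float:
        """log((1/M) sum_i w_i) — the current evidence estimate."""
        return float(logsumexp(self.log_weights) - np.log(self.M))


def incremental_log_weights(chunk_logliks: np.ndarray, delta: float) -> np.ndarray:
    """log of p(chunk|theta_i)^delta given per-particle chunk log-likelihoods."""
    if delta < 0:
        raise ContractError("delta must be >= 0")
    ell = np.asarray(chunk_logliks, float)
    if delta == 0.0:
        return np.zeros_like(ell)
    with np.errstate(invalid="ignore"):
        out = delta * ell
    # delta * -inf is -inf, not nan
    out[np.isneginf(ell)] = -np.inf
    return out


def ess(incr_log_weights: np.ndarray) -> float:
    """(sum w)^2 / sum w^2 computed stably in the log domain; in [1, M]."""
    u = np.asarray(incr_log_weights, float)
    finite = u > -np.inf
    if not np.any(finite):
        raise DegenerateEnsembleError("all incremental weights are zero")
    a = u - np.max(u[finite])
    return float(np.exp(2.0 * logsumexp(a) - logsumexp(2.0 * a)))


def find_delta(chunk_logliks: np.ndarray, lam: float, target_ess: float,
               tol: float = 1e-6, n_scan: int = 16) -> float:
    """Largest admissible temperature increment meeting the ESS target.

    Returns ``1 - lam`` (finish the ladder) whenever the full remaining jump
    already satisfies ``ESS >= target_ess``; otherwise locates the smallest
    root of ``ESS(delta) = target_ess`` on ``(0, 1 - lam)`` by scanning
    ``n_scan`` subintervals for a sign change and bisecting to absolute
    tolerance ``tol``.  The result is floored at an absolute 1/256 so that
    repeated steps always terminate: with ``target_ess == M`` the root
    degenerates to zero, and the floor caps the ladder at 256 steps per
    chunk, each slightly undershooting the target.
    """
    ell = np.asarray(chunk_logliks, float)
    M = ell.size
    if not 0.0 <= lam < 1.0:
        raise ContractError("lam must lie in [0, 1)")
    if not 1.0 <= target_ess <= M:
        raise ContractError("target_ess must lie in [1, M]")
    remaining = 1.0 - lam

    def gap(delta: float) -> float:
        return ess(incremental_log_weights(ell, delta)) - target_ess

    if gap(remaining) >= 0.0:
        return remaining
    xs = np.linspace(0.0, remaining, n_scan + 1)
    lo, hi = 0.0, remaining
    for a, b in zip(xs[:-1], xs[1:]):
        if gap(b) < 0.0:
            lo, hi = a, b
            break
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if gap(mid) >= 0.0:
            lo = mid
        else:
            hi = mid
    return min(max(0.5 * (lo + hi), 1.0 / 256.0), remaining)


def update_weights(ens: ParticleEnsemble, chunk_logliks: np.ndarray,
                   delta: float) -> ParticleEnsemble:
    """Multiply weights by p(chunk|theta_i)^delta (in the log domain, in place)."""
    if not 0.0 <= delta <= 1.0:
        raise ContractError("delta must lie in [0, 1]")
    incr = incremental_log_weights(chunk_logliks, delta)
    if incr.shape[0] != ens.M:
        raise ContractError("one chunk log-likelihood per particle required")
    ens.log_weights = ens.log_weights + incr
    if not np.any(ens.log_weights > -np.inf):
        raise DegenerateEnsembleError("weight update zeroed every particle")
    return ens


def _systematic_offspring(norm_weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    M = norm_weights.size
    positions = (rng.random() + np.arange(M)) / M
    return np.searchsorted(np.cumsum(norm_weights), positions)


def resample(ens: ParticleEnsemble, rng: np.random.Generator,
             method: str = "systematic") -> ParticleEnsemble:
    """Draw particles proportionally to their weights and flatten the weights.

    After resampling every log-weight equals the log of the pre-resampling
    mean weight, so the evidence estimate is exactly preserved.  Velocities
    travel with their particles.
    """
    log_mean = ens.log_mean_weight()
    norm = np.exp(ens.log_weights - logsumexp(ens.log_weights))
    if method == "systematic":
        idx = _systematic_offspring(norm, rng)
    elif method == "multinomial":
        idx = rng.choice(ens.M, size=ens.M, p=norm)
    else:
        raise ContractError(f"unknown resampling method {method!r}")
    return ParticleEnsemble(
        theta=ens.theta[idx].copy(),
        velocity=ens.velocity[idx].copy(),
        log_weights=np.full(ens.M, log_mean),
    )
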