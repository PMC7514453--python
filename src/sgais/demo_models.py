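"""Built-in demonstration models and their synthetic-data generators.

Three models of increasing posterior difficulty are provided:

* **Bayesian linear regression** — 5 standard-normal covariates plus an
  intercept (6 parameters), Gaussian noise with *known* standard deviation.
  Its marginal likelihood is available in closed form (the marginal of the
  responses is itself Gaussian), which makes it the calibration model for
  every sampler in the package.
* **Multiclass (softmax) logistic regression** — 10 covariates, 4 classes,
  one weight vector and bias per class: 44 parameters.
* **Gaussian mixture** — 2-D data, 5 diagonal-covariance components, each
  parameterised by 2 means, 2 log-variances and one mixing logit
  (softmax-normalised): 25 parameters.  Its posterior is multimodal.

All unconstrained parameters carry independent standard-normal priors by
default.  Every model supports stacked parameter arrays (``vectorized``),
which is what makes the particle samplers cheap in pure numpy.

A fourth, deliberately tiny model — a 1-D Gaussian mean with conjugate
normal prior — is included for oracle tests: its evidence, posterior and
predictive are all closed-form.

The module also provides the non-stationary clustered generator used for
change-point experiments: three contiguous phases of 2-D data drawn from
3, then 5, then 7 Gaussian clusters, where each phase's cluster set nests
the previous one and some cluster pairs deliberately overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_softmax, logsumexp, softmax

from .model_api import ContractError, Dataset, ModelSpec

__all__ = [
    "make_linreg_model",
    "make_logreg_model",
    "make_gmm_model",
    "make_gaussian_mean_model",
    "linreg_exact_log_evidence",
    "simulate_dataset",
    "draw_true_parameters",
    "ShiftDatasetSpec",
    "ShiftDataset",
    "simulate_shift_dataset",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


def _std_normal_prior(dim: int, prior_sd: float = 1.0):
    """Independent N(0, prior_sd^2) prior callables on all dim coordinates."""
    var = prior_sd ** 2
    const = 0.5 * dim * (np.log(var) + _LOG_2PI)

    def log_prior(theta):
        return -0.5 * np.sum(theta ** 2, axis=-1) / var - const

    def grad_log_prior(theta):
        return -theta / var

    def sample_prior(rng, size=None):
        shape = (dim,) if size is None else (size, dim)
        return rng.normal(0.0, prior_sd, size=shape)

    return log_prior, grad_log_prior, sample_prior


# ---------------------------------------------------------------------------
# Linear regression (closed-form evidence)
# ---------------------------------------------------------------------------

def _gaussian_linear_log_evidence(X: np.ndarray, y: np.ndarray,
                                  noise_sd: float, prior_sd: float) -> float:
    """log N(y; 0, noise_sd^2 I + prior_sd^2 X X^T) via the Woodbury identity.

    Only d-by-d linear algebra, so it is exact and cheap even for a million
    rows.  The prior_sd -> 0 limit degenerates to independent N(0, noise_sd^2)
    terms.
    """
    n, d = X.shape
    if noise_sd <= 0:
        raise ContractError("noise_sd must be positive (marginal covariance singular)")
    s2, o2 = prior_sd ** 2, noise_sd ** 2
    if n == 0:
        return 0.0
    if s2 == 0.0:
        return float(-0.5 * (n * (_LOG_2PI + np.log(o2)) + y @ y / o2))
    A = o2 * np.eye(d) + s2 * (X.T @ X)          # d x d
    sign, logdet_A = np.linalg.slogdet(A)
    if sign <= 0:
        raise ContractError("marginal covariance not positive definite")
    logdet = (n - d) * np.log(o2) + logdet_A
    Xty = X.T @ y
    quad = (y @ y - s2 * (Xty @ np.linalg.solve(A, Xty))) / o2
    return float(-0.5 * (n * _LOG_2PI + logdet + quad))


def linreg_exact_log_evidence(data: Dataset, noise_sd: float = 1.0,
                              prior_sd: float = 1.0) -> float:
    """Closed-form log evidence of the linear-regression demo model.

    The records are (x_1..x_p, y); the design matrix gains an intercept
    column.  Marginally y ~ N(0, noise_sd^2 I + prior_sd^2 X X^T).
    An empty dataset has evidence 1 (log 0.0).
    """
    records = data.records if isinstance(data, Dataset) else np.asarray(data, float)
    if records.shape[0] == 0:
        if noise_sd <= 0:
            raise ContractError("noise_sd must be positive")
        return 0.0
    Xf, y = records[:, :-1], records[:, -1]
    X = np.column_stack([Xf, np.ones(len(y))])
    return _gaussian_linear_log_evidence(X, y, noise_sd, prior_sd)


def make_linreg_model(n_features: int = 5, noise_sd: float = 1.0,
                      prior_sd: float = 1.0) -> ModelSpec:
    """Bayesian linear regression with known noise sd.

    dim = n_features + 1 (weights then intercept); records are
    (x_1..x_p, y) with standard-normal covariates when simulated.
    """
    if n_features < 1:
        raise ContractError("n_features must be >= 1")
    if noise_sd <= 0:
        raise ContractError("noise_sd must be positive")
    p = n_features
    dim = p + 1
    o2 = noise_sd ** 2
    lp, glp, sp = _std_normal_prior(dim, prior_sd)

    def loglik_terms(theta, records):
        X, y = records[:, :p], records[:, p]
        mean = theta[..., :p] @ X.T + theta[..., p, None]
        resid = y - mean
        return -0.5 * (_LOG_2PI + np.log(o2)) - 0.5 * resid ** 2 / o2

    def grad_loglik_sum(theta, records):
        X, y = records[:, :p], records[:, p]
        resid = (y - (theta[..., :p] @ X.T + theta[..., p, None])) / o2
        gw = resid @ X
        gb = np.sum(resid, axis=-1)
        return np.concatenate([gw, gb[..., None]], axis=-1)

    def sample_records(theta, n, rng):
        theta = np.asarray(theta, float)
        X = rng.normal(size=(n, p))
        y = X @ theta[:p] + theta[p] + rng.normal(0.0, noise_sd, size=n)
        return np.column_stack([X, y])

    return ModelSpec(
        dim=dim,
        record_width=p + 1,
        log_prior=lp,
        grad_log_prior=glp,
        loglik_terms=loglik_terms,
        grad_loglik_sum=grad_loglik_sum,
        sample_prior=sp,
        exact_log_evidence=lambda data: linreg_exact_log_evidence(data, noise_sd, prior_sd),
        sample_records=sample_records,
        name=f"linreg(p={p}, noise_sd={noise_sd})",
        vectorized=True,
    )


# ---------------------------------------------------------------------------
# 1-D conjugate Gaussian mean model (oracle model for tests)
# ---------------------------------------------------------------------------

def make_gaussian_mean_model(noise_sd: float = 1.0, prior_sd: float = 1.0) -> ModelSpec:
    """y ~ N(theta, noise_sd^2) with theta ~ N(0, prior_sd^2); fully conjugate."""
    if noise_sd <= 0 or prior_sd <= 0:
        raise ContractError("standard deviations must be positive")
    o2 = noise_sd ** 2
    lp, glp, sp = _std_normal_prior(1, prior_sd)

    def loglik_terms(theta, records):
        y = records[:, 0]
        resid = y - theta[..., 0, None]
        return -0.5 * (_LOG_2PI + np.log(o2)) - 0.5 * resid ** 2 / o2

    def grad_loglik_sum(theta, records):
        y = records[:, 0]
        resid = (y - theta[..., 0, None]) / o2
        return np.sum(resid, axis=-1)[..., None]

    def exact(data):
        records = data.records if isinstance(data, Dataset) else np.asarray(data, float)
        y = records.reshape(-1)
        X = np.ones((len(y), 1))
        return _gaussian_linear_log_evidence(X, y, noise_sd, prior_sd)

    def sample_records(theta, n, rng):
        return (np.asarray(theta, float)[0] + rng.normal(0.0, noise_sd, size=n))[:, None]

    return ModelSpec(
        dim=1,
        record_width=1,
        log_prior=lp,
        grad_log_prior=glp,
        loglik_terms=loglik_terms,
        grad_loglik_sum=grad_loglik_sum,
        sample_prior=sp,
        exact_log_evidence=exact,
        sample_records=sample_records,
        name=f"gaussian_mean(noise_sd={noise_sd}, prior_sd={prior_sd})",
        vectorized=True,
    )


# ---------------------------------------------------------------------------
# Multiclass logistic regression
# ---------------------------------------------------------------------------

def make_logreg_model(n_features: int = 10, n_classes: int = 4) -> ModelSpec:
    """Softmax-linear classifier; dim = n_classes * (n_features + 1).

    Records are (x_1..x_p, label) with the label stored as a float-coded
    integer in [0, n_classes).  Parameter layout: per class, the weight
    vector then the bias, classes stacked.
    """
    if n_features < 1:
        raise ContractError("n_features must be >= 1")
    if n_classes < 2:
        raise ContractError("n_classes must be >= 2")
    p, K = n_features, n_classes
    dim = K * (p + 1)
    lp, glp, sp = _std_normal_prior(dim)

    def _logits(theta, X):
        th = theta.reshape(theta.shape[:-1] + (K, p + 1))
        W, b = th[..., :p], th[..., p]
        # (..., n, K)
        return np.swapaxes(W @ X.T, -1, -2) + b[..., None, :]

    def loglik_terms(theta, records):
        X = records[:, :p]
        labels = records[:, p].astype(int)
        logits = _logits(theta, X)
        logp = log_softmax(logits, axis=-1)
        return np.take_along_axis(
            logp, np.broadcast_to(labels[:, None], logp.shape[:-1] + (1,)), axis=-1
        )[..., 0]

    def grad_loglik_sum(theta, records):
        X = records[:, :p]
        labels = records[:, p].astype(int)
        logits = _logits(theta, X)
        S = softmax(logits, axis=-1)          # (..., n, K)
        onehot = np.eye(K)[labels]            # (n, K)
        diff = onehot - S
        gW = np.swapaxes(diff, -1, -2) @ X    # (..., K, p)
        gb = np.sum(diff, axis=-2)            # (..., K)
        return np.concatenate([gW, gb[..., None]], axis=-1).reshape(
            theta.shape[:-1] + (dim,)
        )

    def sample_records(theta, n, rng):
        theta = np.asarray(theta, float)
        X = rng.normal(size=(n, p))
        probs = softmax(_logits(theta, X), axis=-1)
        u = rng.random(size=(n, 1))
        labels = (np.cumsum(probs, axis=-1) < u).sum(axis=-1)
        return np.column_stack([X, labels.astype(float)])

    return ModelSpec(
        dim=dim,
        record_width=p + 1,
        log_prior=lp,
        grad_log_prior=glp,
        loglik_terms=loglik_terms,
        grad_loglik_sum=grad_loglik_sum,
        sample_prior=sp,
        sample_records=sample_records,
        name=f"logreg(p={p}, K={K})",
        vectorized=True,
    )


# ---------------------------------------------------------------------------
# Gaussian mixture model
# ---------------------------------------------------------------------------

def make_gmm_model(data_dim: int = 2, n_components: int = 5) -> ModelSpec:
    """Diagonal-covariance Gaussian mixture on unconstrained coordinates.

    Per component: data_dim means, data_dim log-variances, one mixing logit
    (weights are the softmax of the logits), so
    dim = n_components * (2 * data_dim + 1).
    """
    if data_dim < 1:
        raise ContractError("data_dim must be >= 1")
    if n_components < 1:
        raise ContractError("n_components must be >= 1")
    q, K = data_dim, n_components
    dim = K * (2 * q + 1)
    lp, glp, sp = _std_normal_prior(dim)

    def _unpack(theta):
        th = theta.reshape(theta.shape[:-1] + (K, 2 * q + 1))
        return th[..., :q], th[..., q : 2 * q], th[..., 2 * q]

    def _comp_logdens(theta, records):
        """Component log-densities + log-weights; returns (..., n, K)."""
        mu, logvar, logit = _unpack(theta)
        var = np.exp(logvar)
        diff = records[..., None, :] - mu[..., None, :, :]     # (..., n, K, q)
        comp = -0.5 * np.sum(_LOG_2PI + logvar[..., None, :, :] + diff ** 2 / var[..., None, :, :], axis=-1)
        logpi = log_softmax(logit, axis=-1)
        return comp + logpi[..., None, :], diff, var

    def loglik_terms(theta, records):
        joint, _, _ = _comp_logdens(theta, records)
        return logsumexp(joint, axis=-1)

    def grad_loglik_sum(theta, records):
        mu, logvar, logit = _unpack(theta)
        var = np.exp(logvar)
        joint, diff, _ = _comp_logdens(theta, records)
        r = softmax(joint, axis=-1)                            # responsibilities (..., n, K)
        scaled = diff / var[..., None, :, :]
        g_mu = np.einsum("...nk,...nkq->...kq", r, scaled)
        g_logvar = np.einsum(
            "...nk,...nkq->...kq", r, -0.5 + 0.5 * diff ** 2 / var[..., None, :, :]
        )
        pi = softmax(logit, axis=-1)
        n = records.shape[0]
        g_logit = np.sum(r, axis=-2) - n * pi
        out = np.concatenate([g_mu, g_logvar, g_logit[..., None]], axis=-1)
        return out.reshape(theta.shape[:-1] + (dim,))

    def sample_records(theta, n, rng):
        theta = np.asarray(theta, float)
        mu, logvar, logit = _unpack(theta)
        pi = softmax(logit, axis=-1)
        comp = rng.choice(K, size=n, p=pi)
        return mu[comp] + np.sqrt(np.exp(logvar[comp])) * rng.normal(size=(n, q))

    return ModelSpec(
        dim=dim,
        record_width=q,
        log_prior=lp,
        grad_log_prior=glp,
        loglik_terms=loglik_terms,
        grad_loglik_sum=grad_loglik_sum,
        sample_prior=sp,
        sample_records=sample_records,
        name=f"gmm(q={q}, K={K})",
        vectorized=True,
    )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def draw_true_parameters(model: ModelSpec, seed: int) -> np.ndarray:
    """Fixed 'true' parameters for simulation: one documented prior draw."""
    return np.asarray(model.sample_prior(np.random.default_rng(seed)), float)


def simulate_dataset(model: ModelSpec, theta_true: np.ndarray, N: int, seed: int) -> Dataset:
    """N i.i.d. records from the model's conditional at fixed parameters.

    Covariates, where the model has them, are standard normal.  Reproducible
    under the seed; N = 0 yields an empty dataset of the right width.
    """
    if N < 0:
        raise ContractError("N must be >= 0")
    theta_true = model.check_theta(np.asarray(theta_true, float))
    if model.sample_records is None:
        raise ContractError("model provides no record sampler")
    rng = np.random.default_rng(seed)
    if N == 0:
        return Dataset(np.empty((0, model.record_width)))
    return Dataset(model.sample_records(theta_true, N, rng))


# ---------------------------------------------------------------------------
# Non-stationary (distribution-shift) generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShiftDatasetSpec:
    """Three contiguous phases of 2-D clustered data with nested cluster sets.

    Defaults: 1,000 observations from 3 Gaussian clusters, then 9,000 from 5
    (including the first 3), then 90,000 from 7 (including the previous 5).
    Cluster means are fixed by the seed; some pairs are deliberately close so
    that clusters overlap.  All clusters have unit variance.
    """

    phase_sizes: tuple[int, ...] = (1000, 9000, 90000)
    phase_cluster_counts: tuple[int, ...] = (3, 5, 7)
    data_dim: int = 2
    box_halfwidth: float = 5.0
    cluster_sd: float = 1.0
    overlap_offset: float = 1.5

    def __post_init__(self) -> None:
        if len(self.phase_sizes) != len(self.phase_cluster_counts):
            raise ContractError("phase_sizes and phase_cluster_counts must align")
        if any(s < 1 for s in self.phase_sizes):
            raise ContractError("phase sizes must be positive")
        if any(
            b <= a
            for a, b in zip(self.phase_cluster_counts, self.phase_cluster_counts[1:])
        ):
            raise ContractError("cluster counts must strictly increase (nesting)")


@dataclass(frozen=True)
class ShiftDataset:
    """A generated shift dataset plus its provenance."""

    dataset: Dataset
    labels: np.ndarray                 # cluster index per record
    phase_boundaries: tuple[int, ...]  # cumulative phase end indices
    cluster_means: np.ndarray
    spec: ShiftDatasetSpec
    seed: int

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "phase_sizes": list(self.spec.phase_sizes),
            "phase_cluster_counts": list(self.spec.phase_cluster_counts),
            "phase_boundaries": list(self.phase_boundaries),
            "cluster_means": self.cluster_means.tolist(),
            "cluster_sd": self.spec.cluster_sd,
        }


def simulate_shift_dataset(spec: ShiftDatasetSpec = ShiftDatasetSpec(),
                           seed: int = 0) -> ShiftDataset:
    """Generate the phased cluster data described by ``spec``.

    Cluster means are drawn once from a uniform box fixed by the seed and
    reused across phases (nesting).  To guarantee overlapping clusters, every
    third new cluster is placed a fixed small offset away from an existing
    one.  Within a phase, cluster membership is uniform over that phase's
    clusters.
    """
    rng = np.random.default_rng(seed)
    K = spec.phase_cluster_counts[-1]
    q = spec.data_dim
    means = rng.uniform(-spec.box_halfwidth, spec.box_halfwidth, size=(K, q))
    # overlap: clusters 3, 5, ... sit a short offset from earlier clusters
    for k in range(3, K, 2):
        direction = rng.normal(size=q)
        direction /= np.linalg.norm(direction)
        means[k] = means[(k - 3) // 2] + spec.overlap_offset * direction

    records, labels = [], []
    for size, count in zip(spec.phase_sizes, spec.phase_cluster_counts):
        lab = rng.integers(0, count, size=size)
        records.append(means[lab] + rng.normal(0.0, spec.cluster_sd, size=(size, q)))
        labels.append(lab)
    data = Dataset(
        np.concatenate(records, axis=0),
        columns=tuple(f"y{j + 1}" for j in range(q)),
    )
    boundaries = tuple(np.cumsum(spec.phase_sizes).tolist())
    return ShiftDataset(
        dataset=data,
        labels=np.concatenate(labels),
        phase_boundaries=boundaries,
        cluster_means=means,
        spec=spec,
        seed=seed,
    )
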