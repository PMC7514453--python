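"""Model contract and core data containers.

Every sampler in this package operates on a :class:`ModelSpec`: a bundle of
callables describing a Bayesian model for conditionally i.i.d. data — the
log-prior, the per-observation log-likelihood, their gradients, and a prior
sampler.  Parameters always live in an *unconstrained* Euclidean space;
constrained quantities (variances, mixture weights) must be reparameterised
inside the model (log-variance, softmax) because the underdamped Langevin
kernel used throughout assumes unconstrained coordinates.

All likelihood arithmetic is kept in the log domain: products over up to a
million observations underflow in linear space.  A record the model assigns
zero probability yields a log-likelihood of ``-inf`` rather than an
exception; importance-weight handling downstream treats it as weight zero.

Datasets are ordered sequences of fixed-width real records held in a plain
2-D float array, with optional column names and CSV round-tripping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterator, Optional

import numpy as np
import pandas as pd

__all__ = [
    "ContractError",
    "ModelValidationError",
    "Dataset",
    "ModelSpec",
    "log_joint",
    "loglik_terms",
    "grad_loglik_sum",
    "validate_model",
    "GradientCheckReport",
]


class ContractError(ValueError):
    """A caller violated a precondition of the model contract."""


class ModelValidationError(RuntimeError):
    """Analytic gradients disagree with finite differences."""


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dataset:
    """An ordered sequence of fixed-width real observation records.

    Parameters
    ----------
    records
        Array of shape ``(N, record_width)``; all entries must be finite.
    columns
        Optional column names, used for CSV headers.
    """

    records: np.ndarray
    columns: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.records, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.ndim != 2:
            raise ContractError("records must be a 2-D array (N, record_width)")
        if arr.size and not np.all(np.isfinite(arr)):
            raise ContractError("dataset contains non-finite entries")
        object.__setattr__(self, "records", arr)
        if self.columns is not None:
            cols = tuple(str(c) for c in self.columns)
            if len(cols) != arr.shape[1]:
                raise ContractError("column count does not match record width")
            object.__setattr__(self, "columns", cols)

    @property
    def N(self) -> int:
        return self.records.shape[0]

    @property
    def record_width(self) -> int:
        return self.records.shape[1]

    def __len__(self) -> int:
        return self.N

    def iter_chunks(self, chunk_size: int) -> Iterator[np.ndarray]:
        """Yield contiguous record blocks of at most ``chunk_size`` rows."""
        if chunk_size < 1:
            raise ContractError("chunk_size must be >= 1")
        for start in range(0, self.N, chunk_size):
            yield self.records[start : start + chunk_size]

    # -- CSV round trip ------------------------------------------------------

    def to_csv(self, path) -> None:
        cols = self.columns or tuple(f"c{i}" for i in range(self.record_width))
        pd.DataFrame(self.records, columns=list(cols)).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Dataset":
        df = pd.read_csv(path)
        return cls(df.to_numpy(dtype=float), columns=tuple(df.columns))

    @classmethod
    def from_parquet(cls, path) -> "Dataset":
        df = pd.read_parquet(path)
        return cls(df.to_numpy(dtype=float), columns=tuple(df.columns))

    def to_parquet(self, path) -> None:
        cols = self.columns or tuple(f"c{i}" for i in range(self.record_width))
        pd.DataFrame(self.records, columns=list(cols)).to_parquet(path, index=False)


# ---------------------------------------------------------------------------
# ModelSpec
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Contract a Bayesian model must satisfy to be sampled.

    The likelihood factorises over records: ``log p(D|theta) = sum_n
    log p(y_n|theta)``.  ``loglik_terms`` must therefore return one value per
    input record, and ``grad_loglik_sum`` must be additive over record
    concatenation.

    If ``vectorized`` is true, every callable also accepts a stacked
    parameter array of shape ``(M, dim)`` and returns the correspondingly
    stacked result (``(M,)``, ``(M, n)`` or ``(M, dim)``).  The built-in demo
    models are all vectorized; user models need not be — the samplers fall
    back to a Python loop over particles.
    """

    dim: int
    record_width: int
    log_prior: Callable[[np.ndarray], np.ndarray]
    grad_log_prior: Callable[[np.ndarray], np.ndarray]
    loglik_terms: Callable[[np.ndarray, np.ndarray], np.ndarray]
    grad_loglik_sum: Callable[[np.ndarray, np.ndarray], np.ndarray]
    sample_prior: Callable[..., np.ndarray]
    exact_log_evidence: Optional[Callable[[Dataset], float]] = None
    sample_records: Optional[Callable[[np.ndarray, int, np.random.Generator], np.ndarray]] = None
    name: str = ""
    vectorized: bool = False

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ContractError("model must have at least one parameter")
        if self.record_width < 1:
            raise ContractError("record_width must be >= 1")

    def check_theta(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        if theta.shape[-1] != self.dim:
            raise ContractError(
                f"parameter dimension {theta.shape[-1]} != model dim {self.dim}"
            )
        return theta


def _records_of(data) -> np.ndarray:
    if isinstance(data, Dataset):
        return data.records
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def loglik_terms(model: ModelSpec, theta: np.ndarray, data) -> np.ndarray:
    """Per-record log-likelihoods; dispatches stacked theta if supported."""
    theta = model.check_theta(theta)
    records = _records_of(data)
    if theta.ndim == 1 or model.vectorized:
        return model.loglik_terms(theta, records)
    return np.stack([model.loglik_terms(t, records) for t in theta])


def grad_loglik_sum(model: ModelSpec, theta: np.ndarray, data) -> np.ndarray:
    """Gradient of the summed log-likelihood over ``data`` w.r.t. theta."""
    theta = model.check_theta(theta)
    records = _records_of(data)
    if theta.ndim == 1 or model.vectorized:
        return model.grad_loglik_sum(theta, records)
    return np.stack([model.grad_loglik_sum(t, records) for t in theta])


def log_prior(model: ModelSpec, theta: np.ndarray) -> np.ndarray:
    theta = model.check_theta(theta)
    if theta.ndim == 1 or model.vectorized:
        return model.log_prior(theta)
    return np.array([model.log_prior(t) for t in theta])


def grad_log_prior(model: ModelSpec, theta: np.ndarray) -> np.ndarray:
    theta = model.check_theta(theta)
    if theta.ndim == 1 or model.vectorized:
        return model.grad_log_prior(theta)
    return np.stack([model.grad_log_prior(t) for t in theta])


def log_joint(model: ModelSpec, theta: np.ndarray, data) -> float:
    """log p(data, theta) = log-prior plus the sum of per-record terms.

    An empty dataset contributes an empty sum, so the joint reduces to the
    prior density.  ``-inf`` is propagated if any record has zero probability.
    """
    theta = model.check_theta(theta)
    if theta.ndim != 1:
        raise ContractError("log_joint expects a single parameter vector")
    records = _records_of(data)
    lp = float(model.log_prior(theta))
    if records.shape[0] == 0:
        return lp
    terms = np.asarray(model.loglik_terms(theta, records), dtype=float)
    if terms.shape != (records.shape[0],):
        raise ContractError("loglik_terms must return one value per record")
    return lp + float(np.sum(terms))


# ---------------------------------------------------------------------------
# Gradient validation
# ---------------------------------------------------------------------------

@dataclass
class GradientCheckReport:
    n_probes: int
    max_prior_discrepancy: float
    max_loglik_discrepancy: float
    tol: float

    @property
    def ok(self) -> bool:
        return (
            self.max_prior_discrepancy <= self.tol
            and self.max_loglik_discrepancy <= self.tol
        )


def _central_diff(f: Callable[[np.ndarray], float], theta: np.ndarray, step: float) -> np.ndarray:
    g = np.empty_like(theta)
    for j in range(theta.size):
        tp = theta.copy()
        tm = theta.copy()
        tp[j] += step
        tm[j] -= step
        g[j] = (f(tp) - f(tm)) / (2.0 * step)
    return g


def validate_model(
    model: ModelSpec,
    rng: np.random.Generator,
    n_probes: int = 5,
    fd_step: float = 1e-6,
    tol: float = 1e-4,
    n_probe_records: int = 5,
    raise_on_failure: bool = True,
) -> GradientCheckReport:
    """Check analytic gradients against central finite differences.

    Probes are drawn from the prior; probe records are simulated from the
    model at the first probe (models without a record sampler have only
    their prior gradient checked).  Discrepancies are measured relative to
    ``1 + ||grad||_inf``.
    """
    if n_probes < 1:
        raise ContractError("n_probes must be >= 1")
    max_prior = 0.0
    max_ll = 0.0
    records = None
    for k in range(n_probes):
        theta = np.asarray(model.sample_prior(rng), dtype=float).reshape(model.dim)
        if records is None and model.sample_records is not None:
            records = model.sample_records(theta, n_probe_records, rng)

        g_an = np.asarray(model.grad_log_prior(theta), dtype=float)
        g_fd = _central_diff(lambda t: float(model.log_prior(t)), theta, fd_step)
        max_prior = max(max_prior, float(np.max(np.abs(g_an - g_fd)) / (1.0 + np.max(np.abs(g_an)))))

        if records is not None and len(records):
            g_an = np.asarray(model.grad_loglik_sum(theta, records), dtype=float)
            g_fd = _central_diff(
                lambda t: float(np.sum(model.loglik_terms(t, records))), theta, fd_step
            )
            max_ll = max(max_ll, float(np.max(np.abs(g_an - g_fd)) / (1.0 + np.max(np.abs(g_an)))))

    report = GradientCheckReport(n_probes, max_prior, max_ll, tol)
    if raise_on_failure and not report.ok:
        bad = []
        if report.max_prior_discrepancy > tol:
            bad.append(f"grad_log_prior (err {report.max_prior_discrepancy:.3g})")
        if report.max_loglik_discrepancy > tol:
            bad.append(f"grad_loglik_sum (err {report.max_loglik_discrepancy:.3g})")
        raise ModelValidationError("gradient check failed for: " + ", ".join(bad))
    return report
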