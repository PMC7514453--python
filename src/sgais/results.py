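"""Results object shared by all three evidence estimators."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

__all__ = ["EvidenceResults"]


@dataclass
class EvidenceResults:
    """Outcome of an evidence-estimation run.

    Attributes
    ----------
    log_evidence
        The final log marginal-likelihood estimate for all observations.
    trace
        Per-chunk frame (one row for the single-shot baselines) with columns
        n_seen, log_evidence, annealing_steps, predictive_logprob,
        cum_grad_evals.
    grad_evals
        Total per-record gradient evaluations: a hardware-independent cost
        proxy used instead of wall-clock comparisons.
    """

    method: str
    model_name: str
    n_obs: int
    log_evidence: float
    trace: pd.DataFrame
    config: dict
    seed: int
    grad_evals: int
    runtime_s: float
    _trace_obj: Optional[object] = field(default=None, repr=False)

    @property
    def log_evidence_per_obs(self) -> float:
        return self.log_evidence / self.n_obs if self.n_obs else 0.0

    def detect_shift(self, window: int = 5, logp_drop: float = 0.75,
                     step_jump: float = 3.0) -> list[int]:
        from .engine import detect_shift

        if self._trace_obj is None:
            raise ValueError("shift detection requires a chunked (sgais) trace")
        return detect_shift(self._trace_obj, window=window,
                            logp_drop=logp_drop, step_jump=step_jump)

    def summary(self) -> str:
        """Plain-text summary table."""
        lines = [
            f"{'Evidence estimate (' + self.method + ')':^58}",
            "=" * 58,
            f"{'Model:':<18}{self.model_name:<40}",
            f"{'Observations:':<18}{self.n_obs:<12}{'Seed:':<14}{self.seed}",
            f"{'log Z:':<18}{self.log_evidence:<12.4f}{'log Z / N:':<14}"
            f"{self.log_evidence_per_obs:.6f}",
            f"{'Chunks:':<18}{max(len(self.trace) - 1, 1):<12}{'Grad evals:':<14}"
            f"{self.grad_evals:.3g}",
            f"{'Runtime (s):':<18}{self.runtime_s:<12.2f}",
            "=" * 58,
        ]
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = {
            "method": self.method,
            "model": self.model_name,
            "n_obs": self.n_obs,
            "log_evidence": self.log_evidence,
            "log_evidence_per_obs": self.log_evidence_per_obs,
            "grad_evals": self.grad_evals,
            "runtime_s": self.runtime_s,
            "seed": self.seed,
            "config": self.config,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def plot_trace(self, ax=None):
        """Plot log Zhat / n against n (and annealing effort, if chunked)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.trace[self.trace["n_seen"] > 0]
        ax.plot(df["n_seen"], df["log_evidence"] / df["n_seen"], marker=".",
                label=self.method)
        ax.set_xlabel("observations n")
        ax.set_ylabel("log Z / n")
        ax.legend()
        return ax
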