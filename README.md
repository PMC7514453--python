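# sgais — online Bayesian evidence estimation

`sgais` estimates the **marginal likelihood** (evidence)

Z = ∫ p(D|θ) p(θ) dθ

of Bayesian models for conditionally i.i.d. data, at scales where the
classical estimators — nested sampling (NS) and annealed importance
sampling (AIS) — become impractical because they must evaluate the full
likelihood over and over. It is aimed at practitioners doing Bayesian model
comparison, weighted model averaging, or monitoring of streaming data
(e.g. epidemiological or sensor streams) where the evidence must be kept
up to date as observations arrive.

## The method

The evidence factorises into one-step-ahead predictive terms,
log Z = Σₙ log p(yₙ | y₍₋ₙ₎). The estimator absorbs the stream in chunks and
estimates each chunk's predictive probability by annealed importance
sampling *within* a Bayesian-updating step: a chunk enters through the
ladder of tempered targets

f(θ; λ) = p(chunk|θ)^λ · p(past|θ) · p(θ),  λ: 0 → 1,

whose incremental importance weights depend only on the **chunk's**
likelihood, never on the whole data set. Each temperature increment Δ is
chosen adaptively so that the effective sample size
ESS(Δ) = (Σᵢ ωᵢ)² / Σᵢ ωᵢ², ωᵢ = p(chunk|θᵢ)^Δ, of the incremental weights
stays at a target value. Between increments the particles are mutated by
**stochastic gradient Hamiltonian Monte Carlo** (SGHMC),

v′ = v − η ∇Û(θ) − α v + 𝒩(0, 2(α−β̂)η),  θ′ = θ + v′,

where ∇Û is an unbiased mini-batch estimate of the tempered potential's
gradient over the absorbed history. The per-chunk cost is therefore
independent of how much data has already been seen; with a fixed-capacity
uniform **reservoir** holding the history the estimator runs on unbounded
streams. Kinks in the per-chunk predictive trace and spikes in the
annealing effort expose **change-points** in the generating distribution.

Full-likelihood AIS (sigmoidal ladder) and nested sampling (SGHMC
constrained-prior walks, deterministic shrinkage) are included as accuracy
baselines, together with three demo models: Bayesian linear regression
(6 parameters, closed-form evidence), 4-class logistic regression
(44 parameters) and a 2-D, 5-component Gaussian mixture (25 parameters),
all with standard-normal priors on unconstrained parameters and built-in
synthetic-data generators — including a non-stationary 3 → 5 → 7-cluster
generator for change-point experiments.

## Worked example

```python
import sgais as sg

model = sg.make_linreg_model()                       # 5 weights + intercept
theta = sg.draw_true_parameters(model, 0)            # fixed prior draw
data  = sg.simulate_dataset(model, theta, 10_000, seed=1)

result = sg.SGAIS(model, data).fit(seed=1)           # defaults: M=10, ESS*=5,
print(result.summary())                              # chunk=|B|=500, lr=0.1/n
print("exact:", model.exact_log_evidence(data))
```

The same comparison from the shell:

```bash
sgais compare --model linreg --n 10000 --seed 1 --out cmp
```

```
method     N  log_evidence  log_evidence_per_obs  grad_evals  runtime_s
 sgais 10000 -14192.231446             -1.419223     6500000       0.33
   ais 10000 -14292.632914             -1.429263   200000000       5.02
    ns 10000 -14173.192695             -1.417319           0       0.29
exact log Z: -14170.294153730043
```

All three estimators land near the analytic value −14170.29 (the online
estimator within ~0.16% of log Z/N here), while using a small fraction of
the per-record gradient evaluations AIS needs — the column reported as a
hardware-independent cost proxy. Other subcommands: `simulate` (datasets +
manifests, including `--model shift`), `sgais`, `ais`, `ns` (single runs
with trace CSV and summary JSON) and `sweep` (one-at-a-time sensitivity
grids over particles, target ESS, burn-in, learning rate or batch size).

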