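# Methods

## Model contract

All samplers operate on a `ModelSpec`: log-prior, per-record
log-likelihood, their gradients, and a prior sampler, all on an
*unconstrained* parameter space. Constrained quantities are
reparameterised inside the models (log-variances, softmax weights/logits),
because the Langevin kernel assumes unconstrained Euclidean coordinates.
Likelihood arithmetic stays in the log domain throughout; a record of zero
model probability yields −∞ (weight zero downstream) rather than an
exception. Gradient implementations are validated against central finite
differences at prior draws (`validate_model`, relative tolerance 1e-4).

## Demo models

Three demo models of increasing posterior difficulty:

* **Linear regression, 6 parameters** — 5 standard-normal covariates plus
  intercept, *known* noise sd (default 1.0). This choice keeps the
  evidence exactly Gaussian: marginally y ~ N(0, σ²I + s²XXᵀ), evaluated
  with d-dimensional linear algebra (Woodbury / determinant lemma) so it is
  exact at a million rows. Treating the noise scale as unknown
  instead would lose that closed form, which the whole calibration story
  rests on.
* **Logistic regression, 44 parameters** — 10 covariates, 4 classes, one
  weight vector and bias per class (4 × 11).
* **Gaussian mixture, 25 parameters** — 2-D data, 5 diagonal-covariance
  components: per component 2 means, 2 log-variances, 1 mixing logit
  (5 × 5).

Priors are independent standard normal on every unconstrained parameter in
all models: the standard normal keeps the linear-regression evidence
closed-form and the kernel well-conditioned. Simulation draws covariates standard normal and
fixes the "true" parameters as a single documented prior draw.

The non-stationary generator produces three contiguous phases
(1,000 / 9,000 / 90,000 observations by default) from 3, then 5, then 7
unit-variance Gaussian clusters; each phase's cluster set nests the
previous one. Cluster means are drawn once from a uniform box (half-width
5) fixed by the seed, with every second new cluster placed a 1.5-unit
offset from an existing one so that some clusters genuinely overlap.

## The online estimator

Chunked Bayesian updating: a chunk of `chunk_size` records plays the role
of the "next observation"; its log-likelihood is the sum over its records,
and the history term of the stochastic potential

Û(θ) = −λ log p(chunk|θ) − (n_prev/|B|) Σ_{y∈B} log p(y|θ) − log p(θ)

counts all records of previous chunks, with the mini-batch B drawn i.i.d.
with replacement from the history (unbiased for the full potential).
Per chunk: λ starts at 0; each step takes the largest admissible Δ whose
incremental-weight ESS meets the target (root-found by 16-interval scan +
bisection to 1e-6, clipped to 1−λ when the full jump already satisfies the
target), updates the weights by Δ·log p(chunk|θᵢ) *before* mutating, then
runs `burnin_steps` SGHMC updates per particle. log Ẑ after each chunk is
the log mean particle weight; successive differences are the chunks'
predictive log-probabilities, and the telescoping identity holds exactly.

Defaults: M = 10 particles, target ESS 5,
chunk = mini-batch = 500, 20 SGHMC steps per intermediate distribution,
α = 0.2, β̂ = 0, per-observation learning rate 0.1.

Numerical and design choices where the design was genuinely open:

* **Step-size convention.** `lr` is per-observation: the kernel step is
  η = lr / n with n the observations seen up to and including the current
  chunk. A streaming estimator cannot scale by the final data size, so η
  shrinks online as the stream grows.
* **Update order.** Semi-implicit Euler: velocity first, position with the
  new velocity — the standard stable discretisation.
* **Velocities** are zeroed at the start of each chunk's ladder and persist
  across its temperature steps. (Persisting across chunks was measured to
  make no difference on a 44-parameter run; zeroing avoids stale momentum
  after weight updates.)
* **Δ floor.** The adaptive increment is floored at 1/256: if the target
  ESS equals M, the ESS equation's root degenerates to Δ = 0, and the floor
  caps the pathological ladder at 256 steps per chunk instead of hanging.
* **Resampling** (systematic, triggered when the cumulative-weight ESS
  falls below M/2) is available but off by default: with M = 10 particles
  mode collapse is the bigger risk, and enabling it measurably changed
  nothing on the models tested.
* **Degenerate ensembles.** If every particle reaches weight zero the run
  aborts with a diagnostic rather than returning −∞.
* **Seeding.** One root seed; per-chunk substreams are derived via
  `SeedSequence(seed, spawn_key=(chunk,))`, so chunk boundaries decorrelate
  streams. Within a chunk all particles draw from one vectorised stream.

Streaming mode replaces the exhaustive history with a fixed-capacity
uniform reservoir (algorithm R); the history-term scale still uses the true
stream length, so the gradient estimator stays unbiased with respect to the
reservoir's content.

### Change-point flagging

`detect_shift` flags chunk k when its per-observation predictive
log-probability falls more than `logp_drop` below the trailing-window
median, or its annealing-step count exceeds the windowed median by more
than `step_jump`. The default `logp_drop = 0.75` sits above the largest
trailing-median excursion measured on *shuffled* (stationary) runs of the
clustered shift data — the calibration protocol is: run the estimator on a
shuffled copy of the stream, take the largest excursion as the null scale.
Both thresholds live on the data's own log-density scale and should be
recalibrated through that protocol when the data regime differs; wide
mixtures with heavy tail exposure can exceed the default on stationary
data.

## Baselines

**AIS** uses the sigmoidal ladder λ_t = σ(δ(2t/T − 1)), affinely rescaled
to hit 0 and 1 exactly (σ never attains them), with δ = 4 and T = 100 by
default, M = 10 particles, and full-data SGHMC mutation (20 steps per rung,
η = lr/N). Weights accumulate p(D|θ)^(λ_t − λ_{t−1}) evaluated before each
mutation.

**Nested sampling** runs the standard loop with deterministic shrinkage
X_k = exp(−k/n_live), the 1 %-increment stopping rule plus the live-point
slab, and constrained-prior replacement by SGHMC on the prior (default 20
steps, η = 1e-3, α = 0.1 — sized for large-data runs where the constrained
region is small; small toy problems want a larger η, e.g. 0.05). Moves
violating the likelihood bound are rejected with the **momentum reflected**
(v → −v). Reflection matters: zeroing the momentum pins the chain against
the constraint boundary on the side the prior gradient pushes toward,
biasing log Ẑ low by tens of nats on a 2-parameter toy; with reflection the
estimator agrees with the conjugate oracle at the sd ≈ √(H/n_live)
predicted by NS error theory. Wall-clock comparisons are out of scope;
per-record gradient-evaluation counts are reported as a portable cost
proxy.

## What the synthetic generators do and do not cover

All experiments run on data simulated from the demo models themselves (or
the phased cluster generator), so passing tests demonstrate correct
estimation *under the model family*, with i.i.d. records and standard-normal
covariates. They do not probe model misspecification (except the
deliberately under-specified mixture in the shift experiment), correlated
or heavy-tailed covariates, or label noise. The conjugate Gaussian-mean
model provides exact evidence/predictive oracles; grid quadrature serves as
an independent oracle on 2-parameter instances.

## Accuracy behaviour and problem sizes used

* Linear regression (closed form): relative error of log Ẑ/N at the default
  parameters is ≈0.05 % at N = 10⁴ and ≈0.11 % at N = 10⁶ (stable across
  seeds; the residual is a small systematic underestimate from
  discretisation and finite burn-in, not Monte-Carlo noise).
* With exact full-batch gradients on the conjugate model, the replicate
  mean of Ẑ is statistically indistinguishable from Z (500 runs, 3 se) —
  the estimator is unbiased when the kernel is.
* On the 44-parameter logistic model the default burn-in budget leaves an
  equilibration lag that accumulates early: at N = 10⁴ the estimate sits
  ≈1 % below a Laplace reference while nested sampling sits ≈0.4 % below;
  the gap shrinks with more burn-in steps and with N. Method-vs-method
  agreement at N = 10⁴ is ≈0.5 % (logistic) and ≈0.03 % (mixture), with
  seed-to-seed spread of a few tenths of a percent.
* Test and acceptance runs use reduced problem sizes chosen for quick
  iteration: 10⁴ observations for cross-method checks, phases
  100/900/9,000 with chunks of 25 for the change-point surface, 10⁶ only
  for the single headline linear-regression run.

## Known limitations

Inherited from the ingredients: sensitivity to strong multimodality and
phase-change-like posteriors, the curse of dimensionality in the annealing
ladder, and O(η) kernel bias with no Metropolis correction. The adaptive
ladder controls incremental-weight degeneracy but not cumulative particle
impoverishment over very long streams at small M. The nested-sampling
baseline's constrained walk is a generic reconstruction; with very few live
points its error is dominated by the walk's correlation, not by the
√(H/n_live) term.
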