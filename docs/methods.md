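# Methods

## Model

An order-K binary tensor Y ∈ {0,1}^(d1×…×dK) is modeled entrywise as
independent Bernoulli draws with success probability f(θ), where the
parameter tensor Θ admits a rank-R CP decomposition
Θ = Σ_r λ_r a_r^(1) ⊗ … ⊗ a_r^(K), the a_r^(k) have unit norm, and f is a
strictly increasing, symmetric (f(−θ) = 1 − f(θ)), strictly log-concave link.
Three families are implemented, each with a scale parameter σ > 0:

| family    | f(θ)                        | latent-noise view      |
|-----------|-----------------------------|------------------------|
| logistic  | 1/(1 + e^(−θ/σ))            | logistic(σ) noise      |
| probit    | Φ(θ/σ)                      | Gaussian N(0, σ²) noise|
| laplacian | ½e^(θ/σ) (θ<0), 1−½e^(−θ/σ) | Laplace(σ) noise       |

The model is equivalent to observing the 1-bit quantization
Y = 1{Θ + E ≥ 0} of a latent signal-plus-noise tensor, with the noise CDF
determined by the link.  Flipping the 0/1 coding of Y only negates Θ; the
implementation preserves this equivariance exactly (bit-for-bit), which the
test suite asserts.

Estimation maximizes the log-likelihood L_Y(Θ) = Σ log f((2y−1)θ) over
rank-R tensors with an optional max-norm bound ‖Θ‖_max ≤ α.  The default is
α = ∞: the bound exists to tame perfect separation in the noiseless limit,
and with α = ∞ a hard box on the per-row GLM coefficients (|β|_∞ ≤ 10³)
keeps the arithmetic finite instead.

## Algorithm

With all factor matrices but mode k fixed, L is concave in A_k and separates
over its rows: row j is a Bernoulli GLM whose response is the vectorized
slice Y(:, j, :) and whose design is the Khatri–Rao product of the other
factor matrices in ascending mode order.  One outer iteration is

1. for k = 1..K: replace A_k by the row-wise GLM solutions (modes < k
   already updated, as in a Gauss–Seidel sweep);
2. a single global line search: maximize L(γ·A_prev + (1−γ)·A_new) over a
   21-point uniform grid on [0,1], with one golden-section refinement when
   the grid argmax is interior (an endpoint maximum — γ = 0, the common
   case — is returned as-is, since refining toward the interior could only
   move away from it); under finite α, infeasible blends are excluded, and
   if no grid point is feasible the previous iterate is kept with a warning;
3. normalization: columns of modes 1..K−1 are scaled to unit norm and
   sign-canonicalized (largest-magnitude entry nonnegative), scales and
   signs absorbed into mode K.

Because the γ = 1 grid point restores the previous iterate and every row
GLM step is accepted only if it does not decrease its objective, the
recorded objective trace is non-decreasing by construction.

The row GLMs are solved by damped Newton ascent: per-entry score
(log f)'((2y−1)η) and curvature −(log f)''((2y−1)η), a ridge of 10⁻⁸ scaled
by each row's mean curvature diagonal (so the damping survives ill-scaled or
rank-deficient designs, e.g. when two overparametrized components collapse
onto each other), per-row step-halving (up to 30 halvings), and the
coefficient box above; a least-squares fallback covers exactly singular
systems.  All rows of a mode share one design, so the package solves them in a
single batched pass (the per-iteration cost is O(R²·Π_k d_k) plus
O(R³·Σ_k d_k) for the solves, linear in the tensor size at fixed rank).  The
first sweep starts each row at β = 0 — the current random factors carry no
information about the data, and the zero start makes the coding-flip
symmetry exact along the whole optimization path; later sweeps warm-start
from the current rows.  The Laplacian log-likelihood is linear for θ < 0
(curvature 0); the kink at 0 uses the average of the one-sided curvatures,
and the ridge keeps the Newton system well-posed.

Stopping: relative objective change below `tol` (default 10⁻⁴) or `max_iter`
sweeps (default 100).  Multi-start (default 5 consecutive seeds) returns the
run with the highest final objective.  Missing entries (an observation mask
Ω) are dropped from the likelihood, score, and GLM rows; no mode-k slice may
be entirely missing, which is checked on construction.  Rank 0 is legal
everywhere and denotes the constant probability-½ model, the natural BIC
baseline.

## Rank selection and completion

BIC(R) = −2·L_Y(Θ̂(R)) + p_e(R)·log n, with p_e(R) = R(d1+d2) − R² for K = 2
and R(Σ_k d_k − K + 1) for K ≥ 3, and n the number of *observed* entries
(= Π_k d_k when fully observed; the observed count is the effective sample
size under missingness — the reference formulation is silent on this case).
The grid minimizer is returned, ties toward the smaller rank.

Completion predicts P(y = 1) for unobserved cells as f(θ̂).  Mathematically
f maps finite latents into (0,1); under strong signal the double-precision
value can round to exactly 0 or 1, and such entries are clamped to the
nearest representable interior value to preserve the open-interval contract.
The holdout evaluator splits the 1-entries and 0-entries separately (so the
held-out set preserves the observed density), refits on the training mask,
and reports the Mann–Whitney AUC (ties averaged) and the RMSE of predicted
probabilities against held-out labels.

## Metrics

* Loss(Θ̂, Θ) = ‖Θ̂ − Θ‖_F / √(Π_k d_k) — the root-mean-square entrywise
  deviation.  The normalization uses the −1/2 power of the tensor size: that
  is the convention under which the error of the MLE decays as d^−(K−1)/2
  for cubic tensors, the rate the estimator is designed to achieve.  The
  probability-tensor RMSE uses the same normalization.
* relative loss ‖Θ̂ − Θ‖_F / ‖Θ‖_F;
* MER: fraction of entries whose thresholded (at ½) estimated and true
  probabilities disagree.

## Link diagnostics

The steepness and convexity constants
L_α = sup_{|θ|≤α} f′/(f(1−f)) and γ_α = inf_{|θ|≤α} (f′²/f² − f″/f) control
the constants in the estimation-error analysis.  For the logistic family
both have closed forms (L_α = 1/σ exactly); for probit and Laplacian the
package returns the known analytic bounds (upper for L_α, lower for γ_α),
flagged `is_bound=True` — the exact sup/inf are not used by the algorithm,
so numerically optimizing them would add cost without benefit.  The probit
γ_α bound is evaluated with the signal bound α in its Gaussian factor.

## Simulators

The three generators are first-class, seeded, and byte-reproducible; they
define the study conditions for all tests.

* **CP-threshold** — factor entries i.i.d. Uniform[−1,1], Θ rescaled to
  ‖Θ‖_max = 1, then Y = 1{Θ + E ≥ 0} with i.i.d. noise (gaussian, logistic,
  or laplace) at scale σ.  This produces dense tensors whose 1-density is
  near ½; real binary tensors are often much sparser and have structured
  (non-CP) signals, so passing tests here demonstrate correct estimation
  under the model, not robustness to arbitrary real data.
* **Stochastic multi-way block** — each mode's indices are dealt round-robin
  to n_blocks groups after a seeded shuffle (blocks balanced and non-empty);
  block means on the probit scale are Uniform[−1,1] draws, combined per the
  combinatorial, additive (CP rank ≤ 3), or multiplicative (rank 1) rule;
  Y ~ Bernoulli(Φ(latent)).  Fitting a logistic link to these probit data
  reproduces the deliberate-misspecification experiment.
* **Boolean OR-AND** — per-cell factor probabilities i.i.d. Beta(2,4),
  factor bits Bernoulli, entry = OR over components of the AND of its three
  bits, then i.i.d. 0↔1 flips with probability 0.1.  The pre-flip
  conditional mean is 1 − Π_r(1 − p^a p^b p^c), whose average has the closed
  form 1 − (1 − m³)^R with m = 1/3 the Beta(2,4) mean.

### Fitting link for threshold data

The Gaussian-noise threshold model at noise level σ is exactly the probit(σ)
Bernoulli model.  The loss experiments nevertheless fit a logistic link — a
mild, deliberate family misspecification — and use the variance-matched
scale σ·√3/π (`matched_logistic_link`), so the fitted Θ̂ lives on the scale
of the true Θ and Frobenius losses are meaningful.  Rank selection and
iteration counts are invariant to this scale choice (the maximized
likelihood is reparametrization-invariant), so the BIC studies simply use
the logistic link at scale 1.

## Study protocol sizes

The acceptance script runs: rank selection at d=40 (true rank 10, σ=0.1,
grid 5..15) over 10 replications and at d=20 (true rank 5, grid 1..10) over
30 replications, each fit single-start with at most 40 sweeps; and 10 random
initializations at d=60, R=10, σ=10^−0.5 for the convergence-speed study.
Single-start selection is a deliberate economy: spot checks showed the
selected rank is insensitive to extra starts at these signal levels, and the
stopping rule engages long before 40 sweeps.  The test suite repeats the
same protocols at smaller replication counts, plus oracle comparisons
(brute-force likelihood sums, finite-difference scores, generic numerical
maximizers on 4×4×4 instances) and property tests (monotone traces, coding
invariance, error decay in dimension, degradation as σ → 0).

## Known limitations

* Dense arithmetic throughout: coordinate files are an interchange format,
  not an internal representation; very large sparse tensors are out of
  scope, as are Tucker and other decompositions and order-1 tensors.
* The alternating algorithm guarantees monotone ascent, not global
  optimality; multi-start is the only defense against bad local maxima.
* BIC consistency for the selected rank is an open theoretical question;
  empirically it under-selects mildly at small dimensions (d ≈ 20).
* Finite α is enforced only through line-search feasibility, matching the
  algorithm's definition; block updates themselves are unconstrained.
* User-supplied link families are architecturally possible but untested.
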