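# bintensor

Likelihood-based CP decomposition of binary multiway arrays.

Binary tensors are everywhere in the life and social sciences: presence or
absence of fiber connections between brain regions across subjects,
sender × receiver × time email indicators, country × country × relation
political events, user × item × context clicks. `bintensor` models an
order-K 0/1 tensor **Y** as independent Bernoulli draws,

    P(y_{i1..iK} = 1) = f(θ_{i1..iK}),     Θ = Σ_{r=1}^R λ_r a_r^(1) ⊗ ... ⊗ a_r^(K),

where the parameter tensor Θ has a rank-R CP (CANDECOMP/PARAFAC) structure
and `f` is a logistic, probit, or Laplacian link with scale σ.  Equivalently,
Y is the entrywise 1-bit quantization `Y = 1{Θ + E ≥ 0}` of a latent low-rank
signal plus noise with the matching distribution.  The package estimates Θ by
a constrained maximum-likelihood approach

    Θ̂ = argmax L_Y(Θ)  subject to  rank(Θ) = R, ‖Θ‖_max ≤ α,

using an alternating algorithm: with all but one factor matrix fixed, the
objective is concave and the update of mode k splits into d_k independent
Bernoulli GLMs whose shared design is the Khatri–Rao product of the other
factor matrices.  Each sweep ends with a global line search between the old
and new factor collections and a renormalization, so the objective trace is
monotone non-decreasing.  Around the core estimator the package provides

* BIC rank selection: `R̂ = argmin_R  −2 L_Y(Θ̂(R)) + p_e(R) log(Π_k d_k)`
  with `p_e(R) = R(Σ_k d_k − K + 1)` for K ≥ 3;
* missing-entry completion (`f(θ̂)` predicts held-out cells) with AUC/RMSE
  holdout evaluation;
* the evaluation metrics used for such models (normalized Frobenius loss,
  relative loss, probability RMSE, misclassification error rate);
* seeded simulators for three generative models: the CP-threshold model, a
  stochastic multi-way block model, and a boolean OR-AND tensor model;
* a CLI (`bintensor simulate / decompose / select-rank / complete`) that
  exchanges tensors as FROSTT-style `.tns` coordinate text files.

## Worked example

Simulate a rank-1 binary tensor from the threshold model and refit it:

```python
import numpy as np
from bintensor import (FitOptions, decompose, loss_frobenius,
                       matched_logistic_link, simulate_cp_threshold)

sigma = 10**-0.5                      # latent Gaussian noise level
sim = simulate_cp_threshold((15, 15, 15), rank=1, sigma=sigma, seed=3)
link = matched_logistic_link("gaussian", sigma)
res = decompose(sim.Y, link, FitOptions(rank=1, seed=1))
print("iterations:", res.iterations, "converged:", res.converged)
print("loss of fit :", round(loss_frobenius(res.theta_hat, sim.theta_true), 4))
print("loss of zero:", round(loss_frobenius(np.zeros(sim.Y.dims), sim.theta_true), 4))
```

prints

```
iterations: 6 converged: True
loss of fit : 0.0756
loss of zero: 0.2184
```

i.e. the fit converged in 6 sweeps and its root-mean-square entrywise error
against the true signal tensor (0.076) is roughly a third of the trivial
zero-estimator baseline (0.218).  The same workflow from the shell:

```sh
bintensor simulate --model cp --dims 15,15,15 --rank 1 --sigma 0.316 --seed 3 --out sim
bintensor decompose --input sim.tns --dims 15,15,15 --rank 1 --seed 1 --out fit
```

which writes the factor matrices (`fit_mode*.tsv`, `fit_scales.tsv`) and a
JSON run report with the objective trace.

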