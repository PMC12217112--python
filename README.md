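# btties

Bayesian inference for **Bradley–Terry models with tied comparisons**, built
for comparative-judgement studies of small geographic areas.

In a comparative-judgement survey, participants who know a community are
shown pairs of areas ("wards") and asked which has the higher rate of some
hard-to-measure outcome — or whether the two are about equal.  Allowing the
"about equal" (tie) response reduces judge fatigue, but makes posterior
computation harder.  `btties` fits the Rao–Kupper tied Bradley–Terry model
with a Pólya-Gamma-augmented Gibbs sampler, so that spatially correlated
priors on the area qualities remain conjugate and fitting stays fast even
for hundreds of areas.

## Model

Each ward *i* has a latent quality λᵢ ∈ ℝ.  For a comparison of wards *i*
and *j*, with tie parameter δ ≥ 0,

    P(i beats j) = exp(λᵢ) / (exp(λᵢ) + exp(λⱼ + δ))
    P(i ties j)  = (e^{2δ} − 1) · P(i beats j) · P(j beats i)

δ = 0 recovers the standard Bradley–Terry model.  The prior on
λ = (λ₁,…,λ_N) is multivariate normal N(μ, Σ) with a graph-structured
covariance built from the ward adjacency matrix A:

    Σ = α² D^{−1/2} e^A D^{−1/2},   D = diag(e^A),

which has unit diagonal before scaling, so α² is the prior signal variance
and nearby (well-connected) wards get high prior correlation.  α² can be
fixed or given a conjugate inverse-gamma hyperprior; δ gets an Exp(χ) prior.

Writing η_ij = λᵢ − λⱼ − δ, every ordered pair contributes
(e^{η_ij}/(1+e^{η_ij}))^{y_ij+t_ij} to the likelihood.  One Pólya-Gamma
latent z_ij ~ PG(y_ij + t_ij, η_ij) per ordered pair turns this logistic
form into a Gaussian one, giving the closed-form full conditional

    λ | z, δ, α² ~ N(m, S),  S = (XᵀZX + Σ^{−1})^{−1},
    m = S (Xᵀ(κ + δz) + Σ^{−1}μ),   κ_ij = (y_ij + t_ij)/2,

where X is the ±1 design over ordered pairs and Z = diag(z).  δ is updated
by a random-walk Metropolis step on the observed-data likelihood, and α² by
its inverse-gamma full conditional.  A Metropolis–Hastings random-walk
sampler targeting the same posterior is included as a correctness oracle
and efficiency baseline.  Pólya-Gamma draws are exact (Devroye
alternating-series accept–reject, numba-compiled).

## Worked example

```python
import numpy as np
from btties import (PriorSpec, SamplerConfig, SimulationDesign,
                    run_mcmc, simulate_design)

design = SimulationDesign(n_wards=12, target_tie_fraction=0.2, seed=11)
data, truth = simulate_design(design)
print(f"simulated {data.n_comparisons} comparisons ({data.n_ties} ties) "
      f"on {data.n_wards} wards; true delta = {truth['delta']:.3f}")

prior = PriorSpec(base_covariance=truth["base_covariance"],
                  alpha2="inferred", chi=0.01)
trace = run_mcmc(data, prior, SamplerConfig(n_iterations=5000, burn_in=100, seed=1))

lo, med, hi = np.percentile(trace.delta_samples, [2.5, 50, 97.5])
print(f"posterior median delta = {med:.3f} (95% CI {lo:.3f}-{hi:.3f})")
print(f"delta acceptance rate  = {trace.accept_rate_delta:.2f}")
print(trace.summary().sort_values("posterior_median").head(3).to_string(index=False))
```

Output:

```
simulated 120 comparisons (17 ties) on 12 wards; true delta = 0.476
posterior median delta = 0.343 (95% CI 0.210-0.521)
delta acceptance rate  = 0.62
ward  posterior_median  ci_lower  ci_upper  posterior_variance
W008         -0.624343 -1.963810  0.660316            0.432628
W004         -0.617658 -1.939754  0.546845            0.386331
W000         -0.530756 -1.887620  0.701516            0.411632
```

The simulator drew 120 comparisons (ten per ward) from the tied model on a
3×4 ward grid, calibrating δ so that about 20% of comparisons tie.  The
fitted 95% credible interval for δ covers a value close to the truth, and
the summary lists the three wards with the lowest posterior-median quality
(in the motivating application, large *negative* quality means a *high*
rate of the outcome).  With only ten comparisons per ward the per-ward
credible intervals are wide — this is exactly the regime the spatially
correlated prior is designed for.

The same pipeline is available from the shell:

```sh
btties simulate --n-wards 12 --tie-fraction 0.2 --seed 11 --out-dir sim/
btties fit --comparisons sim/comparisons.csv --adjacency sim/adjacency.csv \
           --iters 5000 --burnin 100 --seed 1 --out-dir fit/
btties diagnose --trace fit/trace.csv --out-dir diag/
```

All inputs and outputs are plain CSV (`ward_a,ward_b,outcome` with outcome
`a`/`b`/`tie` for comparisons; an undirected edge list for the adjacency);
every run writes a JSON manifest so it can be reproduced bit-for-bit.

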