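# Methods

This note records the model, the algorithmic and numerical choices, and
what the synthetic-data checks do and do not establish.

## Model and likelihood

Comparisons are aggregated to ordered-pair counts: `y[i, j]` comparisons in
which ward *i* was judged higher than ward *j*, and a symmetric tie count
`t[i, j]`.  Skip responses, if a survey offers them, are simply absent from
the counts: the model defines only win/loss/tie outcomes.  With
η_ij = λ_i − λ_j − δ and σ(·) the logistic function, the tied
(Rao–Kupper-type) model sets P(i beats j) = σ(η_ij) and
P(i ties j) = (e^{2δ} − 1) σ(η_ij) σ(η_ji).

A useful algebraic fact drives the implementation: the tie probability
*equals* (e^{2δ} − 1)·σ(η_ij)·σ(η_ji), so the log-likelihood summed over
unordered pairs,

    Σ_{i<j} [ y_ij log σ(η_ij) + y_ji log σ(η_ji) + t_ij log P(tie) ],

is *identical* (not merely equal up to a constant) to the ordered-pair
form T·log(e^{2δ} − 1) + Σ_{i≠j} (y_ij + t_ij) log σ(η_ij), with T the
total tie count.  Both forms are tested against each other, and the δ
Metropolis update can therefore reuse the ordinary log-likelihood
function.  All probability work is done with log-sigmoids and
`log(e^{2δ} − 1)` evaluated via `expm1`/`log1p`, so quality values of
magnitude 50 and δ in the hundreds (relevant when a vague Exp(0.01) prior
is explored) stay finite.

## Polya-Gamma augmentation

Each ordered pair with positive exposure b_ij = y_ij + t_ij carries one
latent z_ij ~ PG(b_ij, η_ij).  Completing the square on
κ η − z η²/2 with κ = b/2 gives the Gaussian full conditional for λ with
precision XᵀZX + Σ⁻¹ and linear term Xᵀ(κ + δz) + Σ⁻¹μ.  The sign of the
δz term matters and is pinned down by a two-ward quadrature test: the
posterior mean and covariance of the analytic Gaussian match brute-force
2-D lattice integration to better than 1e−6 (lattice sums of
Gaussian-type integrands converge spectrally, so a 601-point grid on
[−9, 9]² is far more accurate than needed).

Sampling from the λ conditional uses a Cholesky factor L of the
*precision*: the draw is m + L⁻ᵀξ; no covariance matrix is ever formed.

PG draws are exact, via the alternating-series accept–reject sampler
(piecewise truncated inverse-Gaussian / truncated-exponential proposal
with changeover at t = 0.64 and tilt |c|/2).  PG(b, c) for integer b ≥ 1
is the sum of b PG(1, c) draws — exposures are small counts here, so the
sum scheme is faster in practice than any large-b approximation and keeps
the sampler exact.  The inner loop is numba-compiled and consumes the
caller's `numpy.random.Generator`, so runs are reproducible from a single
seed.  Moments are validated against the closed forms
E = b·tanh(c/2)/(2c) and Var = b(sinh c − c)sech²(c/2)/(4c³) (limits b/4
and b/24 at c = 0), and the integral identity
(e^x)^a/(1+e^x)^b = 2^{−b} e^{(a−b/2)x} E_{PG(b,0)}[e^{−zx²/2}] is checked
by Monte Carlo on both sides.

## Updates, order, identifiability

One iteration runs: z | λ, δ → λ | z, δ, α² → translation → δ → α².
The δ update is a Gaussian random-walk Metropolis step on the
observed-data posterior (the PG latents are marginalised out; the stated
full conditional for δ contains no z terms), with negative proposals
rejected through the zero prior density.  The default proposal scale is
0.1; `tune_delta_step` is a pilot-run helper that halves/doubles the scale
toward a 20–40% acceptance band.

The likelihood is translation-invariant in λ, so the average quality
Λ = Σλ_i/N is identified only by the prior.  Each iteration recentres λ
and, by default, resamples Λ from its prior law N(1ᵀμ/N, 1ᵀΣ1/N²)
("resample" mode; "center" subtracts only, "none" disables the step).
Resampling Λ from its *marginal* prior law is exact when 1 is an
eigenvector of Σ (e.g. exchangeable or regular-graph covariances) and is
otherwise a deliberate approximation to the conditional law of Λ given
the centred components; all identified quantities (pairwise differences,
δ) are unaffected, which the cross-sampler agreement test confirms.  In
debug mode the sampler asserts at every iteration that translation left
the likelihood unchanged.

α², when inferred, has the conjugate update
InvGamma(shape + N/2, scale + (λ−μ)ᵀΣ₀⁻¹(λ−μ)/2) with Σ₀ the unit-diagonal
base covariance; Σ is rescaled by the scalar rather than refactorised.
Default hyperparameters are shape = scale = 0.01 and χ = 0.01 (vague), the
values used when fitting real survey data.

## Spatial prior

Σ = α² D^{−1/2} e^A D^{−1/2} with D = diag(e^A).  The normalisation gives
exactly unit diagonal, so α² is the marginal prior variance of every ward.
The matrix exponential is computed once per fit (`scipy.linalg.expm`) and
symmetrised to remove round-off asymmetry.  Disconnected graphs are
allowed (e^A remains positive definite) with a logged warning, since
cross-component correlation is then essentially zero.  Small α² means
strong spatial smoothing relative to the (fixed-scale) likelihood signal.

## Samplers compared

The Metropolis–Hastings baseline updates each λ_i with a Gaussian random
walk judged on the local likelihood (only pairs involving ward *i*) plus
the Gaussian prior term, then shares the δ, translation and α² steps.  It
targets the identical posterior and serves two purposes: a correctness
oracle (posterior means of all identified quantities agree with the Gibbs
sampler within Monte-Carlo error) and the efficiency comparator (effective
sample size per second, computed with ArviZ's autocorrelation-based
estimator; constant chains report NaN rather than infinite ESS).

## Correctness testing

Three layers of evidence, all in the test suite and recomputed by
`scripts/acceptance.py`:

1. **Exact pieces** — closed-form examples for probabilities, likelihood
   forms, covariances; quadrature for the λ conditional; prior recovery
   (no-data runs reproduce prior marginals; the δ chain with no data
   passes a KS test against its exponential prior).
2. **Geweke successive-conditional check** — on a 3-ward grid model,
   alternating "simulate data given parameters" with one scan of the
   posterior transition must leave the parameter marginals exactly at the
   prior.  The harness uses Exp(1) for δ and InvGamma(3, 3) for α²: the
   check is valid for any proper hyperparameters, and these keep simulated
   δ values in a range where outcomes are informative (an Exp(0.01) prior
   mean of 100 would make essentially every simulated comparison a tie).
   The translation step is excluded here — it is not one of the model's
   full conditionals (see above) — so the check isolates the three
   conditional updates plus the PG draw.
3. **End-to-end recovery** — 20 synthetic studies (20 wards on a grid,
   200 comparisons, δ calibrated to a ~20% expected tie fraction, α²
   re-inferred under its vague hyperprior): the posterior median of δ
   lands within ±0.25 of the truth in at least 16 of 20, and the mean
   Spearman correlation between true and posterior-median qualities is
   at least 0.7.  At a ~75% tie rate the rank correlation degrades
   relative to ~20% — ties still carry *some* ranking information
   (a tie asserts closeness), but mostly crowd out decisive outcomes.

## Synthetic generator: what it does and does not emulate

`simulate_design` reproduces the study conditions: qualities drawn from
the graph (or normalised-Wishart) prior, comparisons at ten per ward with
pairs uniform over unordered pairs, tie levels set either directly
(δ = 0.5 is typical of real fits) or through the expected tie fraction.
The calibration target is the *population* tie fraction — the tie
probability averaged over all pairs at the true λ — solved by Brent's
method (the fraction is continuous and strictly increasing in δ), not a
realised sample fraction, so it is deterministic and testable.

Not emulated: judge identity and judge-specific reliability (the model has
no judge effects), skip responses, familiarity-restricted pair selection
(supported via an explicit pair list but not defaulted), and order/home
effects.  Passing recovery tests therefore shows the *inference machinery*
is sound under the model's own assumptions; it does not validate the model
against judge heterogeneity or informative skipping in real surveys.

## Problem sizes and numerical defaults

Validation runs use: 2-ward quadrature (601² lattice); 4 wards / 60
comparisons for cross-sampler agreement (5 000 Gibbs vs 100 000
random-walk iterations, mirroring the samplers' different mixing rates);
a 3-ward Geweke chain of 25 000 cycles thinned by 10; 20 replicates of the
20-ward recovery design; and a single 20-ward dataset for the ESS/sec
comparison.  These sizes give stable Monte-Carlo margins (3 standard
errors for moment checks, KS at α = 0.001) while keeping the full suite
fast.  Sampler defaults: 5 000 iterations, burn-in 100, δ step 0.1,
initial state λ = μ, δ = 0.5, α² = 1.

## Known limitations

- The Λ-resampling translation is exact only when 1ᵀΣ has equal entries;
  the package keeps it (it matches the intended algorithm and aids Λ
  mixing) but documents that α² inference couples weakly to the level
  through the quadratic form.
- Exposures must be integers (they are counts by construction); fractional
  PG exposures would need the infinite-sum or saddlepoint samplers, which
  are out of scope.
- The MH baseline's componentwise scan costs O(N · deg) per iteration and
  mixes slowly for large N; it is a baseline, not a recommended sampler.
- No judge-level modelling, multi-way comparisons, or adaptive designs.
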