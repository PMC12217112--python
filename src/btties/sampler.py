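"""MCMC algorithms for the tied Bradley-Terry model.

Two samplers target the same posterior
``p(lambda, delta, alpha^2 | y, t)``:

``run_mcmc``
    The Polya-Gamma Gibbs sampler.  One PG latent z_ij per ordered pair
    with exposure b_ij = y_ij + t_ij > 0 makes the lambda full conditional
    Gaussian:

        z_ij | .  ~  PG(b_ij, x_ij' lambda - delta)
        lambda | .  ~  N(m, S),  S = (X' Z X + Sigma^{-1})^{-1},
                        m = S (X'(kappa + delta z) + Sigma^{-1} mu),

    with kappa_ij = b_ij / 2 (completing the square on
    kappa*eta - z*eta^2/2 with eta = x'lambda - delta gives the linear
    coefficient kappa + delta*z).  delta is updated by a random-walk
    Metropolis step on the observed-data likelihood times its Exp(chi)
    prior, and alpha^2 by its conjugate inverse-gamma full conditional.

``run_mh_baseline``
    A componentwise Gaussian random-walk sampler on lambda (plus the same
    delta step, translation and alpha^2 update).  It is the correctness
    oracle and the efficiency comparator: it needs far more iterations per
    effective sample.

The likelihood is invariant to adding a constant to lambda, so each
iteration recentres the qualities and (by default) resamples the average
quality Lambda from its prior law N(1'mu/N, 1'Sigma 1/N^2).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import scipy.linalg as sla

from .likelihood import (
    ComparisonTable,
    DesignMatrix,
    _log_expm1_2delta,
    _log_sigmoid,
    build_design_matrix,
    log_likelihood_ties,
)
from .polya_gamma import sample_pg_vector
from .spatial import PriorSpec, sample_alpha2, total_quality_distribution

__all__ = [
    "PGLatents",
    "PosteriorTrace",
    "SamplerConfig",
    "ess_per_second",
    "gibbs_update_lambda",
    "gibbs_update_z",
    "lambda_full_conditional",
    "mh_update_delta",
    "prior_reference_draws",
    "run_mcmc",
    "successive_conditional_chain",
    "run_mh_baseline",
    "translate_lambda",
    "tune_delta_step",
]

logger = logging.getLogger(__name__)


@dataclass
class SamplerConfig:
    """Run-length and proposal settings shared by both samplers."""

    n_iterations: int = 5000
    burn_in: int = 100
    delta_step: float = 0.1
    mh_baseline_step: float = 0.1
    seed: int | None = None
    translation: Literal["resample", "center", "none"] = "resample"
    debug: bool = False  # assert likelihood invariance of the translation each iteration

    def __post_init__(self) -> None:
        if self.n_iterations <= 0:
            raise ValueError("n_iterations must be positive")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iterations")
        if self.delta_step <= 0 or self.mh_baseline_step <= 0:
            raise ValueError("proposal step sizes must be positive")


@dataclass
class PGLatents:
    """Polya-Gamma latents, one per design-matrix row."""

    values: np.ndarray  # z_ij > 0
    exposures: np.ndarray  # b_ij = y_ij + t_ij >= 1
    tilts: np.ndarray  # c_ij = x_ij' lambda - delta


@dataclass
class PosteriorTrace:
    """Kept (post burn-in) samples from one MCMC run."""

    ward_labels: list[str]
    lambda_samples: np.ndarray  # (kept, N)
    delta_samples: np.ndarray  # (kept,)
    alpha2_samples: np.ndarray | None  # (kept,) if alpha^2 was inferred
    accept_rate_delta: float
    config: SamplerConfig
    sampler: str = "pg"
    wall_time: float = float("nan")
    accept_rate_lambda: float = float("nan")  # MH baseline only

    @property
    def n_kept(self) -> int:
        return self.delta_samples.size

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(
            self.lambda_samples,
            columns=[f"lambda_{w}" for w in self.ward_labels],
        )
        df.insert(0, "delta", self.delta_samples)
        if self.alpha2_samples is not None:
            df.insert(1, "alpha2", self.alpha2_samples)
        df.insert(0, "iteration", np.arange(self.config.burn_in, self.config.n_iterations))
        return df

    def summary(self):
        """Per-ward posterior median, equal-tailed 95% interval and variance."""
        import pandas as pd

        q = np.percentile(self.lambda_samples, [50, 2.5, 97.5], axis=0)
        return pd.DataFrame(
            {
                "ward": self.ward_labels,
                "posterior_median": q[0],
                "ci_lower": q[1],
                "ci_upper": q[2],
                "posterior_variance": self.lambda_samples.var(axis=0, ddof=1),
            }
        )


# ---------------------------------------------------------------------------
# Full-conditional updates
# ---------------------------------------------------------------------------


def gibbs_update_z(
    X: DesignMatrix, lam: np.ndarray, delta: float, rng: np.random.Generator
) -> PGLatents:
    """Draw each latent from its conditional PG(y_ij + t_ij, x_ij'lambda - delta)."""
    tilts = X.dot(lam) - delta
    values = sample_pg_vector(X.exposures, tilts, rng)
    return PGLatents(values=values, exposures=X.exposures, tilts=tilts)


def lambda_full_conditional(
    X: DesignMatrix,
    z: PGLatents,
    delta: float,
    prior: PriorSpec,
    alpha2: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and precision of the Gaussian full conditional of lambda.

    Precision ``P = X' diag(z) X + Sigma^{-1}`` and mean ``P^{-1} h`` with
    ``h = X'(kappa + delta z) + Sigma^{-1} mu``, ``kappa = (y + t)/2``.
    """
    prec_prior = prior.base_precision() / alpha2
    P = X.weighted_gram(z.values) + prec_prior
    kappa = z.exposures / 2.0
    h = X.transpose_dot(kappa + delta * z.values) + prec_prior @ prior.mean
    return h, P


def gibbs_update_lambda(
    X: DesignMatrix,
    z: PGLatents,
    delta: float,
    prior: PriorSpec,
    alpha2: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw lambda from N(m, S) via a Cholesky factor of the precision.

    Never forms S explicitly: with P = L L' the draw is
    ``m + L'^{-1} xi``, xi ~ N(0, I).
    """
    h, P = lambda_full_conditional(X, z, delta, prior, alpha2)
    try:
        L = np.linalg.cholesky(P)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "lambda full-conditional precision (X'ZX + Sigma^{-1}) is not "
            "positive definite"
        ) from err
    m = sla.cho_solve((L, True), h)
    xi = rng.standard_normal(prior.n_wards)
    return m + sla.solve_triangular(L.T, xi, lower=False)


def _delta_log_target(data: ComparisonTable, lam: np.ndarray, delta: float, chi: float) -> float:
    if delta < 0:
        return -np.inf
    return log_likelihood_ties(data, lam, delta) - chi * delta


def mh_update_delta(
    data: ComparisonTable,
    lam: np.ndarray,
    delta_current: float,
    chi: float,
    step: float,
    rng: np.random.Generator,
) -> tuple[float, bool]:
    """Random-walk Metropolis step for the tie parameter.

    The target is the observed-data likelihood (the PG latents are
    marginalised out) times the Exp(chi) prior; negative proposals have
    zero prior density and are rejected outright.
    """
    proposal = delta_current + step * rng.standard_normal()
    if proposal < 0:
        return delta_current, False
    log_ratio = _delta_log_target(data, lam, proposal, chi) - _delta_log_target(
        data, lam, delta_current, chi
    )
    if np.log(rng.random()) < log_ratio:
        return float(proposal), True
    return float(delta_current), False


def translate_lambda(
    lam: np.ndarray,
    prior: PriorSpec,
    rng: np.random.Generator,
    alpha2: float | None = None,
    mode: str = "resample",
) -> np.ndarray:
    """Recentre the qualities; the likelihood only sees differences.

    ``resample`` subtracts the current average quality Lambda and adds a
    fresh draw from its prior law N(1'mu/N, 1'Sigma 1/N^2); ``center``
    only subtracts; ``none`` is the identity.
    """
    lam = np.asarray(lam, dtype=float)
    if mode == "none":
        return lam
    centred = lam - lam.mean()
    if mode == "center":
        return centred
    if mode != "resample":
        raise ValueError(f"unknown translation mode {mode!r}")
    m, v = total_quality_distribution(prior, alpha2)
    return centred + (m + np.sqrt(v) * rng.standard_normal())


# ---------------------------------------------------------------------------
# Full samplers
# ---------------------------------------------------------------------------


def _prepare(data: ComparisonTable, prior: PriorSpec) -> None:
    if data.n_wards != prior.n_wards:
        raise ValueError(
            f"data has {data.n_wards} wards but prior covariance is "
            f"{prior.n_wards}x{prior.n_wards}"
        )


def _check_finite(it: int, **state) -> None:
    for name, value in state.items():
        if not np.all(np.isfinite(value)):
            raise FloatingPointError(
                f"non-finite {name} at iteration {it}; aborting"
            )


def run_mcmc(
    data: ComparisonTable, prior: PriorSpec, config: SamplerConfig
) -> PosteriorTrace:
    """Polya-Gamma Gibbs sampler.

    Per iteration: z | lambda, delta  ->  lambda | z, delta, alpha^2  ->
    translation  ->  delta (Metropolis)  ->  alpha^2 (conjugate, if the
    prior requests inference).  The first ``burn_in`` iterations are
    discarded.  A fixed seed makes the trace bit-reproducible.
    """
    _prepare(data, prior)
    rng = np.random.default_rng(config.seed)
    X = build_design_matrix(data)
    if X.n_rows == 0:
        logger.warning("no comparisons: posterior equals the prior")

    n = data.n_wards
    kept = config.n_iterations - config.burn_in
    lam = prior.mean.copy()
    delta = 0.5
    alpha2 = 1.0 if prior.infer_alpha2 else float(prior.alpha2)

    lam_out = np.empty((kept, n))
    delta_out = np.empty(kept)
    alpha2_out = np.empty(kept) if prior.infer_alpha2 else None
    n_accept = 0

    t0 = time.perf_counter()
    for it in range(config.n_iterations):
        if X.n_rows > 0:
            z = gibbs_update_z(X, lam, delta, rng)
            lam = gibbs_update_lambda(X, z, delta, prior, alpha2, rng)
        else:
            lam = prior.mean + np.sqrt(alpha2) * (
                prior.base_cholesky() @ rng.standard_normal(n)
            )
        if config.debug:
            before = log_likelihood_ties(data, lam, delta)
        lam = translate_lambda(lam, prior, rng, alpha2, config.translation)
        if config.debug:
            after = log_likelihood_ties(data, lam, delta)
            assert abs(after - before) < 1e-8 * max(1.0, abs(before)), (
                "translation changed the likelihood"
            )
        delta, accepted = mh_update_delta(
            data, lam, delta, prior.chi, config.delta_step, rng
        )
        n_accept += accepted
        if prior.infer_alpha2:
            alpha2 = sample_alpha2(
                lam,
                prior.base_covariance,
                prior.alpha2_shape,
                prior.alpha2_scale,
                rng,
                mean=prior.mean,
            )
        _check_finite(it, lam=lam, delta=delta, alpha2=alpha2)
        k = it - config.burn_in
        if k >= 0:
            lam_out[k] = lam
            delta_out[k] = delta
            if alpha2_out is not None:
                alpha2_out[k] = alpha2
    wall = time.perf_counter() - t0

    return PosteriorTrace(
        ward_labels=list(data.ward_labels),
        lambda_samples=lam_out,
        delta_samples=delta_out,
        alpha2_samples=alpha2_out,
        accept_rate_delta=n_accept / config.n_iterations,
        config=config,
        sampler="pg",
        wall_time=wall,
    )


def run_mh_baseline(
    data: ComparisonTable, prior: PriorSpec, config: SamplerConfig
) -> PosteriorTrace:
    """Componentwise random-walk Metropolis sampler targeting the same posterior.

    Each ward quality gets a Gaussian random-walk proposal judged on its
    local likelihood (only pairs involving that ward) plus the prior;
    delta, the translation and the alpha^2 update are shared with the
    Gibbs sampler.
    """
    _prepare(data, prior)
    rng = np.random.default_rng(config.seed)
    X = build_design_matrix(data)
    n = data.n_wards
    kept = config.n_iterations - config.burn_in

    # rows of the design touching each ward, for O(deg) likelihood deltas
    rows_of = [
        np.flatnonzero((X.rows_i == i) | (X.rows_j == i)) for i in range(n)
    ]
    b = X.exposures.astype(float)
    Q0 = prior.base_precision()

    lam = prior.mean.copy()
    delta = 0.5
    alpha2 = 1.0 if prior.infer_alpha2 else float(prior.alpha2)

    lam_out = np.empty((kept, n))
    delta_out = np.empty(kept)
    alpha2_out = np.empty(kept) if prior.infer_alpha2 else None
    n_accept_delta = 0
    n_accept_lam = 0

    def local_loglik(lam_vec: np.ndarray, rows: np.ndarray) -> float:
        eta = lam_vec[X.rows_i[rows]] - lam_vec[X.rows_j[rows]] - delta
        return float(np.dot(b[rows], _log_sigmoid(eta)))

    t0 = time.perf_counter()
    for it in range(config.n_iterations):
        Q = Q0 / alpha2
        resid = lam - prior.mean
        for i in range(n):
            d = config.mh_baseline_step * rng.standard_normal()
            rows = rows_of[i]
            cur = local_loglik(lam, rows)
            lam_prop = lam.copy()
            lam_prop[i] += d
            prop = local_loglik(lam_prop, rows)
            # prior difference for a single-coordinate move
            dprior = -0.5 * d * d * Q[i, i] - d * float(Q[i] @ resid)
            if np.log(rng.random()) < prop - cur + dprior:
                lam = lam_prop
                resid = lam - prior.mean
                n_accept_lam += 1
        lam = translate_lambda(lam, prior, rng, alpha2, config.translation)
        delta, accepted = mh_update_delta(
            data, lam, delta, prior.chi, config.delta_step, rng
        )
        n_accept_delta += accepted
        if prior.infer_alpha2:
            alpha2 = sample_alpha2(
                lam,
                prior.base_covariance,
                prior.alpha2_shape,
                prior.alpha2_scale,
                rng,
                mean=prior.mean,
            )
        _check_finite(it, lam=lam, delta=delta, alpha2=alpha2)
        k = it - config.burn_in
        if k >= 0:
            lam_out[k] = lam
            delta_out[k] = delta
            if alpha2_out is not None:
                alpha2_out[k] = alpha2
    wall = time.perf_counter() - t0

    return PosteriorTrace(
        ward_labels=list(data.ward_labels),
        lambda_samples=lam_out,
        delta_samples=delta_out,
        alpha2_samples=alpha2_out,
        accept_rate_delta=n_accept_delta / config.n_iterations,
        config=config,
        sampler="mh",
        wall_time=wall,
        accept_rate_lambda=n_accept_lam / (config.n_iterations * n),
    )


# ---------------------------------------------------------------------------
# Diagnostics and helpers
# ---------------------------------------------------------------------------


def effective_sample_size(x: np.ndarray) -> float:
    """ESS of a single chain via the initial-positive-sequence estimator.

    Returns NaN for a (numerically) constant chain rather than infinity.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 4 or np.var(x) < 1e-300:
        return float("nan")
    import arviz as az

    return float(az.ess(x[None, :], method="bulk"))


def ess_per_second(
    trace: PosteriorTrace, wall_time: float | None = None
) -> tuple[float, float]:
    """(ESS/sec of delta, mean ESS/sec over the ward qualities)."""
    if trace.n_kept == 0:
        raise ValueError("empty trace")
    wall = trace.wall_time if wall_time is None else wall_time
    ess_delta = effective_sample_size(trace.delta_samples)
    ess_lams = np.array(
        [effective_sample_size(trace.lambda_samples[:, k]) for k in range(len(trace.ward_labels))]
    )
    return ess_delta / wall, float(np.nanmean(ess_lams)) / wall


def successive_conditional_chain(
    prior: PriorSpec,
    n_comparisons: int,
    n_cycles: int,
    rng: np.random.Generator,
    delta_step: float = 0.5,
) -> dict[str, np.ndarray]:
    """Geweke-style successive-conditional sampler for validating the updates.

    Alternates (i) data simulated from the model at the current parameters
    with (ii) one scan of the posterior transition (z, lambda, delta,
    alpha^2) given that data.  If every conditional update is correct, the
    marginal law of the parameters along the chain is exactly the prior, so
    the returned chains can be compared against iid prior draws.
    """
    from .synthetic import simulate_comparisons

    n = prior.n_wards
    alpha2 = (
        prior.alpha2_scale / rng.gamma(prior.alpha2_shape)
        if prior.infer_alpha2
        else float(prior.alpha2)
    )
    lam = prior.mean + np.sqrt(alpha2) * (prior.base_cholesky() @ rng.standard_normal(n))
    delta = rng.exponential(1.0 / prior.chi)

    out = {
        "lambda_1": np.empty(n_cycles),
        "delta": np.empty(n_cycles),
        "alpha2": np.empty(n_cycles) if prior.infer_alpha2 else None,
    }
    for k in range(n_cycles):
        data = simulate_comparisons(lam, delta, n_comparisons, rng)
        X = build_design_matrix(data)
        z = gibbs_update_z(X, lam, delta, rng)
        lam = gibbs_update_lambda(X, z, delta, prior, alpha2, rng)
        delta, _ = mh_update_delta(data, lam, delta, prior.chi, delta_step, rng)
        if prior.infer_alpha2:
            alpha2 = sample_alpha2(
                lam,
                prior.base_covariance,
                prior.alpha2_shape,
                prior.alpha2_scale,
                rng,
                mean=prior.mean,
            )
            out["alpha2"][k] = alpha2
        out["lambda_1"][k] = lam[0]
        out["delta"][k] = delta
    return out


def prior_reference_draws(
    prior: PriorSpec, n_draws: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """iid draws of (lambda_1, delta, alpha^2) from the joint prior."""
    if prior.infer_alpha2:
        alpha2 = prior.alpha2_scale / rng.gamma(prior.alpha2_shape, size=n_draws)
    else:
        alpha2 = np.full(n_draws, float(prior.alpha2))
    lam1 = prior.mean[0] + np.sqrt(alpha2) * (
        prior.base_cholesky()[0, 0] * rng.standard_normal(n_draws)
    )
    # row 0 of the Cholesky factor has a single nonzero, so lambda_1 above is
    # exact; other components would need the full factor.
    delta = rng.exponential(1.0 / prior.chi, size=n_draws)
    return {
        "lambda_1": lam1,
        "delta": delta,
        "alpha2": alpha2 if prior.infer_alpha2 else None,
    }


def tune_delta_step(
    data: ComparisonTable,
    prior: PriorSpec,
    config: SamplerConfig,
    target: tuple[float, float] = (0.2, 0.4),
    pilot_iterations: int = 500,
    max_rounds: int = 8,
) -> float:
    """Pilot-run halving/doubling of the delta proposal scale.

    Runs short chains until the delta acceptance rate falls in ``target``;
    returns the tuned step without modifying ``config``.
    """
    step = config.delta_step
    for _ in range(max_rounds):
        pilot = replace(
            config,
            n_iterations=pilot_iterations,
            burn_in=0,
            delta_step=step,
        )
        rate = run_mcmc(data, prior, pilot).accept_rate_delta
        if rate < target[0]:
            step /= 2.0
        elif rate > target[1]:
            step *= 2.0
        else:
            break
    return step
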