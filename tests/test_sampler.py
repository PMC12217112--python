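"""Full-conditional updates, translation, both samplers, ESS diagnostics."""

import math

import numpy as np
import pytest
from scipy.stats import expon, kstest

from btties.likelihood import (
    ComparisonTable,
    build_design_matrix,
    log_likelihood_ties,
)
from btties.polya_gamma import pg_mean
from btties.sampler import (
    PosteriorTrace,
    SamplerConfig,
    effective_sample_size,
    ess_per_second,
    gibbs_update_lambda,
    gibbs_update_z,
    lambda_full_conditional,
    mh_update_delta,
    run_mcmc,
    run_mh_baseline,
    translate_lambda,
    tune_delta_step,
)
from btties.spatial import PriorSpec, total_quality_distribution

from conftest import random_table


def two_ward_table(y12, y21=0, t12=0):
    wins = np.array([[0, y12], [y21, 0]])
    ties = np.array([[0, t12], [t12, 0]])
    return ComparisonTable(ward_labels=["A", "B"], wins=wins, ties=ties)


class TestGibbsUpdateZ:
    def test_tilts_are_quality_differences_minus_delta(self, rng):
        data = random_table(5, 10, rng)
        X = build_design_matrix(data)
        lam = rng.normal(size=5)
        z = gibbs_update_z(X, lam, 0.7, rng)
        want = lam[X.rows_i] - lam[X.rows_j] - 0.7
        assert z.tilts == pytest.approx(want, abs=1e-14)
        assert np.array_equal(z.exposures, X.exposures)
        assert np.all(z.values > 0)

    def test_zero_tilt_rows_have_mean_b_over_4(self, rng):
        data = two_ward_table(y12=2, y21=1)  # exposure 3 and 1
        X = build_design_matrix(data)
        draws = np.array(
            [gibbs_update_z(X, np.zeros(2), 0.0, rng).values for _ in range(20000)]
        )
        for r, b in enumerate(X.exposures):
            se = draws[:, r].std(ddof=1) / math.sqrt(draws.shape[0])
            assert draws[:, r].mean() == pytest.approx(pg_mean(b, 0.0), abs=4 * se)

    def test_deterministic_given_seed(self):
        data = two_ward_table(y12=3, t12=1)
        X = build_design_matrix(data)
        z1 = gibbs_update_z(X, np.array([0.2, -0.1]), 0.5, np.random.default_rng(5))
        z2 = gibbs_update_z(X, np.array([0.2, -0.1]), 0.5, np.random.default_rng(5))
        assert np.array_equal(z1.values, z2.values)


def quadrature_moments(kappas, zs, delta, prior, signs, grid=None):
    """Brute-force posterior moments on a 2-D grid for the N=2 conditional.

    Each row contributes exp(kappa*eta - z*eta^2/2), eta = sign*(l1-l2) - delta.
    Gaussian-type integrand, so the lattice sum converges spectrally.
    """
    if grid is None:
        grid = np.linspace(-9.0, 9.0, 601)
    l1, l2 = np.meshgrid(grid, grid, indexing="ij")
    cov = prior.covariance()
    prec = np.linalg.inv(cov)
    r1, r2 = l1 - prior.mean[0], l2 - prior.mean[1]
    logp = -0.5 * (prec[0, 0] * r1**2 + 2 * prec[0, 1] * r1 * r2 + prec[1, 1] * r2**2)
    for kappa, z, s in zip(kappas, zs, signs):
        eta = s * (l1 - l2) - delta
        logp += kappa * eta - 0.5 * z * eta**2
    w = np.exp(logp - logp.max())
    w /= w.sum()
    m1 = (w * l1).sum()
    m2 = (w * l2).sum()
    c11 = (w * (l1 - m1) ** 2).sum()
    c22 = (w * (l2 - m2) ** 2).sum()
    c12 = (w * (l1 - m1) * (l2 - m2)).sum()
    return np.array([m1, m2]), np.array([[c11, c12], [c12, c22]])


class TestLambdaFullConditional:
    def test_matches_quadrature_oracle(self, rng):
        """Pins the completed square: linear coefficient is kappa + delta*z."""
        from btties.sampler import PGLatents

        for trial in range(5):
            y12 = int(rng.integers(1, 4))
            y21 = int(rng.integers(0, 3))
            t12 = int(rng.integers(0, 3))
            data = two_ward_table(y12=y12, y21=y21, t12=t12)
            X = build_design_matrix(data)
            delta = float(rng.uniform(0.0, 1.0))
            zvals = rng.uniform(0.05, 1.5, size=X.n_rows)
            prior = PriorSpec(
                base_covariance=np.array([[1.0, 0.3], [0.3, 1.0]]),
                mean=rng.normal(scale=0.3, size=2),
                alpha2=1.0,
            )
            z = PGLatents(values=zvals, exposures=X.exposures, tilts=np.zeros(X.n_rows))
            h, P = lambda_full_conditional(X, z, delta, prior, 1.0)
            mean = np.linalg.solve(P, h)
            cov = np.linalg.inv(P)

            kappas = X.exposures / 2.0
            signs = np.where(X.rows_i == 0, 1.0, -1.0)
            want_mean, want_cov = quadrature_moments(kappas, zvals, delta, prior, signs)
            assert mean == pytest.approx(want_mean, abs=1e-6)
            assert cov == pytest.approx(want_cov, abs=1e-6)

    def test_no_comparisons_reduces_to_prior(self, rng):
        """Empty design: the draw must come from N(mu, Sigma)."""
        from btties.likelihood import DesignMatrix
        from btties.sampler import PGLatents

        X = DesignMatrix(
            n_wards=3,
            rows_i=np.array([], dtype=np.int64),
            rows_j=np.array([], dtype=np.int64),
            exposures=np.array([], dtype=np.int64),
        )
        prior = PriorSpec(base_covariance=np.eye(3), mean=np.array([1.0, 2.0, 3.0]), alpha2=1.0)
        z = PGLatents(np.array([]), np.array([], dtype=np.int64), np.array([]))
        draws = np.array(
            [gibbs_update_lambda(X, z, 0.2, prior, 1.0, rng) for _ in range(20000)]
        )
        assert draws.mean(axis=0) == pytest.approx(prior.mean, abs=0.05)
        assert draws.var(axis=0) == pytest.approx(np.ones(3), rel=0.08)

    def test_posterior_precision_is_prior_plus_laplacian(self, rng):
        from btties.sampler import PGLatents

        data = random_table(4, 8, rng)
        X = build_design_matrix(data)
        zvals = rng.uniform(0.1, 1.0, size=X.n_rows)
        prior = PriorSpec(base_covariance=np.eye(4), alpha2=2.0)
        z = PGLatents(zvals, X.exposures, np.zeros(X.n_rows))
        _, P = lambda_full_conditional(X, z, 0.3, prior, 2.0)
        laplacian = P - np.eye(4) / 2.0
        assert laplacian.sum(axis=1) == pytest.approx(np.zeros(4), abs=1e-10)


class TestMHUpdateDelta:
    def test_no_data_recovers_exponential_prior(self, rng):
        data = ComparisonTable(
            ward_labels=["A", "B"], wins=np.zeros((2, 2), int), ties=np.zeros((2, 2), int)
        )
        chi = 1.5
        delta, draws = 0.5, []
        for _ in range(40000):
            delta, _ = mh_update_delta(data, np.zeros(2), delta, chi, 0.8, rng)
            draws.append(delta)
        assert kstest(np.array(draws[2000::10]), expon(scale=1 / chi).cdf).pvalue > 0.001

    def test_all_tied_data_pushes_delta_up(self, rng):
        ties = np.array([[0, 20], [20, 0]])
        data = ComparisonTable(
            ward_labels=["A", "B"], wins=np.zeros((2, 2), int), ties=ties
        )
        chi = 1.0
        delta, draws = 0.5, []
        for _ in range(20000):
            delta, _ = mh_update_delta(data, np.zeros(2), delta, chi, 0.5, rng)
            draws.append(delta)
        assert np.mean(draws[2000:]) > 1.0 / chi  # prior mean

    def test_negative_proposals_rejected(self, rng):
        data = two_ward_table(y12=1)
        draws = [
            mh_update_delta(data, np.zeros(2), 0.05, 0.01, 5.0, rng)[0]
            for _ in range(500)
        ]
        assert min(draws) >= 0.0


class TestTranslateLambda:
    def test_likelihood_unchanged(self, rng):
        data = random_table(5, 10, rng)
        prior = PriorSpec(base_covariance=np.eye(5), alpha2=1.0)
        lam = rng.normal(size=5)
        before = log_likelihood_ties(data, lam, 0.4)
        lam2 = translate_lambda(lam, prior, rng, alpha2=1.0)
        assert log_likelihood_ties(data, lam2, 0.4) == pytest.approx(before, rel=1e-12)

    def test_center_mode_zeroes_the_mean(self, rng):
        prior = PriorSpec(base_covariance=np.eye(4), alpha2=1.0)
        lam = translate_lambda(rng.normal(size=4) + 10, prior, rng, 1.0, mode="center")
        assert lam.mean() == pytest.approx(0.0, abs=1e-12)

    def test_long_run_level_matches_prior_law(self, rng):
        prior = PriorSpec(
            base_covariance=np.array([[1.0, 0.5], [0.5, 1.0]]),
            mean=np.array([2.0, 4.0]),
            alpha2=1.0,
        )
        m, v = total_quality_distribution(prior)
        levels = np.array(
            [translate_lambda(rng.normal(size=2), prior, rng, 1.0).mean() for _ in range(10000)]
        )
        assert levels.mean() == pytest.approx(m, abs=4 * math.sqrt(v / 10000))
        assert levels.var() == pytest.approx(v, rel=0.1)


class TestRunMCMC:
    def test_zero_kept_iterations_rejected(self):
        with pytest.raises(ValueError, match="burn_in"):
            SamplerConfig(n_iterations=100, burn_in=100)

    def test_seed_determinism(self, rng):
        data = random_table(4, 10, rng)
        prior = PriorSpec(base_covariance=np.eye(4), alpha2="inferred", chi=1.0)
        cfg = SamplerConfig(n_iterations=300, burn_in=50, seed=11)
        t1 = run_mcmc(data, prior, cfg)
        t2 = run_mcmc(data, prior, cfg)
        assert np.array_equal(t1.lambda_samples, t2.lambda_samples)
        assert np.array_equal(t1.delta_samples, t2.delta_samples)
        assert np.array_equal(t1.alpha2_samples, t2.alpha2_samples)

    def test_trace_shapes_and_invariants(self, rng):
        data = random_table(5, 12, rng)
        prior = PriorSpec(base_covariance=np.eye(5), alpha2="inferred", chi=1.0)
        cfg = SamplerConfig(n_iterations=400, burn_in=100, seed=2, debug=True)
        trace = run_mcmc(data, prior, cfg)
        assert trace.lambda_samples.shape == (300, 5)
        assert trace.n_kept == 300
        assert np.all(trace.delta_samples >= 0)
        assert np.all(trace.alpha2_samples > 0)
        assert 0.0 <= trace.accept_rate_delta <= 1.0

    def test_no_data_recovers_prior_marginals(self, rng):
        """Both samplers on an empty table must reproduce the prior."""
        data = ComparisonTable(
            ward_labels=["A", "B", "C"],
            wins=np.zeros((3, 3), int),
            ties=np.zeros((3, 3), int),
        )
        base = np.array([[1.0, 0.4, 0.1], [0.4, 1.0, 0.4], [0.1, 0.4, 1.0]])
        prior = PriorSpec(base_covariance=base, alpha2=1.0, chi=1.0)
        cfg = SamplerConfig(n_iterations=6000, burn_in=500, seed=3, delta_step=0.8)
        for runner in (run_mcmc, run_mh_baseline):
            trace = runner(data, prior, cfg)
            lam1 = trace.lambda_samples[:, 0]
            assert lam1.mean() == pytest.approx(0.0, abs=0.08)
            assert lam1.var() == pytest.approx(1.0, rel=0.12)
            assert trace.delta_samples.mean() == pytest.approx(1.0, rel=0.15)

    def test_mismatched_prior_dimension(self, rng):
        data = random_table(4, 6, rng)
        prior = PriorSpec(base_covariance=np.eye(3), alpha2=1.0)
        with pytest.raises(ValueError, match="wards"):
            run_mcmc(data, prior, SamplerConfig(n_iterations=10, burn_in=0))


class TestMHBaseline:
    def test_acceptance_rate_decreases_with_step(self, rng):
        data = random_table(5, 15, rng)
        prior = PriorSpec(base_covariance=np.eye(5), alpha2=1.0, chi=1.0)
        rates = []
        for step in (0.05, 0.5, 3.0):
            cfg = SamplerConfig(
                n_iterations=600, burn_in=100, seed=4, mh_baseline_step=step
            )
            rates.append(run_mh_baseline(data, prior, cfg).accept_rate_lambda)
        assert rates[0] > rates[1] > rates[2]


class TestESS:
    def test_white_noise_ess_near_n(self, rng):
        x = rng.standard_normal(20000)
        assert effective_sample_size(x) == pytest.approx(20000, rel=0.10)

    def test_ar1_ess_matches_closed_form(self, rng):
        rho, n = 0.9, 100_000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(n) * math.sqrt(1 - rho**2)
        for k in range(1, n):
            x[k] = rho * x[k - 1] + eps[k]
        want = n * (1 - rho) / (1 + rho)
        assert effective_sample_size(x) == pytest.approx(want, rel=0.15)

    def test_constant_chain_flagged_not_infinite(self):
        assert math.isnan(effective_sample_size(np.ones(1000)))

    def test_ess_per_second_shapes(self, rng):
        data = random_table(4, 8, rng)
        prior = PriorSpec(base_covariance=np.eye(4), alpha2=1.0, chi=1.0)
        trace = run_mcmc(data, prior, SamplerConfig(n_iterations=400, burn_in=100, seed=9))
        ess_d, ess_l = ess_per_second(trace)
        assert ess_d > 0 and ess_l > 0


def test_tune_delta_step_reaches_target_band(rng):
    data = random_table(5, 20, rng)
    prior = PriorSpec(base_covariance=np.eye(5), alpha2=1.0, chi=1.0)
    cfg = SamplerConfig(n_iterations=400, burn_in=0, seed=6, delta_step=5.0)
    step = tune_delta_step(data, prior, cfg, pilot_iterations=400)
    rate = run_mcmc(
        data, prior, SamplerConfig(n_iterations=800, burn_in=0, seed=7, delta_step=step)
    ).accept_rate_delta
    assert 0.1 < rate < 0.6
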