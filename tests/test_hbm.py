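"""Tests for the hierarchical model: joint density, sampler, diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest

from csfpolar.bip import BIPSummary
from csfpolar.csf_core import DEFAULT_PSYCHOMETRIC, PsychometricConfig, p_correct, CSFParams
from csfpolar.design import LOCATIONS, PRIOR_BOXES
from csfpolar.hbm import (
    HBMConfig,
    HBMState,
    bpic,
    gelman_rubin,
    log_joint,
    parameter_count,
    run_mcmc,
)
from csfpolar.synthetic_data import default_study_spec, make_cohort


def _toy_summary(dim_like=None):
    """Synthetic BIP summary with simple diagonal covariance seeds."""
    means = np.array([[1.7, 0.2, 0.45], [1.6, 0.15, 0.45], [1.5, 0.1, 0.45]])
    sds = np.full((3, 3), 0.1)
    return BIPSummary(
        location_means=means, location_sds=sds,
        sigma_bip=np.diag([0.04, 0.02, 0.01] * 3),
        phi_bip=np.stack([np.diag([0.01, 0.01, 0.02])] * 3),
        n_observers=8,
    )


def _trials(rows):
    return pd.DataFrame(rows, columns=[
        "observer_id", "location", "test_id", "trial_index",
        "sf_cpd", "contrast", "response",
    ])


def _simple_state(n_obs=1, mu_shift=0.0):
    theta = np.tile(np.array([[1.7, 0.2, 0.45],
                              [1.6, 0.15, 0.4],
                              [1.5, 0.1, 0.5]]), (n_obs, 1, 1))
    rho = theta.reshape(n_obs, 9) + 0.02
    mu = rho.mean(axis=0) + mu_shift
    sigma = np.diag([0.05, 0.03, 0.02] * 3)
    phi = np.stack([np.diag([0.02, 0.02, 0.03])] * 3)
    return HBMState(theta=theta, rho=rho, mu=mu, sigma=sigma, phi=phi)


class TestLogJoint:
    def test_matches_hand_expanded_density(self):
        """One observer, two trials: every term written out explicitly."""
        cfg = HBMConfig(variant="varying_bandwidth")
        init = _toy_summary()
        state = _simple_state()
        trials = _trials([
            (1, "horizontal", 1, 1, 2.0, 0.05, 1),
            (1, "lower_vertical", 1, 1, 4.0, 0.2, 0),
        ])
        got = log_joint(state, trials, cfg, init)

        def normal_logpdf(x, m, cov):
            d = np.asarray(x) - np.asarray(m)
            inv = np.linalg.inv(cov)
            _, logdet = np.linalg.slogdet(cov)
            return float(-0.5 * (d @ inv @ d)
                         - 0.5 * (len(d) * math.log(2 * math.pi) + logdet))

        p1 = p_correct(2.0, 0.05, CSFParams.from_log10(*state.theta[0, 0]))
        p2 = p_correct(4.0, 0.2, CSFParams.from_log10(*state.theta[0, 1]))
        expected = math.log(p1) + math.log(1 - p2)
        for j in range(3):
            expected += normal_logpdf(state.theta[0, j],
                                      state.rho[0, 3 * j:3 * j + 3], state.phi[j])
        expected += normal_logpdf(state.rho[0], state.mu, state.sigma)
        expected += -sum(math.log(hi - lo) for lo, hi in PRIOR_BOXES) * 3
        v = cfg.wishart_df
        for prec, seed in [(np.linalg.inv(state.sigma), init.sigma_bip)] + [
            (np.linalg.inv(state.phi[j]), init.phi_bip[j]) for j in range(3)
        ]:
            p_dim = prec.shape[0]
            _, logdet = np.linalg.slogdet(prec)
            expected += 0.5 * (v - p_dim - 1) * logdet
            expected += -0.5 * np.trace(v * seed @ prec)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_certain_trial_leaves_density_unchanged(self):
        """A trial with response probability exactly 1 contributes log 1 = 0."""
        cfg = HBMConfig(variant="varying_bandwidth")
        init = _toy_summary()
        state = _simple_state()
        state.theta[0, 0, 0] = np.log10(1e8)  # enormous sensitivity
        psych = PsychometricConfig(lapse=0.0)
        base = _trials([(1, "lower_vertical", 1, 1, 4.0, 0.2, 0)])
        extra = _trials([(1, "lower_vertical", 1, 1, 4.0, 0.2, 0),
                         (1, "horizontal", 1, 1, 2.0, 1.0, 1)])
        a = log_joint(state, base, cfg, init, psych=psych)
        b = log_joint(state, extra, cfg, init, psych=psych)
        assert a == pytest.approx(b, abs=1e-12)

    def test_mu_outside_uniform_support_is_minus_inf(self):
        cfg = HBMConfig(variant="varying_bandwidth")
        state = _simple_state()
        state.mu[0] = math.log10(500)  # beyond the peak-CS ceiling of 200
        got = log_joint(state, _trials([]), cfg, _toy_summary(),
                        observers=np.array([1]))
        assert got == -math.inf


class TestConditionalConjugacy:
    """Gibbs conditionals agree with brute-force slices of the joint."""

    def test_mu_conditional_matches_grid_density(self):
        cfg = HBMConfig(variant="varying_bandwidth")
        init = _toy_summary()
        state = _simple_state(n_obs=4)
        state.rho += 0.05 * np.sin(np.arange(36)).reshape(4, 9)
        trials = _trials([])
        obs = np.arange(1, 5)

        xs = np.linspace(1.55, 1.85, 60)
        logp = []
        for x in xs:
            s = HBMState(state.theta, state.rho, state.mu.copy(),
                         state.sigma, state.phi)
            s.mu[0] = x
            logp.append(log_joint(s, trials, cfg, init, observers=obs))
        logp = np.array(logp)
        dens = np.exp(logp - logp.max())
        dens /= np.trapezoid(dens, xs)

        # closed-form slice of the conjugate N(rho_bar, Sigma/I) conditional
        sigma_inv = np.linalg.inv(state.sigma)
        rho_bar = state.rho.mean(axis=0)
        prec00 = 4 * sigma_inv[0, 0]
        mean0 = rho_bar[0] - (sigma_inv[0, 1:] @ (state.mu[1:] - rho_bar[1:])
                              ) / sigma_inv[0, 0]
        ref = np.exp(-0.5 * prec00 * (xs - mean0) ** 2)
        ref /= np.trapezoid(ref, xs)
        assert np.allclose(dens, ref, atol=1e-6)

    def test_scalar_precision_conditional_is_the_gamma_update(self):
        """Fixed-variant bandwidth variance: the joint sliced over the
        precision matches the Gamma conditional the sampler draws from."""
        cfg = HBMConfig(variant="fixed_bandwidth")
        init = _toy_summary()
        n_obs = 6
        rng = np.random.default_rng(0)
        theta = np.tile(np.array([[1.7, 0.2, 0.45],
                                  [1.6, 0.15, 0.45],
                                  [1.5, 0.1, 0.45]]), (n_obs, 1, 1))
        theta[:, :, 2] = (0.45 + 0.05 * rng.standard_normal(n_obs))[:, None]
        rho = np.concatenate([theta[:, :, :2].reshape(n_obs, 6),
                              theta[:, 0, 2:3] + 0.02], axis=1)
        mu = rho.mean(axis=0)
        mu[6] = min(mu[6], math.log10(3.9))  # keep bandwidth mean in its box
        sigma = np.diag([0.04, 0.02] * 3 + [0.01])
        phi = np.stack([np.diag([0.01, 0.01])] * 3)
        obs = np.arange(1, n_obs + 1)
        trials = _trials([])

        xs = np.linspace(5.0, 400.0, 80)  # precision grid
        logp = []
        for x in xs:
            s = HBMState(theta, rho, mu, sigma, phi.copy(), phi_bw=1.0 / x)
            logp.append(log_joint(s, trials, cfg, init, observers=obs))
        logp = np.array(logp)
        dens = np.exp(logp - logp.max())
        dens /= np.trapezoid(dens, xs)

        v = cfg.wishart_df
        d = theta[:, 0, 2] - rho[:, 6]
        phi_bw_prior = float(init.phi_bip[:, 2, 2].mean())
        shape = 0.5 * (v + n_obs)
        rate = 0.5 * (v * phi_bw_prior + float(d @ d))
        from scipy.stats import gamma as gamma_dist
        ref = gamma_dist.pdf(xs, a=shape, scale=1.0 / rate)
        ref /= np.trapezoid(ref, xs)
        assert np.allclose(dens, ref, atol=1e-4)


class TestGelmanRubin:
    def test_matches_textbook_formula_on_hand_example(self):
        chains = np.array([[1.0, 2.0, 3.0, 4.0, 5.0],
                           [2.0, 3.0, 4.0, 5.0, 7.0]])
        n = 5
        w = (np.var(chains[0], ddof=1) + np.var(chains[1], ddof=1)) / 2
        b_over_n = np.var(chains.mean(axis=1), ddof=1)
        expected = math.sqrt(((n - 1) / n * w + b_over_n) / w)
        # relax the 10-sample floor via stacking the example twice
        stacked = np.concatenate([chains, chains], axis=1)
        w2 = np.mean(np.var(stacked, axis=1, ddof=1))
        b2 = np.var(stacked.mean(axis=1), ddof=1)
        expected2 = math.sqrt((9 / 10 * w2 + b2) / w2)
        assert gelman_rubin(stacked) == pytest.approx(expected2, abs=1e-12)
        assert expected > 1.0  # sanity of the hand formula

    def test_stationary_shuffles_pass_disjoint_chains_fail(self, rng):
        long = rng.standard_normal(4000)
        shuffled = long.reshape(4, 1000)
        assert gelman_rubin(shuffled) < 1.05
        disjoint = np.stack([np.zeros(100) + rng.standard_normal(100) * 0.1,
                             np.full(100, 10.0) + rng.standard_normal(100) * 0.1])
        assert gelman_rubin(disjoint) > 2.0

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))


@pytest.fixture(scope="module")
def small_fit_fixed():
    trials, truth = make_cohort(default_study_spec(n_observers=6),
                                n_trials=80, policy="qcsf", seed=31)
    cfg = HBMConfig(variant="fixed_bandwidth", n_chains=3, n_samples=400,
                    burn_in=300, adaptation=1000, seed=5)
    return run_mcmc(trials, cfg), trials, truth


class TestSampler:
    def test_pooled_sample_count(self, small_fit_fixed):
        fit, _, _ = small_fit_fixed
        assert fit.n_pooled == 3 * 400
        assert HBMConfig().n_chains * HBMConfig().n_samples == 6000

    def test_parameter_counts_per_participant(self):
        assert parameter_count("fixed_bandwidth") == 7
        assert parameter_count("varying_bandwidth") == 9

    def test_fixed_variant_shares_bandwidth_across_locations(self, small_fit_fixed):
        fit, _, _ = small_fit_fixed
        theta = fit.pooled_theta()
        assert np.array_equal(theta[:, :, 0, 2], theta[:, :, 1, 2])
        assert np.array_equal(theta[:, :, 0, 2], theta[:, :, 2, 2])
        pe = fit.point_estimates["bandwidth_oct"].unstack("location")
        assert np.allclose(pe.iloc[:, 0], pe.iloc[:, 1], rtol=1e-6)

    def test_determinism_under_seed(self):
        trials, _ = make_cohort(default_study_spec(n_observers=3),
                                n_trials=20, policy="random", seed=8)
        cfg = HBMConfig(n_chains=2, n_samples=50, burn_in=20, adaptation=50,
                        seed=123)
        a = run_mcmc(trials, cfg)
        b = run_mcmc(trials, cfg)
        assert np.array_equal(a.theta_samples, b.theta_samples)
        assert np.array_equal(a.mu_samples, b.mu_samples)

    def test_point_estimates_track_truth(self, small_fit_fixed):
        fit, _, truth = small_fit_fixed
        m = fit.point_estimates.reset_index().merge(
            truth, on=["observer_id", "location"])
        r = np.corrcoef(np.log10(m["peak_cs_x"]), np.log10(m["peak_cs_y"]))[0, 1]
        assert r > 0.8

    def test_zero_trial_posterior_reproduces_mu_prior(self):
        """With no likelihood the population mean marginal is its
        uniform prior; sample means land near the box midpoints."""
        cfg = HBMConfig(variant="varying_bandwidth", n_chains=3, n_samples=1500,
                        burn_in=500, adaptation=500, seed=2)
        fit = run_mcmc(_trials([]), cfg, init=_toy_summary(),
                       observers=np.arange(1, 9))
        mu = fit.pooled_mu()
        mids = np.array([np.mean(b) for b in PRIOR_BOXES] * 3)[
            [0, 1, 2, 3, 4, 5, 6, 7, 8]]
        # prior SD of a U(a,b) component is width/sqrt(12)
        widths = np.array([b[1] - b[0] for b in PRIOR_BOXES] * 3)
        err = np.abs(mu.mean(axis=0) - mids.reshape(3, 3).ravel()[
            np.arange(9)])
        assert np.all(err < 0.25 * widths)


class TestBPIC:
    def test_refuses_unconverged_fit(self):
        trials, _ = make_cohort(default_study_spec(n_observers=3),
                                n_trials=15, policy="random", seed=9)
        cfg = HBMConfig(n_chains=2, n_samples=60, burn_in=10, adaptation=30,
                        seed=1)
        fit = run_mcmc(trials, cfg)
        if not fit.converged:
            with pytest.raises(RuntimeError):
                bpic(fit, trials)
        res = bpic(fit, trials, require_convergence=False)
        assert res.bpic == pytest.approx(res.mean_deviance + 2 * res.p_d)
        assert res.p_d > 0

    def test_bpic_decomposition(self, small_fit_fixed):
        fit, trials, _ = small_fit_fixed
        res = bpic(fit, trials, require_convergence=False)
        assert res.mean_deviance >= res.deviance_at_mean
        assert res.bpic > res.mean_deviance
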