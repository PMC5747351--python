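"""LNA likelihood and reversible-jump sampler validation.

The likelihood is checked against two independent oracles: a brute-force
joint-Gaussian density (all cross-covariances by direct ODE integration)
and a bootstrap particle filter on SSA data in the large-count regime.
The sampler is checked against its own prior (likelihood switched off), a
fine-grid direct posterior on a frozen one-switch problem, and
parameter-recovery simulations.
"""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from pulseswitch.simulate import ssa_simulate, synthesize_trace
from pulseswitch.ssm import (
    MoveSettings,
    lna_loglik,
    make_default_priors,
    rjmcmc_run,
    run_cohort,
    stationary_moments,
)
from pulseswitch.types import (
    KineticParams,
    LuminescenceTrace,
    PriorSpec,
    SwitchProfile,
)


def joint_gaussian_loglik(trace, profile, params):
    """Brute-force oracle: joint Gaussian over all observations.

    Means and marginal covariances from direct ODE integration of the LNA
    moment equations (solve_ivp, tight tolerances); cross-covariances via
    Cov(xi_k, xi_j) = expm(A dt) V_j.  Independent of the Kalman recursion.
    """
    dm, dp, al, kp = params.delta_m, params.delta_p, params.alpha, params.kappa
    A = np.array([[-dm, 0.0], [al, -dp]])
    m0, V0 = stationary_moments(profile.rates[0], params)

    def rhs(t, y):
        m = y[:2]
        beta = float(profile.rate_at(t))
        D = [beta + dm * m[0], al * m[0] + dp * m[1]]
        V = np.array([[y[2], y[3]], [y[3], y[4]]])
        dV = A @ V + V @ A.T + np.diag(D)
        return [beta - dm * m[0], al * m[0] - dp * m[1],
                dV[0, 0], dV[0, 1], dV[1, 1]]

    times = trace.times
    n = len(times)
    means = np.zeros((n, 2))
    Vs = np.zeros((n, 2, 2))
    y = [m0[0], m0[1], V0[0, 0], V0[0, 1], V0[1, 1]]
    prev = profile.window[0]
    for j, t in enumerate(times):
        if t > prev:
            sol = solve_ivp(rhs, (prev, t), y, rtol=1e-12, atol=1e-12,
                            max_step=0.05)
            y = sol.y[:, -1]
        means[j] = y[:2]
        Vs[j] = [[y[2], y[3]], [y[3], y[4]]]
        prev = t
    Sigma = np.zeros((n, n))
    for j in range(n):
        for k in range(j, n):
            Phi = expm(A * (times[k] - times[j]))
            Sigma[k, j] = Sigma[j, k] = (Phi @ Vs[j])[1, 1]
    Sigma = kp**2 * Sigma + params.sigma2 * np.eye(n)
    return stats.multivariate_normal.logpdf(trace.values, kp * means[:, 1], Sigma)


def random_instance(rng, n_obs=None):
    K = int(rng.integers(0, 3))
    sw = tuple(np.sort(rng.uniform(1.0, 9.0, size=K)))
    rates = tuple(np.exp(rng.normal(np.log(10.0), 0.8, size=K + 1)))
    profile = SwitchProfile(sw, rates, (0.0, 10.0))
    params = KineticParams(
        delta_m=float(np.exp(rng.normal(np.log(0.8), 0.3))),
        delta_p=float(np.exp(rng.normal(np.log(0.4), 0.3))),
        alpha=float(np.exp(rng.normal(np.log(3.0), 0.3))),
        kappa=1.0, sigma=float(rng.uniform(1.0, 5.0)))
    if n_obs is None:
        n_obs = int(rng.integers(1, 6))
    times = np.sort(rng.uniform(0.0, 10.0, size=n_obs))
    values = rng.normal(50.0, 30.0, size=n_obs)
    return LuminescenceTrace("c", times, values), profile, params


class TestLnaLoglik:
    def test_single_observation_is_stationary_gaussian(self):
        params = KineticParams(0.8, 0.4, 3.0, kappa=2.0, sigma=1.5)
        profile = SwitchProfile((), (10.0,), (0.0, 10.0))
        mean, cov = stationary_moments(10.0, params)
        tr = LuminescenceTrace("c", np.array([0.0]), np.array([55.0]))
        ll = lna_loglik(tr, profile, params)
        expected = stats.norm.logpdf(
            55.0, 2.0 * mean[1], math.sqrt(4.0 * cov[1, 1] + 1.5**2))
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_matches_joint_gaussian_oracle(self):
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(30):
            trace, profile, params = random_instance(rng)
            err = abs(lna_loglik(trace, profile, params)
                      - joint_gaussian_loglik(trace, profile, params))
            worst = max(worst, err)
        assert worst < 1e-8

    def test_alpha_perturbation_changes_likelihood(self):
        # with kappa fixed the translation rate is identifiable
        rng = np.random.default_rng(5)
        trace, profile, params = random_instance(rng, n_obs=5)
        bumped = KineticParams(params.delta_m, params.delta_p,
                               params.alpha * 1.2, params.kappa, params.sigma)
        assert lna_loglik(trace, profile, params) != pytest.approx(
            lna_loglik(trace, profile, bumped), abs=1e-6)

    def test_rejects_times_outside_window(self):
        params = KineticParams(0.8, 0.4, 3.0, sigma=1.0)
        profile = SwitchProfile((), (10.0,), (0.0, 5.0))
        tr = LuminescenceTrace("c", np.array([1.0, 6.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="beyond"):
            lna_loglik(tr, profile, params)

    def test_large_count_regime_matches_particle_filter(self):
        """LNA log-lik per observation within 2% of a bootstrap PF estimate."""
        params = KineticParams(delta_m=5.0, delta_p=0.5, alpha=0.5,
                               kappa=1.0, sigma=3.0)
        beta = 500.0
        profile = SwitchProfile((), (beta,), (0.0, 2.5))
        grid = np.arange(0.25, 2.51, 0.25)
        path = ssa_simulate(profile, params, seed=10)
        trace = synthesize_trace(path, params, grid, seed=11)
        ll_lna = lna_loglik(trace, profile, params)

        rng = np.random.default_rng(12)
        n_part = 400
        M = rng.poisson(beta / params.delta_m, size=n_part)
        P = np.full(n_part, int(round(beta * params.alpha
                                      / (params.delta_m * params.delta_p))))
        # pre-equilibrate protein marginal
        M, P = _ssa_propagate_many(M, P, 6.0, beta, params, rng)
        ll_pf = 0.0
        t_prev = 0.0
        for t, y in zip(grid, trace.values):
            M, P = _ssa_propagate_many(M, P, t - t_prev, beta, params, rng)
            logw = stats.norm.logpdf(y, params.kappa * P, params.sigma)
            mx = logw.max()
            w = np.exp(logw - mx)
            ll_pf += mx + math.log(w.mean())
            idx = rng.choice(n_part, size=n_part, p=w / w.sum())
            M, P = M[idx], P[idx]
            t_prev = t
        assert ll_lna / len(grid) == pytest.approx(ll_pf / len(grid), rel=0.02)


def _ssa_propagate_many(M, P, dt, beta, params, rng):
    """Vectorised-ish exact SSA propagation of many independent particles."""
    dm, dp, al = params.delta_m, params.delta_p, params.alpha
    M = M.copy()
    P = P.copy()
    for i in range(len(M)):
        t = 0.0
        m, p = int(M[i]), int(P[i])
        while True:
            a = (beta, dm * m, al * m, dp * p)
            a_tot = a[0] + a[1] + a[2] + a[3]
            t += rng.exponential(1.0 / a_tot)
            if t >= dt:
                break
            u = rng.random() * a_tot
            if u < a[0]:
                m += 1
            elif u < a[0] + a[1]:
                m -= 1
            elif u < a[0] + a[1] + a[2]:
                p += 1
            else:
                p -= 1
        M[i], P[i] = m, p
    return M, P


class TestSampler:
    def test_prior_only_recovers_k_prior(self):
        priors = PriorSpec()
        dummy = LuminescenceTrace("d", np.arange(0, 48.1, 0.25), np.zeros(193))
        ens = rjmcmc_run(dummy, priors, n_iter=200_000, seed=3, prior_only=True)
        # thin beyond K's integrated autocorrelation time (~10^2 iterations)
        k = ens.k_values[::150]
        obs = np.bincount(k, minlength=priors.k_max + 1)
        exp = np.exp(priors.k_log_pmf()) * len(k)
        mask = exp > 5
        chi2 = float(((obs[mask] - exp[mask]) ** 2 / exp[mask]).sum())
        p = stats.chi2.sf(chi2, int(mask.sum()) - 1)
        assert p > 0.01

    def test_constant_trace_posterior_prefers_k0(self, grid_48h, deterministic_mean_trace):
        # noise-free limit: large molecule numbers and tiny measurement
        # noise, so any proposed rate split is sharply resolved and the
        # Occam factor suppresses null switches
        profile = SwitchProfile((), (2000.0,), (0.0, 48.0))
        params = KineticParams(0.6, 0.35, 5.0, sigma=1.0)
        trace = deterministic_mean_trace(profile, params, grid_48h, sigma=1.0,
                                         seed=8)
        priors = make_default_priors([trace])
        ens = rjmcmc_run(trace, priors, n_iter=4000, seed=9)
        k = ens.k_values
        assert np.bincount(k).argmax() == 0
        assert (k == 0).mean() > 0.9

    def test_single_down_switch_recovery(self, grid_48h, deterministic_mean_trace):
        # 5-fold rate drop mid-window: P(K>=1) > 0.95, time within +/- 1 h
        profile = SwitchProfile((24.0,), (50.0, 10.0), (0.0, 48.0))
        params = KineticParams(0.6, 0.35, 5.0, sigma=10.0)
        trace = deterministic_mean_trace(profile, params, grid_48h, sigma=10.0,
                                         seed=13)
        priors = make_default_priors([trace])
        ens = rjmcmc_run(trace, priors, n_iter=4000, seed=14)
        k = ens.k_values
        assert (k >= 1).mean() > 0.95
        down_times = [s.profile.switch_times[int(np.argmin(
            np.abs(np.array(s.profile.switch_times) - 24.0)))]
            for s in ens.samples if s.profile.n_switches]
        assert abs(np.median(down_times) - 24.0) < 1.0

    def test_frozen_two_point_posterior_matches_grid(self):
        """Detailed-balance spot check against a direct fine-grid posterior.

        K pinned at 1 and all rates/parameters pinned by near-degenerate
        priors, so the only free quantity is the switch time; the MCMC
        marginal must match the grid-evaluated posterior in total variation.
        """
        params = KineticParams(0.8, 0.4, 3.0, sigma=2.0)
        window = (0.0, 8.0)
        mu_b, sd_b = np.log(10.0), 0.15
        priors = PriorSpec(
            k_mean=1.0, k_max=1,
            rate_log_median=mu_b, rate_log_sd=sd_b,
            delta_m_log_median=np.log(0.8), delta_m_log_sd=1e-9,
            delta_p_log_median=np.log(0.4), delta_p_log_sd=1e-9,
            alpha_log_median=np.log(3.0), alpha_log_sd=1e-9,
            sigma2_a=1e6, sigma2_b=(1e6 + 1) * 4.0,
        )
        # force K=1 by making K=0 (nearly) impossible in the K prior
        priors.k_log_pmf = lambda: np.array([-1e9, 0.0])
        trace = LuminescenceTrace("c", np.array([2.0, 6.0]),
                                  np.array([60.0, 110.0]))

        # direct posterior of the switch time with the two rates integrated
        # out by Gauss-Hermite quadrature against their log-normal prior
        gh_x, gh_w = np.polynomial.hermite_e.hermegauss(25)
        log_rates = mu_b + sd_b * gh_x
        gh_w = gh_w / gh_w.sum()

        def direct_posterior(s_grid):
            out = np.zeros(len(s_grid))
            for i, s in enumerate(s_grid):
                acc = 0.0
                for xa, wa in zip(log_rates, gh_w):
                    for xb, wb in zip(log_rates, gh_w):
                        prof = SwitchProfile(
                            (s,), (math.exp(xa), math.exp(xb) * (1 + 1e-12)),
                            window)
                        acc += wa * wb * math.exp(
                            lna_loglik(trace, prof, params))
                out[i] = acc
            return out / out.sum()

        ens = rjmcmc_run(trace, priors, n_iter=60_000, seed=21,
                         window=window, burn_in=5_000, min_trace_len=2,
                         moves=MoveSettings(p_birth=0.05, p_death=0.05,
                                            p_shift=0.60, p_rate=0.10,
                                            birth_split_sd=0.15))
        s_samples = np.array([s.profile.switch_times[0] for s in ens.samples
                              if s.profile.n_switches == 1])
        assert len(s_samples) > 0.99 * len(ens.samples)
        edges = np.linspace(0.0, 8.0, 41)
        centers = 0.5 * (edges[:-1] + edges[1:])
        direct = direct_posterior(centers)
        emp, _ = np.histogram(s_samples, bins=edges)
        emp = emp / emp.sum()
        tv = 0.5 * np.abs(emp - direct).sum()
        assert tv < 0.05

    def test_seed_reproducibility_and_distinct_chains(self, grid_48h, deterministic_mean_trace):
        profile = SwitchProfile((20.0,), (40.0, 8.0), (0.0, 48.0))
        params = KineticParams(0.6, 0.35, 5.0, sigma=8.0)
        trace = deterministic_mean_trace(profile, params, grid_48h, sigma=8.0,
                                         seed=2)
        priors = make_default_priors([trace])
        e1 = rjmcmc_run(trace, priors, n_iter=600, seed=5)
        e2 = rjmcmc_run(trace, priors, n_iter=600, seed=5)
        assert [s.log_lik for s in e1.samples] == [s.log_lik for s in e2.samples]
        e3 = rjmcmc_run(trace, priors, n_iter=600, seed=6)
        assert [s.log_lik for s in e1.samples] != [s.log_lik for s in e3.samples]

    def test_short_trace_rejected(self):
        priors = PriorSpec()
        tr = LuminescenceTrace("c", np.arange(5.0), np.ones(5))
        with pytest.raises(ValueError, match="at least 10"):
            rjmcmc_run(tr, priors, n_iter=100, seed=0)


class TestCohortRunner:
    def test_single_cell_matches_direct_run(self, grid_48h, deterministic_mean_trace):
        profile = SwitchProfile((20.0,), (40.0, 8.0), (0.0, 48.0))
        params = KineticParams(0.6, 0.35, 5.0, sigma=8.0)
        trace = deterministic_mean_trace(profile, params, grid_48h, sigma=8.0,
                                         seed=3)
        priors = make_default_priors([trace])
        out = run_cohort([trace], priors, n_iter=500, seed=17)
        assert len(out) == 1 and out[0] is not None
        assert len(out[0]) == 500 - 500 // 3

    def test_failed_cell_does_not_abort_cohort(self, grid_48h, deterministic_mean_trace):
        profile = SwitchProfile((), (20.0,), (0.0, 48.0))
        params = KineticParams(0.6, 0.35, 5.0, sigma=5.0)
        good = deterministic_mean_trace(profile, params, grid_48h, sigma=5.0,
                                        seed=4)
        bad = LuminescenceTrace("bad", np.arange(5.0), np.ones(5))
        priors = make_default_priors([good])
        with pytest.warns(RuntimeWarning, match="failed inference"):
            out = run_cohort([good, bad], priors, n_iter=400, seed=18,
                             hierarchical=False)
        assert out[0] is not None and out[1] is None
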