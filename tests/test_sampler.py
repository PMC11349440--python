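import math

import numpy as np
import pytest
from scipy import stats

from panelar.model import ModelSpec, build_design, log_likelihood, log_prior_order
from panelar.sampler import (
    SamplerError,
    SamplerSettings,
    Trace,
    _draw_gaussian_from_precision,
    gibbs_sweep,
    initial_state,
    log_conditional_order_posterior,
    log_proposal_tau,
    log_target_tau,
    order_proposal_logprobs,
    propose_order,
    run_chain,
    update_eta,
    update_mu,
    update_sigma_eta,
    update_sigma_tau,
    update_tau,
    update_tau_k,
    update_theta_k,
    update_xi,
)
from panelar.synthetic import SimulationConfig, simulate_panel


class _ZeroNoise:
    """rng stub whose standard normals are all zero: draws collapse to the mean."""

    def standard_normal(self, n):
        return np.zeros(n)


class _UnitGamma:
    """rng stub with gamma = 1: inverse-gamma draws return the scale exactly."""

    def gamma(self, shape):
        return 1.0


class TestOrderProposal:
    def test_small_lambda_is_uniform(self):
        logq = order_proposal_logprobs(2, lam=1e-12, p_max=4)
        np.testing.assert_allclose(np.exp(logq), 0.25, rtol=1e-9)

    def test_known_value(self):
        """lam = ln 2, p_max = 2, from p = 1: weights 1, 1/2 -> q(1->1) = 2/3."""
        q = np.exp(order_proposal_logprobs(1, math.log(2.0), 2))
        np.testing.assert_allclose(q, [2 / 3, 1 / 3], rtol=1e-12)

    def test_normalization_and_symmetry(self):
        for p in range(1, 6):
            q = np.exp(order_proposal_logprobs(p, 1.0, 5))
            assert q.sum() == pytest.approx(1.0)
            assert np.argmax(q) == p - 1  # self-move is the mode

    def test_empirical_frequencies(self):
        rng = np.random.default_rng(0)
        n = 20_000
        draws = np.array([propose_order(1, math.log(2.0), 2, rng)[0] for _ in range(n)])
        freq = (draws == 1).mean()
        se = math.sqrt((2 / 3) * (1 / 3) / n)
        assert abs(freq - 2 / 3) < 3 * se

    def test_returns_both_logq(self):
        rng = np.random.default_rng(1)
        p_new, lf, lb = propose_order(1, 1.0, 3, rng)
        assert math.exp(order_proposal_logprobs(1, 1.0, 3)[p_new - 1]) == pytest.approx(math.exp(lf))
        assert math.exp(order_proposal_logprobs(p_new, 1.0, 3)[0]) == pytest.approx(math.exp(lb))


class TestOrderMarginal:
    def test_matches_dense_gaussian(self, tiny_design, informative_spec, tiny_state):
        """Woodbury evaluation equals the brute-force joint Gaussian density."""
        spec, state = informative_spec, tiny_state
        for p in (1, 2):
            st_p = state.copy()
            st_p.p = p
            blocks = tiny_design.at(p)
            u, V = spec.u_vec(p), spec.V_mat(p)
            W = np.concatenate([blk.y - state.eta[blk.year_idx] for blk in blocks])
            mean = np.concatenate([blk.X @ u for blk in blocks])
            n_tot = len(W)
            cov = np.zeros((n_tot, n_tot))
            offs = np.cumsum([0] + [blk.n for blk in blocks])
            for k, bk in enumerate(blocks):
                for j, bj in enumerate(blocks):
                    C = bk.X @ V @ bj.X.T
                    if k == j:
                        C = C + state.xi * (bk.X @ bk.X.T) + np.eye(bk.n) / state.tau_k[k]
                    cov[offs[k]:offs[k + 1], offs[j]:offs[j + 1]] = C
            expected = (
                stats.multivariate_normal.logpdf(W, mean, cov)
                + log_prior_order(p, tiny_design.p_max)
            )
            got = log_conditional_order_posterior(p, st_p, tiny_design, spec)
            assert got == pytest.approx(expected, rel=1e-10, abs=1e-8)

    def test_plugin_limit(self, tiny_design, informative_spec, tiny_state):
        """v = 0 and xi = 0 pin every coefficient at u: marginal = plug-in."""
        spec = ModelSpec(p_max=2, a=3.0, b=2.0, a_sigma=3.0, b_sigma=2.0,
                         a_eta=3.0, b_eta=2.0, a_xi=3.0, b_xi=2.0,
                         u=0.3, v=0.0, lam=1.0)
        state = tiny_state.copy()
        state.xi = 0.0
        for p in (1, 2):
            blocks = tiny_design.at(p)
            theta = np.tile(spec.u_vec(p), (tiny_design.m, 1))
            expected = (
                log_likelihood(theta, state.eta, state.tau_k, blocks)
                + log_prior_order(p, 2)
            )
            st_p = state.copy()
            st_p.p = p
            got = log_conditional_order_posterior(p, st_p, tiny_design, spec)
            assert got == pytest.approx(expected, rel=1e-10)


class TestCoefficientUpdates:
    def test_update_mu_mean_matches_direct_inverse(self, tiny_design, informative_spec, tiny_state):
        """Woodbury mu-update mean equals the naive O(n^3) computation."""
        spec, state = informative_spec, tiny_state
        p = state.p
        u, V = spec.u_vec(p), spec.V_mat(p)
        A = np.linalg.inv(V)
        b = A @ u
        for k, blk in enumerate(tiny_design.at(p)):
            C = np.eye(blk.n) / state.tau_k[k] + state.xi * (blk.X @ blk.X.T)
            Cinv = np.linalg.inv(C)
            A = A + blk.X.T @ Cinv @ blk.X
            b = b + blk.X.T @ Cinv @ (blk.y - state.eta[blk.year_idx])
        expected_mean = np.linalg.solve(A, b)
        got = update_mu(state, tiny_design, spec, _ZeroNoise())
        np.testing.assert_allclose(got, expected_mean, rtol=1e-9)

    def test_update_theta_k_mean(self, tiny_design, informative_spec, tiny_state):
        state = tiny_state
        blk = tiny_design.at(state.p)[0]
        P = np.eye(state.p + 1) / state.xi + state.tau_k[0] * (blk.X.T @ blk.X)
        h = state.mu / state.xi + state.tau_k[0] * (
            blk.X.T @ (blk.y - state.eta[blk.year_idx])
        )
        expected = np.linalg.solve(P, h)
        got = update_theta_k(state, 0, tiny_design, informative_spec, _ZeroNoise())
        np.testing.assert_allclose(got, expected, rtol=1e-10)

    def test_theta_shrinks_to_mu_as_xi_vanishes(self, tiny_design, informative_spec, tiny_state):
        state = tiny_state.copy()
        state.xi = 1e-12
        got = update_theta_k(state, 0, tiny_design, informative_spec, _ZeroNoise())
        np.testing.assert_allclose(got, state.mu, atol=1e-5)

    def test_theta_prior_limit_as_tau_vanishes(self, tiny_design, informative_spec, tiny_state):
        state = tiny_state.copy()
        state.tau_k = np.array([1e-14, 1e-14])
        got = update_theta_k(state, 0, tiny_design, informative_spec, _ZeroNoise())
        np.testing.assert_allclose(got, state.mu, atol=1e-6)

    def test_draw_gaussian_from_precision_moments(self):
        rng = np.random.default_rng(7)
        P = np.array([[2.0, 0.6], [0.6, 1.5]])
        h = np.array([1.0, -0.5])
        draws = np.array([_draw_gaussian_from_precision(P, h, rng) for _ in range(20_000)])
        np.testing.assert_allclose(draws.mean(0), np.linalg.solve(P, h), atol=0.02)
        np.testing.assert_allclose(np.cov(draws.T), np.linalg.inv(P), atol=0.03)


class TestEtaUpdate:
    def test_mean_and_precision_single_location(self, tiny_design, informative_spec, tiny_state):
        """Each year appears once per location; conditional is per-year conjugate."""
        state = tiny_state
        blocks = tiny_design.at(state.p)
        prec = np.full(tiny_design.n_eta, 1.0 / state.sigma2_eta)
        rhs = np.zeros(tiny_design.n_eta)
        for k, blk in enumerate(blocks):
            resid = blk.y - blk.X @ state.theta[k]
            np.add.at(prec, blk.year_idx, state.tau_k[k])
            np.add.at(rhs, blk.year_idx, state.tau_k[k] * resid)
        got = update_eta(state, tiny_design, informative_spec, _ZeroNoise())
        np.testing.assert_allclose(got, rhs / prec, rtol=1e-12)

    def test_zero_residual_zero_mean(self, tiny_design, informative_spec, tiny_state):
        """theta reproduces y exactly -> eta conditional is centred at 0."""
        state = tiny_state.copy()
        for blk in tiny_design.at(state.p):
            blk.y[:] = 0.0
        state.theta = np.zeros_like(state.theta)
        got = update_eta(state, tiny_design, informative_spec, _ZeroNoise())
        np.testing.assert_allclose(got, 0.0, atol=1e-14)


class TestVarianceUpdates:
    def test_sigma_tau_scale(self, informative_spec, tiny_state):
        """tau_k all equal to tau -> scale collapses to b_sigma."""
        state = tiny_state.copy()
        state.tau_k = np.full(2, state.tau)
        got = update_sigma_tau(state, informative_spec, _UnitGamma())
        assert got == pytest.approx(informative_spec.b_sigma)

    def test_sigma_eta_scale(self, informative_spec, tiny_state):
        state = tiny_state.copy()
        state.eta = np.ones(3)
        got = update_sigma_eta(state, informative_spec, _UnitGamma())
        assert got == pytest.approx(informative_spec.b_eta + 1.5)

    def test_xi_scale(self, informative_spec, tiny_state):
        state = tiny_state.copy()
        state.theta = state.mu + np.vstack([
            np.array([1.0, 0.0, 0.0]), np.array([0.0, -1.0, 0.0])
        ])
        got = update_xi(state, informative_spec, _UnitGamma())
        assert got == pytest.approx(informative_spec.b_xi + 1.0)

    def test_sigma_eta_distribution(self, informative_spec, tiny_state):
        """Full draws follow IG(a_eta + n/2, b_eta + eta'eta/2) (KS check)."""
        state = tiny_state.copy()
        rng = np.random.default_rng(19)
        draws = np.array([
            update_sigma_eta(state, informative_spec, rng) for _ in range(4000)
        ])
        shape = informative_spec.a_eta + len(state.eta) / 2
        scale = informative_spec.b_eta + 0.5 * float(state.eta @ state.eta)
        p = stats.kstest(draws, stats.invgamma(shape, scale=scale).cdf).pvalue
        assert p > 0.01


class TestTauUpdates:
    def test_reduced_equals_general_tau(self, informative_spec, tiny_state):
        """Same rng stream: the reduced ratio reproduces the general path."""
        for seed in range(20):
            r1, r2 = np.random.default_rng(seed), np.random.default_rng(seed)
            t_red = update_tau(tiny_state, informative_spec, r1, reduced=True)
            t_gen = update_tau(tiny_state, informative_spec, r2, reduced=False)
            assert t_red == pytest.approx(t_gen, rel=1e-12)

    def test_reduced_equals_general_tau_k(self, tiny_design, informative_spec, tiny_state):
        for seed in range(20):
            r1, r2 = np.random.default_rng(seed), np.random.default_rng(seed)
            t_red = update_tau_k(tiny_state, 0, tiny_design, informative_spec, r1, reduced=True)
            t_gen = update_tau_k(tiny_state, 0, tiny_design, informative_spec, r2, reduced=False)
            assert t_red == pytest.approx(t_gen, rel=1e-12)

    def test_target_proposal_cancellation_identity(self, tiny_state):
        """log target - log proposal differs from the Gamma(a+1, b) kernel by a constant."""
        a, b = 3.0, 2.0
        tau_k, s2 = tiny_state.tau_k, tiny_state.sigma2_tau
        vals = []
        for tau in (0.3, 0.9, 1.7, 4.2):
            diff = (
                log_target_tau(tau, tau_k, s2, a, b)
                - log_proposal_tau(tau, tau_k, s2)
                - (a * math.log(tau) - b * tau)
            )
            vals.append(diff)
        np.testing.assert_allclose(vals, vals[0], rtol=1e-10)

    def test_acceptance_counters(self, tiny_design, informative_spec, tiny_state):
        rng = np.random.default_rng(2)
        counters = {}
        for _ in range(50):
            update_tau(tiny_state, informative_spec, rng, counters)
        assert counters["tau_proposed"] == 50
        assert 0 <= counters.get("tau_accepted", 0) <= 50


class TestRunChain:
    def test_determinism(self, tiny_design, informative_spec):
        settings = SamplerSettings(iterations=200, burn_in=50, thinning=2, seed=9)
        t1 = run_chain(tiny_design, informative_spec, settings)
        t2 = run_chain(tiny_design, informative_spec, settings)
        for name in ("p", "tau", "sigma2_tau", "sigma2_eta", "xi"):
            np.testing.assert_array_equal(getattr(t1, name), getattr(t2, name))
        np.testing.assert_array_equal(
            np.nan_to_num(t1.mu, nan=-999), np.nan_to_num(t2.mu, nan=-999)
        )

    def test_different_seeds_differ(self, tiny_design, informative_spec):
        s1 = SamplerSettings(iterations=200, burn_in=50, thinning=2, seed=9)
        s2 = SamplerSettings(iterations=200, burn_in=50, thinning=2, seed=10)
        t1 = run_chain(tiny_design, informative_spec, s1)
        t2 = run_chain(tiny_design, informative_spec, s2)
        assert not np.array_equal(t1.tau, t2.tau)

    def test_retained_count_and_pmf(self, tiny_design, informative_spec):
        settings = SamplerSettings(iterations=230, burn_in=30, thinning=4, seed=1)
        trace = run_chain(tiny_design, informative_spec, settings)
        assert len(trace) == 50
        pmf = trace.order_pmf()
        assert sum(pmf.values()) == pytest.approx(1.0)
        assert set(pmf) <= {1, 2}

    def test_order_recovery_smoke(self):
        """Strong AR(2) signal: the chain concentrates on p = 2."""
        cfg = SimulationConfig(m=10, n=31, p=2, mu=(0.0, 0.3, -0.5), seed=4)
        panel = simulate_panel(cfg)
        spec = ModelSpec(p_max=3)
        settings = SamplerSettings(iterations=1200, burn_in=300, thinning=2, seed=3)
        trace = run_chain(panel.growth_arrays(), spec, settings)
        pmf = trace.order_pmf()
        assert max(pmf, key=pmf.get) == 2
        assert pmf[2] > 0.8

    def test_two_seed_agreement(self):
        """Independent chains agree on posterior means (loose Gelman-Rubin style)."""
        cfg = SimulationConfig(m=8, n=25, p=1, mu=(0.1, 0.4), seed=12)
        panel = simulate_panel(cfg)
        spec = ModelSpec(p_max=2)
        means = []
        for seed in (21, 22):
            settings = SamplerSettings(iterations=1500, burn_in=500, thinning=2, seed=seed)
            trace = run_chain(panel.growth_arrays(), spec, settings)
            sel = trace.p == 1
            means.append(trace.mu[sel, :2].mean(axis=0))
        np.testing.assert_allclose(means[0], means[1], atol=0.08)

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            SamplerSettings(iterations=10, burn_in=10)
        with pytest.raises(ValueError):
            SamplerSettings(iterations=10, burn_in=0, thinning=0)

    def test_trace_save_round_trip(self, tiny_design, informative_spec, tmp_path):
        settings = SamplerSettings(iterations=60, burn_in=10, thinning=1, seed=2)
        trace = run_chain(tiny_design, informative_spec, settings)
        csv = tmp_path / "trace.csv"
        manifest = tmp_path / "manifest.json"
        trace.save(csv, manifest)
        import json
        import pandas as pd

        df = pd.read_csv(csv, na_values=["NA"])
        assert len(df) == len(trace)
        np.testing.assert_allclose(df["tau"].to_numpy(), trace.tau)
        meta = json.loads(manifest.read_text())
        assert meta["settings"]["seed"] == 2
        assert "versions" in meta

    def test_initial_state_validates(self, tiny_design, informative_spec):
        state = initial_state(tiny_design, informative_spec, p_init=1)
        state.validate(2)
        state.tau = -1.0
        with pytest.raises(SamplerError):
            state.validate(2)

    def test_gibbs_sweep_fixed_order_when_pmax_one(self):
        rng = np.random.default_rng(0)
        years = np.arange(2000, 2012)
        growth = {f"L{k}": (years, rng.normal(0, 0.4, 12)) for k in range(3)}
        design = build_design(growth, 1)
        spec = ModelSpec(p_max=1, a=3, b=2, a_sigma=3, b_sigma=2,
                         a_eta=3, b_eta=2, a_xi=3, b_xi=2, u=0.0, v=1.0)
        state = initial_state(design, spec)
        for _ in range(20):
            state = gibbs_sweep(state, design, spec, rng)
            assert state.p == 1
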