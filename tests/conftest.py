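"""Shared fixtures: tiny panels, informative priors, grid-oracle helpers."""

import math

import numpy as np
import pytest
from scipy import stats

from panelar.model import ModelSpec, build_design
from panelar.sampler import initial_state


@pytest.fixture
def tiny_design():
    """m=2 locations, 8 growth rates each, p_max=2 -> 6 usable observations."""
    rng = np.random.default_rng(5)
    years = np.arange(2000, 2008)
    growth = {f"L{k}": (years, rng.normal(0, 0.5, size=8)) for k in range(2)}
    return build_design(growth, 2)


@pytest.fixture
def informative_spec():
    """Proper priors with finite moments, for distributional checks."""
    return ModelSpec(p_max=2, a=3.0, b=2.0, a_sigma=3.0, b_sigma=2.0,
                     a_eta=3.0, b_eta=2.0, a_xi=3.0, b_xi=2.0,
                     u=0.3, v=0.8, lam=1.0)


@pytest.fixture
def tiny_state(tiny_design, informative_spec):
    """A fixed, generic interior point of the parameter space at p=2."""
    rng = np.random.default_rng(6)
    state = initial_state(tiny_design, informative_spec, p_init=2)
    state.mu = rng.normal(0, 0.3, 3)
    state.theta = state.mu + rng.normal(0, 0.2, (2, 3))
    state.eta = rng.normal(0, 0.3, tiny_design.n_eta)
    state.tau_k = np.array([1.7, 0.6])
    state.tau = 1.1
    state.sigma2_tau = 0.3
    state.sigma2_eta = 0.2
    state.xi = 0.4
    return state


def log_joint(state, design, spec):
    """Independent composition of the joint posterior from scipy densities.

    Used as the oracle for conditional-distribution checks; deliberately
    avoids every analytic shortcut the sampler uses.
    """
    p = state.p
    blocks = design.at(p)
    lp = 0.0
    lp += stats.invgamma.logpdf(1 / state.tau, spec.a, scale=spec.b) - 2 * math.log(state.tau)
    lp += stats.invgamma.logpdf(state.sigma2_tau, spec.a_sigma, scale=spec.b_sigma)
    lp += stats.invgamma.logpdf(state.sigma2_eta, spec.a_eta, scale=spec.b_eta)
    lp += stats.invgamma.logpdf(state.xi, spec.a_xi, scale=spec.b_xi)
    lp += stats.multivariate_normal.logpdf(state.mu, spec.u_vec(p), spec.V_mat(p))
    for k, blk in enumerate(blocks):
        lp += stats.norm.logpdf(state.theta[k], state.mu, math.sqrt(state.xi)).sum()
        lp += (
            stats.norm.logpdf(math.log(1 / state.tau_k[k]),
                              math.log(1 / state.tau), math.sqrt(state.sigma2_tau))
            - math.log(state.tau_k[k])
        )
        resid = blk.y - blk.X @ state.theta[k] - state.eta[blk.year_idx]
        lp += stats.norm.logpdf(resid, 0, 1 / math.sqrt(state.tau_k[k])).sum()
    lp += stats.norm.logpdf(state.eta, 0, math.sqrt(state.sigma2_eta)).sum()
    return lp


def grid_conditional_moments(value_grid, set_value, state, design, spec):
    """Mean/variance of a 1-D conditional by dense evaluation of the joint."""
    lps = np.empty(len(value_grid))
    for i, v in enumerate(value_grid):
        st = state.copy()
        set_value(st, v)
        lps[i] = log_joint(st, design, spec)
    w = np.exp(lps - lps.max())
    w /= np.trapezoid(w, value_grid)
    mean = np.trapezoid(w * value_grid, value_grid)
    var = np.trapezoid(w * (value_grid - mean) ** 2, value_grid)
    return mean, var, (value_grid, w)
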