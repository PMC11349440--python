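"""Reversible-jump Metropolis-within-Gibbs sampler for the panel AR model.

One sweep updates, in order: the AR order p (reversible jump with mu and all
theta_k integrated out analytically), the coefficient block (mu, theta_k) by
exact Gibbs draws, the yearly effects eta, the variance components
(sigma2_tau, sigma2_eta, xi) by conjugate inverse-gamma draws, and the
precision hierarchy (tau, tau_k) by independence Metropolis-Hastings steps
whose acceptance ratios reduce to gamma-density ratios.

The trans-order move follows the marginalized reversible-jump recipe: because
p(mu, theta | rest, Y) is available analytically, the acceptance ratio only
needs the conditional order posterior p(p | Phi-, Y), obtained by integrating
mu and theta out of the Gaussian likelihood in closed form.  On acceptance
the coefficient block is refreshed by an immediate Gibbs draw at the new
dimension.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .model import ModelSpec, PanelDesign, build_design, log_prior_order

logger = logging.getLogger(__name__)

LOG2PI = math.log(2.0 * math.pi)
_JITTER = 1e-10


class SamplerError(RuntimeError):
    pass


@dataclass
class SamplerSettings:
    """Run-length and proposal controls for one chain."""

    iterations: int = 50_000
    burn_in: int = 10_000
    thinning: int = 5
    seed: int = 0
    p_init: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("need 0 <= burn_in < iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class ChainState:
    """One MCMC state: current order and every model parameter."""

    p: int
    mu: np.ndarray          # (p+1,)
    theta: np.ndarray       # (m, p+1)
    eta: np.ndarray         # (n_eta,)
    tau: float
    tau_k: np.ndarray       # (m,)
    sigma2_tau: float
    sigma2_eta: float
    xi: float

    def validate(self, p_max: int) -> None:
        if not 1 <= self.p <= p_max:
            raise SamplerError(f"order {self.p} outside 1..{p_max}")
        positive = {"tau": self.tau, "sigma2_tau": self.sigma2_tau,
                    "sigma2_eta": self.sigma2_eta, "xi": self.xi}
        for name, val in positive.items():
            if not val > 0:
                raise SamplerError(f"{name} must be > 0, got {val}")
        if np.any(self.tau_k <= 0):
            raise SamplerError("all tau_k must be > 0")
        if self.mu.shape != (self.p + 1,) or self.theta.shape[1] != self.p + 1:
            raise SamplerError("mu/theta dimension does not match order")

    def copy(self) -> "ChainState":
        return ChainState(
            p=self.p, mu=self.mu.copy(), theta=self.theta.copy(),
            eta=self.eta.copy(), tau=self.tau, tau_k=self.tau_k.copy(),
            sigma2_tau=self.sigma2_tau, sigma2_eta=self.sigma2_eta, xi=self.xi,
        )


def initial_state(design: PanelDesign, spec: ModelSpec, p_init: int = 1) -> ChainState:
    m = design.m
    return ChainState(
        p=p_init,
        mu=np.zeros(p_init + 1),
        theta=np.zeros((m, p_init + 1)),
        eta=np.zeros(design.n_eta),
        tau=1.0,
        tau_k=np.ones(m),
        sigma2_tau=1.0,
        sigma2_eta=1.0,
        xi=1.0,
    )


# ---------------------------------------------------------------------------
# order proposal and marginalized order posterior


def order_proposal_logprobs(p: int, lam: float, p_max: int) -> np.ndarray:
    """log q(p -> p') over p' = 1..p_max, q proportional to exp(-lam |p'-p|)."""
    if lam <= 0:
        raise ValueError("lam must be > 0")
    pp = np.arange(1, p_max + 1)
    logw = -lam * np.abs(pp - p)
    return logw - _logsumexp(logw)


def propose_order(p: int, lam: float, p_max: int, rng) -> tuple[int, float, float]:
    """Draw p' ~ q(p -> .); return (p', log q(p->p'), log q(p'->p)).

    Self-moves are allowed (|p'-p| = 0 has weight 1).  Both proposal log
    probabilities are returned so the exact Hastings ratio can be formed:
    near the boundaries the normalizer of q depends on the current order and
    the q-ratio does not cancel.
    """
    logq = order_proposal_logprobs(p, lam, p_max)
    p_new = int(rng.choice(np.arange(1, p_max + 1), p=np.exp(logq)))
    logq_back = order_proposal_logprobs(p_new, lam, p_max)
    return p_new, float(logq[p_new - 1]), float(logq_back[p - 1])


def _logsumexp(x):
    x = np.asarray(x, dtype=float)
    c = x.max()
    return c + np.log(np.exp(x - c).sum())


def _chol(mat):
    """Cholesky with one jittered retry; second failure is a hard error."""
    try:
        return cho_factor(mat, lower=True)
    except LinAlgError:
        jittered = mat + _JITTER * np.eye(mat.shape[0])
        return cho_factor(jittered, lower=True)


def log_conditional_order_posterior(
    p: int, state: ChainState, design: PanelDesign, spec: ModelSpec
) -> float:
    """log p(p | Phi-, Y) up to a p-independent constant.

    mu ~ N(u, V) and theta_k ~ N(mu, xi I) are integrated out of the Gaussian
    likelihood: writing W_k = Y_k - Z_k eta, the stacked W is Gaussian with
    mean X_k u and covariance

        Cov(W_k, W_j) = X_k V X_j^T + delta_kj (xi X_k X_k^T + I / tau_k).

    The block-diagonal part is handled per location with the matrix inversion
    lemma (G_k = I/xi + tau_k X_k^T X_k), the shared-mu coupling X V X^T by a
    second Woodbury step of rank p+1, so cost is O(sum n_k (p+1)^2).  The
    order prior p(p) oc 1/(p+1)! is included.
    """
    blocks = design.at(p)
    xi, eta, tau_k = state.xi, state.eta, state.tau_k
    u = spec.u_vec(p)
    V = spec.V_mat(p)
    use_V = bool(np.any(V))
    d = p + 1
    logdet_sum = 0.0
    quad_sum = 0.0
    if use_V:
        cV = _chol(V)
        logdetV = 2.0 * np.log(np.diag(cV[0])).sum()
        M = cho_solve(cV, np.eye(d))  # accumulates V^-1 + sum_k X^T A^-1 X
        bvec = np.zeros(d)
    n_total = 0
    for k, blk in enumerate(blocks):
        tk = float(tau_k[k])
        W = blk.y - eta[blk.year_idx]
        r = W - blk.X @ u
        n_total += blk.n
        if xi > 0:
            G = np.eye(d) / xi + tk * blk.XtX
            cG = _chol(G)
            logdetG = 2.0 * np.log(np.diag(cG[0])).sum()
            Ainv_r = tk * r - tk**2 * (blk.X @ cho_solve(cG, blk.X.T @ r))
            logdet_sum += -blk.n * math.log(tk) + logdetG + d * math.log(xi)
            if use_V:
                Ginv = cho_solve(cG, np.eye(d))
                M += np.eye(d) / xi - Ginv / xi**2
        else:
            Ainv_r = tk * r
            logdet_sum += -blk.n * math.log(tk)
            if use_V:
                M += tk * blk.XtX
        quad_sum += float(r @ Ainv_r)
        if use_V:
            bvec += blk.X.T @ Ainv_r
    if use_V:
        cM = _chol(M)
        logdet_sum += 2.0 * np.log(np.diag(cM[0])).sum() + logdetV
        quad_sum -= float(bvec @ cho_solve(cM, bvec))
    loglik = -0.5 * (n_total * LOG2PI + logdet_sum + quad_sum)
    return loglik + log_prior_order(p, design.p_max)


def order_move(state: ChainState, design: PanelDesign, spec: ModelSpec, rng,
               counters: dict | None = None) -> ChainState:
    """One reversible-jump order update; refreshes (mu, theta) on acceptance."""
    p = state.p
    p_new, logq_fwd, logq_back = propose_order(p, spec.lam, design.p_max, rng)
    if counters is not None:
        counters["order_proposed"] = counters.get("order_proposed", 0) + 1
    if p_new == p:
        if counters is not None:
            counters["order_accepted"] = counters.get("order_accepted", 0) + 1
        return state
    log_r = (
        log_conditional_order_posterior(p_new, state, design, spec)
        - log_conditional_order_posterior(p, state, design, spec)
        + logq_back
        - logq_fwd
    )
    if np.log(rng.uniform()) < log_r:
        state.p = p_new
        state.mu = update_mu(state, design, spec, rng)
        state.theta = np.vstack(
            [update_theta_k(state, k, design, spec, rng) for k in range(design.m)]
        )
        if counters is not None:
            counters["order_accepted"] = counters.get("order_accepted", 0) + 1
    return state


# ---------------------------------------------------------------------------
# Gibbs conditionals for the coefficient block (mu and theta integrated/joint)


def update_mu(state: ChainState, design: PanelDesign, spec: ModelSpec, rng) -> np.ndarray:
    """Draw mu | Phi-, Y with every theta_k integrated out.

    Marginally W_k = Y_k - Z_k eta ~ N(X_k mu, I/tau_k + xi X_k X_k^T), so the
    posterior precision is V^-1 + sum_k X_k^T (I/tau_k + xi X_k X_k^T)^-1 X_k;
    via the inversion lemma the k-th summand equals I/xi - G_k^-1/xi^2 with
    G_k = I/xi + tau_k X_k^T X_k, matching the printed composite form.
    """
    p = state.p
    d = p + 1
    blocks = design.at(p)
    u = spec.u_vec(p)
    V = spec.V_mat(p)
    cV = _chol(V)
    A = cho_solve(cV, np.eye(d))
    b = cho_solve(cV, u)
    xi = state.xi
    for k, blk in enumerate(blocks):
        tk = float(state.tau_k[k])
        W = blk.y - state.eta[blk.year_idx]
        if xi > 0:
            G = np.eye(d) / xi + tk * blk.XtX
            cG = _chol(G)
            A += np.eye(d) / xi - cho_solve(cG, np.eye(d)) / xi**2
            b += (tk / xi) * cho_solve(cG, blk.X.T @ W)
        else:
            A += tk * blk.XtX
            b += tk * (blk.X.T @ W)
    return _draw_gaussian_from_precision(A, b, rng)


def update_theta_k(state: ChainState, k: int, design: PanelDesign, spec: ModelSpec, rng) -> np.ndarray:
    """Draw theta_k | mu, Phi-, Y ~ N(P^-1 h, P^-1), P = I/xi + tau_k X^T X."""
    blk = design.at(state.p)[k]
    d = state.p + 1
    tk = float(state.tau_k[k])
    W = blk.y - state.eta[blk.year_idx]
    P = np.eye(d) / state.xi + tk * blk.XtX
    h = state.mu / state.xi + tk * (blk.X.T @ W)
    return _draw_gaussian_from_precision(P, h, rng)


def _draw_gaussian_from_precision(P, h, rng):
    """Sample N(P^-1 h, P^-1) via Cholesky of the precision."""
    c = _chol(P)
    mean = cho_solve(c, h)
    L = np.tril(c[0])
    z = rng.standard_normal(len(h))
    return mean + np.linalg.solve(L.T, z)


# ---------------------------------------------------------------------------
# Gibbs conditionals for Phi- (conjugate)


def update_eta(state: ChainState, design: PanelDesign, spec: ModelSpec, rng) -> np.ndarray:
    """Draw eta | rest: Gaussian with diagonal precision.

    Each observation row maps to exactly one calendar year, so
    sum_k tau_k Z_k^T Z_k is diagonal and the draw factorizes per year.
    """
    blocks = design.at(state.p)
    prec = np.full(design.n_eta, 1.0 / state.sigma2_eta)
    rhs = np.zeros(design.n_eta)
    for k, blk in enumerate(blocks):
        tk = float(state.tau_k[k])
        resid = blk.y - blk.X @ state.theta[k]
        np.add.at(prec, blk.year_idx, tk)
        np.add.at(rhs, blk.year_idx, tk * resid)
    mean = rhs / prec
    return mean + rng.standard_normal(design.n_eta) / np.sqrt(prec)


def update_sigma_tau(state: ChainState, spec: ModelSpec, rng) -> float:
    """sigma2_tau | rest ~ IG(a_sigma + m/2, b_sigma + 1/2 sum dev^2)."""
    dev = np.log(1.0 / state.tau_k) - math.log(1.0 / state.tau)
    shape = spec.a_sigma + len(state.tau_k) / 2.0
    scale = spec.b_sigma + 0.5 * float(dev @ dev)
    return _draw_inverse_gamma(shape, scale, rng)


def update_sigma_eta(state: ChainState, spec: ModelSpec, rng) -> float:
    """sigma2_eta | rest ~ IG(a_eta + n_eta/2, b_eta + eta^T eta / 2)."""
    shape = spec.a_eta + len(state.eta) / 2.0
    scale = spec.b_eta + 0.5 * float(state.eta @ state.eta)
    return _draw_inverse_gamma(shape, scale, rng)


def update_xi(state: ChainState, spec: ModelSpec, rng) -> float:
    """xi | rest ~ IG(a_xi + m(p+1)/2, b_xi + 1/2 sum ||theta_k - mu||^2)."""
    dev = state.theta - state.mu
    shape = spec.a_xi + dev.size / 2.0
    scale = spec.b_xi + 0.5 * float((dev * dev).sum())
    return _draw_inverse_gamma(shape, scale, rng)


def _draw_inverse_gamma(shape, scale, rng) -> float:
    return float(scale / rng.gamma(shape))


# ---------------------------------------------------------------------------
# Metropolis-Hastings for the precision hierarchy


def log_target_tau(tau: float, tau_k: np.ndarray, sigma2_tau: float,
                   a: float, b: float) -> float:
    """Unnormalized log conditional of tau (general path, used as cross-check).

    1/tau ~ IG(a, b) contributes tau^(a-1) e^(-b tau); each location
    contributes the log-normal hierarchy density of log(1/tau_k) around
    log(1/tau).
    """
    m = len(tau_k)
    lbar = float(np.mean(np.log(1.0 / tau_k)))
    s2 = sigma2_tau / m
    x = math.log(1.0 / tau)
    return (a - 1.0) * math.log(tau) - b * tau - 0.5 * (x - lbar) ** 2 / s2


def log_proposal_tau(tau: float, tau_k: np.ndarray, sigma2_tau: float) -> float:
    """Log density (in tau) of the independence proposal log(1/tau) ~ N(lbar, s2/m)."""
    m = len(tau_k)
    lbar = float(np.mean(np.log(1.0 / tau_k)))
    s2 = sigma2_tau / m
    x = math.log(1.0 / tau)
    return -0.5 * (x - lbar) ** 2 / s2 - 0.5 * math.log(2.0 * math.pi * s2) - math.log(tau)


def update_tau(state: ChainState, spec: ModelSpec, rng,
               counters: dict | None = None, reduced: bool = True) -> float:
    """Independence-MH draw of tau.

    Proposal: log(1/tau') ~ N(mean_k log(1/tau_k), sigma2_tau/m).  The normal
    factor and Jacobian cancel between target and proposal, so the Hastings
    ratio reduces to the ratio of Gamma(a+1, rate=b) densities:
    log r = a (log tau' - log tau) - b (tau' - tau).  ``reduced=False`` uses
    the general target/proposal ratio (identical up to roundoff).
    """
    s2 = state.sigma2_tau / len(state.tau_k)
    lbar = float(np.mean(np.log(1.0 / state.tau_k)))
    tau_prop = math.exp(-rng.normal(lbar, math.sqrt(s2)))
    if reduced:
        log_r = spec.a * (math.log(tau_prop) - math.log(state.tau)) - spec.b * (tau_prop - state.tau)
    else:
        log_r = (
            log_target_tau(tau_prop, state.tau_k, state.sigma2_tau, spec.a, spec.b)
            - log_target_tau(state.tau, state.tau_k, state.sigma2_tau, spec.a, spec.b)
            + log_proposal_tau(state.tau, state.tau_k, state.sigma2_tau)
            - log_proposal_tau(tau_prop, state.tau_k, state.sigma2_tau)
        )
    if counters is not None:
        counters["tau_proposed"] = counters.get("tau_proposed", 0) + 1
    if np.log(rng.uniform()) < log_r:
        if counters is not None:
            counters["tau_accepted"] = counters.get("tau_accepted", 0) + 1
        return tau_prop
    return state.tau


def log_target_tau_k(tau_kv: float, ssr: float, n_k: int, tau: float,
                     sigma2_tau: float) -> float:
    """Unnormalized log conditional of one tau_k (general path)."""
    x = math.log(1.0 / tau_kv)
    return (
        0.5 * n_k * math.log(tau_kv)
        - 0.5 * ssr * tau_kv
        - 0.5 * (x - math.log(1.0 / tau)) ** 2 / sigma2_tau
        - math.log(tau_kv)
    )


def update_tau_k(state: ChainState, k: int, design: PanelDesign, spec: ModelSpec,
                 rng, counters: dict | None = None, reduced: bool = True) -> float:
    """Independence-MH draw of tau_k; proposal log(1/tau_k') ~ N(log(1/tau), sigma2_tau).

    The hierarchy factor cancels against the proposal; the Hastings ratio is
    the ratio of Gamma(n_k/2 + 1, rate = SSR_k/2) densities at the proposed
    and current precision.
    """
    blk = design.at(state.p)[k]
    resid = blk.y - blk.X @ state.theta[k] - state.eta[blk.year_idx]
    ssr = float(resid @ resid)
    cur = float(state.tau_k[k])
    prop = math.exp(-rng.normal(math.log(1.0 / state.tau), math.sqrt(state.sigma2_tau)))
    if reduced:
        log_r = 0.5 * blk.n * (math.log(prop) - math.log(cur)) - 0.5 * ssr * (prop - cur)
    else:
        lq = lambda t: (
            -0.5 * (math.log(1.0 / t) - math.log(1.0 / state.tau)) ** 2 / state.sigma2_tau
            - math.log(t)
        )
        log_r = (
            log_target_tau_k(prop, ssr, blk.n, state.tau, state.sigma2_tau)
            - log_target_tau_k(cur, ssr, blk.n, state.tau, state.sigma2_tau)
            + lq(cur) - lq(prop)
        )
    if counters is not None:
        counters["tau_k_proposed"] = counters.get("tau_k_proposed", 0) + 1
    if np.log(rng.uniform()) < log_r:
        if counters is not None:
            counters["tau_k_accepted"] = counters.get("tau_k_accepted", 0) + 1
        return prop
    return cur


# ---------------------------------------------------------------------------
# full sweep, trace, chain driver


def gibbs_sweep(state: ChainState, design: PanelDesign, spec: ModelSpec, rng,
                counters: dict | None = None, order_moves: bool = True) -> ChainState:
    """One complete sweep over all blocks, in the documented order."""
    if order_moves and design.p_max > 1:
        state = order_move(state, design, spec, rng, counters)
    state.mu = update_mu(state, design, spec, rng)
    state.theta = np.vstack(
        [update_theta_k(state, k, design, spec, rng) for k in range(design.m)]
    )
    state.eta = update_eta(state, design, spec, rng)
    state.sigma2_tau = update_sigma_tau(state, spec, rng)
    state.sigma2_eta = update_sigma_eta(state, spec, rng)
    state.xi = update_xi(state, spec, rng)
    state.tau = update_tau(state, spec, rng, counters)
    state.tau_k = np.asarray(
        [update_tau_k(state, k, design, spec, rng, counters) for k in range(design.m)]
    )
    return state


@dataclass
class Trace:
    """Retained MCMC draws (order-varying vectors padded with NaN)."""

    p: np.ndarray            # (R,)
    mu: np.ndarray           # (R, p_max+1)
    theta: np.ndarray        # (R, m, p_max+1)
    eta: np.ndarray          # (R, n_eta)
    tau: np.ndarray
    tau_k: np.ndarray        # (R, m)
    sigma2_tau: np.ndarray
    sigma2_eta: np.ndarray
    xi: np.ndarray
    counters: dict
    settings: SamplerSettings
    spec: ModelSpec
    locations: list = field(default_factory=list)
    year_levels: np.ndarray = field(default_factory=lambda: np.array([]))

    def __len__(self) -> int:
        return len(self.p)

    @property
    def acceptance_rates(self) -> dict:
        c = self.counters
        out = {}
        for name in ("order", "tau", "tau_k"):
            prop = c.get(f"{name}_proposed", 0)
            out[name] = c.get(f"{name}_accepted", 0) / prop if prop else float("nan")
        return out

    def order_pmf(self) -> dict:
        vals, counts = np.unique(self.p, return_counts=True)
        return {int(v): float(c) / len(self.p) for v, c in zip(vals, counts)}

    def to_frame(self) -> pd.DataFrame:
        R, p1 = self.mu.shape
        cols = {"iteration": np.arange(R), "p": self.p}
        for j in range(p1):
            cols[f"mu{j}"] = self.mu[:, j]
        for k in range(self.theta.shape[1]):
            for j in range(p1):
                cols[f"theta_{k}_{j}"] = self.theta[:, k, j]
        for t in range(self.eta.shape[1]):
            cols[f"eta_{t}"] = self.eta[:, t]
        cols["tau"] = self.tau
        for k in range(self.tau_k.shape[1]):
            cols[f"tau_{k}"] = self.tau_k[:, k]
        cols["sigma2_tau"] = self.sigma2_tau
        cols["sigma2_eta"] = self.sigma2_eta
        cols["xi"] = self.xi
        return pd.DataFrame(cols)

    def save(self, csv_path, manifest_path=None) -> None:
        self.to_frame().to_csv(csv_path, index=False, float_format="%.17g", na_rep="NA")
        if manifest_path is not None:
            spec_dict = asdict(self.spec)
            for key in ("u", "v"):
                if np.ndim(spec_dict[key]) > 0:
                    spec_dict[key] = np.asarray(spec_dict[key]).tolist()
            manifest = {
                "settings": asdict(self.settings),
                "spec": spec_dict,
                "counters": {k: int(v) for k, v in self.counters.items()},
                "locations": list(map(str, self.locations)),
                "year_levels": np.asarray(self.year_levels).tolist(),
                "versions": _versions(),
            }
            with open(manifest_path, "w") as fh:
                json.dump(manifest, fh, indent=2)


def _versions() -> dict:
    import scipy
    import panelar

    return {"numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__, "panelar": panelar.__version__}


def run_chain(panel_or_design, spec: ModelSpec, settings: SamplerSettings) -> Trace:
    """Run one reversible-jump chain and return the retained draws.

    ``panel_or_design`` may be a PanelData / growth-array mapping (a design is
    built at ``spec.p_max``) or a prebuilt :class:`~panelar.model.PanelDesign`.
    Reproducible given ``settings.seed``; aborts with a state dump if any
    parameter goes non-finite.
    """
    design = (
        panel_or_design
        if isinstance(panel_or_design, PanelDesign)
        else build_design(panel_or_design, spec.p_max)
    )
    if design.p_max != spec.p_max:
        raise SamplerError("design p_max does not match spec.p_max")
    rng = np.random.default_rng(settings.seed)
    state = initial_state(design, spec, settings.p_init)
    state.validate(spec.p_max)
    counters: dict = {}
    n_keep = (settings.iterations - settings.burn_in + settings.thinning - 1) // settings.thinning
    m, d = design.m, spec.p_max + 1
    store = {
        "p": np.zeros(n_keep, dtype=int),
        "mu": np.full((n_keep, d), np.nan),
        "theta": np.full((n_keep, m, d), np.nan),
        "eta": np.zeros((n_keep, design.n_eta)),
        "tau": np.zeros(n_keep),
        "tau_k": np.zeros((n_keep, m)),
        "sigma2_tau": np.zeros(n_keep),
        "sigma2_eta": np.zeros(n_keep),
        "xi": np.zeros(n_keep),
    }
    kept = 0
    report_every = max(1, settings.iterations // 10)
    for it in range(settings.iterations):
        state = gibbs_sweep(state, design, spec, rng, counters)
        _check_finite(state, it)
        if it >= settings.burn_in and (it - settings.burn_in) % settings.thinning == 0:
            d_cur = state.p + 1
            store["p"][kept] = state.p
            store["mu"][kept, :d_cur] = state.mu
            store["theta"][kept, :, :d_cur] = state.theta
            store["eta"][kept] = state.eta
            store["tau"][kept] = state.tau
            store["tau_k"][kept] = state.tau_k
            store["sigma2_tau"][kept] = state.sigma2_tau
            store["sigma2_eta"][kept] = state.sigma2_eta
            store["xi"][kept] = state.xi
            kept += 1
        if (it + 1) % report_every == 0:
            logger.info("iteration %d/%d (p=%d)", it + 1, settings.iterations, state.p)
    return Trace(
        **{k: v[:kept] for k, v in store.items()},
        counters=counters,
        settings=settings,
        spec=spec,
        locations=design.locations,
        year_levels=design.year_levels,
    )


def _check_finite(state: ChainState, it: int) -> None:
    arrays = {"mu": state.mu, "theta": state.theta, "eta": state.eta,
              "tau_k": state.tau_k}
    scalars = {"tau": state.tau, "sigma2_tau": state.sigma2_tau,
               "sigma2_eta": state.sigma2_eta, "xi": state.xi}
    bad = [n for n, a in arrays.items() if not np.all(np.isfinite(a))]
    bad += [n for n, s in scalars.items() if not math.isfinite(s)]
    if bad:
        raise SamplerError(
            f"non-finite parameter(s) {bad} at iteration {it}; state: "
            f"p={state.p}, tau={state.tau}, sigma2_tau={state.sigma2_tau}, "
            f"sigma2_eta={state.sigma2_eta}, xi={state.xi}"
        )
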