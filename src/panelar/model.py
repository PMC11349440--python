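"""Hierarchical panel autoregression with unknown order: model definition.

Growth rates of m location series form a panel AR(p) with mixed effects:

    Y_kt = theta_0k + sum_{j=1..p} theta_jk Y_{k,t-j} + eta_t + e_kt,

where e_kt ~ N(0, 1/tau_k) with a log-normal hierarchy
log(1/tau_k) = log(1/tau) + N(0, sigma2_tau), eta_t ~ N(0, sigma2_eta) is a
yearly effect shared by all locations (spatial synchrony), and the
location-level coefficient vectors are exchangeable around a common mean:
theta_k = mu + eps_k, eps_k ~ N(0, xi I).

Priors: 1/tau ~ IG(a, b); sigma2_tau ~ IG(a_sigma, b_sigma); sigma2_eta ~
IG(a_eta, b_eta); xi ~ IG(a_xi, b_xi); mu ~ N(u, V); and the AR order itself
gets p(p) proportional to 1/(p+1)! on 1..p_max, penalizing high orders.

The likelihood conditions on the first ``p_max`` observations of every
series for every candidate order, so order comparisons inside the
reversible-jump sampler always use an identical response set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml


class ModelError(ValueError):
    pass


@dataclass
class ModelSpec:
    """AR order bounds, prior hyperparameters and the order-proposal decay.

    Scalar ``u``/``v`` expand to the mean vector ``u 1`` and covariance
    ``v I`` at whatever dimension ``p + 1`` the current order requires.
    Inverse-gamma parameters are (shape, scale).
    """

    p_max: int = 5
    a: float = 0.01          # 1/tau ~ IG(a, b)
    b: float = 0.01
    a_sigma: float = 0.01    # sigma2_tau ~ IG(a_sigma, b_sigma)
    b_sigma: float = 0.01
    a_eta: float = 0.01      # sigma2_eta ~ IG(a_eta, b_eta)
    b_eta: float = 0.01
    a_xi: float = 0.01       # xi ~ IG(a_xi, b_xi)
    b_xi: float = 0.01
    u: float | np.ndarray = 0.0
    v: float | np.ndarray = 100.0
    lam: float = 1.0         # order-proposal decay rate

    def __post_init__(self) -> None:
        for name in ("a", "b", "a_sigma", "b_sigma", "a_eta", "b_eta", "a_xi", "b_xi"):
            if getattr(self, name) <= 0:
                raise ModelError(f"inverse-gamma hyperparameter {name} must be > 0")
        if self.p_max < 1:
            raise ModelError("p_max must be >= 1")
        if self.lam <= 0:
            raise ModelError("lam must be > 0")
        if np.ndim(self.v) == 0 and np.asarray(self.v) < 0:
            raise ModelError("prior variance v must be >= 0")

    def u_vec(self, p: int) -> np.ndarray:
        u = np.asarray(self.u, dtype=float)
        if u.ndim == 0:
            return np.full(p + 1, float(u))
        if len(u) < p + 1:
            raise ModelError("prior mean u shorter than p + 1")
        return u[: p + 1].copy()

    def V_mat(self, p: int) -> np.ndarray:
        v = np.asarray(self.v, dtype=float)
        if v.ndim == 0:
            return float(v) * np.eye(p + 1)
        if v.ndim == 1:
            return np.diag(v[: p + 1])
        V = v[: p + 1, : p + 1]
        if not np.allclose(V, V.T):
            raise ModelError("prior covariance V must be symmetric")
        return V.copy()

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        for k in ("u", "v"):
            if np.ndim(d[k]) > 0:
                d[k] = np.asarray(d[k]).tolist()
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, text_or_path) -> "ModelSpec":
        try:
            with open(text_or_path) as fh:
                d = yaml.safe_load(fh)
        except (OSError, TypeError):
            d = yaml.safe_load(text_or_path)
        for k in ("u", "v"):
            if isinstance(d.get(k), list):
                d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


@dataclass
class LocationDesign:
    """Design blocks for one location at one candidate order.

    ``X`` is n_k x (p+1) with an intercept column then lag columns
    Y_{t-1}..Y_{t-p}; ``y`` the responses; ``year_idx`` maps each row to its
    calendar-year slot in the shared eta vector.
    """

    location: object
    X: np.ndarray
    y: np.ndarray
    year_idx: np.ndarray
    _xtx: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def XtX(self) -> np.ndarray:
        if self._xtx is None:
            self._xtx = self.X.T @ self.X
        return self._xtx


def _contiguous_runs(years: np.ndarray, values: np.ndarray):
    """Split a year-indexed series into runs of consecutive years."""
    if len(years) == 0:
        return
    breaks = np.flatnonzero(np.diff(years) != 1) + 1
    for chunk_y, chunk_v in zip(np.split(years, breaks), np.split(values, breaks)):
        yield chunk_y, chunk_v


@dataclass
class PanelDesign:
    """All per-order design matrices for a growth-rate panel.

    Built once; ``at(p)`` returns the blocks for order ``p``.  The response
    set (rows t = p_max+1 .. n within every contiguous run) is identical for
    every order, which makes the conditional order posterior comparable
    across orders.
    """

    p_max: int
    year_levels: np.ndarray
    blocks: dict = field(default_factory=dict)  # p -> list[LocationDesign]
    dropped: list = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.blocks[self.p_max])

    @property
    def n_eta(self) -> int:
        return len(self.year_levels)

    @property
    def locations(self) -> list:
        return [b.location for b in self.blocks[self.p_max]]

    def at(self, p: int) -> list:
        if not 1 <= p <= self.p_max:
            raise ModelError(f"order {p} outside 1..{self.p_max}")
        return self.blocks[p]

    @property
    def n_obs(self) -> int:
        return sum(b.n for b in self.blocks[self.p_max])


def build_design(panel, p_max: int) -> PanelDesign:
    """Construct lagged design matrices for orders 1..p_max.

    ``panel`` is a mapping location -> (years, growth_rates) or a
    ``PanelData``.  Within each contiguous run the responses start at the
    (p_max+1)-th year so that all candidate orders share them.  Locations
    contributing no usable rows are dropped with a warning.
    """
    if hasattr(panel, "growth_arrays"):
        panel = panel.growth_arrays()
    rows = {}  # location -> (resp_years, resp, lag matrix at p_max)
    dropped = []
    for loc, (years, y) in panel.items():
        years = np.asarray(years)
        y = np.asarray(y, dtype=float)
        r_years, r_y, r_lags = [], [], []
        for cy, cv in _contiguous_runs(years, y):
            L = len(cv)
            for t in range(p_max, L):
                r_years.append(cy[t])
                r_y.append(cv[t])
                r_lags.append(cv[t - p_max:t][::-1])  # (Y_{t-1}, ..., Y_{t-p_max})
        if not r_years:
            dropped.append(loc)
            continue
        rows[loc] = (np.asarray(r_years), np.asarray(r_y), np.asarray(r_lags))
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} location(s) with series too short for p_max={p_max}: {dropped}",
            stacklevel=2,
        )
    if not rows:
        raise ModelError("no location has enough data for the requested p_max")
    year_levels = np.unique(np.concatenate([v[0] for v in rows.values()]))
    year_pos = {y: i for i, y in enumerate(year_levels)}
    blocks = {}
    for p in range(1, p_max + 1):
        blocks[p] = [
            LocationDesign(
                location=loc,
                X=np.column_stack([np.ones(len(ry)), lags[:, :p]]),
                y=ry,
                year_idx=np.asarray([year_pos[yy] for yy in yrs], dtype=int),
            )
            for loc, (yrs, ry, lags) in rows.items()
        ]
    return PanelDesign(p_max=p_max, year_levels=year_levels, blocks=blocks, dropped=dropped)


def log_prior_order(p: int, p_max: int, normalized: bool = True) -> float:
    """log p(p) with p(p) proportional to 1/(p+1)! on 1..p_max."""
    if not 1 <= p <= p_max:
        raise ModelError(f"order {p} outside 1..{p_max}")
    logw = -math.lgamma(p + 2)
    if not normalized:
        return logw
    norm = math.log(sum(math.exp(-math.lgamma(q + 2)) for q in range(1, p_max + 1)))
    return logw - norm


def log_likelihood(theta, eta, tau_k, blocks) -> float:
    """Conditional Gaussian log likelihood of the panel given all parameters.

    ``theta`` is (m, p+1), ``eta`` (n_eta,), ``tau_k`` (m,) precisions;
    ``blocks`` the per-location designs at the current order.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    tau_k = np.atleast_1d(np.asarray(tau_k, dtype=float))
    eta = np.asarray(eta, dtype=float)
    if len(blocks) != theta.shape[0] or len(blocks) != len(tau_k):
        raise ModelError("theta / tau_k / design dimension mismatch")
    total = 0.0
    for k, blk in enumerate(blocks):
        if theta.shape[1] != blk.X.shape[1]:
            raise ModelError("theta dimension does not match design at this order")
        resid = blk.y - blk.X @ theta[k] - eta[blk.year_idx]
        total += 0.5 * blk.n * (np.log(tau_k[k]) - np.log(2.0 * np.pi))
        total -= 0.5 * tau_k[k] * float(resid @ resid)
    return float(total)
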