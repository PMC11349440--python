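"""Posterior summarization and convergence diagnostics.

Geweke's diagnostic compares the mean of an early chain segment (default the
first 10%) with a late segment (default the last 50%), standardized by
spectral-density-at-zero standard errors so autocorrelation inflates the
denominator appropriately.  Posterior summaries of order-varying parameters
condition on the modal AR order, so one coherent coefficient set is reported
per fitted panel.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


class DiagnosticsError(ValueError):
    pass


def spectral_density_zero(x: np.ndarray, bandwidth: int | None = None) -> float:
    """Spectral density at frequency zero via a Bartlett-windowed sum.

    Newey-West style: S(0) = gamma_0 + 2 sum_{l=1..L} w_l gamma_l with
    Bartlett weights w_l = 1 - l/(L+1) and automatic truncation
    L = floor(4 (n/100)^(2/9)).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if bandwidth is None:
        bandwidth = int(math.floor(4.0 * (n / 100.0) ** (2.0 / 9.0)))
    xc = x - x.mean()
    gamma0 = float(xc @ xc) / n
    s = gamma0
    for lag in range(1, min(bandwidth, n - 1) + 1):
        w = 1.0 - lag / (bandwidth + 1.0)
        s += 2.0 * w * float(xc[lag:] @ xc[:-lag]) / n
    return s


def geweke_z(chain, first_frac: float = 0.1, last_frac: float = 0.5) -> float:
    """Geweke convergence z-statistic for one scalar sample path.

    z = (mean_first - mean_last) / sqrt(se_first^2 + se_last^2) with
    se^2 = S(0)/n_segment.  Large |z| flags disagreement between the start
    and the end of the chain, i.e. non-convergence.
    """
    x = np.asarray(chain, dtype=float)
    n = len(x)
    if n < 100:
        raise DiagnosticsError("chain too short for the Geweke diagnostic (need >= 100)")
    if not (0 < first_frac and 0 < last_frac and first_frac + last_frac <= 1):
        raise DiagnosticsError("need 0 < first_frac + last_frac <= 1")
    n_a = int(math.floor(first_frac * n))
    n_b = int(math.floor(last_frac * n))
    a, b = x[:n_a], x[n - n_b:]
    var = spectral_density_zero(a) / n_a + spectral_density_zero(b) / n_b
    if var <= 0:
        raise DiagnosticsError("zero spectral variance; chain is degenerate")
    return float((a.mean() - b.mean()) / math.sqrt(var))


@dataclass
class PosteriorSummary:
    """Per-parameter mean/sd/Geweke z plus the posterior over AR order."""

    table: pd.DataFrame
    order_pmf: dict
    modal_order: int

    def __post_init__(self) -> None:
        total = sum(self.order_pmf.values())
        if abs(total - 1.0) > 1e-9:
            raise DiagnosticsError(f"order pmf sums to {total}, not 1")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.17g")

    def order_pmf_json(self, path=None) -> str:
        text = json.dumps({str(k): v for k, v in sorted(self.order_pmf.items())}, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def __str__(self) -> str:
        lines = ["Posterior summary (conditional on modal order "
                 f"p = {self.modal_order})", ""]
        lines.append(self.table.to_string(index=False, float_format=lambda v: f"{v: .4f}"))
        lines.append("")
        pmf = ", ".join(f"P(p={k}) = {v:.3f}" for k, v in sorted(self.order_pmf.items()))
        lines.append(f"AR order posterior: {pmf}")
        return "\n".join(lines)


def _row(name: str, draws: np.ndarray) -> dict:
    draws = np.asarray(draws, dtype=float)
    try:
        z = geweke_z(draws)
    except DiagnosticsError:
        z = float("nan")
    return {"parameter": name, "mean": float(draws.mean()),
            "sd": float(draws.std(ddof=1)) if len(draws) > 1 else 0.0,
            "geweke_z": z}


def summarize(trace, include_eta: bool = False, include_theta: bool = False) -> PosteriorSummary:
    """Posterior summary of a sampler trace.

    Order-invariant parameters are summarized over all retained draws;
    mu (and optionally theta) conditional on the modal order.  The order pmf
    comes from order occupancy across retained draws.
    """
    if len(trace) == 0:
        raise DiagnosticsError("empty trace")
    pmf = trace.order_pmf()
    modal = max(sorted(pmf), key=lambda k: pmf[k])
    sel = trace.p == modal
    rows = []
    for j in range(modal + 1):
        rows.append(_row(f"mu{j}", trace.mu[sel, j]))
    if include_theta:
        for k in range(trace.theta.shape[1]):
            for j in range(modal + 1):
                rows.append(_row(f"theta_{k}_{j}", trace.theta[sel, k, j]))
    rows.append(_row("tau", trace.tau))
    rows.append(_row("sigma2_tau", trace.sigma2_tau))
    rows.append(_row("sigma2_eta", trace.sigma2_eta))
    rows.append(_row("xi", trace.xi))
    if include_eta:
        for t in range(trace.eta.shape[1]):
            rows.append(_row(f"eta_{t}", trace.eta[:, t]))
    return PosteriorSummary(table=pd.DataFrame(rows), order_pmf=pmf, modal_order=int(modal))
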