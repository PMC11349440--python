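"""Model/Results interface for fitting the hierarchical panel AR model.

Typical use::

    model = PanelARModel.from_dataframe(growth_df, p_max=5)
    res = model.fit(iterations=20_000, burn_in=5_000, seed=1)
    print(res.summary())
    res.cycles()          # quasi-periods from the posterior-mean coefficients
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from . import cycles as _cycles
from .diagnostics import PosteriorSummary, summarize
from .model import ModelSpec, PanelDesign, build_design
from .sampler import SamplerSettings, Trace, run_chain


class PanelARModel:
    """Bayesian hierarchical panel autoregression with unknown AR order.

    Parameters
    ----------
    panel : PanelData, SyntheticPanel or mapping location -> (years, rates)
        Growth-rate series per location.
    spec : ModelSpec, optional
        Priors, order bounds and proposal decay; defaults are diffuse.
    """

    def __init__(self, panel, spec: ModelSpec | None = None):
        self.spec = spec if spec is not None else ModelSpec()
        self.panel = panel
        self.design: PanelDesign = build_design(panel, self.spec.p_max)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, spec: ModelSpec | None = None,
                       value_col: str = "growth_rate", p_max: int | None = None):
        """Build from a tidy frame with columns location, year, ``value_col``."""
        if p_max is not None:
            spec = ModelSpec(p_max=p_max) if spec is None else spec
            if spec.p_max != p_max:
                raise ValueError("p_max argument conflicts with spec.p_max")
        growth = {}
        for loc, sub in df.dropna(subset=[value_col]).groupby("location"):
            sub = sub.sort_values("year")
            growth[loc] = (sub["year"].to_numpy(), sub[value_col].to_numpy(float))
        return cls(growth, spec)

    @property
    def m(self) -> int:
        return self.design.m

    def fit(self, iterations: int = 50_000, burn_in: int = 10_000,
            thinning: int = 5, seed: int = 0, p_init: int = 1) -> "PanelARResults":
        settings = SamplerSettings(iterations=iterations, burn_in=burn_in,
                                   thinning=thinning, seed=seed, p_init=p_init)
        trace = run_chain(self.design, self.spec, settings)
        return PanelARResults(self, trace)


class PanelARResults:
    """Posterior draws plus derived summaries for one fitted panel."""

    def __init__(self, model: PanelARModel, trace: Trace):
        self.model = model
        self.trace = trace
        self._summary: PosteriorSummary | None = None

    # -- posterior over the AR order ------------------------------------
    @property
    def order_pmf(self) -> dict:
        return self.trace.order_pmf()

    @property
    def modal_order(self) -> int:
        pmf = self.order_pmf
        return int(max(sorted(pmf), key=lambda k: pmf[k]))

    # -- coefficient summaries (conditional on the modal order) ----------
    @property
    def mu_mean(self) -> np.ndarray:
        sel = self.trace.p == self.modal_order
        return self.trace.mu[sel, : self.modal_order + 1].mean(axis=0)

    def mu_credible_interval(self, level: float = 0.95) -> np.ndarray:
        """(p+1, 2) equal-tailed interval per mu component, modal order."""
        sel = self.trace.p == self.modal_order
        draws = self.trace.mu[sel, : self.modal_order + 1]
        alpha = 1.0 - level
        return np.column_stack(
            [np.quantile(draws, alpha / 2, axis=0),
             np.quantile(draws, 1 - alpha / 2, axis=0)]
        )

    def summarize(self, **kwargs) -> PosteriorSummary:
        return summarize(self.trace, **kwargs)

    def summary(self) -> str:
        if self._summary is None:
            self._summary = self.summarize()
        header = (
            f"Hierarchical panel AR model: m = {self.model.m} locations, "
            f"{self.model.design.n_obs} observations, p_max = {self.model.spec.p_max}\n"
            f"Retained draws: {len(self.trace)}; acceptance rates: "
            + ", ".join(f"{k} {v:.2f}" for k, v in self.trace.acceptance_rates.items())
            + "\n"
        )
        return header + str(self._summary)

    # -- cycle structure -------------------------------------------------
    def cycles(self) -> _cycles.CycleReport:
        """Quasi-periods from posterior-mean AR coefficients at the modal order."""
        return _cycles.cycle_lengths(self.mu_mean[1:])

    def posterior_periods(self) -> pd.DataFrame:
        """Cycle lengths propagated through every retained modal-order draw."""
        sel = self.trace.p == self.modal_order
        draws = self.trace.mu[sel, 1: self.modal_order + 1]
        return _cycles.posterior_periods(draws)

    # -- persistence ------------------------------------------------------
    def save(self, directory) -> None:
        os.makedirs(directory, exist_ok=True)
        self.trace.save(os.path.join(directory, "trace.csv"),
                        os.path.join(directory, "manifest.json"))
        s = self.summarize()
        s.to_csv(os.path.join(directory, "summary.csv"))
        s.order_pmf_json(os.path.join(directory, "order_pmf.json"))
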