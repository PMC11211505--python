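"""Model / Results objects tying the pipeline together.

Usage mirrors the common statistical-modelling idiom::

    model = CARSpatioTemporalPoisson(panel, graph, ModelSpec.model1())
    res = model.fit(iters=20000, burnin=10000, thin=5, chains=4, seed=7)
    res.summary()          # posterior table with RR column
    res.dic()              # ModelFitStats
    res.risk_report()      # per-area RR / exceedance / hot-cold / trend
"""

from __future__ import annotations

from functools import cached_property

import numpy as np
import pandas as pd

from .design import ModelSpec
from .panel import AdjacencyGraph, ArealPanel, read_graph, read_panel
from .risk import interaction_trend_summary, make_risk_report
from .sampler import PosteriorDraws, compute_dic, run_mcmc, summarize_draws
from .standardize import expected_counts

__all__ = ["CARSpatioTemporalPoisson", "CARSTResults"]


class CARSpatioTemporalPoisson:
    """Poisson areal model with BYM spatial effects and linear trends.

    O_it ~ Poisson(E_it rho_it),
    log rho_it = alpha + s_i + u_i + X_i beta + (gamma + delta_i) time_t,
    s, delta ~ ICAR(graph), u ~ iid Normal, Gamma hyperpriors on precisions.
    """

    def __init__(self, panel: ArealPanel, graph: AdjacencyGraph,
                 spec: ModelSpec | None = None, expected=None):
        if graph.n != panel.n_areas:
            raise ValueError(
                f"graph has {graph.n} nodes but panel has {panel.n_areas} areas"
            )
        self.panel = panel
        self.graph = graph
        self.spec = spec if spec is not None else ModelSpec.model1()
        if expected is None:
            self.E = panel.E if panel.E is not None else expected_counts(panel, "unit")
        elif isinstance(expected, str):
            self.E = expected_counts(panel, expected)
        else:
            E = np.asarray(expected, dtype=float)
            if E.ndim == 0:
                E = np.full((panel.n_areas, panel.n_times), float(E))
            if E.shape != (panel.n_areas, panel.n_times) or np.any(E <= 0):
                raise ValueError("expected counts must be a positive N x T matrix")
            self.E = E

    @classmethod
    def from_files(cls, counts_path, graph_path, covariates_path=None,
                   spec=None, expected=None):
        panel = read_panel(counts_path, covariates_path)
        graph = read_graph(graph_path)
        return cls(panel, graph, spec=spec, expected=expected)

    def fit(self, iters: int = 20000, burnin: int = 10000, thin: int = 5,
            chains: int = 4, seed: int | None = None, **kwargs) -> "CARSTResults":
        draws = run_mcmc(
            self.panel, self.graph, self.spec, E=self.E,
            iters=iters, burnin=burnin, thin=thin, chains=chains, seed=seed,
            **kwargs,
        )
        return CARSTResults(self, draws)


class CARSTResults:
    """Posterior draws plus derived summaries for a fitted model."""

    def __init__(self, model: CARSpatioTemporalPoisson, draws: PosteriorDraws):
        self.model = model
        self.draws = draws

    @cached_property
    def _summary(self) -> pd.DataFrame:
        return summarize_draws(self.draws)

    def summary(self) -> pd.DataFrame:
        return self._summary

    def param_mean(self, name: str) -> float:
        return float(self._summary.loc[name, "mean"])

    def credible_interval(self, name: str):
        row = self._summary.loc[name]
        return float(row["q2.5"]), float(row["q97.5"])

    def dic(self):
        return compute_dic(self.draws, self.model.panel, self.model.E, self.model.spec)

    def risk_report(self, threshold: float = 0.5) -> pd.DataFrame:
        return make_risk_report(self.draws, threshold=threshold)

    def trend_summary(self) -> pd.DataFrame:
        return interaction_trend_summary(self.draws)

    def plot_exceedance(self, threshold: float = 0.5, ax=None):
        """Bar chart of per-area exceedance probabilities."""
        import matplotlib.pyplot as plt

        report = self.risk_report(threshold)
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3.5))
        color = ["#b2182b" if l == "hot" else "#2166ac" for l in report["label"]]
        ax.bar(report["area_id"].astype(str), report["exceed_prob"], color=color)
        ax.axhline(threshold, ls="--", c="k", lw=0.8)
        ax.set_ylabel("P(spatial RR > 1 | data)")
        ax.tick_params(axis="x", rotation=90)
        return ax

    def __repr__(self):
        d = self.draws
        return (
            f"<CARSTResults model={self.model.spec.model_id} "
            f"areas={d.n_areas} draws={d.n_draws}>"
        )
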